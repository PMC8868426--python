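"""Minimal mzML I/O for SRM chromatograms.

Writes standards-conformant mzML holding one chromatogram per SRM channel
(time array in minutes, intensity array in counts, 64-bit floats, no
compression), with the precursor/product isolation window target m/z
recorded so channels can be matched by mass.  The reader handles the same
chromatogram subset of mzML 1.1 (32/64-bit floats, optional zlib
compression, time unit conversion to minutes) with the standard library's
XML parser.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np

from .peaks import ChromatogramTrace

__all__ = ["write_mzml_traces", "read_mzml_traces"]

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    extra = ""
    if unit == "minute":
        extra = (
            ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
        )
    elif unit == "counts":
        extra = (
            ' unitCvRef="MS" unitAccession="MS:1000131"'
            ' unitName="number of detector counts"'
        )
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{escape(name)}"'
        f' value="{escape(value)}"{extra}/>'
    )


def _chromatogram_xml(index: int, trace: ChromatogramTrace) -> str:
    n = len(trace)
    time_b64 = _encode(trace.times)
    int_b64 = _encode(trace.intensities)
    q1 = trace.precursor_mz
    q3 = trace.product_mz
    cid = f"SRM SIC Q1={q1} Q3={q3} {trace.transition}"
    parts = [
        f'<chromatogram index="{index}" id="{escape(cid, {chr(34): "&quot;"})}"'
        f' defaultArrayLength="{n}">',
        _cv("MS:1001473", "selected reaction monitoring chromatogram"),
    ]
    if q1 is not None:
        parts += [
            "<precursor><isolationWindow>",
            _cv("MS:1000827", "isolation window target m/z", str(q1)),
            "</isolationWindow></precursor>",
        ]
    if q3 is not None:
        parts += [
            "<product><isolationWindow>",
            _cv("MS:1000827", "isolation window target m/z", str(q3)),
            "</isolationWindow></product>",
        ]
    parts += [
        '<binaryDataArrayList count="2">',
        f'<binaryDataArray encodedLength="{len(time_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv("MS:1000595", "time array", unit="minute"),
        f"<binary>{time_b64}</binary>",
        "</binaryDataArray>",
        f'<binaryDataArray encodedLength="{len(int_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv("MS:1000515", "intensity array", unit="counts"),
        f"<binary>{int_b64}</binary>",
        "</binaryDataArray>",
        "</binaryDataArrayList>",
        "</chromatogram>",
    ]
    return "".join(parts)


def write_mzml_traces(
    traces: Sequence[ChromatogramTrace], path: str | Path, run_id: str = "run"
) -> None:
    """Write SRM traces as an mzML file with one chromatogram per channel."""
    traces = list(traces)
    chroms = "".join(_chromatogram_xml(i, tr) for i, tr in enumerate(traces))
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry'
        ' Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
        '<fileDescription><fileContent>'
        + _cv("MS:1001473", "selected reaction monitoring chromatogram")
        + "</fileContent></fileDescription>"
        '<softwareList count="1"><software id="mxpquant" version="0.1.0"/></softwareList>'
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>'
        '<dataProcessingList count="1"><dataProcessing id="dp1">'
        '<processingMethod order="1" softwareRef="mxpquant"/>'
        "</dataProcessing></dataProcessingList>"
        f'<run id="{escape(run_id, {chr(34): "&quot;"})}" '
        'defaultInstrumentConfigurationRef="IC1">'
        f'<chromatogramList count="{len(traces)}" defaultDataProcessingRef="dp1">'
        + chroms
        + "</chromatogramList></run></mzML>"
    )
    Path(path).write_text(doc)


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> dict[str, str]:
    return {
        child.get("accession", ""): child.get("value", "")
        for child in elem
        if _strip_ns(child.tag) == "cvParam"
    }


def _iter_named(elem: ET.Element, name: str):
    for child in elem.iter():
        if _strip_ns(child.tag) == name:
            yield child


def _decode_array(bda: ET.Element) -> tuple[np.ndarray, dict[str, str]]:
    params: dict[str, str] = {}
    unit = ""
    binary_text = ""
    for child in bda.iter():
        tag = _strip_ns(child.tag)
        if tag == "cvParam":
            params[child.get("accession", "")] = child.get("value", "")
            if child.get("accession") in ("MS:1000595", "MS:1000515"):
                unit = child.get("unitName", "")
        elif tag == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if "MS:1000595" in params and unit == "second":
        values = values / 60.0
    params["unit"] = unit
    return values, params


def _target_mz(chrom: ET.Element, which: str) -> float | None:
    for node in _iter_named(chrom, which):
        params = {}
        for win in _iter_named(node, "isolationWindow"):
            params.update(_cv_params(win))
        value = params.get("MS:1000827")  # isolation window target m/z
        if value:
            return float(value)
    return None


def read_mzml_traces(path: str | Path) -> list[ChromatogramTrace]:
    """Read all chromatograms with time/intensity arrays from an mzML file."""
    traces: list[ChromatogramTrace] = []
    sample_id = Path(path).stem
    root = ET.parse(str(path)).getroot()
    for chrom in _iter_named(root, "chromatogram"):
        times = intensities = None
        for bda in _iter_named(chrom, "binaryDataArray"):
            values, params = _decode_array(bda)
            if "MS:1000595" in params:  # time array
                times = values
            elif "MS:1000515" in params:  # intensity array
                intensities = values
        if times is None or intensities is None:
            continue
        cid = chrom.get("id", "")
        label = cid.split(" Q3=")[-1].split(" ", 1)[-1] if " Q3=" in cid else cid
        traces.append(
            ChromatogramTrace(
                transition=label,
                times=times,
                intensities=np.clip(intensities, 0.0, None),
                sample_id=sample_id,
                precursor_mz=_target_mz(chrom, "precursor"),
                product_mz=_target_mz(chrom, "product"),
            )
        )
    return traces
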