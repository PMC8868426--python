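"""Calibration, LOD/LOQ, recovery, matrix effect, CV and sample quantitation.

The assay's figures of merit follow the usual targeted-LC-MS/MS validation
arithmetic:

* Calibration: ordinary least squares of response (analyte area / internal
  standard area by default, or absolute area) against concentration over
  the levels at or above the LOQ; R² from the same fit.
* LOD / LOQ: the lowest prepared level whose median replicate S/N reaches
  3 and 10 respectively, snapped to the prepared dilution grid (no
  interpolation between levels).
* Recovery: 100 x area(spiked sample) / area(spiked extract).
* Matrix effect: 100 x area(spiked extract) / area(neat standard);
  below 100% is ion suppression, above 100% ion enhancement.
* CV: 100 x sd/mean over replicates; the inter-day CV is the CV of the
  daily means across assay days.
* Quantitation: response = analyte area / IS area, concentration =
  (response - intercept) / slope in pmol/µL of final extract, with an
  optional dilution-chain back-calculation to the source material.

The calibration API follows the model/results convention: build a
:class:`Calibration` from measured responses (or straight from a simulated
series), call :meth:`~Calibration.fit`, and read estimates, diagnostics
and ``summary()`` off the returned :class:`CalibrationResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem import AcylState, parse_species
from .peaks import ChromatogramTrace, PeakResult, find_peak
from .transitions import TransitionRegistry

__all__ = [
    "LOD_SNR",
    "LOQ_SNR",
    "NOT_REACHED",
    "InsufficientDataError",
    "InternalStandardError",
    "Calibration",
    "CalibrationResult",
    "RatioResult",
    "SampleQuantResult",
    "rt_windows_from_scenario",
    "measure_sample",
    "fit_calibration",
    "determine_lod_loq",
    "compute_recovery",
    "compute_matrix_effect",
    "compute_cv",
    "quantify_sample",
    "validation_report",
]

#: S/N thresholds defining detection and quantification.
LOD_SNR = 3.0
LOQ_SNR = 10.0

#: Sentinel reported when no prepared level reaches the required S/N.
NOT_REACHED = math.inf


class InsufficientDataError(ValueError):
    """Too few usable calibration levels to fit a model."""


class InternalStandardError(RuntimeError):
    """The internal-standard peak failed QC in a sample."""


def _ooh_label(derivative_label: str) -> str:
    """Report species as the parent hydroperoxide (FA 18:2-OOH) rather than
    the measured derivative (FA 18:2-OOMxP)."""
    sp = parse_species(derivative_label)
    if sp.state is AcylState.OOMXP:
        return sp.with_state(AcylState.OOH).label
    return sp.label


def rt_windows_from_scenario(scenario, half_width: float = 0.3) -> dict[str, tuple[float, float]]:
    """Retention-time windows (± ``half_width`` min) around each scenario
    species' expected elution time — assay metadata for the peak picker."""
    return {
        s.label: (s.peak.retention_time - half_width, s.peak.retention_time + half_width)
        for s in scenario.all_species
    }


def measure_sample(
    sample,
    registry: TransitionRegistry,
    rt_windows: Mapping[str, tuple[float, float]],
    min_snr: float = LOD_SNR,
) -> dict[str, PeakResult]:
    """Integrate every registry channel present in a sample.

    ``sample`` is anything with ``.traces`` (a simulated Sample) or a plain
    sequence of traces.  Channels without an RT window are skipped.
    """
    traces: Sequence[ChromatogramTrace] = getattr(sample, "traces", sample)
    results: dict[str, PeakResult] = {}
    for trace in traces:
        if trace.transition not in registry or trace.transition not in rt_windows:
            continue
        results[trace.transition] = find_peak(
            trace, rt_windows[trace.transition], min_snr=min_snr
        )
    return results


# ---------------------------------------------------------------------------
# LOD / LOQ
# ---------------------------------------------------------------------------


def determine_lod_loq(
    snr_by_level: Mapping[float, Sequence[float]],
    lod_snr: float = LOD_SNR,
    loq_snr: float = LOQ_SNR,
) -> tuple[float, float]:
    """LOD/LOQ from per-level replicate S/N values.

    LOD is the lowest prepared level whose median replicate S/N >= 3, LOQ
    the lowest with median S/N >= 10; levels are restricted to the
    prepared grid.  When no level qualifies the sentinel ``math.inf`` is
    returned (above the top prepared level).
    """
    if not snr_by_level:
        raise ValueError("snr_by_level must not be empty")
    lod = loq = NOT_REACHED
    for level in sorted(snr_by_level):
        med = float(np.median(np.asarray(list(snr_by_level[level]), dtype=float)))
        if lod is NOT_REACHED and med >= lod_snr:
            lod = float(level)
        if loq is NOT_REACHED and med >= loq_snr:
            loq = float(level)
    if lod > loq:  # an S/N >= 10 level is by definition also detected
        lod = loq
    return lod, loq


# ---------------------------------------------------------------------------
# Calibration model / results
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Fitted response-vs-concentration line with sensitivity limits.

    ``response_mode`` is ``area_ratio_to_IS`` (default) or
    ``absolute_area``; concentrations are pmol/µL of final extract.
    """

    species: str
    slope: float
    intercept: float
    r_squared: float
    lod: float
    loq: float
    linear_range: tuple[float, float]
    response_mode: str
    nobs: int
    slope_stderr: float = math.nan
    intercept_stderr: float = math.nan

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InsufficientDataError(
                f"{self.species}: non-positive calibration slope {self.slope:g}; "
                "model not accepted"
            )
        if not self.lod <= self.loq:
            raise ValueError("LOD must be <= LOQ")

    def predict(self, concentration: float) -> float:
        """Expected response at a concentration (pmol/µL)."""
        return self.intercept + self.slope * concentration

    def invert(self, response: float) -> float:
        """Concentration (pmol/µL) back-calculated from a response."""
        return (response - self.intercept) / self.slope

    def plot(self, levels=None, responses=None, ax=None):
        """Plot the fitted line (and measured points if given); requires
        matplotlib (``pip install mxpquant[plot]``)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if levels is not None and responses is not None:
            ax.plot(levels, responses, "o", label="measured")
        lo, hi = self.linear_range
        ax.plot(
            [lo, hi],
            [self.predict(lo), self.predict(hi)],
            "-",
            label=f"y = {self.slope:.4g} x + {self.intercept:.4g} (R$^2$={self.r_squared:.3f})",
        )
        ax.set_xlabel("concentration (pmol/µL)")
        ax.set_ylabel(
            "area ratio to IS" if self.response_mode == "area_ratio_to_IS" else "peak area"
        )
        ax.set_title(self.species)
        ax.legend()
        return ax

    def summary(self) -> str:
        lod = "> top level" if math.isinf(self.lod) else f"{self.lod:g}"
        loq = "> top level" if math.isinf(self.loq) else f"{self.loq:g}"
        lines = [
            f"Calibration: {self.species}",
            f"  response mode : {self.response_mode}",
            f"  fit           : y = {self.slope:.6g} x + {self.intercept:.6g}"
            f"  (n = {self.nobs})",
            f"  slope se      : {self.slope_stderr:.3g}",
            f"  R^2           : {self.r_squared:.4f}",
            f"  linear range  : {self.linear_range[0]:g}-{self.linear_range[1]:g} pmol/uL",
            f"  LOD (S/N>=3)  : {lod} pmol/uL",
            f"  LOQ (S/N>=10) : {loq} pmol/uL",
        ]
        return "\n".join(lines)


@dataclass
class Calibration:
    """Calibration data for one species, ready to fit.

    Parameters
    ----------
    levels
        Prepared concentration per measurement (pmol/µL).
    areas
        Analyte peak areas, parallel to ``levels``.
    is_areas
        Internal-standard areas per measurement (required for the
        area-ratio response mode).
    snrs
        Analyte S/N per measurement, used for LOD/LOQ and for excluding
        sub-LOQ levels from the line fit.
    """

    levels: Sequence[float]
    areas: Sequence[float]
    is_areas: Sequence[float] | None = None
    snrs: Sequence[float] | None = None
    species: str = ""
    response_mode: str = "area_ratio_to_IS"

    def __post_init__(self) -> None:
        n = len(self.levels)
        if len(self.areas) != n or (self.is_areas is not None and len(self.is_areas) != n):
            raise ValueError("levels, areas and is_areas must be parallel")
        if self.snrs is not None and len(self.snrs) != n:
            raise ValueError("snrs must be parallel to levels")
        if self.response_mode not in ("area_ratio_to_IS", "absolute_area"):
            raise ValueError(f"unknown response mode {self.response_mode!r}")
        if self.response_mode == "area_ratio_to_IS" and self.is_areas is None:
            raise ValueError("area-ratio mode requires is_areas")

    @classmethod
    def from_series(
        cls,
        series,
        species_label: str,
        registry: TransitionRegistry,
        rt_windows: Mapping[str, tuple[float, float]],
        response_mode: str = "area_ratio_to_IS",
    ) -> "Calibration":
        """Measure a simulated :class:`~mxpquant.simulate.CalibrationSeries`.

        Peaks are integrated per sample for the analyte and the internal
        standard; only measured traces are used (never the ground truth).
        """
        is_label = registry.internal_standard.label
        levels, areas, is_areas, snrs = [], [], [], []
        for sample, level in zip(series.samples, series.levels):
            measured = measure_sample(sample, registry, rt_windows)
            peak = measured[species_label]
            levels.append(level)
            areas.append(peak.area)
            snrs.append(peak.snr)
            is_areas.append(measured[is_label].area if is_label in measured else math.nan)
        return cls(
            levels=levels,
            areas=areas,
            is_areas=is_areas,
            snrs=snrs,
            species=species_label,
            response_mode=response_mode,
        )

    def fit(self, min_levels: int = 4) -> CalibrationResult:
        """OLS of response vs concentration over levels at/above the LOQ.

        Sub-LOQ levels are excluded from the line but still determine the
        LOD/LOQ.  Fewer than ``min_levels`` usable distinct levels is an
        error.
        """
        levels = np.asarray(self.levels, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if self.snrs is not None:
            snr_by_level: dict[float, list[float]] = {}
            for level, snr in zip(levels, self.snrs):
                snr_by_level.setdefault(float(level), []).append(float(snr))
            lod, loq = determine_lod_loq(snr_by_level)
        else:
            lod, loq = float(np.min(levels)), float(np.min(levels))
        usable = levels >= (loq if not math.isinf(loq) else math.inf)
        n_distinct = len(set(levels[usable].tolist()))
        if n_distinct < min_levels:
            raise InsufficientDataError(
                f"{self.species or 'calibration'}: only {n_distinct} usable "
                f"level(s) at/above LOQ; need >= {min_levels}"
            )
        if self.response_mode == "area_ratio_to_IS":
            responses = areas / np.asarray(self.is_areas, dtype=float)
        else:
            responses = areas
        x, y = levels[usable], responses[usable]
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = (float(v) for v in ols.params)
        se_int, se_slope = (float(v) for v in ols.bse)
        return CalibrationResult(
            species=self.species,
            slope=slope,
            intercept=intercept,
            r_squared=float(ols.rsquared),
            lod=lod,
            loq=loq,
            linear_range=(float(x.min()), float(x.max())),
            response_mode=self.response_mode,
            nobs=int(ols.nobs),
            slope_stderr=se_slope,
            intercept_stderr=se_int,
        )


def fit_calibration(
    series,
    species_label: str,
    registry: TransitionRegistry,
    rt_windows: Mapping[str, tuple[float, float]],
    response_mode: str = "area_ratio_to_IS",
) -> CalibrationResult:
    """Measure and fit a calibration series for one species (convenience)."""
    return Calibration.from_series(
        series, species_label, registry, rt_windows, response_mode
    ).fit()


# ---------------------------------------------------------------------------
# Recovery, matrix effect, CV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatioResult:
    """Replicate mean ± sd of a percent area ratio."""

    mean_pct: float
    sd_pct: float
    n: int
    classification: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tail = f" ({self.classification})" if self.classification else ""
        return f"{self.mean_pct:.1f} ± {self.sd_pct:.1f}%{tail}"


def _paired_ratio(numerators, denominators, what: str) -> RatioResult:
    num = np.atleast_1d(np.asarray(numerators, dtype=float))
    den = np.atleast_1d(np.asarray(denominators, dtype=float))
    if num.shape != den.shape:
        raise ValueError(f"{what}: replicate arrays must have equal length")
    if np.any(den <= 0):
        raise ValueError(f"{what}: denominator areas must be > 0")
    ratios = 100.0 * num / den
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return RatioResult(mean_pct=float(np.mean(ratios)), sd_pct=sd, n=ratios.size)


def compute_recovery(spiked_sample_area, spiked_extract_area) -> RatioResult:
    """Extraction recovery: 100 x area(spiked sample) / area(spiked extract).

    Scalars give a single ratio; equal-length replicate arrays are paired
    and reported as mean ± sd.
    """
    return _paired_ratio(spiked_sample_area, spiked_extract_area, "recovery")


def compute_matrix_effect(spiked_extract_area, neat_standard_area) -> RatioResult:
    """Matrix effect: 100 x area(spiked extract) / area(neat standard).

    Values below 100% indicate ion suppression, above 100% ion enhancement.
    """
    res = _paired_ratio(spiked_extract_area, neat_standard_area, "matrix effect")
    if res.mean_pct < 100.0:
        label = "ion suppression"
    elif res.mean_pct > 100.0:
        label = "ion enhancement"
    else:
        label = "none"
    return RatioResult(res.mean_pct, res.sd_pct, res.n, classification=label)


def compute_cv(values, grouping: str = "standard") -> float:
    """Coefficient of variation in percent.

    ``standard`` and ``intraday`` expect a flat sequence of >= 3 replicate
    measurements and return 100 x sd/mean.  ``interday`` expects a sequence
    of per-day replicate sequences (>= 3 days) and returns the CV of the
    daily means.
    """
    if grouping not in ("standard", "intraday", "interday"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping == "interday":
        days = [np.asarray(list(day), dtype=float) for day in values]
        if len(days) < 3:
            raise ValueError(f"interday CV needs >= 3 days, got {len(days)}")
        vals = np.array([float(np.mean(day)) for day in days])
    else:
        vals = np.asarray(list(values), dtype=float)
        if vals.size < 3:
            raise ValueError(f"CV needs >= 3 replicates, got {vals.size}")
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError("CV undefined: mean of replicates is 0")
    return 100.0 * float(np.std(vals, ddof=1)) / mean


# ---------------------------------------------------------------------------
# Sample quantitation
# ---------------------------------------------------------------------------


@dataclass
class SampleQuantResult:
    """Per-sample concentration table plus QC outcome.

    ``ok`` is False when the internal standard failed QC; no
    concentrations are emitted in that case.
    """

    sample_id: str
    ok: bool
    table: pd.DataFrame
    qc_message: str = ""


def quantify_sample(
    sample,
    registry: TransitionRegistry,
    calibrations: Mapping[str, CalibrationResult],
    rt_windows: Mapping[str, tuple[float, float]],
    sample_id: str | None = None,
    source_volume_ul: float | None = None,
    final_volume_ul: float = 100.0,
    per_ml: bool = False,
) -> SampleQuantResult:
    """Quantify every calibrated species in one sample.

    The internal-standard peak must be detected with S/N >= 10, otherwise
    the whole sample fails QC.  Per species the response is analyte area /
    IS area (or absolute area per the calibration's mode), inverted through
    the calibration line to pmol/µL of final extract.  Optionally the
    dilution chain back-calculates to the source material: concentration x
    final_volume / source_volume (x 1000 when reporting per mL).

    Flags: ``ND`` below S/N 3, ``<LOQ`` between detection and
    quantification, ``at_LOQ`` at the limit, ``extrapolated`` outside the
    fitted range.
    """
    traces: Sequence[ChromatogramTrace] = getattr(sample, "traces", sample)
    sid = sample_id if sample_id is not None else getattr(sample, "sample_id", "")
    measured = measure_sample(sample, registry, rt_windows)
    is_label = registry.internal_standard.label
    is_peak = measured.get(is_label)
    if is_peak is None or not is_peak.detected or is_peak.snr < LOQ_SNR:
        snr = 0.0 if is_peak is None else is_peak.snr
        return SampleQuantResult(
            sample_id=sid,
            ok=False,
            table=pd.DataFrame(
                columns=[
                    "sample", "species", "area", "is_area", "response",
                    "concentration", "units", "flags",
                ]
            ),
            qc_message=(
                f"internal standard {is_label} failed QC "
                f"(S/N {snr:.1f} < {LOQ_SNR:g}); no concentrations emitted"
            ),
        )

    scale, units = 1.0, "pmol/uL extract"
    if source_volume_ul is not None:
        if source_volume_ul <= 0:
            raise ValueError("source_volume_ul must be > 0")
        scale = final_volume_ul / source_volume_ul
        units = "pmol/uL source"
        if per_ml:
            scale *= 1000.0
            units = "pmol/mL source"

    rows = []
    for label, peak in measured.items():
        if label == is_label or label not in calibrations:
            continue
        cal = calibrations[label]
        flags: list[str] = []
        if not peak.detected or peak.snr < LOD_SNR:
            rows.append(
                {
                    "sample": sid,
                    "species": _ooh_label(label),
                    "area": peak.area,
                    "is_area": is_peak.area,
                    "response": math.nan,
                    "concentration": math.nan,
                    "units": units,
                    "flags": "ND",
                }
            )
            continue
        response = (
            peak.area / is_peak.area
            if cal.response_mode == "area_ratio_to_IS"
            else peak.area
        )
        conc = cal.invert(response)
        if peak.snr < LOQ_SNR or conc < cal.loq:
            flags.append("<LOQ")
        if math.isclose(conc, cal.loq, rel_tol=1e-3):
            flags.append("at_LOQ")
        if conc > cal.linear_range[1] or conc < cal.linear_range[0]:
            flags.append("extrapolated")
        rows.append(
            {
                "sample": sid,
                "species": _ooh_label(label),
                "area": peak.area,
                "is_area": is_peak.area,
                "response": response,
                "concentration": conc * scale,
                "units": units,
                "flags": ";".join(flags),
            }
        )
    table = pd.DataFrame(rows)
    return SampleQuantResult(sample_id=sid, ok=True, table=table)


# ---------------------------------------------------------------------------
# Validation report (recovery / matrix effect / CV per species)
# ---------------------------------------------------------------------------


def validation_report(
    scenario,
    registry: TransitionRegistry,
    replicates: int = 5,
    days: int = 3,
    rt_half_width: float = 0.3,
) -> pd.DataFrame:
    """Simulate and compute a full method-validation table.

    One row per analyte: recovery mean ± sd, matrix effect, and the
    standard / intra-day / inter-day CVs of the area response, following
    the usual validation-table layout.
    """
    from .simulate import simulate_replicate_set, simulate_validation_set

    rt_windows = rt_windows_from_scenario(scenario, rt_half_width)
    valset = simulate_validation_set(scenario, replicates=replicates, registry=registry)

    def areas(samples, label):
        return [
            measure_sample(s, registry, rt_windows)[label].area for s in samples
        ]

    day_sets = [
        simulate_replicate_set(scenario, n_replicates=replicates, day=d, registry=registry)
        for d in range(days)
    ]

    rows = []
    for settings in scenario.species:
        label = settings.label
        neat = areas(valset.neat_standard, label)
        extract = areas(valset.spiked_extract, label)
        spiked = areas(valset.spiked_sample, label)
        rec = compute_recovery(spiked, extract)
        mat = compute_matrix_effect(extract, neat)
        per_day = [areas(day_samples, label) for day_samples in day_sets]
        rows.append(
            {
                "species": _ooh_label(label),
                "recovery_pct": round(rec.mean_pct, 1),
                "recovery_sd": round(rec.sd_pct, 1),
                "matrix_effect_pct": round(mat.mean_pct, 1),
                "cv_standard_pct": round(compute_cv(neat, "standard"), 1),
                "cv_intraday_pct": round(compute_cv(per_day[0], "intraday"), 1),
                "cv_interday_pct": round(compute_cv(per_day, "interday"), 1),
            }
        )
    return pd.DataFrame(rows)
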