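"""Molecular formula and monoisotopic mass arithmetic for fatty acyl species.

The analytes are unsaturated fatty acids (FA), their hydroperoxides (FA
C:db-OOH, the -OOH group allylic to a double bond) and the 2-methoxypropene
(2-MxP) perketal derivatives (FA C:db-OOMxP) actually measured by the SRM
assay.  Derivatization caps -OOH as -OO-C(CH3)2-OCH3, a net addition of
C4H8O (72.0575 Da), and the derivative ionizes as the sodiated molecule
[M+Na]+ in positive mode.

Formula ladder for a fatty acyl with ``n`` carbons and ``db`` double bonds::

    FREE   C_n H_(2n-2*db) O2         (the plain carboxylic acid)
    -OOH   FREE  + O2
    -OOMxP -OOH  + C4H8O

Monoisotopic masses are pinned to CODATA/IUPAC values so that exact-mass
results are reproducible to 1e-6 Da.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "AcylState",
    "FattyAcylSpecies",
    "MolecularFormula",
    "Adduct",
    "ADDUCTS",
    "SpeciesParseError",
    "SpeciesValidationError",
    "parse_species",
    "formula_of",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_half_away",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "O": 15.99491462,
    "Na": 22.98976928,
}

#: Electron rest mass (Da); adduct ions gain/lose it together with the charge.
ELECTRON_MASS: float = 0.00054858


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (m/z reporting convention).

    Python's built-in ``round`` is banker's rounding; instrument software
    and the transition tables this package mirrors round 0.5 up in
    magnitude instead.
    """
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


class SpeciesParseError(ValueError):
    """A species label does not match the ``FA <C>:<db>[-OOH|-OOMxP]`` grammar."""


class SpeciesValidationError(ValueError):
    """A species label parses but is chemically impossible."""


class AcylState(Enum):
    """Derivatization state of a fatty acyl chain."""

    FREE = "free"
    OOH = "ooh"
    OOMXP = "oomxp"


_STATE_SUFFIX = {AcylState.FREE: "", AcylState.OOH: "-OOH", AcylState.OOMXP: "-OOMxP"}


@dataclass(frozen=True)
class FattyAcylSpecies:
    """A fatty acyl identified by carbon count, double-bond count and state.

    Parameters
    ----------
    carbons
        Number of carbons in the acyl chain (>= 2).
    double_bonds
        Number of C=C double bonds; at most ``(carbons - 2) // 2`` for an
        unbranched acyl, and at least 1 for the -OOH/-OOMxP states because
        hydroperoxidation requires an allylic position.
    state
        FREE (plain acid), OOH (hydroperoxide) or OOMXP (2-MxP perketal).
    """

    carbons: int
    double_bonds: int
    state: AcylState = AcylState.FREE

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise SpeciesValidationError(
                f"carbons must be >= 2, got {self.carbons}"
            )
        if self.double_bonds < 0:
            raise SpeciesValidationError(
                f"double_bonds must be >= 0, got {self.double_bonds}"
            )
        max_db = (self.carbons - 2) // 2
        if self.double_bonds > max_db:
            raise SpeciesValidationError(
                f"FA {self.carbons}:{self.double_bonds} exceeds the chemical "
                f"maximum of {max_db} double bonds for {self.carbons} carbons"
            )
        if self.state is not AcylState.FREE and self.double_bonds < 1:
            raise SpeciesValidationError(
                f"FA {self.carbons}:{self.double_bonds}{_STATE_SUFFIX[self.state]}: "
                "hydroperoxidation requires at least one double bond "
                "(the -OOH group is allylic to a C=C)"
            )

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``"FA 18:2-OOMxP"``; round-trips through the parser."""
        return f"FA {self.carbons}:{self.double_bonds}{_STATE_SUFFIX[self.state]}"

    def with_state(self, state: AcylState) -> "FattyAcylSpecies":
        return FattyAcylSpecies(self.carbons, self.double_bonds, state)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_SPECIES_RE = re.compile(
    r"^FA\s*(?P<carbons>\d+):(?P<db>\d+)(?P<suffix>-OOH|-OOMxP)?(?:\s*\(IS\))?$"
)

_SUFFIX_STATE = {None: AcylState.FREE, "-OOH": AcylState.OOH, "-OOMxP": AcylState.OOMXP}


def parse_species(label: str) -> FattyAcylSpecies:
    """Parse a label like ``"FA 18:2-OOMxP"`` into a :class:`FattyAcylSpecies`.

    The grammar is ``FA <carbons>:<double_bonds>[-OOH|-OOMxP]``; a trailing
    ``(IS)`` internal-standard marker is tolerated and ignored.

    Raises
    ------
    SpeciesParseError
        If the label does not match the grammar (the message names the label).
    SpeciesValidationError
        If the parsed counts are chemically impossible (e.g. a saturated
        acyl with an -OOH suffix).
    """
    m = _SPECIES_RE.match(label.strip())
    if m is None:
        raise SpeciesParseError(
            f"cannot parse species label {label!r}: expected "
            "'FA <carbons>:<double_bonds>[-OOH|-OOMxP]'"
        )
    return FattyAcylSpecies(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("db")),
        state=_SUFFIX_STATE[m.group("suffix")],
    )


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count map supporting element-wise addition and subtraction."""

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {el: int(n) for el, n in self.element_counts.items() if n != 0}
        for el, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C22H42NaO5"``."""
        counts: Counter[str] = Counter()
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula string {formula!r}")
        return cls(dict(counts))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = Counter(self.element_counts)
        counts.update(other.element_counts)
        return MolecularFormula(dict(counts))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = Counter(self.element_counts)
        counts.subtract(other.element_counts)
        return MolecularFormula(dict(counts))  # raises if any count < 0

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.element_counts)

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self.element_counts,
            key=lambda el: (el != "C", el != "H", el),
        )
        return "".join(
            f"{el}{self.element_counts[el] if self.element_counts[el] != 1 else ''}"
            for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


_O2 = MolecularFormula({"O": 2})
_MXP = MolecularFormula({"C": 4, "H": 8, "O": 1})  # 2-methoxypropene addition


def formula_of(species: FattyAcylSpecies) -> MolecularFormula:
    """Neutral molecular formula of a fatty acyl species.

    FREE acid is C_n H_(2n-2*db) O2; hydroperoxidation adds O2; 2-MxP
    derivatization adds C4H8O on top.  Adducts are applied separately by
    :func:`adduct_mz`.
    """
    free = MolecularFormula(
        {"C": species.carbons, "H": 2 * species.carbons - 2 * species.double_bonds, "O": 2}
    )
    if species.state is AcylState.FREE:
        return free
    if species.state is AcylState.OOH:
        return free + _O2
    return free + _O2 + _MXP


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass (Da) of a neutral formula; empty formula -> 0.0.

    Raises
    ------
    ValueError
        If the formula contains an element outside the pinned mass table.
    """
    unsupported = sorted(set(formula) - set(ELEMENT_MASSES))
    if unsupported:
        raise ValueError(
            f"unsupported element(s) {', '.join(unsupported)}; "
            f"supported: {', '.join(sorted(ELEMENT_MASSES))}"
        )
    return sum(n * ELEMENT_MASSES[el] for el, n in formula.element_counts.items())


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionization adduct.

    ``delta_mass`` is the signed mass difference between the ion and the
    neutral molecule, including the electron gained or lost with the charge.
    """

    name: str
    delta_mass: float
    charge_sign: int

    def __post_init__(self) -> None:
        if self.charge_sign not in (+1, -1):
            raise ValueError("only singly charged adducts are supported")


ADDUCTS: Mapping[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", -ELEMENT_MASSES["H"] + ELECTRON_MASS, -1),
    "[M+H]+": Adduct("[M+H]+", +ELEMENT_MASSES["H"] - ELECTRON_MASS, +1),
    "[M+Na]+": Adduct("[M+Na]+", +ELEMENT_MASSES["Na"] - ELECTRON_MASS, +1),
}

# Typography seen in the literature: Unicode minus and thin spaces.
_ADDUCT_NORMALIZE = str.maketrans({"−": "-", " ": None})


def _resolve_adduct(adduct: Adduct | str) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    key = adduct.translate(_ADDUCT_NORMALIZE)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; known: {', '.join(ADDUCTS)}"
        ) from None


def adduct_mz(neutral_mass: float, adduct: Adduct | str, ndigits: int | None = None) -> float:
    """m/z of a singly charged adduct ion of a neutral of the given mass.

    Parameters
    ----------
    neutral_mass
        Monoisotopic mass of the neutral molecule (Da), > 0.
    adduct
        An :class:`Adduct` or one of the registered names
        (``"[M-H]-"``, ``"[M+H]+"``, ``"[M+Na]+"``).
    ndigits
        Optional reporting precision: 4 decimals for exact-mass work,
        1 decimal for SRM tables; ``None`` returns the unrounded value.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be > 0, got {neutral_mass}")
    mz = neutral_mass + _resolve_adduct(adduct).delta_mass
    return round_half_away(mz, ndigits) if ndigits is not None else mz


def ppm_error(experimental: float, theoretical: float) -> float:
    """Relative mass error in parts-per-million.

    ``(experimental - theoretical) / theoretical * 1e6``.  The value is
    returned unrounded; report to 2 decimals via :func:`round_half_away`.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return (experimental - theoretical) / theoretical * 1e6
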