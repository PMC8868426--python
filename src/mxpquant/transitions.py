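"""SRM transition prediction and the default FAOOMxP assay registry.

The sodiated 2-MxP derivatives fragment with unsaturation-dependent neutral
losses: poly-unsaturated species (db >= 2) lose the MxP unit, nominally
72.0 Da (C4H8O), while mono-unsaturated species show an empirical loss of
202.1 Da whose fragment chemistry is not characterized.  The shipped
registry holds the instrument-optimized precursor/product m/z, collision
energies and tube-lens voltages for the eight assayed species; those
printed values are authoritative for acquisition and matching, and the
theoretical predictions here serve as advisory QC (instrument-tuned m/z
deviate from theory by up to ~0.13 Da).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from .chem import (
    AcylState,
    FattyAcylSpecies,
    adduct_mz,
    formula_of,
    monoisotopic_mass,
    parse_species,
    round_half_away,
)

__all__ = [
    "MXP_NEUTRAL_LOSS",
    "MONOENE_NEUTRAL_LOSS",
    "SRMTransition",
    "TransitionRegistry",
    "TransitionNotFoundError",
    "RegistryValidation",
    "predict_parent_mz",
    "predict_product_mz",
    "build_registry",
    "load_registry",
    "validate_against_registry",
    "export_transition_list",
]

#: Nominal neutral loss (Da) of the 2-MxP unit, C4H8O, for db >= 2 species.
MXP_NEUTRAL_LOSS = 72.0
#: Empirical neutral loss (Da) observed for mono-unsaturated derivatives.
MONOENE_NEUTRAL_LOSS = 202.1

_CSV_COLUMNS = (
    "species",
    "precursor_mz",
    "product_mz",
    "collision_energy",
    "tube_lens",
    "polarity",
    "is_internal_standard",
)


@dataclass(frozen=True)
class SRMTransition:
    """One precursor -> product SRM channel with its instrument parameters."""

    species: FattyAcylSpecies
    parent_mz: float
    product_mz: float
    collision_energy: float
    tube_lens: float
    polarity: str = "positive"
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if not (self.parent_mz > self.product_mz > 0):
            raise ValueError(
                f"{self.species.label}: need parent_mz > product_mz > 0, "
                f"got {self.parent_mz}/{self.product_mz}"
            )
        if not 5 <= self.collision_energy <= 50:
            raise ValueError(
                f"{self.species.label}: collision energy {self.collision_energy} V "
                "outside the plausible 5-50 V range"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    @property
    def label(self) -> str:
        return self.species.label


class TransitionNotFoundError(KeyError):
    """Requested species has no transition in the registry."""


@dataclass
class TransitionRegistry:
    """Ordered collection of SRM transitions with a flagged internal standard."""

    entries: Sequence[SRMTransition]

    def __post_init__(self) -> None:
        labels = [t.label for t in self.entries]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate species in registry: {', '.join(dupes)}")
        self._by_label = {t.label: t for t in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SRMTransition]:
        return iter(self.entries)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def get(self, label: str) -> SRMTransition:
        try:
            return self._by_label[label]
        except KeyError:
            raise TransitionNotFoundError(
                f"no transition for {label!r}; registry has: "
                + ", ".join(self._by_label)
            ) from None

    @property
    def internal_standard(self) -> SRMTransition:
        flagged = [t for t in self.entries if t.is_internal_standard]
        if len(flagged) != 1:
            raise ValueError(
                f"registry must flag exactly one internal standard, found {len(flagged)}"
            )
        return flagged[0]

    @property
    def analytes(self) -> list[SRMTransition]:
        return [t for t in self.entries if not t.is_internal_standard]


def predict_parent_mz(species: FattyAcylSpecies) -> float:
    """Theoretical [M+Na]+ m/z of a 2-MxP derivative, rounded to 1 decimal.

    Only OOMXP-state species are assayed in positive mode; any other state
    is an error.
    """
    if species.state is not AcylState.OOMXP:
        raise ValueError(
            f"{species.label}: only -OOMxP derivatives are assayed as [M+Na]+; "
            "derivatize (state OOMXP) before predicting SRM channels"
        )
    return adduct_mz(monoisotopic_mass(formula_of(species)), "[M+Na]+", ndigits=1)


def predict_product_mz(species: FattyAcylSpecies, parent_mz: float) -> float:
    """Product-ion m/z from the unsaturation-dependent neutral-loss rules.

    db >= 2 loses the MxP unit (72.0 Da); db = 1 loses the empirical
    202.1 Da.  Saturated species carry no hydroperoxide and are an error.
    """
    if species.state is not AcylState.OOMXP:
        raise ValueError(f"{species.label}: product prediction requires the -OOMxP state")
    if species.double_bonds == 0:
        raise ValueError(f"{species.label}: no product-ion rule for saturated acyls")
    loss = MXP_NEUTRAL_LOSS if species.double_bonds >= 2 else MONOENE_NEUTRAL_LOSS
    return round_half_away(parent_mz - loss, 1)


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("1", "true", "yes", "y")


def load_registry(path: str | Path) -> TransitionRegistry:
    """Load a transition registry from a CSV file (column schema as exported)."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"{path}: transition CSV missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            entries.append(
                SRMTransition(
                    species=parse_species(row["species"]),
                    parent_mz=float(row["precursor_mz"]),
                    product_mz=float(row["product_mz"]),
                    collision_energy=float(row["collision_energy"]),
                    tube_lens=float(row["tube_lens"]),
                    polarity=row["polarity"].strip() or "positive",
                    is_internal_standard=_parse_bool(row["is_internal_standard"]),
                )
            )
    return TransitionRegistry(entries)


def build_registry() -> TransitionRegistry:
    """The default 8-channel FAOOMxP assay shipped with the package.

    Values are the instrument-optimized precursor/product m/z, collision
    energy (V) and tube lens (V) for each derivative, with FA 19:1-OOMxP
    flagged as the internal standard; they are packaged data, not
    re-predicted.
    """
    with resources.as_file(
        resources.files("mxpquant.data").joinpath("default_transitions.csv")
    ) as path:
        return load_registry(path)


def export_transition_list(registry: TransitionRegistry, path: str | Path) -> None:
    """Write the registry as a vendor-style transition-list CSV (round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for t in registry:
            writer.writerow(
                [
                    t.label,
                    repr(t.parent_mz),
                    repr(t.product_mz),
                    repr(t.collision_energy),
                    repr(t.tube_lens),
                    t.polarity,
                    "true" if t.is_internal_standard else "false",
                ]
            )


@dataclass(frozen=True)
class Deviation:
    species: str
    field: str  # "parent" or "product"
    predicted: float
    registry: float

    @property
    def delta(self) -> float:
        return self.predicted - self.registry


@dataclass
class RegistryValidation:
    """Outcome of comparing theoretical predictions against registry values."""

    deviations: list[Deviation]
    tolerance: float

    # 1e-9 guard absorbs float representation error in 1-decimal m/z deltas
    @property
    def passed(self) -> bool:
        return all(abs(d.delta) <= self.tolerance + 1e-9 for d in self.deviations)

    @property
    def offenders(self) -> list[Deviation]:
        return [d for d in self.deviations if abs(d.delta) > self.tolerance + 1e-9]

    @property
    def max_abs_delta(self) -> float:
        return max((abs(d.delta) for d in self.deviations), default=0.0)

    def to_rows(self) -> list[dict]:
        return [
            {
                "species": d.species,
                "field": d.field,
                "predicted": d.predicted,
                "registry": d.registry,
                "delta": d.delta,
                "within_tolerance": abs(d.delta) <= self.tolerance + 1e-9,
            }
            for d in self.deviations
        ]


def validate_against_registry(
    registry: TransitionRegistry, tolerance: float = 0.2
) -> RegistryValidation:
    """QC a registry: deviation of predicted parent/product m/z per species.

    PASS iff every |predicted - registry| <= tolerance; deviations are
    listed in descending magnitude.  The default 0.2 Da covers the largest
    known print-vs-theory gap while still rejecting neighboring species
    (minimum inter-species parent spacing in the default assay is 2.0).
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    if len(registry) == 0:
        raise ValueError("cannot validate an empty registry")
    deviations: list[Deviation] = []
    for t in registry:
        parent_pred = predict_parent_mz(t.species)
        deviations.append(Deviation(t.label, "parent", parent_pred, t.parent_mz))
        deviations.append(
            Deviation(
                t.label,
                "product",
                predict_product_mz(t.species, t.parent_mz),
                t.product_mz,
            )
        )
    deviations.sort(key=lambda d: abs(d.delta), reverse=True)
    return RegistryValidation(deviations, tolerance)


def predicted_registry() -> TransitionRegistry:
    """A registry built purely from theory (parent and product predicted)."""
    entries = []
    for t in build_registry():
        parent = predict_parent_mz(t.species)
        entries.append(
            replace(t, parent_mz=parent, product_mz=predict_product_mz(t.species, parent))
        )
    return TransitionRegistry(entries)
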