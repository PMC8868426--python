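"""Synthetic SRM chromatogram generator with a ground-truth ledger.

Every downstream stage (peak picking, calibration, LOD/LOQ, recovery,
matrix effect, CV, quantitation) is testable against simulated data whose
generative parameters are known.  A scenario describes one virtual assay:
per-species true concentration, response factor and peak model, plus
baseline, noise, drift, matrix multipliers, replicate CV and the sampling
scheme.  The generator emits samples (one trace per SRM channel) together
with a :class:`GroundTruth` ledger; estimators must never read the ledger —
it exists so tests can compare estimates with truth.

The defaults emulate the validated assay conditions: a 6-minute run
sampled at 5 points/s, a ten-level calibration series at 0.01, 0.1, 1,
2.5, 5, 7.5, 10, 25, 50 and 100 pmol/µL with a constant internal-standard
amount (10 pmol/µL in the final extract, i.e. 10 µL of 100 µM IS made up
to 100 µL), a 50 pmol/µL validation spike, ion suppression of 0.91 for the
internal standard (with 1.02 and 1.20 enhancement for the two species that
show it), and an extraction recovery fraction of 0.70.

Trace intensity model::

    y(t) = baseline + drift * t + amplitude * shape(t; RT, sigma, tau) + N(0, noise_sd)

with ``amplitude = concentration * response_factor * matrix_multiplier``
(times a lognormal replicate multiplier when replicate_cv > 0) and the
shape normalized to unit apex height.  Negative values are clipped to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .chem import parse_species
from .peaks import ChromatogramTrace, write_traces_csv
from .transitions import TransitionRegistry, build_registry

__all__ = [
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_SPIKE_LEVEL",
    "DEFAULT_IS_CONCENTRATION",
    "DEFAULT_MATRIX_MULTIPLIERS",
    "PeakModel",
    "SpeciesSettings",
    "SimScenario",
    "Sample",
    "GroundTruth",
    "CalibrationSeries",
    "ValidationSet",
    "default_scenario",
    "load_scenario",
    "simulate_trace",
    "simulate_sample",
    "simulate_calibration_series",
    "simulate_replicate_set",
    "simulate_validation_set",
    "write_samples",
]

#: Calibration dilution series (pmol/µL) used to establish linearity.
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (
    0.01, 0.1, 1.0, 2.5, 5.0, 7.5, 10.0, 25.0, 50.0, 100.0,
)
#: Spike level (pmol/µL) used for recovery / matrix-effect validation.
DEFAULT_SPIKE_LEVEL = 50.0
#: Internal-standard concentration in the final extract (pmol/µL).
DEFAULT_IS_CONCENTRATION = 10.0

#: Per-species ion suppression/enhancement multipliers for matrix scenarios:
#: enhancement for FA 18:1 and FA 22:1 derivatives, suppression elsewhere.
DEFAULT_MATRIX_MULTIPLIERS: Mapping[str, float] = {
    "FA 18:1-OOMxP": 1.02,
    "FA 22:1-OOMxP": 1.20,
}
_DEFAULT_SUPPRESSION = 0.91

#: Extraction recovery fraction typical of the derivatization workflow.
DEFAULT_RECOVERY_FRACTION = 0.70


@dataclass(frozen=True)
class PeakModel:
    """Elution peak shape: Gaussian or exponentially modified Gaussian."""

    retention_time: float
    width_sigma: float = 0.05
    shape: str = "gaussian"
    tailing_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be > 0")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be > 0")
        if self.tailing_tau < 0:
            raise ValueError("tailing_tau must be >= 0")
        if self.shape not in ("gaussian", "exponentially_modified_gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.shape == "exponentially_modified_gaussian" and self.tailing_tau == 0:
            raise ValueError("EMG shape requires tailing_tau > 0")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-apex peak profile evaluated on the time grid (minutes)."""
        z = (t - self.retention_time) / self.width_sigma
        if self.shape == "gaussian":
            return np.exp(-0.5 * z * z)
        # EMG: Gaussian convolved with a one-sided exponential tail,
        # renormalized to unit apex on this grid.
        from scipy.special import erfc

        s, tau = self.width_sigma, self.tailing_tau
        arg = s / (math.sqrt(2.0) * tau) - (t - self.retention_time) / (math.sqrt(2.0) * s)
        h = np.exp(0.5 * (s / tau) ** 2 - (t - self.retention_time) / tau) * erfc(arg)
        peak = float(h.max())
        return h / peak if peak > 0 else h


@dataclass(frozen=True)
class SpeciesSettings:
    """Generative parameters for one assayed species."""

    label: str  # derivative (-OOMxP) label matching the transition registry
    true_concentration: float = DEFAULT_SPIKE_LEVEL  # pmol/µL
    response_factor: float = 2000.0  # apex intensity per (pmol/µL)
    peak: PeakModel = field(default_factory=lambda: PeakModel(retention_time=3.0))
    matrix_multiplier: float = 1.0

    def __post_init__(self) -> None:
        parse_species(self.label)  # validates the grammar
        if self.true_concentration < 0:
            raise ValueError("true_concentration must be >= 0")
        if self.response_factor <= 0:
            raise ValueError("response_factor must be > 0")
        if self.matrix_multiplier <= 0:
            raise ValueError("matrix_multiplier must be > 0")


@dataclass(frozen=True)
class SimScenario:
    """One virtual assay: species set, noise model and sampling scheme.

    ``seed`` is mandatory — every simulated data set must be reproducible.
    """

    seed: int
    species: tuple[SpeciesSettings, ...]
    internal_standard: SpeciesSettings
    baseline_level: float = 50.0
    noise_sd: float = 50.0
    drift_slope: float = 0.0
    replicate_cv: float = 0.0
    sampling_rate: float = 5.0  # points per second
    run_length: float = 6.0  # minutes
    recovery_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("scenario seed must be an integer (reproducibility)")
        if self.noise_sd < 0 or self.baseline_level < 0:
            raise ValueError("noise_sd and baseline_level must be >= 0")
        if not 0 <= self.replicate_cv < 1:
            raise ValueError("replicate_cv must be in [0, 1)")
        if self.sampling_rate <= 0 or self.run_length <= 0:
            raise ValueError("sampling_rate and run_length must be > 0")
        if not 0 < self.recovery_fraction <= 1.5:
            raise ValueError("recovery_fraction must be in (0, 1.5]")
        labels = [s.label for s in self.species] + [self.internal_standard.label]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate species labels in scenario")
        for s in self.species + (self.internal_standard,):
            if not s.peak.retention_time < self.run_length:
                raise ValueError(
                    f"{s.label}: retention time {s.peak.retention_time} min outside "
                    f"the {self.run_length} min run"
                )

    @property
    def all_species(self) -> tuple[SpeciesSettings, ...]:
        return self.species + (self.internal_standard,)

    def species_settings(self, label: str) -> SpeciesSettings:
        for s in self.all_species:
            if s.label == label:
                return s
        raise KeyError(f"species {label!r} not in scenario")

    def time_grid(self) -> np.ndarray:
        dt = 1.0 / (self.sampling_rate * 60.0)  # minutes per point
        n = int(round(self.run_length * self.sampling_rate * 60.0)) + 1
        return np.arange(n) * dt


def default_scenario(
    seed: int,
    registry: TransitionRegistry | None = None,
    replicate_cv: float = 0.0,
    noise_sd: float = 50.0,
) -> SimScenario:
    """Scenario covering the full default assay.

    Retention times are evenly spaced 1.5–5.5 min in registry order;
    matrix multipliers and recovery follow the validated-assay defaults.
    """
    registry = registry or build_registry()
    rts = np.linspace(1.5, 5.5, len(registry))
    analytes = []
    is_settings = None
    for rt, t in zip(rts, registry):
        settings = SpeciesSettings(
            label=t.label,
            true_concentration=(
                DEFAULT_IS_CONCENTRATION if t.is_internal_standard else DEFAULT_SPIKE_LEVEL
            ),
            peak=PeakModel(retention_time=float(rt)),
            matrix_multiplier=DEFAULT_MATRIX_MULTIPLIERS.get(t.label, _DEFAULT_SUPPRESSION),
        )
        if t.is_internal_standard:
            is_settings = settings
        else:
            analytes.append(settings)
    if is_settings is None:
        raise ValueError("registry has no internal standard")
    return SimScenario(
        seed=seed,
        species=tuple(analytes),
        internal_standard=is_settings,
        replicate_cv=replicate_cv,
        noise_sd=noise_sd,
        recovery_fraction=DEFAULT_RECOVERY_FRACTION,
    )


# ---------------------------------------------------------------------------
# Trace and sample generation
# ---------------------------------------------------------------------------


@dataclass
class Sample:
    """One simulated injection: a trace per SRM channel."""

    sample_id: str
    traces: list[ChromatogramTrace]

    def get(self, label: str) -> ChromatogramTrace:
        for tr in self.traces:
            if tr.transition == label:
                return tr
        raise KeyError(f"sample {self.sample_id!r} has no trace for {label!r}")


def _species_rng(scenario: SimScenario, label: str, stream: int = 0) -> np.random.Generator:
    # Stable per-(stream, species) substream so trace generation does not
    # depend on iteration order.
    idx = [s.label for s in scenario.all_species].index(label)
    return np.random.default_rng([scenario.seed & 0x7FFFFFFF, stream, idx])


def _registry_mz(label: str, registry: TransitionRegistry | None) -> tuple[float | None, float | None]:
    if registry is not None and label in registry:
        t = registry.get(label)
        return t.parent_mz, t.product_mz
    return None, None


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the requested CV (keeps signal > 0)."""
    if cv <= 0:
        return 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * s * s, sigma=s))


def simulate_trace(
    scenario: SimScenario,
    species: str | SpeciesSettings,
    concentration: float | None = None,
    stream: int = 0,
    sample_id: str = "sim",
    apply_matrix: bool = True,
    extra_multiplier: float = 1.0,
    registry: TransitionRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> ChromatogramTrace:
    """Simulate the trace of one species; seeded and reproducible.

    The same scenario, species and stream always produce the identical
    trace bit-for-bit.
    """
    settings = (
        species if isinstance(species, SpeciesSettings) else scenario.species_settings(species)
    )
    conc = settings.true_concentration if concentration is None else concentration
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    rng = rng if rng is not None else _species_rng(scenario, settings.label, stream)
    t = scenario.time_grid()
    matrix = settings.matrix_multiplier if apply_matrix else 1.0
    amplitude = conc * settings.response_factor * matrix * extra_multiplier
    y = scenario.baseline_level + scenario.drift_slope * t + amplitude * settings.peak.profile(t)
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=t.size)
    q1, q3 = _registry_mz(settings.label, registry)
    return ChromatogramTrace(
        transition=settings.label,
        times=t,
        intensities=np.clip(y, 0.0, None),
        sample_id=sample_id,
        precursor_mz=q1,
        product_mz=q3,
    )


def simulate_sample(
    scenario: SimScenario,
    sample_id: str,
    stream: int,
    concentrations: Mapping[str, float] | None = None,
    apply_matrix: bool = True,
    amplitude_scale: Mapping[str, float] | None = None,
    registry: TransitionRegistry | None = None,
) -> Sample:
    """Simulate one injection with every scenario species present."""
    traces = []
    for settings in scenario.all_species:
        rng = _species_rng(scenario, settings.label, stream)
        rep_mult = _lognormal_multiplier(rng, scenario.replicate_cv)
        scale = (amplitude_scale or {}).get(settings.label, 1.0)
        conc = (
            concentrations.get(settings.label, settings.true_concentration)
            if concentrations is not None
            else settings.true_concentration
        )
        traces.append(
            simulate_trace(
                scenario,
                settings,
                concentration=conc,
                sample_id=sample_id,
                apply_matrix=apply_matrix,
                extra_multiplier=rep_mult * scale,
                registry=registry,
                rng=rng,
            )
        )
    return Sample(sample_id=sample_id, traces=traces)


# ---------------------------------------------------------------------------
# Ground truth ledger
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Generative truth emitted alongside every simulated set.

    Tests compare estimates against it; estimators must never read it.
    """

    seed: int
    noise_sd: float
    baseline_level: float
    drift_slope: float
    replicate_cv: float
    recovery_fraction: float
    is_label: str
    is_concentration: float
    species: dict[str, dict]
    levels: tuple[float, ...] = ()

    @classmethod
    def from_scenario(cls, scenario: SimScenario, levels: Sequence[float] = ()) -> "GroundTruth":
        return cls(
            seed=scenario.seed,
            noise_sd=scenario.noise_sd,
            baseline_level=scenario.baseline_level,
            drift_slope=scenario.drift_slope,
            replicate_cv=scenario.replicate_cv,
            recovery_fraction=scenario.recovery_fraction,
            is_label=scenario.internal_standard.label,
            is_concentration=scenario.internal_standard.true_concentration,
            species={
                s.label: {
                    "true_concentration": s.true_concentration,
                    "response_factor": s.response_factor,
                    "matrix_multiplier": s.matrix_multiplier,
                    "retention_time": s.peak.retention_time,
                    "width_sigma": s.peak.width_sigma,
                }
                for s in scenario.all_species
            },
            levels=tuple(levels),
        )

    def expected_area(self, label: str, concentration: float, with_matrix: bool = True) -> float:
        """Ideal peak area (intensity*seconds) for a Gaussian peak."""
        info = self.species[label]
        matrix = info["matrix_multiplier"] if with_matrix else 1.0
        amplitude = concentration * info["response_factor"] * matrix
        return amplitude * info["width_sigma"] * math.sqrt(2.0 * math.pi) * 60.0

    def expected_ratio_slope(self, label: str) -> float:
        """Generative slope of (analyte area / IS area) vs concentration."""
        return self.expected_area(label, 1.0) / self.expected_area(
            self.is_label, self.is_concentration
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Sample-set generators
# ---------------------------------------------------------------------------


@dataclass
class CalibrationSeries:
    samples: list[Sample]
    levels: list[float]  # per-sample level, parallel to samples
    replicate: list[int]
    ground_truth: GroundTruth


def simulate_calibration_series(
    scenario: SimScenario,
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    replicates: int = 1,
    batch: int = 0,
    registry: TransitionRegistry | None = None,
) -> CalibrationSeries:
    """Dilution series: analyte amplitudes scale with level, IS constant.

    ``batch`` decorrelates repeated series (e.g. different assay days).
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if any(level < 0 for level in levels):
        raise ValueError("levels must be non-negative")
    samples, out_levels, out_reps = [], [], []
    for rep in range(replicates):
        for li, level in enumerate(levels):
            stream = 1_000_000 * (batch + 1) + 1000 * rep + li
            conc = {s.label: level for s in scenario.species}
            sample = simulate_sample(
                scenario,
                sample_id=f"cal_b{batch}_r{rep}_L{level:g}",
                stream=stream,
                concentrations=conc,
                registry=registry,
            )
            samples.append(sample)
            out_levels.append(float(level))
            out_reps.append(rep)
    return CalibrationSeries(
        samples=samples,
        levels=out_levels,
        replicate=out_reps,
        ground_truth=GroundTruth.from_scenario(scenario, levels),
    )


def simulate_replicate_set(
    scenario: SimScenario,
    n_replicates: int,
    concentration: float | None = None,
    day: int = 0,
    registry: TransitionRegistry | None = None,
) -> list[Sample]:
    """n injections of the same material (for CV studies); ``day`` shifts the
    random substream so inter-day sets are independent."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conc = (
        None
        if concentration is None
        else {s.label: concentration for s in scenario.species}
    )
    return [
        simulate_sample(
            scenario,
            sample_id=f"rep_d{day}_r{i}",
            stream=2_000_000 + 10_000 * day + i,
            concentrations=conc,
            registry=registry,
        )
        for i in range(n_replicates)
    ]


@dataclass
class ValidationSet:
    """Neat standard / spiked extract / spiked sample triple for recovery
    and matrix-effect estimation."""

    neat_standard: list[Sample]
    spiked_extract: list[Sample]
    spiked_sample: list[Sample]
    spike_level: float
    ground_truth: GroundTruth


def simulate_validation_set(
    scenario: SimScenario,
    spike_level: float = DEFAULT_SPIKE_LEVEL,
    replicates: int = 5,
    registry: TransitionRegistry | None = None,
) -> ValidationSet:
    """Generate the three sample types used in method validation.

    neat standard   amplitude = c * RF
    spiked extract  amplitude = c * RF * matrix_multiplier
    spiked sample   amplitude = c * RF * matrix_multiplier * recovery_fraction

    so the downstream recovery and matrix-effect estimators must recover
    the generative fractions.
    """
    conc = {s.label: spike_level for s in scenario.species}
    recovery_scale = {s.label: scenario.recovery_fraction for s in scenario.all_species}
    neat, extract, spiked = [], [], []
    for rep in range(replicates):
        neat.append(
            simulate_sample(
                scenario,
                sample_id=f"neat_r{rep}",
                stream=3_000_000 + rep,
                concentrations=conc,
                apply_matrix=False,
                registry=registry,
            )
        )
        extract.append(
            simulate_sample(
                scenario,
                sample_id=f"extract_r{rep}",
                stream=4_000_000 + rep,
                concentrations=conc,
                apply_matrix=True,
                registry=registry,
            )
        )
        spiked.append(
            simulate_sample(
                scenario,
                sample_id=f"spiked_r{rep}",
                stream=5_000_000 + rep,
                concentrations=conc,
                apply_matrix=True,
                amplitude_scale=recovery_scale,
                registry=registry,
            )
        )
    return ValidationSet(
        neat_standard=neat,
        spiked_extract=extract,
        spiked_sample=spiked,
        spike_level=spike_level,
        ground_truth=GroundTruth.from_scenario(scenario),
    )


# ---------------------------------------------------------------------------
# Scenario files and sample output
# ---------------------------------------------------------------------------


def _species_from_mapping(entry: Mapping, default_rt: float) -> SpeciesSettings:
    peak = PeakModel(
        retention_time=float(entry.get("retention_time", default_rt)),
        width_sigma=float(entry.get("width_sigma", 0.05)),
        shape=entry.get("shape", "gaussian"),
        tailing_tau=float(entry.get("tailing_tau", 0.0)),
    )
    return SpeciesSettings(
        label=entry["label"],
        true_concentration=float(entry.get("concentration", DEFAULT_SPIKE_LEVEL)),
        response_factor=float(entry.get("response_factor", 2000.0)),
        peak=peak,
        matrix_multiplier=float(entry.get("matrix_multiplier", 1.0)),
    )


def load_scenario(path: str | Path) -> SimScenario:
    """Load a scenario from YAML; a missing ``seed`` is an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario YAML must be a mapping")
    if "seed" not in raw:
        raise ValueError(f"{path}: scenario must declare an integer 'seed'")
    species_entries = raw.get("species", [])
    if not species_entries:
        raise ValueError(f"{path}: scenario must list at least one species")
    n = len(species_entries) + 1
    rts = np.linspace(1.5, 5.5, n)
    species = tuple(
        _species_from_mapping(e, default_rt=float(rts[i]))
        for i, e in enumerate(species_entries)
    )
    is_entry = raw.get(
        "internal_standard",
        {"label": "FA 19:1-OOMxP", "concentration": DEFAULT_IS_CONCENTRATION},
    )
    internal_standard = _species_from_mapping(is_entry, default_rt=float(rts[-1]))
    return SimScenario(
        seed=int(raw["seed"]),
        species=species,
        internal_standard=internal_standard,
        baseline_level=float(raw.get("baseline_level", 50.0)),
        noise_sd=float(raw.get("noise_sd", 50.0)),
        drift_slope=float(raw.get("drift_slope", 0.0)),
        replicate_cv=float(raw.get("replicate_cv", 0.0)),
        sampling_rate=float(raw.get("sampling_rate", 5.0)),
        run_length=float(raw.get("run_length", 6.0)),
        recovery_fraction=float(raw.get("recovery_fraction", 1.0)),
    )


def write_samples(
    samples: Sequence[Sample],
    out_dir: str | Path,
    fmt: str = "csv",
    registry: TransitionRegistry | None = None,
) -> list[Path]:
    """Write one file per sample in the internal CSV and/or mzML format."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sample in samples:
        if fmt in ("csv", "both"):
            p = out_dir / f"{sample.sample_id}.csv"
            write_traces_csv(sample.traces, p)
            written.append(p)
        if fmt in ("mzml", "both"):
            from .mzml_io import write_mzml_traces

            traces = sample.traces
            if registry is not None:
                traces = [
                    replace(tr, **dict(zip(("precursor_mz", "product_mz"), _registry_mz(tr.transition, registry))))
                    for tr in traces
                ]
            p = out_dir / f"{sample.sample_id}.mzML"
            write_mzml_traces(traces, p, run_id=sample.sample_id)
            written.append(p)
        if fmt not in ("csv", "mzml", "both"):
            raise ValueError(f"unknown output format {fmt!r}")
    return written
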