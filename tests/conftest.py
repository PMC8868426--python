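import pytest
from hypothesis import settings

from mxpquant.simulate import PeakModel, SimScenario, SpeciesSettings
from mxpquant.transitions import build_registry

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return build_registry()


def make_scenario(
    seed: int,
    noise_sd: float = 0.0,
    replicate_cv: float = 0.0,
    response_factor: float = 2000.0,
    matrix_multiplier: float = 1.0,
    recovery_fraction: float = 1.0,
    run_length: float = 6.0,
    baseline_level: float = 50.0,
    label: str = "FA 18:2-OOMxP",
    rt: float = 2.0,
    is_rt: float = 4.0,
    sigma: float = 0.05,
) -> SimScenario:
    """Single-analyte scenario with on-grid retention times (2.0 / 4.0 min
    at 5 points/s) so noise-free peak integration is phase-identical for
    analyte and internal standard."""
    if is_rt >= run_length:  # keep the IS inside shortened runs, on-grid
        is_rt = run_length - 0.4
    analyte = SpeciesSettings(
        label,
        true_concentration=50.0,
        response_factor=response_factor,
        peak=PeakModel(retention_time=rt, width_sigma=sigma),
        matrix_multiplier=matrix_multiplier,
    )
    istd = SpeciesSettings(
        "FA 19:1-OOMxP",
        true_concentration=10.0,
        response_factor=2000.0,
        peak=PeakModel(retention_time=is_rt, width_sigma=sigma),
    )
    return SimScenario(
        seed=seed,
        species=(analyte,),
        internal_standard=istd,
        noise_sd=noise_sd,
        baseline_level=baseline_level,
        replicate_cv=replicate_cv,
        run_length=run_length,
        recovery_fraction=recovery_fraction,
    )


@pytest.fixture
def simple_scenario():
    return make_scenario(seed=1234)
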