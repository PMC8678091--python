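import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from taskcoact import (
    DesignSpec,
    GroundTruth,
    build_stimulus_series,
    detect_source_events,
    generate_schedule,
)

#: reduced-scale run used by most unit tests: same trial structure and TR
#: as the full design, fewer trials and volumes, so the suite stays fast.
SMALL_SPEC = DesignSpec(
    n_memory_sets=12,
    n_positive=5,
    n_lure=5,
    n_negative=2,
    n_volumes=180,
    n_rois=4,
)


@pytest.fixture(scope="session")
def small_spec() -> DesignSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_schedule():
    return generate_schedule(SMALL_SPEC, seed=123)


@pytest.fixture(scope="session")
def small_encoding_series(small_schedule):
    return build_stimulus_series(small_schedule, "encoding")


@pytest.fixture(scope="session")
def small_retrieval_series(small_schedule):
    return build_stimulus_series(small_schedule, "retrieval")


@pytest.fixture(scope="session")
def small_encoding_events(small_encoding_series, small_schedule):
    return detect_source_events(small_encoding_series, small_schedule)


@pytest.fixture(scope="session")
def default_spec() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def default_schedule(default_spec):
    return generate_schedule(default_spec, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def encoding_only(truth: GroundTruth) -> GroundTruth:
    """Zero the retrieval amplitudes so BOLD responds to memory sets only."""
    eff = truth.effects.copy()
    eff.loc[eff["phase"] == "retrieval", "amplitude"] = 0.0
    return GroundTruth(
        effects=eff,
        ar1=truth.ar1,
        noise_sd=truth.noise_sd,
        drift_amplitude=truth.drift_amplitude,
        behavior=truth.behavior,
        seed=truth.seed,
    )
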