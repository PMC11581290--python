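import numpy as np
import pytest

from gelflq.model import LaneProfile
from gelflq.synthetic import (
    DEFAULT_LADDER_SIZES,
    ExperimentSpec,
    calibration_from_law,
    synth_experiment,
)


@pytest.fixture(scope="session")
def law_cal():
    """Exact calibration for the default synthetic migration law."""
    return calibration_from_law()


@pytest.fixture(scope="session")
def ivt_experiment():
    """Default triplicate IVT-mRNA degradation experiment plus truth table."""
    spec = ExperimentSpec(base_seed=11)
    runs, truth = synth_experiment(spec)
    return spec, runs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_profile(values, label="lane"):
    return LaneProfile(label=label, values=np.asarray(values, dtype=float))


@pytest.fixture
def profile_factory():
    return make_profile
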