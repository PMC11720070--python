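import numpy as np
import pytest

from alphatau import CohortConfig, compute_inverse
from alphatau.source import build_head_model


@pytest.fixture(scope="session")
def model200():
    return build_head_model(n_voxels=200)


@pytest.fixture(scope="session")
def op200(model200):
    return compute_inverse(model200)


@pytest.fixture(scope="session")
def model100():
    return build_head_model(n_voxels=100)


@pytest.fixture(scope="session")
def op100(model100):
    return compute_inverse(model100)


@pytest.fixture()
def small_cfg():
    """A small, fast cohort configuration (not the study conditions)."""
    return CohortConfig(
        group_sizes={"Healthy": 4, "noADMCI": 4, "ADMCI": 6},
        seed=123, duration_s=30.0, head_n_voxels=100,
    )


def pytest_configure(config):
    try:
        from hypothesis import settings

        settings.register_profile("ci", derandomize=True, max_examples=25,
                                  deadline=None)
        settings.load_profile("ci")
    except ImportError:
        pass
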