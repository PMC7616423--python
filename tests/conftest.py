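import numpy as np
import pytest
from hypothesis import settings

from iedgan.preprocessing import extract_segments, preprocess_paired
from iedgan.synthesis import SynthesisConfig, simulate_subject

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthesisConfig:
    """Small, fast cohort configuration used across unit tests."""
    return SynthesisConfig(n_subjects=2, duration_s=90.0, n_ieds_per_subject=40,
                           visibility_fraction=0.25, seed=11)


@pytest.fixture(scope="session")
def tiny_subject(tiny_cfg):
    return simulate_subject(tiny_cfg, 0)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_subject):
    return preprocess_paired(tiny_subject)


@pytest.fixture(scope="session")
def tiny_segments(tiny_preprocessed):
    return extract_segments(tiny_preprocessed, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
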