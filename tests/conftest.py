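import numpy as np
import pytest

from mstates import (
    DynamicsSpec,
    PipelineConfig,
    make_canonical_templates,
    simulate_subject,
    standard_1020_montage,
)


@pytest.fixture(scope="session")
def montage64():
    return standard_1020_montage()


@pytest.fixture(scope="session")
def templates64(montage64):
    return make_canonical_templates(montage64)


@pytest.fixture(scope="session")
def small_subject(templates64):
    """One noisy 20-s subject at 500 Hz for pipeline-level tests."""
    dyn = DynamicsSpec(snr=10.0)
    rec, gt = simulate_subject(templates64, dyn, length_s=20.0, fs=500.0, seed=11)
    return rec, gt


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config matched to 500 Hz fixtures (20 ms smoothing floor)."""
    return PipelineConfig(min_tf=10)


def rle_oracle(labels):
    """Independent run-length encoding: list of (class, start, stop)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i))
            start = i
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
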