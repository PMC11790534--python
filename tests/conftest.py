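import numpy as np
import pytest

from wienerfit.generate import (
    GroundTruth,
    exp1_design,
    exp2_design,
    generate_experiment1,
    generate_experiment2,
)


@pytest.fixture(scope="session")
def exp1_small():
    """A small but fittable modality-design table (t split, shared drift)."""
    truth = GroundTruth(rho_subject=1.0)
    return generate_experiment1(exp1_design(n_subjects=6, trials_per_block=24, seed=41), truth)


@pytest.fixture(scope="session")
def exp2_small():
    """A small cued-design table generated from the default ground truth."""
    return generate_experiment2(exp2_design(n_subjects=6, trials_per_block=24, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
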