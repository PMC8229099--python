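import numpy as np
import pandas as pd
import pytest

from methylclass.simulate import SimulationConfig, simulate_cohort
from methylclass.types import BetaMatrix, SampleSheet


def make_beta(values, cpg_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, float)
    cpg_ids = cpg_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=cpg_ids, columns=sample_ids))


@pytest.fixture
def small_beta() -> BetaMatrix:
    rng = np.random.default_rng(0)
    return make_beta(rng.uniform(0, 1, size=(20, 10)))


@pytest.fixture(scope="session")
def planted_cohort():
    """8 balanced subtypes with strong planted signatures (session-wide)."""
    sizes = {f"G{i}": 10 for i in range(8)}
    config = SimulationConfig(n_cpgs=450, subtype_sizes=sizes,
                              n_signature_cpgs=50, effect_delta=0.4,
                              noise_sd=0.05, n_undefined=0, seed=42)
    return simulate_cohort(config)


@pytest.fixture
def two_group_beta():
    """Two planted groups separated by delta-beta 0.4 over 30 CpGs."""
    rng = np.random.default_rng(7)
    n_cpgs, n_per = 30, 10
    base = np.full((n_cpgs, 2 * n_per), 0.3)
    base[:, n_per:] += 0.4
    base += rng.normal(0, 0.05, base.shape)
    beta = make_beta(np.clip(base, 0, 1))
    labels = ["a"] * n_per + ["b"] * n_per
    return beta, labels
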