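import numpy as np
import pandas as pd
import pytest

from crossclust.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-platform cohort for pipeline-level tests."""
    return simulate_cohort(SimConfig(n_genes=400, n_samples_per_platform=36,
                                     n_subtypes=3, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort used by the stochastic-property tests."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts():
    """3-gene × 2-sample count matrix with easy arithmetic."""
    return pd.DataFrame(
        {"s1": [250, 750, 0], "s2": [100, 300, 600]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
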