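import numpy as np
import pandas as pd
import pytest

from modrep import synthio
from modrep.counts_io import CountMatrix, SampleSheet


@pytest.fixture
def toy_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"s1": [10, 0, 5], "s2": [20, 1, 5]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
    )


@pytest.fixture
def two_group_sheet():
    def make(n_a: int, n_b: int, group_a: str = "HC", group_b: str = "pSS"):
        ids = [f"s{i}" for i in range(n_a + n_b)]
        return SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "group": [group_a] * n_a + [group_b] * n_b,
                    "cohort": "discovery",
                }
            )
        )

    return make


def nb_counts(rng, mu, alpha):
    """Sample NB counts with variance mu + alpha*mu^2 (Poisson when alpha=0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


@pytest.fixture
def nb_sampler():
    return nb_counts


@pytest.fixture
def small_cohort():
    cfg = synthio.small_config(seed=101)
    return synthio.generate_cohort(cfg, "discovery")
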