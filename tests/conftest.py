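import numpy as np
import pytest

from mr2sample.summary_io import (
    HarmonizedDataset,
    HarmonizedPair,
    load_pd_ad_dataset,
)


@pytest.fixture(scope="session")
def pd_ad():
    """The packaged 39-variant harmonized PD->AD dataset."""
    return load_pd_ad_dataset()


@pytest.fixture
def make_dataset():
    """Factory for small harmonized datasets from effect arrays."""

    def _make(beta_x, se_x, beta_y, se_y, ids=None):
        n = len(beta_x)
        ids = ids or [f"rs{i + 1}" for i in range(n)]
        pairs = [
            HarmonizedPair(
                snp_id=ids[i],
                beta_x=float(beta_x[i]),
                se_x=float(se_x[i]),
                beta_y=float(beta_y[i]),
                se_y=float(se_y[i]),
            )
            for i in range(n)
        ]
        return HarmonizedDataset(pairs)

    return _make


@pytest.fixture
def random_dataset(make_dataset):
    """Factory for seeded random datasets of a given size."""

    def _make(j, seed=0):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.4, j)
        sx = rng.uniform(0.005, 0.05, j)
        by = rng.normal(0.1 * bx, 0.02)
        sy = rng.uniform(0.01, 0.08, j)
        return make_dataset(bx, sx, by, sy)

    return _make
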