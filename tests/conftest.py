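import numpy as np
import pytest

from mrhet.data_model import SummaryDataSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_dataset():
    """Factory for random valid summary datasets."""

    def _make(m=8, rng=None, seed=0):
        if rng is None:
            rng = np.random.default_rng(seed)
        alpha = rng.uniform(0.05, 0.5, m) * rng.choice([-1.0, 1.0], m)
        sigma = rng.uniform(0.05, 0.2, m)
        beta_out = 0.3 * alpha + rng.normal(0, sigma)
        return SummaryDataSet(
            snp_id=np.array([f"rs{j}" for j in range(m)]),
            alpha=alpha,
            beta_out=beta_out,
            sigma_out=sigma,
        )

    return _make
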