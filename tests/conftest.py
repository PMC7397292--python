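import numpy as np
import pytest

from mrkit.types import HarmonizedInstrument, HarmonizedVariant


def make_instrument(beta_x, se_x, beta_y, se_y, rsids=None):
    """Build a HarmonizedInstrument from plain arrays (test convenience)."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if rsids is None:
        rsids = [f"rs{i + 1}" for i in range(beta_x.size)]
    variants = tuple(
        HarmonizedVariant(
            rsid=rsids[i],
            beta_x=float(beta_x[i]),
            se_x=float(se_x[i]),
            beta_y=float(beta_y[i]),
            se_y=float(se_y[i]),
            effect_allele="T",
            other_allele="C",
        )
        for i in range(beta_x.size)
    )
    return HarmonizedInstrument(variants=variants)


def random_instrument(rng, n=10, theta=0.3):
    """A random strong-instrument draw with true causal slope ``theta``."""
    beta_x = rng.uniform(0.05, 0.3, n) * rng.choice([-1.0, 1.0], n)
    se_x = rng.uniform(0.005, 0.02, n)
    se_y = rng.uniform(0.005, 0.05, n)
    beta_y = theta * beta_x + rng.normal(0.0, se_y)
    return make_instrument(beta_x, se_x, beta_y, se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
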