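import numpy as np
import pytest

from releff import TwoGroupSample


def make_sample(a, b, d_stack=None):
    """Build a TwoGroupSample from per-group 1-D (or 2-D) value arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
        b = b[:, None]
    values = np.vstack([a, b])
    group = np.array(["A"] * a.shape[0] + ["B"] * b.shape[0])
    return TwoGroupSample(values, group)


def brute_force_relative_effect(a, b):
    """Pairwise-kernel double sum: mean of I{a<b} + 0.5 I{a=b} over all pairs."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(np.mean((a < b) + 0.5 * (a == b)))


def mid_ecdf(sample_values, x):
    """Normalized (mid-) empirical cdf of sample_values evaluated at x."""
    sample_values = np.asarray(sample_values, dtype=float)
    return float((np.sum(sample_values < x) + 0.5 * np.sum(sample_values == x)) / sample_values.size)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_sample(rng):
    """A 5+5, d=3 continuous sample."""
    values = rng.random((10, 3))
    return TwoGroupSample(values, np.array(["A"] * 5 + ["B"] * 5))
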