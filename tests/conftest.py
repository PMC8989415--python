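import numpy as np
import pytest

from ubia import BinaryDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_data():
    """Rows {110, 011, 110}: hand-countable statistics."""
    return BinaryDataset(np.array([[1, 1, 0], [0, 1, 1], [1, 1, 0]], dtype=np.uint8))


@pytest.fixture
def small_random_data(rng):
    """Dense enough that words of order 2-3 occur, M=100, N=8."""
    return BinaryDataset((rng.random((100, 8)) < 0.25).astype(np.uint8))


def exact_loglik(data: BinaryDataset, perturbations: dict) -> float:
    """Independent oracle: exact log-likelihood of the data under the
    log-linear model anchored at the independent null (marginals n_i/M),
    with coefficients of the listed supports perturbed by the given deltas.

    Enumerates all 2^N states; usable for N <= 12 or so.
    """
    M, N = data.M, data.N
    p = data.values.sum(axis=0) / M
    assert np.all((p > 0) & (p < 1)), "oracle needs non-constant columns"
    states = ((np.arange(2 ** N)[:, None] >> np.arange(N)[None, :]) & 1).astype(float)
    logw = states @ np.log(p) + (1 - states) @ np.log(1 - p)
    for sup, delta in perturbations.items():
        logw = logw + delta * states[:, list(sup)].prod(axis=1)
    logZ = np.logaddexp.reduce(logw)
    idx = (data.values.astype(np.int64) * (2 ** np.arange(N))).sum(axis=1)
    return float(logw[idx].sum() - M * logZ)


def richardson_second(f, delta: float = 1e-3):
    """Second derivative of a 1-argument function at 0, Richardson-refined."""

    def second(d):
        return (f(d) - 2.0 * f(0.0) + f(-d)) / d**2

    return (4.0 * second(delta / 2) - second(delta)) / 3.0


def richardson_first(f, delta: float = 1e-3):
    def first(d):
        return (f(d) - f(-d)) / (2.0 * d)

    return (4.0 * first(delta / 2) - first(delta)) / 3.0
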