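"""Empirical counts and null-model moments of binary words.

The null model is the product of marginals matching each unit's empirical
activation frequency n_i/M.  For a word with support V (a set of units), the
relevant quantities are

* the empirical frequency  sigma_bar = n_V / M, where n_V counts samples in
  which every unit of V is 1,
* the null expectation     <sigma_V> = prod_{i in V} n_i / M,
* the null variance        var(sigma_V) = <sigma_V>(1 - <sigma_V>)
  (words are indicators, sigma^2 = sigma), and
* the null covariance of two words, which is nonzero only when their supports
  overlap:  cov = prod_{union} n_k/M - <sigma_V><sigma_W>.

Counting uses exact integer arithmetic; null moments are floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import BinaryDataset, WordSupport

__all__ = [
    "CandidateStat",
    "column_frequencies",
    "word_count",
    "null_expectation",
    "null_variance",
    "null_covariance",
    "flip_majority_columns",
    "constant_units",
    "write_candidate_stats",
]


@dataclass(frozen=True)
class CandidateStat:
    """Moment statistics of one candidate word."""

    support: WordSupport
    n_mu: int
    sigma_bar: float
    null_mean: float
    null_var: float

    @property
    def order(self) -> int:
        return self.support.order

    @property
    def deviation(self) -> float:
        """Empirical frequency minus null expectation (sign = over/under)."""
        return self.sigma_bar - self.null_mean


def column_frequencies(data: BinaryDataset) -> np.ndarray:
    """Per-unit activation counts n_i (length N, integers in [0, M])."""
    return data.values.sum(axis=0, dtype=np.int64)


def word_count(data: BinaryDataset, support: Sequence[int]) -> int:
    """Number of samples in which every unit of ``support`` is 1."""
    sup = support if isinstance(support, WordSupport) else WordSupport(sorted(set(support)))
    if max(sup) >= data.N:
        raise IndexError(f"support {tuple(sup)} out of range for N={data.N}")
    return int(data.values[:, list(sup)].all(axis=1).sum())


def null_expectation(n: np.ndarray, M: int, support: Sequence[int]) -> float:
    """Null-model word probability: product over the support of n_i/M."""
    if M <= 0:
        raise ValueError("M must be positive")
    n = np.asarray(n)
    if np.any(n[list(support)] > M):
        raise ValueError("unit count exceeds sample count M")
    return float(np.prod(n[list(support)] / M))


def null_variance(null_mean: float) -> float:
    """Indicator variance p(1-p) under the null."""
    if not 0.0 <= null_mean <= 1.0:
        raise ValueError(f"null mean {null_mean} outside [0, 1]")
    return float(null_mean * (1.0 - null_mean))


def null_covariance(
    n: np.ndarray, M: int, support_a: Sequence[int], support_b: Sequence[int]
) -> float:
    """Null covariance of two words; exactly 0 for disjoint supports."""
    sa, sb = set(support_a), set(support_b)
    if not sa & sb:
        return 0.0
    union = sorted(sa | sb)
    pa = null_expectation(n, M, sorted(sa))
    pb = null_expectation(n, M, sorted(sb))
    return float(null_expectation(n, M, union) - pa * pb)


def candidate_stat(data: BinaryDataset, support: Sequence[int], n: np.ndarray | None = None) -> CandidateStat:
    """Full moment statistics for one support (reference scalar path)."""
    sup = support if isinstance(support, WordSupport) else WordSupport(support)
    if n is None:
        n = column_frequencies(data)
    cnt = word_count(data, sup)
    mean = null_expectation(n, data.M, sup)
    return CandidateStat(
        support=sup,
        n_mu=cnt,
        sigma_bar=cnt / data.M,
        null_mean=mean,
        null_var=null_variance(mean),
    )


def constant_units(data: BinaryDataset) -> np.ndarray:
    """Boolean mask of units that are constant (n_i = 0 or n_i = M).

    Constant units carry no signal: their null variance is 0 and their fields
    vanish, so they are excluded from candidate supports.
    """
    n = column_frequencies(data)
    return (n == 0) | (n == data.M)


def flip_majority_columns(data: BinaryDataset) -> tuple[BinaryDataset, np.ndarray]:
    """Complement columns whose activation frequency exceeds 1/2.

    Keeps the mean activation q = mean_i n_i/M below 1/2, the regime in which
    the collective effect of absent high-order words on the indicator system
    is provably negligible.  Columns at exactly 1/2 are left unchanged.
    """
    n = column_frequencies(data)
    mask = n / data.M > 0.5
    values = data.values.copy()
    values[:, mask] = 1 - values[:, mask]
    flipped = BinaryDataset(values, list(data.labels), data.flip_mask ^ mask)
    return flipped, mask


def write_candidate_stats(stats: Iterable[CandidateStat], path: str | Path, delimiter: str = ",") -> None:
    """Write candidate statistics as delimited text (supports ';'-joined)."""
    stats = list(stats)
    frame = pd.DataFrame(
        {
            "support": [";".join(map(str, s.support)) for s in stats],
            "n_mu": [s.n_mu for s in stats],
            "sigma_bar": [s.sigma_bar for s in stats],
            "null_mean": [s.null_mean for s in stats],
            "null_var": [s.null_var for s in stats],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)
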