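"""Spike-train / behavior front end for neuro-behavioral dictionaries.

Converts trials of spike times plus one scalar acoustic feature per trial
(e.g. pitch, amplitude, spectral entropy of a song syllable) into the binary
matrix the dictionary pipeline consumes: spikes in the premotor window
(default 40 ms before the feature measurement) are binarized into 2 ms bins
(1 = at least one spike), the behavior is binarized by a median split, a
percentile window, or terciles, and the behavior bit becomes column 0 of an
N = 21-unit dataset.  Words containing column 0 are codewords: spike
patterns predictive of the behavior.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BinaryDataset, WordSupport
from .calibration import Dictionary

__all__ = [
    "TrialSet",
    "EncodingConfig",
    "read_trials",
    "write_trials",
    "binarize_spikes",
    "binarize_behavior",
    "assemble_neurobehavioral",
    "dictionary_statistics",
    "word_isi",
    "make_synthetic_trials",
]

logger = logging.getLogger(__name__)


@dataclass
class TrialSet:
    """Per-trial spike times (ms, negative = before the feature measurement)
    and scalar behavioral features."""

    spikes: list[np.ndarray]
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=np.float64) for s in self.spikes]
        if len(self.spikes) != len(self.features):
            raise ValueError("one feature row per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass(frozen=True)
class EncodingConfig:
    """Binarization parameters.

    bin_width: time resolution in ms (the scale at which spike timing is
        informative for the songbird motor code).
    window: premotor window length in ms; window/bin_width must be integral.
    scheme: 'median' | 'percentile' | 'tercile'.
    lo, hi: percentile bounds for the percentile-window scheme.
    tercile: 0 (low), 1 (medium), 2 (high).
    polarity: with False (default) the median scheme maps above-median to 1;
        True swaps the labels.
    """

    bin_width: float = 2.0
    window: float = 40.0
    scheme: str = "median"
    lo: float = 0.0
    hi: float = 20.0
    tercile: int = 2
    polarity: bool = False

    def __post_init__(self) -> None:
        n = self.window / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must be an integer multiple of bin_width")
        if self.scheme not in ("median", "percentile", "tercile"):
            raise ValueError(f"unknown behavior scheme {self.scheme!r}")
        if not (0 <= self.lo <= self.hi <= 100):
            raise ValueError("percentile bounds must satisfy 0 <= lo <= hi <= 100")
        if self.tercile not in (0, 1, 2):
            raise ValueError("tercile index must be 0, 1 or 2")

    @property
    def n_bins(self) -> int:
        return int(round(self.window / self.bin_width))


def binarize_spikes(trials: TrialSet, config: EncodingConfig) -> np.ndarray:
    """Binary (trials x n_bins) matrix: bin t is 1 iff at least one spike
    falls in [-window + (t-1)*dt, -window + t*dt) (half-open; boundary spikes
    go to the later bin)."""
    n_bins = config.n_bins
    out = np.zeros((trials.n_trials, n_bins), dtype=np.uint8)
    dropped = 0
    for r, s in enumerate(trials.spikes):
        idx = np.floor((s + config.window) / config.bin_width).astype(int)
        inside = (idx >= 0) & (idx < n_bins)
        dropped += int((~inside).sum())
        out[r, idx[inside]] = 1
    if dropped:
        logger.info("%d spikes outside the %g ms window ignored", dropped, config.window)
    return out


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """Nearest-rank percentile: 100 * (# values <= x) / n."""
    values = np.asarray(values, dtype=np.float64)
    order = np.sort(values)
    return 100.0 * np.searchsorted(order, values, side="right") / values.size


def binarize_behavior(values: np.ndarray, config: EncodingConfig) -> np.ndarray:
    """One bit per trial from the scalar behavioral feature."""
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("behavioral values must be finite")
    if np.unique(values).size < 2:
        raise ValueError("behavioral values are all identical; no split possible")
    if config.scheme == "median":
        bits = (values > np.median(values)).astype(np.uint8)
        return (1 - bits) if config.polarity else bits
    pct = _percentile_rank(values)
    if config.scheme == "percentile":
        lo, hi = config.lo, config.hi
    else:
        lo = config.tercile * 100.0 / 3.0
        hi = (config.tercile + 1) * 100.0 / 3.0
    bits = ((pct > lo) | (lo == 0.0)) & (pct <= hi)
    return bits.astype(np.uint8)


def assemble_neurobehavioral(
    behavior_bits: np.ndarray, spike_matrix: np.ndarray, config: EncodingConfig | None = None
) -> BinaryDataset:
    """Stack the behavior bit as column 0 ahead of the time-bin columns."""
    behavior_bits = np.asarray(behavior_bits, dtype=np.uint8)
    spike_matrix = np.asarray(spike_matrix, dtype=np.uint8)
    if behavior_bits.shape[0] != spike_matrix.shape[0]:
        raise ValueError(
            f"{behavior_bits.shape[0]} behavior bits vs {spike_matrix.shape[0]} spike rows"
        )
    values = np.column_stack([behavior_bits, spike_matrix])
    dt = config.bin_width if config else 2.0
    window = config.window if config else dt * spike_matrix.shape[1]
    labels = ["behavior"] + [
        f"bin_{-window + t * dt:g}ms" for t in range(1, spike_matrix.shape[1] + 1)
    ]
    return BinaryDataset(values, labels)


# ---------------------------------------------------------------------------
# dictionary statistics


def word_isi(support: WordSupport, bin_width: float = 2.0) -> float | None:
    """Mean gap (ms) between consecutive active bins of a word's spike part
    (behavior bit excluded); None for words with fewer than two spike bins."""
    bins = [i for i in support if i != 0]
    if len(bins) < 2:
        return None
    gaps = np.diff(sorted(bins))
    return float(np.mean(gaps) * bin_width)


def dictionary_statistics(
    dictionaries: dict[str, list[Dictionary]], bin_width: float = 2.0
) -> dict:
    """Summary statistics across dictionaries grouped by behavioral feature.

    Returns per-spike-order codeword proportions (an m-spike codeword has
    support size m+1 including the behavior bit), mean ISI of codewords vs
    significant non-coding words, cross-feature codeword overlap counts, and
    mean dictionary / codeword counts.
    """
    order_counts: dict[int, int] = {}
    cw_isi, noncw_isi = [], []
    sizes, cw_counts = [], []
    cw_by_feature: dict[str, set] = {}
    for feat, dicts in dictionaries.items():
        cw_sets = set()
        for d in dicts:
            sizes.append(len(d))
            cws = d.codewords
            cw_counts.append(len(cws))
            for e in d.entries:
                isi = word_isi(e.support, bin_width)
                if e.is_codeword:
                    n_spikes = e.support.order - 1
                    order_counts[n_spikes] = order_counts.get(n_spikes, 0) + 1
                    cw_sets.add(tuple(i for i in e.support if i != 0))
                    if isi is not None:
                        cw_isi.append(isi)
                elif isi is not None:
                    noncw_isi.append(isi)
        cw_by_feature[feat] = cw_sets
    total_cw = sum(order_counts.values())
    feats = list(cw_by_feature)
    overlaps = {}
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            overlaps[(feats[i], feats[j])] = len(
                cw_by_feature[feats[i]] & cw_by_feature[feats[j]]
            )
    triple = (
        len(set.intersection(*cw_by_feature.values())) if len(feats) >= 2 else None
    )
    return {
        "mean_dictionary_size": float(np.mean(sizes)) if sizes else 0.0,
        "mean_codewords": float(np.mean(cw_counts)) if cw_counts else 0.0,
        "codeword_order_proportions": {
            k: v / total_cw for k, v in sorted(order_counts.items())
        }
        if total_cw
        else {},
        "mean_isi_codewords": float(np.mean(cw_isi)) if cw_isi else None,
        "mean_isi_noncoding": float(np.mean(noncw_isi)) if noncw_isi else None,
        "pairwise_overlap": {f"{a}&{b}": v for (a, b), v in overlaps.items()},
        "all_feature_overlap": triple,
    }


# ---------------------------------------------------------------------------
# synthetic trial fixtures (no real recordings required)


def make_synthetic_trials(
    n_trials: int = 400,
    codewords: list[tuple[tuple[int, ...], float, float]] | None = None,
    background_rate: float = 0.15,
    rng: np.random.Generator | None = None,
    n_bins: int = 20,
    bin_width: float = 2.0,
) -> TrialSet:
    """Synthetic trials with spike patterns injected conditionally on behavior.

    ``codewords`` lists (spike-bin tuple (1-based column indices), probability
    of injection when the feature is above its median, probability when
    below).  Background spikes are Bernoulli per bin.  Spikes are placed at
    bin centers, so binarization round-trips exactly.  This emulates the
    statistical structure of premotor recordings (sparse spiking, a few
    behavior-locked patterns); it has no refractoriness or rate modulation.
    """
    rng = rng or np.random.default_rng()
    codewords = codewords or []
    window = n_bins * bin_width
    feature = rng.normal(size=n_trials)
    high = feature > np.median(feature)
    spikes = []
    for r in range(n_trials):
        bins = rng.random(n_bins) < background_rate
        for cw_bins, p_hi, p_lo in codewords:
            p = p_hi if high[r] else p_lo
            if rng.random() < p:
                for b in cw_bins:
                    bins[b - 1] = True
        centers = -window + (np.flatnonzero(bins) + 0.5) * bin_width
        spikes.append(centers)
    return TrialSet(spikes=spikes, features=pd.DataFrame({"pitch": feature}))


# ---------------------------------------------------------------------------
# I/O: one row per trial: id, features..., semicolon-joined spike times


def read_trials(path: str | Path, delimiter: str = ",") -> TrialSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trial file: {path}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise ValueError(f"empty trial file: {path}")
    header = rows[0]
    if header[0].strip().lower() != "trial":
        raise ValueError("trial file must start with a header: trial,<features...>,spikes")
    feature_names = [h.strip() for h in header[1:-1]]
    spikes, feats = [], []
    for row in rows[1:]:
        if not row:
            continue
        feats.append([float(x) for x in row[1:-1]])
        cell = row[-1].strip()
        spikes.append(
            np.array([float(x) for x in cell.split(";") if x != ""], dtype=np.float64)
        )
    return TrialSet(spikes=spikes, features=pd.DataFrame(feats, columns=feature_names))


def write_trials(trials: TrialSet, path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["trial"] + trials.feature_names + ["spikes"])
        for i, s in enumerate(trials.spikes):
            writer.writerow(
                [i]
                + [repr(float(v)) for v in trials.features.iloc[i]]
                + [";".join(f"{t:g}" for t in s)]
            )
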