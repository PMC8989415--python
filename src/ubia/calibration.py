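"""Shuffle-null threshold calibration and dictionary extraction.

There is no first-principles magnetization threshold, so it is calibrated
empirically: each unit's column is permuted independently across samples
(destroying all dependence while preserving every marginal count n_i
exactly), the full pipeline is re-run on R such shuffles, and n_false(m) —
the mean number of words whose magnetization exceeds m on shuffled data,
where every detection is false by construction — is mapped out.  Words enter
the dictionary when m_mu > m_star, the smallest threshold keeping n_false at
or below the target (default 0.5: about half a falsely detected word per
dataset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BinaryDataset, WordSupport
from .moments import flip_majority_columns
from .candidates import CandidateConfig, IsingSystem, build_system
from .meanfield import MeanFieldTrajectory, SolverOptions, solve_trajectory

__all__ = [
    "PipelineConfig",
    "CalibrationCurve",
    "DictionaryEntry",
    "Dictionary",
    "shuffle_dataset",
    "false_discovery_curve",
    "threshold_for",
    "extract_dictionary",
    "consistency_check",
    "interaction_pruning_fraction",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end extraction parameters.

    R: number of column shuffles used to map n_false(m).
    n_false_target: admitted false words per dataset at the chosen threshold.
    flip: complement columns more active than 1/2 before analysis (keeps the
        mean activation low so absent high-order words are negligible).
    output_index: unit index of the behavioral/output bit; words containing
        it are flagged as codewords (None: no output bit).
    """

    candidates: CandidateConfig = field(default_factory=CandidateConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    R: int = 100
    n_false_target: float = 0.5
    flip: bool = False
    output_index: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CalibrationCurve:
    """n_false as a non-increasing function of the magnetization threshold."""

    m_grid: np.ndarray       # ascending thresholds
    n_false: np.ndarray      # mean detections above each threshold
    R: int
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.m_grid, "n_false": self.n_false})


@dataclass(frozen=True)
class DictionaryEntry:
    support: WordSupport
    magnetization: float
    field: float
    deviation: float          # sigma_bar - <sigma>; sign gives over/under
    is_codeword: bool

    @property
    def over_represented(self) -> bool:
        return self.deviation > 0


@dataclass
class Dictionary:
    """The irreducible set of significant words for one dataset."""

    entries: list[DictionaryEntry]
    threshold: float
    config: PipelineConfig
    system: IsingSystem | None = None
    trajectory: MeanFieldTrajectory | None = None
    curve: CalibrationCurve | None = None
    flip_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def supports(self) -> list[WordSupport]:
        return [e.support for e in self.entries]

    @property
    def codewords(self) -> list[DictionaryEntry]:
        return [e for e in self.entries if e.is_codeword]

    def to_json_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "config": self.config.to_dict(),
            "entries": [
                {
                    "support": list(e.support),
                    "magnetization": e.magnetization,
                    "field": e.field,
                    "deviation": e.deviation,
                    "over_represented": bool(e.over_represented),
                    "is_codeword": bool(e.is_codeword),
                }
                for e in self.entries
            ],
        }
        if self.trajectory is not None:
            d["eps"] = self.trajectory.diagnostics()
        if self.flip_mask is not None:
            d["flip_mask"] = [bool(x) for x in self.flip_mask]
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "support": [";".join(map(str, e.support)) for e in self.entries],
                "order": [e.support.order for e in self.entries],
                "magnetization": [e.magnetization for e in self.entries],
                "field": [e.field for e in self.entries],
                "over_represented": [e.over_represented for e in self.entries],
                "is_codeword": [e.is_codeword for e in self.entries],
            }
        )


def shuffle_dataset(data: BinaryDataset, rng: np.random.Generator) -> BinaryDataset:
    """Permute each column independently: marginals n_i preserved exactly,
    all inter-column dependence destroyed."""
    values = rng.permuted(data.values, axis=0)
    return BinaryDataset(values, list(data.labels), data.flip_mask.copy())


def _final_magnetizations(data: BinaryDataset, config: PipelineConfig):
    system = build_system(data, config.candidates)
    traj = solve_trajectory(system, data.M, config.solver)
    return system, traj


def false_discovery_curve(
    data: BinaryDataset,
    config: PipelineConfig,
    R: int | None = None,
    rng: np.random.Generator | None = None,
) -> CalibrationCurve:
    """Run the full pipeline on R column-shuffled copies and invert the
    counts of detections into n_false(m) on the grid of observed
    magnetizations."""
    R = R if R is not None else config.R
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = rng or np.random.default_rng()
    all_m: list[np.ndarray] = []
    for _ in range(R):
        shuffled = shuffle_dataset(data, rng)
        _, traj = _final_magnetizations(shuffled, config)
        all_m.append(traj.final_m)
    pooled = np.concatenate(all_m) if all_m else np.zeros(0)
    grid = np.unique(pooled)
    grid = np.concatenate(([-1.0], grid))
    # count of magnetizations strictly above each threshold, averaged over R
    if pooled.size:
        srt = np.sort(pooled)
        above = pooled.size - np.searchsorted(srt, grid, side="right")
    else:
        above = np.zeros(grid.size, dtype=int)
    return CalibrationCurve(m_grid=grid, n_false=above / R, R=R)


def threshold_for(curve: CalibrationCurve, n_false_target: float) -> float:
    """Smallest threshold on the grid with n_false <= target (conservative:
    between grid points the higher one is chosen)."""
    ok = curve.n_false <= n_false_target
    if not ok.any():
        import warnings

        warnings.warn(
            "n_false target unreachable on the calibration grid; "
            "using the maximum observed magnetization", stacklevel=2,
        )
        return float(curve.m_grid[-1])
    return float(curve.m_grid[np.argmax(ok)])


def extract_dictionary(
    data: BinaryDataset,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Dictionary:
    """Full run: optional flip, candidate enumeration + filtering, fields,
    top-n_max selection, mean-field sweep to eps_max, shuffle-calibrated
    threshold, and thresholding into a dictionary."""
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng()
    flip_mask = None
    if config.flip:
        data, flip_mask = flip_majority_columns(data)
    system, traj = _final_magnetizations(data, config)
    curve = false_discovery_curve(data, config, rng=rng)
    m_star = threshold_for(curve, config.n_false_target)
    m_final = traj.final_m
    dev = system.deviation
    entries = [
        DictionaryEntry(
            support=system.supports[i],
            magnetization=float(m_final[i]),
            field=float(system.h[i]),
            deviation=float(dev[i]),
            is_codeword=(
                config.output_index is not None
                and config.output_index in system.supports[i]
            ),
        )
        for i in np.flatnonzero(m_final > m_star)
    ]
    entries.sort(key=lambda e: -e.magnetization)
    return Dictionary(
        entries=entries, threshold=m_star, config=config,
        system=system, trajectory=traj, curve=curve, flip_mask=flip_mask,
    )


def consistency_check(dict_a: Dictionary, dict_b: Dictionary) -> int:
    """Count codeword supports anomalous in the same direction in two
    dictionaries built with complementary output labels.

    The same spike pattern cannot code for a feature being simultaneously
    above and below its median, so such coincidences estimate the false
    discovery rate on real data.
    """
    if dict_a.config.candidates != dict_b.config.candidates or (
        dict_a.config.output_index != dict_b.config.output_index
    ):
        raise ValueError("dictionaries built with mismatched configurations")
    signs_a = {e.support: e.over_represented for e in dict_a.codewords}
    count = 0
    for e in dict_b.codewords:
        if e.support in signs_a and signs_a[e.support] == e.over_represented:
            count += 1
    return count


def interaction_pruning_fraction(
    system: IsingSystem,
    trajectory: MeanFieldTrajectory,
    dictionary: Dictionary,
) -> float | None:
    """Fraction of candidates whose field exceeds the smallest field of any
    retained dictionary word yet were excluded by the exchange interactions.

    Dictionary words always carry positive fields, and without couplings the
    magnetization is monotone in h, so this fraction is exactly 0 for J = 0;
    a positive value measures how strongly word-word competition pruned the
    dictionary.  Returns None for an empty dictionary (undefined).
    """
    if len(dictionary) == 0:
        return None
    retained = set(dictionary.supports)
    min_h = min(e.field for e in dictionary.entries)
    large = [i for i in range(system.size) if system.h[i] > min_h]
    if not large:
        return 0.0
    removed = sum(1 for i in large if system.supports[i] not in retained)
    return removed / len(large)
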