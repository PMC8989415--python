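"""Binary dataset container and delimited-text I/O.

A dataset is an M x N matrix of {0, 1} entries: M samples (trials, rows) of N
binary units (time bins, mutations, ... columns).  All downstream statistics
are computed against the independent null model that matches each unit's
marginal activation frequency ``n_i / M``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["BinaryDataset", "WordSupport", "read_binary_matrix", "write_binary_matrix"]


class WordSupport(tuple):
    """A word: a nonempty, strictly increasing set of unit indices.

    Behaves as a plain tuple of ints; ``order`` is the number of units.
    """

    __slots__ = ()

    def __new__(cls, indices: Sequence[int]) -> "WordSupport":
        idx = tuple(int(i) for i in indices)
        if len(idx) == 0:
            raise ValueError("word support must be nonempty")
        if any(i < 0 for i in idx):
            raise ValueError(f"negative unit index in support {idx}")
        if any(a >= b for a, b in zip(idx, idx[1:])):
            raise ValueError(f"support indices must be strictly increasing, got {idx}")
        return super().__new__(cls, idx)

    @property
    def order(self) -> int:
        return len(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"WordSupport{tuple(self)}"


def _validate_binary(values: np.ndarray) -> None:
    bad = (values != 0) & (values != 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary entry {values[r, c]!r} at row {r}, column {c}; "
            "entries must be exactly 0 or 1"
        )


@dataclass
class BinaryDataset:
    """M x N binary matrix with unit labels and an optional relabeling mask.

    ``flip_mask[i]`` is True when unit i was complemented (sigma -> 1 - sigma)
    by :func:`ubia.moments.flip_majority_columns`; supports reported downstream
    refer to the (possibly flipped) columns, and the mask lets reports map them
    back to the original polarity.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    flip_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("dataset must have M >= 1 samples and N >= 1 units")
        _validate_binary(self.values)
        self.values = self.values.astype(np.uint8, copy=False)
        if not self.labels:
            self.labels = [f"u{i}" for i in range(self.N)]
        if len(self.labels) != self.N:
            raise ValueError(f"{len(self.labels)} labels for {self.N} units")
        if self.flip_mask is None:
            self.flip_mask = np.zeros(self.N, dtype=bool)
        else:
            self.flip_mask = np.asarray(self.flip_mask, dtype=bool)
            if self.flip_mask.shape != (self.N,):
                raise ValueError("flip_mask length must equal N")

    @property
    def M(self) -> int:
        return int(self.values.shape[0])

    @property
    def N(self) -> int:
        return int(self.values.shape[1])

    def copy(self) -> "BinaryDataset":
        return BinaryDataset(
            self.values.copy(), list(self.labels), self.flip_mask.copy()
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if "\t" in sample.splitlines()[0]:
        return "\t"
    return ","


def read_binary_matrix(path: str | Path, delimiter: str | None = None) -> BinaryDataset:
    """Read a delimited {0,1} matrix, one sample per row.

    A header row of unit labels is detected when the first row contains any
    non-numeric field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input file: {path}")
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim) if row]
    if not rows:
        raise ValueError(f"empty input file: {path}")

    def _numeric(row: list[str]) -> bool:
        try:
            [float(x) for x in row]
            return True
        except ValueError:
            return False

    labels: list[str] = []
    if not _numeric(rows[0]):
        labels = [x.strip() for x in rows[0]]
        rows = rows[1:]
    try:
        values = np.array([[float(x) for x in row] for row in rows])
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    if not np.array_equal(values, values.astype(int)):
        raise ValueError(f"non-integer entries in {path}; matrix must be binary")
    return BinaryDataset(values.astype(np.uint8), labels)


def write_binary_matrix(data: BinaryDataset, path: str | Path, delimiter: str = ",", header: bool = True) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if header:
            writer.writerow(data.labels)
        for row in data.values:
            writer.writerow([int(x) for x in row])
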