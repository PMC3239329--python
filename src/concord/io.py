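"""Data containers and delimited-text input for multi-experiment significance matrices.

A study is represented by a feature-by-experiment matrix: one row per feature
(typically a gene or probe set), one column per experiment, and each cell
holding a p-value — or any ranking measure the user has mapped onto a common
[0, 1] scale where small means significant.  The number of experiments ``L``
is always inferred from the number of numeric columns; it is never a user
parameter.

All downstream statistics are evaluated on a grid of significance thresholds
``h`` on the unit interval; :func:`make_grid` builds that grid.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PValueMatrix",
    "ThresholdGrid",
    "MatrixValidationError",
    "GridError",
    "read_pvalue_matrix",
    "make_grid",
]


class MatrixValidationError(ValueError):
    """Raised when an input matrix violates the p-value matrix contract."""


class GridError(ValueError):
    """Raised for an invalid threshold-grid specification."""


@dataclass
class PValueMatrix:
    """An ``n x L`` matrix of ranking measures in [0, 1] with feature identifiers.

    Parameters
    ----------
    feature_ids
        Unique identifier per row (e.g. probe-set IDs).  Row order is
        whatever the input file used; no sorting is ever performed.
    values
        ``n x L`` float array, every entry in [0, 1], no missing values.
    experiment_names
        One name per column.
    """

    feature_ids: np.ndarray
    values: np.ndarray
    experiment_names: list[str]

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.experiment_names = [str(c) for c in self.experiment_names]
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")
        n, L = self.values.shape
        if L < 2:
            raise MatrixValidationError(
                f"need at least 2 experiment columns, found {L}"
            )
        if len(self.experiment_names) != L:
            raise MatrixValidationError(
                f"{len(self.experiment_names)} experiment names for {L} columns"
            )
        if len(self.feature_ids) != n:
            raise MatrixValidationError(
                f"{len(self.feature_ids)} feature ids for {n} rows"
            )
        if pd.unique(self.feature_ids).size != n:
            dupes = pd.Series(self.feature_ids)
            dupes = dupes[dupes.duplicated()].unique()
            raise MatrixValidationError(
                f"duplicate feature ids: {', '.join(map(str, dupes[:5]))}"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"missing or non-finite value at feature {self.feature_ids[r]!r}, "
                f"column {self.experiment_names[c]!r}"
            )
        out = (self.values < 0) | (self.values > 1)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise MatrixValidationError(
                f"value {self.values[r, c]} outside [0, 1] at feature "
                f"{self.feature_ids[r]!r}, column {self.experiment_names[c]!r}"
            )

    @property
    def n(self) -> int:
        """Total number of features."""
        return self.values.shape[0]

    @property
    def L(self) -> int:
        """Number of experiments (lists)."""
        return self.values.shape[1]

    def to_frame(self, id_name: str = "Name") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.experiment_names)
        df.insert(0, id_name, self.feature_ids)
        return df

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class ThresholdGrid:
    """A strictly increasing sequence of thresholds in (0, 1]."""

    h_values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "h_values", np.asarray(self.h_values, dtype=float))
        h = self.h_values
        if h.size < 1:
            raise GridError("grid must contain at least one threshold")
        if (h <= 0).any() or (h > 1).any():
            raise GridError("thresholds must lie in (0, 1]")
        if h.size > 1 and not (np.diff(h) > 0).all():
            raise GridError("thresholds must be strictly increasing")

    @property
    def H(self) -> int:
        return self.h_values.size

    def __len__(self) -> int:
        return self.H

    def index_of(self, h: float) -> int:
        """Index of threshold ``h`` on the grid (nearest within half a step)."""
        i = int(np.argmin(np.abs(self.h_values - h)))
        if abs(self.h_values[i] - h) > self.step / 2 + 1e-12:
            raise GridError(f"threshold {h} is not on the grid")
        return i


def make_grid(start: float = 0.01, stop: float = 1.0, step: float = 0.01) -> ThresholdGrid:
    """Build the arithmetic threshold grid ``start, start+step, ... <= stop``.

    The default 0.01..1.00 in steps of 0.01 gives the conventional
    100-threshold scan of the probability scale.
    """
    if step <= 0:
        raise GridError(f"step must be positive, got {step}")
    if not (0 < start <= stop <= 1):
        raise GridError(f"need 0 < start <= stop <= 1, got start={start}, stop={stop}")
    count = int(np.floor((stop - start) / step + 1e-9)) + 1
    # Rounding kills the float drift of repeated addition (0.01 * 99 != 0.99).
    h = np.round(start + step * np.arange(count), 12)
    h = h[h <= stop + 1e-12]
    return ThresholdGrid(h_values=h, step=float(step))


def read_pvalue_matrix(
    path: str | Path,
    delimiter: str = ",",
    id_column: int | str = 0,
    drop_missing: bool = False,
) -> PValueMatrix:
    """Read a feature-by-experiment p-value matrix from delimited text.

    The file must have a header row naming the experiments and one
    identifier column (by default the first).  Every other column must be
    numeric and is taken as one experiment; at least two are required.

    Parameters
    ----------
    path
        Input CSV/TSV file.
    delimiter
        Field separator, ``","`` by default.
    id_column
        Name or positional index of the feature-identifier column.
    drop_missing
        If true, rows with any missing cell are dropped (with a logged
        count) instead of raising.  The statistics need every feature
        classified in every list, so partial rows cannot be used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=0, skipinitialspace=True)
    if isinstance(id_column, str):
        if id_column not in df.columns:
            raise MatrixValidationError(f"id column {id_column!r} not found in {path}")
        id_name = id_column
    else:
        id_name = df.columns[id_column]
    value_cols = [c for c in df.columns if c != id_name]
    if len(value_cols) < 2:
        raise MatrixValidationError(
            f"{path}: found {len(value_cols)} experiment column(s); at least 2 required"
        )
    ids = df[id_name].astype(str).to_numpy(dtype=object)
    vals = pd.DataFrame(index=df.index)
    for c in value_cols:
        try:
            vals[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise MatrixValidationError(
                f"{path}: column {c!r} contains a non-numeric value ({exc})"
            ) from exc
    arr = vals.to_numpy(dtype=float)
    missing = ~np.isfinite(arr)
    if missing.any():
        if drop_missing:
            keep = ~missing.any(axis=1)
            dropped = int((~keep).sum())
            logger.warning("dropping %d row(s) with missing values", dropped)
            ids, arr = ids[keep], arr[keep]
        else:
            r, c = np.argwhere(missing)[0]
            raise MatrixValidationError(
                f"{path}: missing value at feature {ids[r]!r}, column "
                f"{value_cols[c]!r} (pass drop_missing=True to drop such rows)"
            )
    return PValueMatrix(feature_ids=ids, values=arr, experiment_names=value_cols)
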