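"""Association-ratio curve T(h) and its Monte Carlo permutation test.

At a significance threshold ``h`` a feature is *called* in list ``l`` when
its value is ``<= h``.  With marginal counts ``O_l(h)`` per list and a common
count ``O(h)`` (called in every list), independence of the lists would put

    E(h) = n * prod_l (O_l(h) / n) = prod_l O_l(h) / n**(L-1)

features in common by chance.  The association ratio

    T(h) = O(h) / E(h)

measures how strongly the lists agree; working with the ratio over the whole
threshold grid avoids committing to a single significance cutoff up front.
The ordinal statistic ``T(h_max) = max_h T(h)`` is the maximal deviation from
independence, and it is tested by permutation: the first list is held fixed
while every other column is independently shuffled across features, which
preserves all marginal counts but destroys any relation between the lists.
Each replicate contributes its own curve maximum, a draw from the null
distribution of T(h_max).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PValueMatrix, ThresholdGrid, make_grid

__all__ = [
    "RatioCurve",
    "MaxStatistic",
    "PermutationResult",
    "DegenerateCurveError",
    "count_at_threshold",
    "expected_common",
    "ratio_statistic",
    "ratio_curve",
    "find_hmax",
    "mc_pvalue",
    "permutation_test",
]


class DegenerateCurveError(ValueError):
    """Raised when T(h) is undefined at every threshold of a curve."""


@dataclass
class RatioCurve:
    """Per-threshold counts and the association ratio.

    ``T`` is NaN wherever the expected count is zero (some marginal empty);
    such thresholds carry no information and are excluded from maximization.
    """

    h_values: np.ndarray
    marginal_counts: np.ndarray  # H x L
    common_count: np.ndarray  # H
    expected_count: np.ndarray  # H
    T: np.ndarray  # H, NaN where undefined
    n: int
    L: int
    experiment_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.experiment_names or [f"list{l + 1}" for l in range(self.L)]
        df = pd.DataFrame({"h": self.h_values})
        for l, name in enumerate(names):
            df[f"DE_{name}"] = self.marginal_counts[:, l]
        df["common"] = self.common_count
        df["expected"] = self.expected_count
        df["T"] = self.T
        return df

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class MaxStatistic:
    """The maximum of T over the grid and where it occurs."""

    h_max: float
    T_max: float
    common_at_hmax: int
    index: int  # position of h_max on the grid


@dataclass
class PermutationResult:
    """Null max-statistics from B column permutations and the Monte Carlo p."""

    B: int
    null_max: np.ndarray
    p_value: float
    T_max_observed: float
    seed: int | None

    @property
    def p_display(self) -> str:
        """Human-readable p-value; an empirical 0 prints as '< 1/B'."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.B:g}"
        return f"{self.p_value:g}"


def count_at_threshold(P: PValueMatrix, h: float) -> tuple[np.ndarray, int]:
    """Marginal counts per list and the common count at one threshold.

    A feature is counted in list ``l`` when ``p_l <= h`` (inclusive), and in
    the common count when that holds in every list.
    """
    if not 0 < h <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {h}")
    called = P.values <= h
    marginals = called.sum(axis=0).astype(int)
    common = int(called.all(axis=1).sum())
    return marginals, common


def expected_common(marginals: Sequence[int], n: int) -> float:
    """Expected common count under independence: ``prod(marginals) / n**(L-1)``.

    For two lists this is the familiar ``O_1+ * O_+1 / n``.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    m = np.asarray(marginals, dtype=float)
    if (m < 0).any() or (m > n).any():
        raise ValueError("marginal counts must lie in [0, n]")
    return float(np.prod(m) / n ** (len(m) - 1))


def ratio_statistic(common: int, expected: float) -> float:
    """Observed/expected ratio; NaN when the expectation is zero."""
    if expected < 0 or common < 0:
        raise ValueError("counts must be non-negative")
    if expected == 0:
        return float("nan")
    return common / expected


def ratio_curve(P: PValueMatrix, grid: ThresholdGrid | None = None) -> RatioCurve:
    """Evaluate counts, expectations and T(h) on the whole threshold grid.

    Equivalent to applying :func:`count_at_threshold` at every ``h`` but
    vectorized through per-column sorting: the marginal count at ``h`` is the
    number of sorted values ``<= h``, and the common count is the same with
    the per-feature maximum across lists.
    """
    if grid is None:
        grid = make_grid()
    h = grid.h_values
    sorted_cols = np.sort(P.values, axis=0)
    marginals = np.empty((grid.H, P.L), dtype=int)
    for l in range(P.L):
        marginals[:, l] = np.searchsorted(sorted_cols[:, l], h, side="right")
    row_max = np.sort(P.values.max(axis=1))
    common = np.searchsorted(row_max, h, side="right").astype(int)
    expected = marginals.prod(axis=1, dtype=float) / P.n ** (P.L - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(expected > 0, common / expected, np.nan)
    return RatioCurve(
        h_values=h.copy(),
        marginal_counts=marginals,
        common_count=common,
        expected_count=expected,
        T=T,
        n=P.n,
        L=P.L,
        experiment_names=list(P.experiment_names),
    )


def find_hmax(curve: RatioCurve) -> MaxStatistic:
    """Locate the maximum of T(h); ties broken toward the smallest h."""
    T = curve.T
    defined = np.isfinite(T)
    if not defined.any():
        raise DegenerateCurveError("T(h) is undefined at every threshold")
    T_max = np.nanmax(T)
    idx = int(np.flatnonzero(defined & (T == T_max))[0])
    return MaxStatistic(
        h_max=float(curve.h_values[idx]),
        T_max=float(T_max),
        common_at_hmax=int(curve.common_count[idx]),
        index=idx,
    )


def mc_pvalue(null_max: np.ndarray, t_observed: float) -> float:
    """Monte Carlo p-value: fraction of null maxima >= the observed maximum."""
    null_max = np.asarray(null_max, dtype=float)
    if null_max.size == 0:
        raise ValueError("need at least one null replicate")
    return float(np.mean(null_max >= t_observed))


def permutation_test(
    P: PValueMatrix,
    grid: ThresholdGrid | None = None,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Monte Carlo permutation test of T(h_max).

    The first column stays fixed; each of the other columns is independently
    permuted across features in every replicate, so the replicate curves
    sample the null of independent lists with the observed marginals.  Each
    replicate is re-maximized over the grid, and the p-value is the fraction
    of replicate maxima at least as large as the observed T(h_max).

    Permutation changes only the common count — every marginal count, and
    hence the expected count, is invariant — which is what makes the
    replicate loop cheap.
    """
    if B < 1:
        raise ValueError(f"B must be at least 1, got {B}")
    if grid is None:
        grid = make_grid()
    if rng is None:
        rng = np.random.default_rng(seed)
    observed_curve = ratio_curve(P, grid)
    observed = find_hmax(observed_curve)
    expected = observed_curve.expected_count
    positive = expected > 0
    h = grid.h_values
    cols = [np.ascontiguousarray(P.values[:, l]) for l in range(P.L)]
    null_max = np.empty(B, dtype=float)
    for b in range(B):
        row_max = cols[0]
        for l in range(1, P.L):
            row_max = np.maximum(row_max, rng.permutation(cols[l]))
        common_b = np.searchsorted(np.sort(row_max), h, side="right")
        Tb = common_b[positive] / expected[positive]
        null_max[b] = Tb.max()
    return PermutationResult(
        B=B,
        null_max=null_max,
        p_value=mc_pvalue(null_max, observed.T_max),
        T_max_observed=observed.T_max,
        seed=seed,
    )
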