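"""Multinomial-Dirichlet model of the joint significance table and the ratio R(h).

At each threshold ``h`` every feature falls into one of ``2**L`` cells
according to its pattern of calls (``p_l <= h`` per list); the cell counts
are modelled as a single multinomial draw with a conjugate symmetric
Dirichlet prior.  The quantity of interest is

    R(h) = p_all / prod_l m_l,

the probability that a feature is significant in *every* list divided by the
product of its marginal significance probabilities — the probability a
feature would enter the common list by chance under independence.  R is the
Bayesian counterpart of the frequentist ratio T, but it propagates the
uncertainty on all the counts: conjugacy makes the posterior a single
Dirichlet from which R is sampled directly, giving credible intervals at
every threshold.

Two decision rules select a reporting threshold from the posterior summaries:

* ``h_max`` — the threshold maximizing the posterior median of R among
  thresholds whose credible interval excludes 1 (high specificity);
* ``h_2`` — the largest threshold where the median of R is at least 2, i.e.
  where the common list is at least double its chance expectation (a balance
  of specificity and sensitivity).  Either rule can be inapplicable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PValueMatrix, ThresholdGrid

logger = logging.getLogger(__name__)

__all__ = [
    "JointCellTable",
    "PosteriorSummary",
    "BayesRules",
    "joint_cells",
    "two_list_cells",
    "r_statistic",
    "posterior_draws",
    "summarize_posterior",
    "posterior_curve",
    "apply_rules",
]

DEFAULT_LEVELS = (0.025, 0.5, 0.975)


@dataclass
class JointCellTable:
    """Counts of the ``2**L`` significance patterns at one threshold.

    Cell ``k`` holds the number of features whose pattern has bit ``l`` set
    (``k >> l & 1``) exactly when the feature is called in list ``l``.  The
    all-ones cell ``2**L - 1`` is the common count; the all-zeros cell holds
    the features significant nowhere.
    """

    h: float
    cells: np.ndarray
    n: int
    L: int

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.size != 2**self.L:
            raise ValueError(f"expected {2**self.L} cells, got {self.cells.size}")
        if (self.cells < 0).any():
            raise ValueError("cell counts must be non-negative")
        if self.cells.sum() != self.n:
            raise ValueError(
                f"cells sum to {self.cells.sum()}, expected n = {self.n}"
            )

    @property
    def common(self) -> int:
        """Count of features significant in every list."""
        return int(self.cells[-1])

    def marginal(self, l: int) -> int:
        """Count of features significant in list ``l`` (any pattern with bit l)."""
        idx = np.arange(2**self.L)
        return int(self.cells[(idx >> l) & 1 == 1].sum())

    @property
    def marginals(self) -> np.ndarray:
        return np.array([self.marginal(l) for l in range(self.L)])


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior quantiles of R at one threshold."""

    h: float
    quantiles: dict[float, float]
    n_draws: int
    excludes_one: bool
    n_dropped: int = 0

    @property
    def median(self) -> float:
        return self.quantiles[0.5]

    @property
    def lower(self) -> float:
        return self.quantiles[min(self.quantiles)]

    @property
    def upper(self) -> float:
        return self.quantiles[max(self.quantiles)]


@dataclass(frozen=True)
class BayesRules:
    """Thresholds selected by the two posterior decision rules (None = n/a)."""

    h_max_bayes: float | None
    R_at_hmax: float | None
    h2: float | None
    R_at_h2: float | None


def joint_cells(P: PValueMatrix, h: float) -> JointCellTable:
    """Tally each feature's L-bit significance pattern at threshold ``h``."""
    if not 0 < h <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {h}")
    called = P.values <= h
    pattern = (called.astype(np.int64) << np.arange(P.L)).sum(axis=1)
    cells = np.bincount(pattern, minlength=2**P.L)
    return JointCellTable(h=h, cells=cells, n=P.n, L=P.L)


def two_list_cells(common: int, marginal1: int, marginal2: int, n: int, h: float = float("nan")) -> JointCellTable:
    """Build the 4-cell table of a two-list study from its published counts.

    Useful when only the common count, the two marginal counts and the total
    are reported: the cells are (common, only-list-1, only-list-2, neither).
    """
    cells = np.array(
        [
            n - marginal1 - marginal2 + common,  # pattern 00
            marginal1 - common,  # pattern 10 (list 1 only)
            marginal2 - common,  # pattern 01 (list 2 only)
            common,  # pattern 11
        ]
    )
    return JointCellTable(h=h, cells=cells, n=n, L=2)


def r_statistic(p: np.ndarray) -> np.ndarray | float:
    """R = p(all lists) / prod of marginal probabilities.

    Accepts a single probability vector over the ``2**L`` patterns or a batch
    with the cell axis last.  Returns NaN wherever a marginal probability is
    zero (R carries no information there).
    """
    p = np.asarray(p, dtype=float)
    K = p.shape[-1]
    L = int(np.log2(K))
    if 2**L != K:
        raise ValueError(f"cell axis length {K} is not a power of two")
    idx = np.arange(K)
    denom = np.ones(p.shape[:-1], dtype=float)
    for l in range(L):
        denom = denom * p[..., (idx >> l) & 1 == 1].sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, p[..., -1] / denom, np.nan)
    return float(R) if R.ndim == 0 else R


def posterior_draws(
    table: JointCellTable,
    alpha: float = 1.0,
    n_draws: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample R from the conjugate posterior of the cell probabilities.

    With a symmetric Dirichlet(alpha) prior the posterior is
    Dirichlet(cells + alpha); each sampled probability vector is mapped
    through :func:`r_statistic`.  Draws with a zero sampled marginal (only
    possible for empty cells with a tiny ``alpha``) are dropped with a
    logged count.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_draws < 1:
        raise ValueError(f"n_draws must be at least 1, got {n_draws}")
    if rng is None:
        rng = np.random.default_rng(seed)
    concentration = table.cells + alpha
    draws = r_statistic(rng.dirichlet(concentration, size=n_draws))
    bad = ~np.isfinite(draws)
    if bad.any():
        logger.warning("dropping %d draw(s) with a degenerate marginal", bad.sum())
        draws = draws[~bad]
    return draws


def summarize_posterior(
    draws: np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    h: float = float("nan"),
) -> PosteriorSummary:
    """Empirical posterior quantiles of R at the requested levels.

    Quantiles use linear interpolation of order statistics.  The interval
    is judged against 1 with the outermost requested levels.
    """
    draws = np.asarray(draws, dtype=float)
    finite = np.isfinite(draws)
    n_dropped = int((~finite).sum())
    draws = draws[finite]
    if draws.size == 0:
        raise ValueError("no finite draws to summarize")
    levels = sorted(float(q) for q in levels)
    values = np.quantile(draws, levels)
    quantiles = dict(zip(levels, map(float, values)))
    lower, upper = quantiles[levels[0]], quantiles[levels[-1]]
    return PosteriorSummary(
        h=h,
        quantiles=quantiles,
        n_draws=int(draws.size),
        excludes_one=bool(lower > 1.0 or upper < 1.0),
        n_dropped=n_dropped,
    )


def posterior_curve(
    P: PValueMatrix,
    grid: ThresholdGrid,
    alpha: float = 1.0,
    n_draws: int = 1000,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int | None = None,
) -> list[PosteriorSummary]:
    """Posterior summary of R at every threshold of the grid.

    Each threshold is analysed marginally with its own independent stream of
    posterior draws (streams are spawned from ``seed``, so the whole curve is
    reproducible).
    """
    streams = np.random.SeedSequence(seed).spawn(grid.H)
    out = []
    for h, ss in zip(grid.h_values, streams):
        table = joint_cells(P, float(h))
        draws = posterior_draws(
            table, alpha=alpha, n_draws=n_draws, rng=np.random.default_rng(ss)
        )
        out.append(summarize_posterior(draws, levels=levels, h=float(h)))
    return out


def apply_rules(summaries: Sequence[PosteriorSummary]) -> BayesRules:
    """Select thresholds by the two posterior decision rules.

    Rule 1 (``h_max``): among thresholds whose credible interval excludes 1,
    the one maximizing the posterior median (smallest h on a tie).  Rule 2
    (``h_2``): the largest threshold with median >= 2.  A rule that cannot be
    satisfied is reported as None (not applicable).
    """
    h_max_bayes = R_at_hmax = None
    best = -np.inf
    for s in summaries:
        if s.excludes_one and np.isfinite(s.median) and s.median > best:
            best = s.median
            h_max_bayes, R_at_hmax = s.h, s.median
    h2 = R_at_h2 = None
    for s in summaries:
        if np.isfinite(s.median) and s.median >= 2.0:
            if h2 is None or s.h > h2:
                h2, R_at_h2 = s.h, s.median
    return BayesRules(h_max_bayes=h_max_bayes, R_at_hmax=R_at_hmax, h2=h2, R_at_h2=R_at_h2)
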