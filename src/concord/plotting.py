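"""Diagnostic plots: the T(h) curve, the permutation null, and R(h) intervals."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayesian import BayesRules, PosteriorSummary
from .frequentist import MaxStatistic, PermutationResult, RatioCurve

__all__ = ["plot_ratio_curve", "plot_null_histogram", "plot_posterior_intervals"]


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_ratio_curve(
    curve: RatioCurve, maxstat: MaxStatistic | None, path: str | Path
) -> None:
    """T(h) against the threshold, with T(h_max) marked by a dotted line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.h_values, curve.T, lw=1.2, color="tab:blue")
    if maxstat is not None:
        ax.axhline(maxstat.T_max, ls=":", color="k", lw=0.8)
        ax.annotate(
            f"T(h_max) = {maxstat.T_max:.2f} at h = {maxstat.h_max:g} "
            f"({maxstat.common_at_hmax} in common)",
            xy=(maxstat.h_max, maxstat.T_max),
            xytext=(5, 5),
            textcoords="offset points",
            fontsize=8,
        )
    ax.set_xlabel("threshold h")
    ax.set_ylabel("T(h)")
    _save(fig, path)


def plot_null_histogram(result: PermutationResult, path: str | Path) -> None:
    """Histogram of the permutation null maxima with the observed value marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.null_max, bins=30, color="lightgray", edgecolor="gray")
    ax.axvline(result.T_max_observed, ls=":", color="k")
    ax.set_xlabel("Tb(h_max) under independence")
    ax.set_ylabel("count")
    ax.set_title(f"p {result.p_display} ({result.B} permutations)", fontsize=9)
    _save(fig, path)


def plot_posterior_intervals(
    summaries: Sequence[PosteriorSummary],
    rules: BayesRules | None,
    path: str | Path,
) -> None:
    """Posterior median of R(h) with its credible band and rule thresholds."""
    h = np.array([s.h for s in summaries])
    med = np.array([s.median for s in summaries])
    lo = np.array([s.lower for s in summaries])
    hi = np.array([s.upper for s in summaries])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(h, lo, hi, color="tab:blue", alpha=0.2, label="credible interval")
    ax.plot(h, med, color="tab:blue", lw=1.2, label="median R(h)")
    ax.axhline(1.0, color="gray", lw=0.8)
    if rules is not None:
        if rules.h_max_bayes is not None:
            ax.axvline(rules.h_max_bayes, ls=":", color="k", lw=0.8)
        if rules.h2 is not None:
            ax.axvline(rules.h2, ls="--", color="k", lw=0.8)
    ax.set_xlabel("threshold h")
    ax.set_ylabel("R(h)")
    ax.legend(fontsize=8)
    _save(fig, path)
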