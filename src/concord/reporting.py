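"""Summary tables and common-feature extraction.

Combines the frequentist curve and the Bayesian per-threshold summaries into
one decision table (one row per applicable rule) and extracts the list of
features significant in every experiment at a chosen threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayesian import BayesRules, PosteriorSummary
from .frequentist import MaxStatistic, RatioCurve
from .io import PValueMatrix

__all__ = [
    "ConsistencyError",
    "DecisionReport",
    "CommonFeatureList",
    "create_table",
    "extract_features",
]


class ConsistencyError(ValueError):
    """Raised when report inputs were not computed on the same matrix/grid."""


@dataclass
class DecisionReport:
    """One row per decision rule, with full-precision values.

    Columns: ``rule``, ``h``, ``T`` (frequentist rows only), ``R_median``,
    ``ci_low``, ``ci_high``, ``common`` and one significant-count column per
    experiment.  :meth:`display` renders the conventional 2-decimal view.
    """

    table: pd.DataFrame
    ci_levels: tuple[float, float]

    def display(self) -> pd.DataFrame:
        """Rounded (2 d.p.) presentation copy with a combined CI column."""
        df = self.table.copy()
        for col in ("T", "R_median"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        df["CI"] = [
            "" if pd.isna(lo) else f"{lo:.2f} - {hi:.2f}"
            for lo, hi in zip(self.table["ci_low"], self.table["ci_high"])
        ]
        return df.drop(columns=["ci_low", "ci_high"])

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.table.to_csv(path, sep=delimiter, index=False)


@dataclass
class CommonFeatureList:
    """Features significant in every list at ``threshold``, with their p-values."""

    rule: str
    threshold: float
    frame: pd.DataFrame  # Name + one p-value column per experiment, ID-sorted

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_ids(self) -> list[str]:
        return self.frame.iloc[:, 0].tolist()

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        # Scientific notation keeps tiny p-values legible, as in the
        # conventional extracted-feature listings.
        self.frame.to_csv(
            path, sep=delimiter, index=False, float_format="%.6e"
        )


def _summary_at(
    summaries: Sequence[PosteriorSummary], h: float
) -> PosteriorSummary | None:
    for s in summaries:
        if np.isclose(s.h, h, atol=1e-9):
            return s
    return None


def create_table(
    curve: RatioCurve,
    maxstat: MaxStatistic,
    summaries: Sequence[PosteriorSummary],
    rules: BayesRules,
    extra_h: Sequence[float] | None = None,
) -> DecisionReport:
    """Assemble the decision table from the two analyses.

    Rows: the frequentist ``h_max`` (always; carries T and, when the
    Bayesian rule lands on the same threshold, the posterior columns), a
    separate Bayesian ``h_max`` row when the two rules disagree, the ``h_2``
    row when rule 2 applies, and any user-supplied extra thresholds.  All
    values are carried over from the inputs — nothing is recomputed.
    """
    if len(summaries) != curve.h_values.size or not np.allclose(
        [s.h for s in summaries], curve.h_values
    ):
        raise ConsistencyError(
            "posterior summaries were not computed on the ratio curve's grid"
        )
    some = summaries[0]
    levels = sorted(some.quantiles)
    ci_levels = (levels[0], levels[-1])
    names = curve.experiment_names or [f"list{l + 1}" for l in range(curve.L)]

    def row(rule: str, h: float, with_T: bool) -> dict:
        i = int(np.flatnonzero(np.isclose(curve.h_values, h, atol=1e-9))[0])
        s = _summary_at(summaries, h)
        r: dict = {
            "rule": rule,
            "h": float(h),
            "T": float(curve.T[i]) if with_T else np.nan,
            "R_median": s.median if s else np.nan,
            "ci_low": s.lower if s else np.nan,
            "ci_high": s.upper if s else np.nan,
            "common": int(curve.common_count[i]),
        }
        for l, name in enumerate(names):
            r[f"DE_{name}"] = int(curve.marginal_counts[i, l])
        return r

    rows = []
    bayes_same = rules.h_max_bayes is not None and np.isclose(
        rules.h_max_bayes, maxstat.h_max, atol=1e-9
    )
    label = "h_max (freq & Bayesian)" if bayes_same else "h_max (frequentist)"
    rows.append(row(label, maxstat.h_max, with_T=True))
    if rules.h_max_bayes is not None and not bayes_same:
        rows.append(row("h_max (Bayesian)", rules.h_max_bayes, with_T=False))
    if rules.h2 is not None:
        rows.append(row("h_2", rules.h2, with_T=False))
    for h in extra_h or ():
        rows.append(row(f"h = {h:g}", float(h), with_T=True))
    return DecisionReport(table=pd.DataFrame(rows), ci_levels=ci_levels)


def extract_features(
    P: PValueMatrix, h: float, rule: str = "user"
) -> CommonFeatureList:
    """List the features significant in every experiment at threshold ``h``.

    The output is sorted lexicographically by feature ID and carries each
    feature's p-value in every list; an empty list is allowed.
    """
    if not 0 < h <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {h}")
    mask = (P.values <= h).all(axis=1)
    df = pd.DataFrame(P.values[mask], columns=P.experiment_names)
    df.insert(0, "Name", P.feature_ids[mask])
    df = df.sort_values("Name", kind="stable").reset_index(drop=True)
    return CommonFeatureList(rule=rule, threshold=float(h), frame=df)
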