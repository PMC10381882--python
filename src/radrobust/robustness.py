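"""Normality-gated robustness scoring of features across segmentation classes.

For each feature, the three class-wise samples (original / over / under)
are gated by per-group Shapiro–Wilk tests: if every group looks normal
the parametric branch (one-way ANOVA, Welch t-tests) is used, otherwise
the nonparametric branch (Kruskal–Wallis, Mann–Whitney U).  The *overall
robustness score* is the p-value of the three-group test; the
*segmentation-specific scores* are the p-values of the pairwise
original-vs-over and original-vs-under tests.  High scores mean the
feature's distribution is stable under segmentation perturbation.

No multiple-testing correction is applied: the scores are raw p-values
by definition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ABNORMALITIES, METADATA_COLUMNS, PATHOLOGIES, VIEWS

logger = logging.getLogger(__name__)

Gate = Literal["parametric", "nonparametric"]

REPORT_COLUMNS = [
    "stratum",
    "family",
    "feature",
    "test_used",
    "overall_score",
    "over_score",
    "under_score",
    "n_original",
    "n_over",
    "n_under",
]


def score_from_pvalue(p: float) -> float:
    """The robustness-score definition: the score *is* the test p-value.

    A feature whose comparison test yields p = 0.02 receives score 0.02
    (non-robust); p = 0.80 receives score 0.80 (robust).  Clamped to
    [0, 1] defensively.
    """
    return float(min(max(p, 0.0), 1.0))


def normality_gate(groups: Sequence[np.ndarray], alpha: float = 0.05) -> Gate:
    """Shapiro–Wilk on each group: parametric iff every group's p > alpha.

    A zero-range group (Shapiro–Wilk undefined) gates nonparametric.
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise ValueError("normality gate requires every group size ≥ 3")
        if np.ptp(g) == 0:
            return "nonparametric"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(g).pvalue <= alpha:
                return "nonparametric"
    return "parametric"


def overall_score(
    g_original: np.ndarray,
    g_over: np.ndarray,
    g_under: np.ndarray,
    gate: Gate | None = None,
    alpha: float = 0.05,
) -> float:
    """p-value of ANOVA (parametric gate) or Kruskal–Wallis across classes."""
    groups = [np.asarray(g, dtype=float) for g in (g_original, g_over, g_under)]
    if gate is None:
        gate = normality_gate(groups, alpha)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: H = 0 / F undefined → robust
    if gate == "parametric":
        p = stats.f_oneway(*groups).pvalue
    else:
        p = stats.kruskal(*groups).pvalue
    return score_from_pvalue(p)


def pairwise_score(
    g_original: np.ndarray,
    g_perturbed: np.ndarray,
    gate: Gate | None = None,
    alpha: float = 0.05,
) -> float:
    """Two-sided p-value of Welch's t-test or Mann–Whitney U.

    The U test uses the exact distribution when both groups have ≤ 8
    observations and the pooled sample is tie-free, and the tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    a = np.asarray(g_original, dtype=float)
    b = np.asarray(g_perturbed, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("pairwise score requires both group sizes ≥ 3")
    if gate is None:
        gate = normality_gate([a, b], alpha)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if gate == "parametric":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    else:
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return score_from_pvalue(p)


@dataclass(frozen=True)
class Stratum:
    """Row filter over (abnormality, pathology, view); 'all' disables a filter."""

    abnormality: str = "all"
    pathology: str = "all"
    view: str = "all"

    def __post_init__(self) -> None:
        if self.abnormality not in ABNORMALITIES + ("all",):
            raise ValueError(f"bad abnormality filter {self.abnormality!r}")
        if self.pathology not in PATHOLOGIES + ("all",):
            raise ValueError(f"bad pathology filter {self.pathology!r}")
        if self.view not in VIEWS + ("all",):
            raise ValueError(f"bad view filter {self.view!r}")

    def label(self) -> str:
        return f"{self.abnormality}/{self.pathology}/{self.view}"

    def select(self, table: pd.DataFrame) -> pd.DataFrame:
        sel = pd.Series(True, index=table.index)
        if self.abnormality != "all":
            sel &= table["abnormality"] == self.abnormality
        if self.pathology != "all":
            sel &= table["pathology"] == self.pathology
        if self.view != "all":
            sel &= table["view"] == self.view
        return table[sel]


def default_strata() -> list[Stratum]:
    """Per-abnormality × per-pathology strata, each at view all/CC/MLO."""
    return [
        Stratum(a, p, v)
        for a in ABNORMALITIES
        for p in PATHOLOGIES
        for v in ("all", "CC", "MLO")
    ]


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def score_features(
    table: pd.DataFrame, stratum: Stratum | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Robustness report for every feature column within one stratum.

    Cases without a complete triplet (degenerate erosions) are excluded.
    Raises if fewer than 3 complete cases fall in the stratum.
    """
    stratum = stratum or Stratum()
    sub = stratum.select(table)
    complete = sub.groupby("case_id")["segmentation_class"].nunique()
    keep = complete[complete == 3].index
    dropped = complete.index.difference(keep)
    if len(dropped):
        logger.warning(
            "stratum %s: excluding %d case(s) without complete triplets",
            stratum.label(),
            len(dropped),
        )
    sub = sub[sub["case_id"].isin(keep)]
    if len(keep) < 3:
        raise ValueError(
            f"stratum {stratum.label()} has {len(keep)} complete cases; need ≥ 3"
        )

    by_class = {
        cls: sub[sub["segmentation_class"] == cls] for cls in ("original", "over", "under")
    }
    rows = []
    for feat in _feature_columns(sub):
        groups = {
            cls: df[feat].to_numpy(dtype=float)[~np.isnan(df[feat].to_numpy(dtype=float))]
            for cls, df in by_class.items()
        }
        if min(len(g) for g in groups.values()) < 3:
            logger.warning("feature %s: too many missing values; skipped", feat)
            continue
        gate = normality_gate(list(groups.values()), alpha)
        rows.append(
            {
                "stratum": stratum.label(),
                "family": feat.split(".", 1)[0],
                "feature": feat,
                "test_used": "ANOVA+t-test" if gate == "parametric" else "Kruskal-Wallis+Mann-Whitney",
                "overall_score": overall_score(
                    groups["original"], groups["over"], groups["under"], gate=gate
                ),
                "over_score": pairwise_score(groups["original"], groups["over"], gate=gate),
                "under_score": pairwise_score(groups["original"], groups["under"], gate=gate),
                "n_original": len(groups["original"]),
                "n_over": len(groups["over"]),
                "n_under": len(groups["under"]),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def assign_levels(report: pd.DataFrame) -> pd.DataFrame:
    """Binary robustness level per stratum: overall_score ≥ stratum median →
    'high', below → 'low' (all-equal scores → all 'high').  The median
    split is a documented convention; the source analysis ranks scores
    without stating a cutoff.
    """
    out = report.copy()
    levels = pd.Series(index=out.index, dtype=object)
    for _, idx in out.groupby("stratum").groups.items():
        scores = out.loc[idx, "overall_score"]
        if len(scores) < 2:
            raise ValueError("assign_levels requires ≥ 2 scored features per stratum")
        levels.loc[idx] = np.where(scores >= scores.median(), "high", "low")
    out["level"] = levels
    return out


def class_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of each score type per (stratum, family)."""
    if report.empty:
        raise ValueError("empty report")
    rows = []
    for (stratum, family), grp in report.groupby(["stratum", "family"], sort=True):
        for score_type in ("overall_score", "over_score", "under_score"):
            vals = grp[score_type].dropna().to_numpy()
            if vals.size == 0:
                logger.warning("%s/%s: no %s values; omitted", stratum, family, score_type)
                continue
            q = np.percentile(vals, [0, 25, 50, 75, 100])
            rows.append(
                {
                    "stratum": stratum,
                    "family": family,
                    "score_type": score_type,
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                    "n_features": vals.size,
                }
            )
    return pd.DataFrame(rows)


def plot_class_summary(report: pd.DataFrame, path: str, score_type: str = "overall_score") -> None:
    """Boxplots of the score distribution per feature family, per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = sorted(report["stratum"].unique())
    fig, axes = plt.subplots(len(strata), 1, figsize=(7, 2.5 * len(strata)), squeeze=False)
    for ax, stratum in zip(axes[:, 0], strata):
        grp = report[report["stratum"] == stratum]
        families = sorted(grp["family"].unique())
        data = [grp.loc[grp["family"] == f, score_type].dropna() for f in families]
        ax.boxplot(data, tick_labels=families)
        ax.set_ylabel(score_type)
        ax.set_title(stratum)
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
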