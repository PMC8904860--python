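"""Biomarker screening between resistance groups.

Expression markers are ranked by ROC AUC (rank statistic with midrank ties)
between resistant and sensitive cases; alteration frequencies are compared per
group with two-sided Fisher exact tests; serial pre/on/post expression values
receive monotone trend calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerResult",
    "auc",
    "marker_screen",
    "intersect_screens",
    "group_alteration_frequency",
    "trend_classify",
]


@dataclass(frozen=True)
class MarkerResult:
    gene: str
    auc: float
    direction: str  # "higher_in_resistant" | "lower_in_resistant" | "none"
    flag_predictive: bool
    n_resistant: int
    n_sensitive: int


def auc(scores_resistant: Sequence[float], scores_sensitive: Sequence[float]) -> float:
    """ROC AUC as P(resistant > sensitive) + 1/2 P(tie), via the U statistic."""
    a = np.asarray(scores_resistant, dtype=float)
    b = np.asarray(scores_sensitive, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def marker_screen(expr: pd.DataFrame, labels: Mapping[str, str],
                  auc_threshold: float = 0.80) -> list[MarkerResult]:
    """Per-gene AUC between resistant and sensitive samples.

    ``expr`` is genes x samples; ``labels`` maps sample -> "resistant" or
    "sensitive".  Markers are flagged when AUC exceeds the threshold and
    ranked by AUC (descending) with ties broken by gene name.
    """
    res_cols = [s for s in expr.columns if labels.get(s) == "resistant"]
    sen_cols = [s for s in expr.columns if labels.get(s) == "sensitive"]
    if len(res_cols) < 2 or len(sen_cols) < 2:
        raise ValueError("need at least two samples per group")
    out = []
    for gene, row in expr.iterrows():
        a = auc(row[res_cols].to_numpy(float), row[sen_cols].to_numpy(float))
        direction = ("higher_in_resistant" if a > 0.5
                     else "lower_in_resistant" if a < 0.5 else "none")
        out.append(MarkerResult(gene=str(gene), auc=a, direction=direction,
                                flag_predictive=a > auc_threshold,
                                n_resistant=len(res_cols),
                                n_sensitive=len(sen_cols)))
    out.sort(key=lambda m: (-m.auc, m.gene))
    return out


def intersect_screens(discovery: Sequence[MarkerResult],
                      validation: Sequence[MarkerResult]) -> list[str]:
    """Genes flagged predictive in two independent screens (cross-validated
    markers); no cross-platform normalization is attempted."""
    d = {m.gene for m in discovery if m.flag_predictive}
    v = {m.gene for m in validation if m.flag_predictive}
    return sorted(d & v)


def group_alteration_frequency(alterations: pd.DataFrame,
                               labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene alteration frequency per group with Fisher exact p values.

    ``alterations`` is genes x samples boolean; every sample must be labeled.
    Frequencies are reported both raw and rounded to two decimals (percent);
    the BH-adjusted q column is an extra beyond the Fisher p values.
    """
    groups = sorted(set(labels.values()))
    unknown = [s for s in alterations.columns if s not in labels]
    if unknown:
        raise ValueError(f"unlabeled samples: {unknown}")
    cols = {g: [s for s in alterations.columns if labels[s] == g] for g in groups}
    rows = []
    for gene, row in alterations.iterrows():
        rec: dict = {"gene": gene}
        for g in groups:
            n = len(cols[g])
            k = int(row[cols[g]].astype(bool).sum())
            rec[f"count_{g}"] = k
            rec[f"n_{g}"] = n
            rec[f"freq_{g}"] = k / n if n else float("nan")
            rec[f"freq_pct_{g}"] = round(100.0 * k / n, 2) if n else float("nan")
        if len(groups) == 2:
            g1, g2 = groups
            table = [[rec[f"count_{g1}"], rec[f"n_{g1}"] - rec[f"count_{g1}"]],
                     [rec[f"count_{g2}"], rec[f"n_{g2}"] - rec[f"count_{g2}"]]]
            rec["fisher_p"] = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(rec)
    df = pd.DataFrame(rows)
    if "fisher_p" in df.columns and len(df):
        df["fisher_q_bh"] = multipletests(df["fisher_p"], method="fdr_bh")[1]
    return df


def trend_classify(values: Sequence[float], min_support: int = 2,
                   tolerance: float = 0.0) -> str:
    """Monotone trend call over ordered timepoints (pre, on, post, ...).

    "increasing" when at least ``min_support`` consecutive intervals rise and
    no interval falls by more than ``tolerance``; symmetric for "decreasing";
    otherwise "none".  Invariant to adding a constant.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two timepoints")
    if np.isnan(v).any():
        raise ValueError("missing timepoint value")
    d = np.diff(v)
    n_up = int(np.sum(d > tolerance))
    n_down = int(np.sum(d < -tolerance))
    if n_up >= min_support and np.all(d >= -tolerance):
        return "increasing"
    if n_down >= min_support and np.all(d <= tolerance):
        return "decreasing"
    return "none"


def trend_screen(expr: pd.DataFrame, timepoint_order: Sequence[str],
                 min_support: int = 2, tolerance: float = 0.0) -> pd.DataFrame:
    """Trend call per gene over ordered timepoint columns; genes with missing
    values are skipped with a log entry."""
    rows = []
    for gene, row in expr.iterrows():
        try:
            vals = [float(row[t]) for t in timepoint_order]
            label = trend_classify(vals, min_support=min_support, tolerance=tolerance)
        except (KeyError, ValueError) as exc:
            logger.info("skipping %s: %s", gene, exc)
            continue
        rows.append({"gene": gene, "trend": label,
                     **{t: row[t] for t in timepoint_order}})
    return pd.DataFrame(rows)
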