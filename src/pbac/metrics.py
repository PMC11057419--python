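"""Evaluation statistics: AUROC, AUPRC, z-scores, effect size, Wilcoxon test.

Conventions fixed here for bit-stable reports:

* AUROC via the Mann–Whitney rank statistic with midranks for ties, i.e.
  P(score_pos > score_neg) + ½·P(tie).
* AUPRC as step-wise average precision (no trapezoidal interpolation).
* z-scores use the population (n) denominator.
* Effect size = mean(z[responders]) − mean(z[non-responders]) on cohort-level
  z-scored predicted IC50; negative values mean responders are predicted more
  sensitive.  The accompanying p-value is a two-sided Wilcoxon rank-sum
  (Mann–Whitney) test on the raw predictions: exact enumeration for small
  tie-free samples (n ≤ 12 combined), normal approximation with tie
  correction otherwise.
* p < 0.05 is flagged as significant in reports; no multiple-testing
  correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .io import ResponseLabels

__all__ = [
    "EvaluationReport",
    "auroc",
    "auprc",
    "zscore",
    "effect_size",
    "wilcoxon_ranksum",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05
EXACT_WILCOXON_MAX_N = 12


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs (e.g. AUROC
    with a single class present)."""


@dataclass
class EvaluationReport:
    """AUROC/AUPRC (classification), effect size and Wilcoxon p (regression
    head), class counts, and an optional per-fold breakdown."""

    auroc: float | None = None
    auprc: float | None = None
    effect_size: float | None = None
    wilcoxon_p: float | None = None
    n_pos: int = 0
    n_neg: int = 0
    folds: list["EvaluationReport"] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("auroc", "auprc"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.wilcoxon_p is not None and not (0.0 < self.wilcoxon_p <= 1.0):
            raise ValueError(f"wilcoxon_p={self.wilcoxon_p} outside (0, 1]")

    @property
    def significant(self) -> bool | None:
        if self.wilcoxon_p is None:
            return None
        return self.wilcoxon_p < SIGNIFICANCE_LEVEL

    def to_frame(self) -> pd.DataFrame:
        """Tabular form, one row per fold plus a summary row."""
        rows = []
        for i, f in enumerate(self.folds):
            rows.append({"fold": i, **f._row()})
        rows.append({"fold": "mean", **self._row()})
        return pd.DataFrame(rows)

    def _row(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "effect_size": self.effect_size,
            "wilcoxon_p": self.wilcoxon_p,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            **self.meta,
        }

    def to_dict(self) -> dict:
        d = self._row()
        if self.folds:
            d["folds"] = [f._row() for f in self.folds]
        return d


def _as_binary(labels) -> np.ndarray:
    if isinstance(labels, ResponseLabels):
        return labels.labels
    y = np.asarray(labels).astype(int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return y


def auroc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + ½ P(tie),
    computed via the midrank Mann–Whitney statistic."""
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve as step-wise average precision.
    Tied scores are grouped at a common threshold, so the value does not
    depend on input order."""
    y = _as_binary(labels)
    if y.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive samples")
    # clip float round-off just past the endpoints
    return float(np.clip(average_precision_score(y, np.asarray(scores, float)), 0.0, 1.0))


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, population sd 1.  Zero variance is an error
    (the downstream effect size would be undefined)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero variance: z-scores (and effect size) undefined")
    return (x - x.mean()) / sd


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when the combined sample is small (≤ 12) and tie-free;
    otherwise the normal approximation with tie correction (no continuity
    correction, so equal-rank groups give exactly p = 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: no evidence either way
    if tie_free and pooled.size <= EXACT_WILCOXON_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def effect_size(pred_ic50, labels) -> tuple[float, float]:
    """Group difference of predicted-IC50 z-scores between responders and
    non-responders, with a two-sided Wilcoxon rank-sum p-value.

    z-scores are taken over the pooled cohort; effect =
    mean(z[responders]) − mean(z[non-responders]).  Responders are predicted
    more sensitive (lower IC50) when the effect is negative.
    """
    y = _as_binary(labels)
    x = np.asarray(pred_ic50, float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite predicted IC50 values")
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("effect size undefined: a group is empty")
    z = zscore(x)
    effect = float(z[y == 1].mean() - z[y == 0].mean())
    p = wilcoxon_ranksum(x[y == 1], x[y == 0])
    return effect, p
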