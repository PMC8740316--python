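"""ROI-level statistics: mean extraction, ROC discrimination, correlation.

Covers the behavioral/clinical side of the analysis: averaging a PerAF map
over a labelled region, asking how well that regional mean separates
patients from controls (ROC/AUC with bootstrap or DeLong confidence
interval), correlating it with behavioral scores (Pearson r with the
two-tailed t-transform p), and the pooled two-sample t-test on published
summary statistics used for demographic tables.  A packaged fixture
provides the printed Hospital Anxiety and Depression Scale scores of the
two 17-subject groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .peraf import PerAFMap

__all__ = [
    "RocResult",
    "CorrelationResult",
    "roi_mean",
    "roc_auc",
    "pearson_r",
    "summary_t",
    "hads_fixture",
]


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    positive_group: str
    flipped: bool
    fpr: np.ndarray
    tpr: np.ndarray
    n_boot: int
    seed: int | None


@dataclass
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


def roi_mean(pmap: PerAFMap, labels: np.ndarray, roi_id: int) -> float:
    """Mean map value over in-mask, defined voxels carrying ``roi_id``."""
    labels = np.asarray(labels)
    if labels.shape != pmap.values.shape:
        raise ValueError("label volume shape does not match map")
    sel = (labels == roi_id) & pmap.defined
    if not sel.any():
        raise ValueError(f"ROI {roi_id} has no defined in-mask voxels")
    return float(pmap.values[sel].mean())


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg), via ranks."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI via the placement-value covariance estimator."""
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_auc(
    scores: np.ndarray,
    groups: np.ndarray,
    positive_group: str | int | None = None,
    orientation: str = "auto",
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> RocResult:
    """ROC AUC for separating two groups by a scalar score.

    The AUC is the rank (Mann-Whitney) statistic with ties counted half,
    identical to the trapezoidal area under the empirical ROC curve.  With
    ``orientation="auto"`` scores are flipped if needed so the reported AUC
    is at least 0.5, and the flip is recorded — regions where patients show
    either higher or lower amplitude are then reported on a common scale.
    The 95% CI is a stratified bootstrap percentile interval by default;
    ``ci_method="delong"`` uses the DeLong asymptotic interval instead.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labs = pd.unique(groups)
    if len(labs) != 2:
        raise ValueError("exactly two groups required")
    if positive_group is None:
        positive_group = labs[0]
    if positive_group not in labs:
        raise ValueError(f"positive_group {positive_group!r} not present")
    pos = scores[groups == positive_group]
    neg = scores[groups != positive_group]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    auc = _rank_auc(pos, neg)
    flipped = False
    if orientation == "auto" and auc < 0.5:
        scores = -scores
        pos, neg = -pos, -neg
        auc = 1.0 - auc
        flipped = True
    elif orientation not in ("auto", "fixed"):
        raise ValueError("orientation must be 'auto' or 'fixed'")
    y_true = (groups == positive_group).astype(int)
    fpr, tpr, _ = roc_curve(y_true, scores)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            boots[b] = _rank_auc(bp, bn)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    elif ci_method == "delong":
        ci = _delong_ci(pos, neg, auc)
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'delong'")
    ci = (min(ci[0], auc), max(ci[1], auc))
    return RocResult(
        auc=auc,
        ci95=ci,
        positive_group=str(positive_group),
        flipped=flipped,
        fpr=fpr,
        tpr=tpr,
        n_boot=n_boot if ci_method == "bootstrap" else 0,
        seed=seed,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed p.

    Pairs with a missing value in either variable are dropped.  The p value
    comes from ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_two_tailed=float(p), n=n)


def summary_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summaries (mean2 minus mean1).

    Returns ``(t, df, p_two_tailed)`` with ``df = n1 + n2 - 2``.  This is the
    statistic printed in demographic comparison tables, recomputable from the
    published mean +/- SD rows.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean2 - mean1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


# Published HADS anxiety (AS) and depression (DS) subscores of the two
# 17-subject groups; 0-21 scale.
_HADS_PATIENTS = [
    (7, 7), (4, 5), (6, 6), (9, 9), (8, 8), (11, 10), (10, 10), (7, 7),
    (12, 11), (8, 8), (8, 8), (11, 10), (7, 6), (8, 7), (13, 12), (5, 6),
    (8, 9),
]
_HADS_CONTROLS = [
    (3, 2), (3, 2), (3, 2), (3, 1), (4, 3), (4, 2), (3, 2), (1, 2),
    (1, 1), (1, 2), (3, 3), (3, 2), (2, 2), (3, 2), (5, 3), (3, 1),
    (4, 3),
]


def hads_fixture() -> pd.DataFrame:
    """The packaged HADS scores: 34 subjects, columns ``anxiety_score`` /
    ``depression_score``, indexed ``patient1..17`` and ``hc1..17``."""
    rows = []
    for i, (a, d) in enumerate(_HADS_PATIENTS, start=1):
        rows.append((f"patient{i}", "patient", a, d))
    for i, (a, d) in enumerate(_HADS_CONTROLS, start=1):
        rows.append((f"hc{i}", "control", a, d))
    df = pd.DataFrame(
        rows, columns=["subject_id", "group", "anxiety_score", "depression_score"]
    )
    return df.set_index("subject_id")
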