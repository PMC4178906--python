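"""Diagnostic evaluation of an integer score against a binary gold standard.

All routines use the decision rule *score >= threshold => predicted
positive* (the triage convention: higher score, sicker patient).

The AUROC is computed as the tie-corrected pair-comparison probability

    AUROC = P(S+ > S-) + 0.5 * P(S+ = S-)

over positive/negative pairs, which equals the trapezoidal area under the
empirical ROC polygon. Confidence intervals come from DeLong's structural-
component variance estimator (default) or a stratified percentile
bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocPoint",
    "RocAnalysis",
    "CutoffPerformance",
    "ScoreDisposal",
    "roc_curve",
    "auroc",
    "auroc_ci",
    "analyze_score",
    "confusion_at_cutoff",
    "cutoff_sweep",
    "disposal_by_score",
    "youden_optimal_cutoff",
]

logger = logging.getLogger("pmews")


@dataclass(frozen=True)
class RocPoint:
    """Operating point of the rule ``score >= threshold``."""

    threshold: int
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocAnalysis:
    """ROC curve with its AUROC and 95% confidence interval."""

    points: tuple[RocPoint, ...]
    auroc: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class CutoffPerformance:
    """Confusion-matrix counts and derived metrics at one cutoff."""

    cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


@dataclass(frozen=True)
class ScoreDisposal:
    """Per-score-value disposal counts (the score-by-disposal distribution)."""

    table: pd.DataFrame  # columns: score, n, n_needs_ems, proportion_needs_ems


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    y = y.astype(int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    if y.all() or not y.any():
        raise ValueError("degenerate cohort: labels contain a single class")
    return s, y


def roc_curve(scores, labels) -> list[RocPoint]:
    """One operating point per integer threshold in [min-1, max+1].

    The endpoints (sensitivity 1, specificity 0) and (0, 1) are always
    included; sensitivity is non-increasing in the threshold.
    """
    s, y = _validate(scores, labels)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    lo = int(np.floor(s.min())) - 1
    hi = int(np.ceil(s.max())) + 1
    thresholds = np.arange(lo, hi + 1)
    # count of scores >= t via sorted search
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg, thresholds, side="left") / len(neg)
    return [
        RocPoint(int(t), float(se), float(sp))
        for t, se, sp in zip(thresholds, sens, spec)
    ]


def _placement_values(pos: np.ndarray, neg: np.ndarray):
    """Per-observation placement components of the Mann-Whitney statistic.

    ``v10[i]`` is the fraction of negatives that positive i beats (ties
    half); ``v01[j]`` the fraction of positives that negative j loses to.
    """
    neg_sorted = np.sort(neg)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / len(neg)
    pos_sorted = np.sort(pos)
    lt = np.searchsorted(pos_sorted, neg, side="right")
    ge = np.searchsorted(pos_sorted, neg, side="left")
    v01 = ((len(pos) - lt) + 0.5 * (lt - ge)) / len(pos)
    return v10, v01


def auroc(scores, labels) -> float:
    """Tie-corrected area under the ROC curve."""
    s, y = _validate(scores, labels)
    v10, _ = _placement_values(s[y == 1], s[y == 0])
    return float(v10.mean())


def _delong_ci(pos, neg, alpha):
    v10, v01 = _placement_values(pos, neg)
    theta = v10.mean()
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    se = np.sqrt(s10 / len(pos) + s01 / len(neg))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.clip(theta - z * se, 0, 1)), float(np.clip(theta + z * se, 0, 1))


def _bootstrap_ci(pos, neg, alpha, n_boot, seed):
    if n_boot < 100:
        logger.warning(
            "bootstrap with %d replicates (<100); interval will be unstable",
            n_boot,
        )
    rng = np.random.default_rng(seed)
    m, n = len(pos), len(neg)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):  # stratified: resample within each class
        p = pos[rng.integers(0, m, m)]
        q = neg[rng.integers(0, n, n)]
        v10, _ = _placement_values(p, q)
        stats_[b] = v10.mean()
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def auroc_ci(
    scores,
    labels,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided (1-alpha) confidence interval for the AUROC."""
    s, y = _validate(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    if method == "delong":
        return _delong_ci(pos, neg, alpha)
    if method == "bootstrap":
        return _bootstrap_ci(pos, neg, alpha, n_boot, seed)
    raise ValueError(f"unknown CI method {method!r}")


def analyze_score(
    scores,
    labels,
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocAnalysis:
    """Full ROC analysis: curve, AUROC and confidence interval."""
    points = roc_curve(scores, labels)
    a = auroc(scores, labels)
    lo, hi = auroc_ci(scores, labels, ci_method, alpha, n_boot, seed)
    y = np.asarray(labels).astype(int)
    return RocAnalysis(
        points=tuple(points),
        auroc=a,
        ci_low=lo,
        ci_high=hi,
        ci_method=ci_method,
        n_positive=int(y.sum()),
        n_negative=int((1 - y).sum()),
    )


def confusion_at_cutoff(scores, labels, cutoff: int) -> CutoffPerformance:
    """Confusion matrix and metrics for the rule ``score >= cutoff``.

    A cutoff outside the observed score range is valid (all-positive or
    all-negative prediction) and logs a warning. Undefined proportions
    (zero denominator) are reported as NaN.
    """
    s, y = _validate(scores, labels)
    if cutoff < s.min() or cutoff > s.max():
        logger.warning(
            "cutoff %s outside observed score range [%g, %g]",
            cutoff,
            s.min(),
            s.max(),
        )
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def ratio(a, b):
        return a / b if b else float("nan")

    return CutoffPerformance(
        cutoff=int(cutoff),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def cutoff_sweep(scores, labels) -> list[CutoffPerformance]:
    """confusion_at_cutoff for every integer threshold in [min, max+1]."""
    s, _ = _validate(scores, labels)
    lo = int(np.floor(s.min()))
    hi = int(np.ceil(s.max())) + 1
    return [confusion_at_cutoff(scores, labels, c) for c in range(lo, hi + 1)]


def disposal_by_score(scores, labels) -> ScoreDisposal:
    """Counts and needs-EMS proportion per observed score value.

    Score levels with no patients are omitted.
    """
    s, y = _validate(scores, labels)
    df = pd.DataFrame({"score": s.astype(int), "label": y})
    g = df.groupby("score")["label"].agg(n="size", n_needs_ems="sum").reset_index()
    g["proportion_needs_ems"] = g["n_needs_ems"] / g["n"]
    return ScoreDisposal(table=g)


def youden_optimal_cutoff(points: Sequence[RocPoint]) -> int:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the higher (more specific) cutoff.
    """
    if not points:
        raise ValueError("empty ROC")
    best = max(points, key=lambda p: (p.sensitivity + p.specificity - 1, p.threshold))
    return int(best.threshold)
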