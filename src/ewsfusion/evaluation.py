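"""Discrimination, calibration and threshold analysis for risk scores.

Discrimination is summarised by the c-statistic (AUROC), computed as the
Mann-Whitney concordance probability — the probability that a randomly
chosen event-positive observation scores above a randomly chosen negative
one, ties counted half.  Confidence intervals use the DeLong structural-
components variance estimate with a normal approximation.  Calibration is
assessed by binning the index and comparing observed event rates against
mean predicted risk.  Threshold analysis matches a candidate score's
operating point to a reference score's specificity (e.g. NEWS triggers 5
and 7) and tabulates sensitivity/specificity/PPV/NPV for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")


def c_statistic(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 0.5 P(equal)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    r = rankdata(s)  # midranks
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def c_statistic_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, clipped to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size

    # structural components via midranks (fast DeLong)
    all_r = rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = rankdata(pos), rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # per-positive component
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # per-negative component
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    if var <= 0:
        warnings.warn("degenerate DeLong variance (all ties); returning the full interval")
        return (0.0, 1.0)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_curve(scores, labels) -> pd.DataFrame:
    """Monotone (FPR, TPR) staircase from (0,0) to (1,1), one row per threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def calibration_table(scores, labels, bin_width: float = 0.05) -> pd.DataFrame:
    """Observed event rate per equal-width score bin over [0, 1]; empty bins omitted."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    idx = np.minimum((s / bin_width).astype(int), n_bins - 1)
    df = pd.DataFrame({"bin": idx, "score": s, "event": y})
    g = df.groupby("bin", sort=True)
    out = pd.DataFrame(
        {
            "bin_low": g["bin"].first() * bin_width,
            "mean_score": g["score"].mean(),
            "observed_rate": g["event"].mean(),
            "n": g["event"].size(),
        }
    ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class ThresholdReport:
    """Operating characteristics of the rule ``score >= threshold`` flags positive."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]  # None when nothing is flagged
    npv: Optional[float]
    n_flagged: int


def threshold_report(scores, labels, threshold: float) -> ThresholdReport:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    flag = s >= threshold
    tp = int((flag & y).sum())
    fp = int((flag & ~y).sum())
    fn = int((~flag & y).sum())
    tn = int((~flag & ~y).sum())
    return ThresholdReport(
        threshold=float(threshold),
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
        n_flagged=tp + fp,
    )


@dataclass(frozen=True)
class MatchedThresholdResult:
    target_threshold: float
    specificity_attained: bool
    reference: ThresholdReport
    target: ThresholdReport


def matched_specificity_threshold(
    reference_scores, reference_threshold: float, target_scores, labels
) -> MatchedThresholdResult:
    """Smallest target threshold whose specificity reaches the reference's.

    Both score vectors must describe the same labelled observations.  When
    even the strictest target threshold cannot reach the reference
    specificity, the maximum-specificity threshold is reported with
    ``specificity_attained=False``.
    """
    ref_scores = np.asarray(reference_scores, dtype=float)
    tgt = np.asarray(target_scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    ref_report = threshold_report(ref_scores, y, reference_threshold)

    # specificity of `tgt >= thr` is non-decreasing in thr over candidate
    # thresholds (the distinct scores, plus one above the maximum)
    candidates = np.unique(tgt)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    neg = tgt[~y]
    spec = np.array([(neg < thr).mean() for thr in candidates])
    ok = spec >= ref_report.specificity
    if ok.any():
        thr = float(candidates[int(np.argmax(ok))])  # first (smallest) attaining
        attained = True
    else:
        thr = float(candidates[int(np.argmax(spec))])
        attained = False
    return MatchedThresholdResult(
        target_threshold=thr,
        specificity_attained=attained,
        reference=ref_report,
        target=threshold_report(tgt, y, thr),
    )
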