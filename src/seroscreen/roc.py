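"""Empirical ROC analysis with threshold selection at a fixed specificity.

Scores are serum marker concentrations; a subject is called positive when
its score is at or above the threshold (high marker implies disease).
Candidate thresholds are the distinct observed scores plus a +inf
sentinel, so the curve always contains the (sensitivity 0, specificity 1)
corner and every achievable operating point.  The AUC is the trapezoidal
area over (1 - specificity, sensitivity), which for this construction
equals the pairwise-comparison probability P(case > control) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RocResult", "roc_curve", "auc", "threshold_at_specificity"]


@dataclass
class RocResult:
    """Ordered ROC operating points and the area under the curve.

    ``points`` has columns threshold, sensitivity, specificity, sorted by
    threshold ascending (the +inf sentinel last).
    """

    points: pd.DataFrame = field(repr=False)
    auc: float

    def __post_init__(self) -> None:
        s = self.points
        assert ((s["sensitivity"] >= 0) & (s["sensitivity"] <= 1)).all()
        assert ((s["specificity"] >= 0) & (s["specificity"] <= 1)).all()
        assert 0.0 <= self.auc <= 1.0


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC curve from scores and case/control labels.

    Parameters
    ----------
    scores
        Marker values, one per subject.
    labels
        Boolean-like, True/1 for cases.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need at least one case and one control")

    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    case_scores = scores[labels]
    ctrl_scores = scores[~labels]
    sens = np.array([(case_scores >= t).sum() / n_case for t in thresholds])
    spec = np.array([(ctrl_scores < t).sum() / n_ctrl for t in thresholds])
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(points=points, auc=_trapezoid_auc(points))


def _trapezoid_auc(points: pd.DataFrame) -> float:
    # integrate sensitivity over FPR = 1 - specificity; thresholds ascending
    # means FPR descending, so flip for a positively oriented integral
    fpr = (1.0 - points["specificity"].to_numpy())[::-1]
    tpr = points["sensitivity"].to_numpy()[::-1]
    return float(np.trapezoid(tpr, fpr))


def auc(result: RocResult) -> float:
    """Area under the ROC curve (trapezoidal)."""
    return result.auc


def pairwise_auc(scores, labels) -> float:
    """AUC as the case-vs-control pairwise win rate, with half credit for ties.

    Exact O(n_case * n_ctrl) computation; the independent counterpart of
    the trapezoidal area and the Mann-Whitney U statistic scaled to [0,1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    case = scores[labels][:, None]
    ctrl = scores[~labels][None, :]
    wins = (case > ctrl).sum() + 0.5 * (case == ctrl).sum()
    return float(wins / (case.shape[0] * ctrl.shape[1]))


def threshold_at_specificity(
    result: RocResult, target_specificity: float
) -> tuple[float, float, float]:
    """Best operating point subject to a specificity constraint.

    Among thresholds whose attained specificity is at least the target,
    returns the one with maximal sensitivity, breaking ties toward the
    lower threshold.  Returns (threshold, sensitivity, attained
    specificity).  The +inf sentinel (specificity 1) guarantees
    feasibility for any target in (0, 1).
    """
    if not 0 < target_specificity < 1:
        raise ValueError("target specificity must be in (0, 1)")
    pts = result.points
    ok = pts[pts["specificity"] >= target_specificity]
    if ok.empty:  # unreachable with the sentinel; defensive
        raise RuntimeError("no threshold attains the target specificity")
    best_sens = ok["sensitivity"].max()
    best = ok[ok["sensitivity"] == best_sens].iloc[0]  # lowest threshold wins ties
    return float(best["threshold"]), float(best["sensitivity"]), float(best["specificity"])
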