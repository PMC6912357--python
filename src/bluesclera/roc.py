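"""ROC analysis of the blue-percentile score.

Higher BP is read as evidence of iron deficiency ("score ≥ threshold"
means test positive).  Every distinct score serves as a candidate
threshold; the AUC is the trapezoidal area, identical to the tie-corrected
Mann–Whitney statistic U/(n₁·n₀), with a DeLong confidence interval.
Three standard optimal-threshold indices are reported: Youden
max(sens + spec − 1), Liu max(sens·spec), and efficiency max(accuracy);
ties resolve to the smallest score achieving the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCAnalysis", "OptimalThreshold", "roc_analysis", "delong_variance"]


@dataclass(frozen=True)
class OptimalThreshold:
    threshold: float
    sensitivity: float
    specificity: float
    index_value: float


@dataclass(frozen=True)
class ROCAnalysis:
    """ROC points, AUC with 95% CI, and the three optimal thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    optimal: dict[str, OptimalThreshold]
    n_pos: int
    n_neg: int


def delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC from placement values."""
    # V10_i: fraction of negatives each positive beats (ties count 1/2).
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    if len(pos) < 2 or len(neg) < 2:
        return float("nan")
    return float(v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg))


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
) -> ROCAnalysis:
    """Full ROC analysis of a score against a binary disease label.

    ``labels`` is truthy for diseased; positivity direction is
    "score ≥ threshold → positive".  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC analysis requires both classes present")

    thresholds = np.unique(scores)  # ascending
    # sens(t) = P(pos >= t), spec(t) = P(neg < t); vectorized by sorting.
    sens = 1.0 - np.searchsorted(np.sort(pos), thresholds, side="left") / pos.size
    spec = np.searchsorted(np.sort(neg), thresholds, side="left") / neg.size

    # AUC via midranks = tie-corrected Mann–Whitney U / (n1 n0).
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    var = delong_variance(pos, neg)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var) if np.isfinite(var) else np.nan
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    accuracy = (sens * pos.size + spec * neg.size) / scores.size
    optimal = {}
    for name, objective in (
        ("youden", sens + spec - 1.0),
        ("liu", sens * spec),
        ("efficiency", accuracy),
    ):
        i = int(np.argmax(objective))  # first max → smallest threshold
        optimal[name] = OptimalThreshold(
            threshold=float(thresholds[i]),
            sensitivity=float(sens[i]),
            specificity=float(spec[i]),
            index_value=float(objective[i]),
        )
    return ROCAnalysis(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), auc_ci95=(float(ci[0]), float(ci[1])),
        optimal=optimal, n_pos=int(pos.size), n_neg=int(neg.size),
    )
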