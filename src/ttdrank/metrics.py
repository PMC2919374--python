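"""Discrimination and calibration metrics for responder prediction.

The overall score OS lives in [-1, 1]; for calibration assessment it is
mapped to a probability scale by the affine transform ``(OS + 1) / 2``
(configurable).  The Brier score is decomposed the Murphy way over
equal-width probability bins into reliability, resolution and uncertainty;
the identity ``brier = reliability - resolution + uncertainty`` holds
exactly for the binned forecasts (each forecast replaced by its bin's mean).
Discrimination is assessed with a rank-based ROC/AUC where tied scores
receive half credit, equivalent to the normalized Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationReport",
    "binned_brier_score",
    "brier_decomposition",
    "brier_score",
    "calibration_report",
    "os_to_probability",
    "roc_auc",
    "roc_curve_points",
]


def os_to_probability(os_values) -> np.ndarray:
    """Map overall scores from [-1, 1] to the probability scale [0, 1]."""
    return (np.asarray(os_values, dtype=float) + 1.0) / 2.0


def _check_pairs(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    return p, y


def brier_score(probabilities, outcomes) -> float:
    """Mean squared difference between forecast probability and outcome."""
    p, y = _check_pairs(probabilities, outcomes)
    return float(np.mean((p - y) ** 2))


def brier_decomposition(
    probabilities, outcomes, bins: int = 10
) -> tuple[float, float, float]:
    """Murphy decomposition (reliability, resolution, uncertainty).

    Forecasts are grouped into ``bins`` equal-width probability bins; empty
    bins contribute zero.  Reliability uses each bin's mean forecast, so the
    identity ``rel - res + unc`` recovers the Brier score of the *binned*
    forecasts exactly; against the raw forecasts it differs by the
    within-bin forecast variance.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    p, y = _check_pairs(probabilities, outcomes)
    n = p.size
    idx = np.minimum((p * bins).astype(int), bins - 1)
    base_rate = float(np.mean(y))
    reliability = 0.0
    resolution = 0.0
    for k in range(bins):
        mask = idx == k
        n_k = int(mask.sum())
        if n_k == 0:
            continue
        f_k = float(np.mean(p[mask]))
        o_k = float(np.mean(y[mask]))
        reliability += n_k * (f_k - o_k) ** 2
        resolution += n_k * (o_k - base_rate) ** 2
    reliability /= n
    resolution /= n
    uncertainty = base_rate * (1.0 - base_rate)
    return reliability, resolution, uncertainty


def binned_brier_score(probabilities, outcomes, bins: int = 10) -> float:
    """Brier score after discretizing each forecast to its bin's mean; this
    is the quantity the Murphy components recombine to exactly."""
    p, y = _check_pairs(probabilities, outcomes)
    idx = np.minimum((p * bins).astype(int), bins - 1)
    p_binned = p.copy()
    for k in np.unique(idx):
        mask = idx == k
        p_binned[mask] = np.mean(p[mask])
    return float(np.mean((p_binned - y) ** 2))


def roc_auc(scores, outcomes) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, with ties counted half.  Equals the normalized Mann-Whitney U."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties with half credit
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(scores, outcomes) -> list[tuple[float, float, float]]:
    """Threshold sweep: (threshold, sensitivity, specificity) at every
    distinct score, predicting positive when score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n_pos = float(np.sum(y == 1))
    n_neg = float(np.sum(y == 0))
    points = []
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tp = float(np.sum(pred & (y == 1)))
        tn = float(np.sum(~pred & (y == 0)))
        points.append((float(t), tp / n_pos, tn / n_neg))
    return points


def _operating_point(scores, outcomes, threshold: float) -> tuple[float, float, float]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    pred = s >= threshold
    tp = float(np.sum(pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    n_pos = float(np.sum(y == 1))
    n_neg = float(np.sum(y == 0))
    return (
        threshold,
        tp / n_pos if n_pos else float("nan"),
        tn / n_neg if n_neg else float("nan"),
    )


@dataclass
class CalibrationReport:
    """Joint discrimination/calibration summary of a forecast set."""

    brier: float
    brier_binned: float
    reliability: float
    resolution: float
    uncertainty: float
    auc: float
    n: int
    operating_point: tuple[float, float, float]
    threshold_sweep: list[tuple[float, float, float]] = field(default_factory=list)


def calibration_report(
    probabilities, outcomes, bins: int = 10, decision_threshold: float = 0.5
) -> CalibrationReport:
    """Compute Brier score, Murphy decomposition, AUC and the ROC sweep,
    reporting the operating point at the stated decision threshold."""
    p, y = _check_pairs(probabilities, outcomes)
    rel, res, unc = brier_decomposition(p, y, bins)
    return CalibrationReport(
        brier=brier_score(p, y),
        brier_binned=binned_brier_score(p, y, bins),
        reliability=rel,
        resolution=res,
        uncertainty=unc,
        auc=roc_auc(p, y),
        n=int(p.size),
        operating_point=_operating_point(p, y, decision_threshold),
        threshold_sweep=roc_curve_points(p, y),
    )
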