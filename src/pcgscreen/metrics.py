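"""Evaluation statistics for screening models.

AUC is the rank (Mann-Whitney) formulation: the probability that a randomly
chosen positive outranks a randomly chosen negative, with ties counted 1/2.
Confidence intervals for proportions are exact Clopper-Pearson; fold-level
statistics from cross-validation are summarised with a t interval, treating
per-fold values as i.i.d. draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RocResult:
    """AUC with sensitivity/specificity at a threshold and their CIs."""

    auc: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    n_pos: int
    n_neg: int


def auc(scores, labels) -> float:
    """Area under the ROC curve, ties counted one half.

    Parameters
    ----------
    scores : array-like of float
        Higher score means more likely positive.
    labels : array-like of bool/int
        Positive class membership.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[labels].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval via beta-quantile inversion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def fold_ci(fold_statistics, level: float = 0.95):
    """Mean and t-interval over per-fold statistics.

    Returns ``(mean, low, high, ok)``; with fewer than two defined folds the
    point estimate is returned with ``ok=False`` and a degenerate interval.
    """
    vals = np.asarray([v for v in fold_statistics if v is not None and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no defined fold statistics")
    m = float(vals.mean())
    if vals.size < 2:
        return m, m, m, False
    k = vals.size
    sd = float(vals.std(ddof=1))
    t = float(stats.t.ppf(0.5 + level / 2, k - 1))
    half = t * sd / math.sqrt(k)
    return m, m - half, m + half, True


def kappa_and_agreement(rater1, rater2):
    """Cohen's kappa and percent agreement for two binary rating vectors.

    Dichotomisation (e.g. murmur grade >= 1) happens before the call. When
    both raters are constant and identical, chance agreement is 1 and kappa
    is undefined: ``(nan, 1.0)`` is returned.
    """
    r1 = np.asarray(rater1).astype(bool)
    r2 = np.asarray(rater2).astype(bool)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    n = r1.size
    if n == 0:
        raise ValueError("empty rating vectors")
    p_o = float((r1 == r2).mean())
    p1, p2 = float(r1.mean()), float(r2.mean())
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e >= 1.0 - 1e-15:
        return float("nan"), p_o
    kappa = (p_o - p_e) / (1 - p_e)
    return float(kappa), p_o


def sensitivity_specificity(scores, labels, threshold: float):
    """Sensitivity and specificity of the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = float((pred & labels).sum() / n_pos) if n_pos else float("nan")
    spec = float((~pred & ~labels).sum() / n_neg) if n_neg else float("nan")
    return sens, spec


def roc_result(scores, labels, threshold: float, level: float = 0.95) -> RocResult:
    """Bundle AUC and thresholded operating point with exact CIs."""
    labels_b = np.asarray(labels).astype(bool)
    n_pos = int(labels_b.sum())
    n_neg = int((~labels_b).sum())
    sens, spec = sensitivity_specificity(scores, labels_b, threshold)
    tp = int(round(sens * n_pos)) if n_pos else 0
    tn = int(round(spec * n_neg)) if n_neg else 0
    return RocResult(
        auc=auc(scores, labels_b),
        sensitivity=sens,
        specificity=spec,
        sens_ci=exact_binomial_ci(tp, n_pos, level) if n_pos else (float("nan"),) * 2,
        spec_ci=exact_binomial_ci(tn, n_neg, level) if n_neg else (float("nan"),) * 2,
        n_pos=n_pos,
        n_neg=n_neg,
    )
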