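"""Evaluation and model-comparison statistics.

Confusion metrics with Youden's index, trapezoidal ROC AUC, bootstrap
confidence intervals (B = 100, full-size resamples with replacement),
McNemar's chi-square test with a directional binomial follow-up, and the
paired-bootstrap AUC difference t-test (B shared resamples, t with B - 1
degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricSet",
    "BootstrapResult",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_metric",
    "mcnemar_test",
    "paired_bootstrap_auc_test",
]


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity, Youden's J and AUC at one threshold."""

    accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float


@dataclass(frozen=True)
class BootstrapResult:
    """Point value plus bootstrap mean/sd and a 95% interval."""

    point: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    B: int


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == "case").astype(int)
    return y.astype(int)


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Standard 2x2-derived metrics; ``labels`` are 0/1 or 'control'/'case'.

    Raises if either class is absent, naming the missing class, since
    sensitivity or specificity would be undefined.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise ValueError("no positive (case) labels: sensitivity undefined")
    if n_neg == 0:
        raise ValueError("no negative (control) labels: specificity undefined")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    return MetricSet(
        accuracy=(tp + tn) / y.size,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        auc=roc_auc(s, y),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Ties in scores are handled so the result equals the Mann-Whitney U
    statistic normalized by ``n_pos * n_neg``.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative TP/FP counts at each distinct threshold (descending scores)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def bootstrap_metric(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    B: int = 100,
    seed: int = 0,
    percentile: bool = False,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Bootstrap a metric over ``B`` full-size resamples with replacement.

    Resamples in which the metric is undefined (e.g. a single-class draw)
    are redrawn, up to ``max_redraws`` attempts each, then an error is
    raised. The 95% interval is the normal approximation ``mean +- 1.96 sd``;
    with ``percentile=True`` the 2.5/97.5 empirical percentiles are used
    instead.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    n = s.size
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = metric_fn(s[idx], y[idx])
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"metric undefined on {max_redraws} consecutive resamples"
            )
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1))
    if percentile:
        ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    else:
        ci_low, ci_high = mean - 1.96 * sd, mean + 1.96 * sd
    return BootstrapResult(
        point=float(metric_fn(s, y)),
        mean=mean,
        sd=sd,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        B=B,
    )


def mcnemar_test(
    correct_a, correct_b, continuity_correction: bool = False
) -> tuple[float, float, Optional[float]]:
    """McNemar's paired test on two classifiers' correctness vectors.

    With discordant counts ``n01`` (A wrong, B right) and ``n10`` (A right,
    B wrong): ``chi2 = (n01 - n10)^2 / (n01 + n10)``, p from chi-square with
    1 df. If p < 0.05 a one-sided exact binomial follow-up reports the
    probability of at least ``max(n01, n10)`` successes in ``n01 + n10``
    trials at rate 1/2, identifying which pipeline performed better;
    otherwise the third element is None.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("correctness vectors must be equal-length 1-D, length >= 1")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    n_disc = n01 + n10
    if n_disc == 0:
        raise ValueError("no discordant pairs: McNemar test undefined")
    diff = abs(n01 - n10)
    if continuity_correction:
        diff = max(diff - 1, 0)
    chi2 = diff**2 / n_disc
    p = float(sps.chi2.sf(chi2, df=1))
    direction_p = None
    if p < 0.05:
        k = max(n01, n10)
        direction_p = float(sps.binom.sf(k - 1, n_disc, 0.5))
    return float(chi2), p, direction_p


def paired_bootstrap_auc_test(
    scores_a, scores_b, labels, B: int = 100, seed: int = 0
) -> tuple[float, float, float]:
    """One-sided paired-bootstrap test that pipeline A's AUC exceeds B's.

    Draws ``B`` shared resamples (the same indices for both score vectors),
    computes the per-replicate AUC difference, and tests its mean against
    zero with a t statistic ``mean / (sd / sqrt(B))`` on ``B - 1`` degrees
    of freedom. Identical score vectors give p = 1 by convention.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary_labels(labels)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score vectors and labels must have equal length")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = y.size
    diffs = np.empty(B)
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == 0 and yb.max() == 1:
                break
        else:
            raise ValueError("could not draw a two-class resample")
        diffs[b] = roc_auc(sa[idx], yb) - roc_auc(sb[idx], yb)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        # degenerate replicate distribution: no evidence either way
        return mean_diff, 0.0, 1.0 if mean_diff <= 0 else 0.0
    t = mean_diff / (sd / np.sqrt(B))
    p = float(sps.t.sf(t, df=B - 1))
    return mean_diff, float(t), p
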