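"""ROC-based inference implemented from first principles.

The estimator throughout is the Mann-Whitney AUROC: over all positive x
negative score pairs, a positive outranking a negative scores 1, a tie
scores 1/2.  This equals the trapezoidal area under the empirical ROC
curve.  On top of it sit a stratified percentile bootstrap for confidence
intervals, the Mason-Graham significance test for H0: AUC = 0.5 (exact
Mann-Whitney enumeration at small n, tie-corrected normal approximation
otherwise), the paired DeLong test for comparing two correlated AUCs, and
cutoff-based confusion metrics.

Ties matter here: classifier probabilities that are vote fractions over a
finite forest produce tied scores routinely, so every routine half-credits
ties rather than assuming continuous scores.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "ConfusionMetrics",
    "auroc",
    "bootstrap_auc_ci",
    "mason_graham_p",
    "delong_paired_test",
    "confusion_at_cutoff",
    "auroc_by_group",
    "roc_curve_points",
]


@dataclass
class RocResult:
    """AUROC with optional bootstrap CI and significance p-value."""

    auc: float
    n_pos: int
    n_neg: int
    ci_level: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    p_value: Optional[float] = None
    method_tag: str = "mann-whitney"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("RocResult requires at least one case per class")
        if self.ci_lower is not None and not (
            self.ci_lower <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_upper
        ):
            raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class ConfusionMetrics:
    """Counts and derived rates at a fixed probability cutoff.

    The tie rule matches the classifiers: a score strictly above the cutoff
    is called positive; a score exactly at the cutoff is called negative.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: Optional[float] = field(init=False)
    npv: Optional[float] = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        if total == 0:
            raise ValueError("empty confusion table")
        self.sensitivity = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")
        self.specificity = self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")
        if self.tp + self.fp:
            self.ppv = self.tp / (self.tp + self.fp)
        else:
            self.ppv = None
            warnings.warn("no predicted positives: PPV undefined", stacklevel=2)
        if self.tn + self.fn:
            self.npv = self.tn / (self.tn + self.fn)
        else:
            self.npv = None
            warnings.warn("no predicted negatives: NPV undefined", stacklevel=2)
        self.accuracy = (self.tp + self.tn) / total

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    labels = labels.astype(bool) if labels.dtype == bool else np.asarray(labels, dtype=float) > 0.5
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need both classes present (got {n_pos} positives, {n_neg} negatives)"
        )
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    return scores, labels, n_pos, n_neg


def _auc_core(scores: np.ndarray, labels: np.ndarray) -> float:
    """Midrank formula for the Mann-Whitney AUC (ties half-credited)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc(scores, labels) -> RocResult:
    """Mann-Whitney AUROC of ``scores`` for binary ``labels``.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with ties counted 1/2; equivalently the
    trapezoidal area under the empirical ROC curve.
    """
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    return RocResult(auc=_auc_core(scores, labels), n_pos=n_pos, n_neg=n_neg)


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> RocResult:
    """Stratified bootstrap percentile CI for the AUROC.

    Positives and negatives are resampled with replacement separately, so
    every replicate retains both classes. ``method='bca'`` applies the
    bias-corrected and accelerated adjustment to the percentile points.
    """
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    if n_pos < 2 or n_neg < 2:
        raise ValueError("bootstrap CI needs at least 2 cases per class")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    point = _auc_core(scores, labels)

    boot = np.empty(n_boot)
    boot_labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    for b in range(n_boot):
        ps = pos[rng.integers(0, n_pos, n_pos)]
        ns = neg[rng.integers(0, n_neg, n_neg)]
        boot[b] = _auc_core(np.concatenate([ps, ns]), boot_labels)

    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    elif method == "bca":
        # bias correction from the bootstrap distribution, acceleration from
        # jackknife-over-cases influence values
        z0 = norm.ppf(np.clip(np.mean(boot < point), 1e-6, 1 - 1e-6))
        jack = np.empty(scores.size)
        for i in range(scores.size):
            mask = np.ones(scores.size, bool)
            mask[i] = False
            jack[i] = _auc_core(scores[mask], labels[mask])
        d = jack.mean() - jack
        denom = 6.0 * (d**2).sum() ** 1.5
        a = (d**3).sum() / denom if denom > 0 else 0.0
        za, zb = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
        p_lo = norm.cdf(z0 + (z0 + za) / (1 - a * (z0 + za)))
        p_hi = norm.cdf(z0 + (z0 + zb) / (1 - a * (z0 + zb)))
        lo, hi = np.quantile(boot, [p_lo, p_hi])
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    lo = min(lo, point)
    hi = max(hi, point)
    return RocResult(
        auc=point,
        n_pos=n_pos,
        n_neg=n_neg,
        ci_level=level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        seed=seed,
        method_tag=f"mann-whitney/bootstrap-{method}",
    )


def _exact_mann_whitney_p(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-sided p by full enumeration of label assignments to the scores.

    Under H0 the positive labels are an exchangeable subset of the pooled
    scores; p = P(AUC* >= observed AUC) over all C(n, n_pos) assignments.
    """
    n = scores.size
    n_pos = int(labels.sum())
    observed = _auc_core(scores, labels)
    count = 0
    total = 0
    idx = np.arange(n)
    lab = np.zeros(n, dtype=bool)
    for combo in itertools.combinations(idx, n_pos):
        lab[:] = False
        lab[list(combo)] = True
        total += 1
        if _auc_core(scores, lab) >= observed - 1e-12:
            count += 1
    return count / total


def mason_graham_p(
    scores,
    labels,
    alternative: str = "greater",
    exact_max_n: int = 12,
) -> float:
    """Significance of the AUROC against H0: AUC = 0.5.

    Uses the exact Mann-Whitney permutation null when the pooled sample is
    small (n <= ``exact_max_n``), otherwise the tie-corrected normal
    approximation of the Mann-Whitney U statistic. One-sided toward
    AUC > 0.5 by default; ``alternative='two-sided'`` doubles the smaller
    tail.
    """
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    n = n_pos + n_neg
    if n <= exact_max_n:
        p_greater = _exact_mann_whitney_p(scores, labels)
        if alternative == "greater":
            return float(p_greater)
        p_less = _exact_mann_whitney_p(-scores, labels)
        return float(min(1.0, 2.0 * min(p_greater, p_less)))

    auc = _auc_core(scores, labels)
    u = auc * n_pos * n_neg
    mu = n_pos * n_neg / 2.0
    # tie correction: subtract sum(t^3 - t) over tie groups
    _, counts = np.unique(scores, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = (n_pos * n_neg / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all scores tied
        return 1.0
    sd = math.sqrt(var)
    # continuity correction: U is lattice-valued, and the enumeration
    # convention is P(U* >= u) / P(U* <= u) including the observed value
    p_greater = float(norm.sf((u - 0.5 - mu) / sd))
    if alternative == "greater":
        return p_greater
    if alternative == "two-sided":
        p_less = float(norm.cdf((u + 0.5 - mu) / sd))
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative {alternative!r}")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: per-positive and per-negative empirical
    probabilities of outranking the other class (ties half-credited)."""
    pos = scores[labels]
    neg = scores[~labels]
    # V10[i] = P_hat(pos_i > neg) ; V01[j] = P_hat(pos > neg_j)
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_paired_test(scores_a, scores_b, labels):
    """Paired DeLong test for H0: AUC_a = AUC_b on the same participants.

    Returns ``(auc_a, auc_b, z, p_two_sided)``. The variance of the AUC
    difference uses the empirical covariance of the placement values, so the
    pairing of the two score vectors is fully exploited.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    scores_a, labels_bool, n_pos, n_neg = _validate(scores_a, labels)
    scores_b, _, _, _ = _validate(scores_b, labels)

    v10_a, v01_a = _placements(scores_a, labels_bool)
    v10_b, v01_b = _placements(scores_b, labels_bool)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())

    def cov(x, y):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    s10 = np.array([[cov(v10_a, v10_a), cov(v10_a, v10_b)],
                    [cov(v10_b, v10_a), cov(v10_b, v10_b)]])
    s01 = np.array([[cov(v01_a, v01_a), cov(v01_a, v01_b)],
                    [cov(v01_b, v01_a), cov(v01_b, v01_b)]])
    s = s10 / n_pos + s01 / n_neg
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def confusion_at_cutoff(scores, labels, cutoff: float = 0.5) -> ConfusionMetrics:
    """Confusion metrics at a probability cutoff (score > cutoff => positive)."""
    scores, labels, _, _ = _validate(scores, labels)
    pred = scores > cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff)


def auroc_by_group(scores, labels, groups) -> dict:
    """Per-group AUROCs plus the pooled result.

    Groups missing one of the classes are skipped with a warning (a
    single-center cohort with only controls has no ROC curve).
    Returns ``{"pooled": RocResult, group_id: RocResult, ...}``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    out = {"pooled": auroc(scores, labels)}
    for g in np.unique(groups):
        mask = groups == g
        try:
            out[g.item() if hasattr(g, "item") else g] = auroc(scores[mask], labels[mask])
        except ValueError:
            warnings.warn(f"group {g!r} lacks one class; skipped", stacklevel=2)
    return out


def roc_curve_points(scores, labels):
    """Empirical ROC curve as (fpr, tpr) arrays, thresholds descending,
    anchored at (0,0) and (1,1)."""
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # collapse tied thresholds: keep last index of each distinct score
    keep = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return fpr, tpr
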