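"""Statistical comparison of percent-change classifiers against visual labels.

The question these routines answer: how well does a continuous percent-change
score (2D area, solid volume, whole volume) separate images that a
neuroradiologist called progressive (or responding) from those they did not?
The toolkit is the standard one for paired diagnostic comparisons:

* empirical ROC curves and the Mann–Whitney AUC,
* stratified bootstrap confidence intervals (positives and negatives
  resampled separately, preserving class counts),
* the paired DeLong test for correlated AUC differences,
* sensitivity/specificity sweeps over a threshold grid with the
  "80% sensitivity inside the 95% CI" selection rule,
* weighted kappa for ordinal inter-reader agreement, and
* Friedman / one-way ANOVA / Wilcoxon rank-sum group comparisons.

Orientation convention: scores are signed percent changes; for detecting
progression the raw change is used (larger = more progressed), for detecting
response the negated change is used, so "score >= threshold" is always the
positive call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .criteria import BTRADS_ORDER


class DegenerateLabelsError(ValueError):
    """ROC analysis needs at least one positive and one negative label."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    positive_label: str = "PD"
    orientation: int = +1

    def trapezoid_auc(self) -> float:
        """Area under this empirical curve by the trapezoid rule."""
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class CIFraction:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ThresholdPerformance:
    threshold: float
    sensitivity: CIFraction
    specificity: CIFraction
    selected: bool = False


@dataclass(frozen=True)
class KappaResult:
    kappa_weighted: float
    kappa_unweighted: float
    observed_agreement: float
    weight_scheme: str = "linear"
    ci: Optional[tuple[float, float]] = None


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateLabelsError(
            "need at least one positive and one negative label"
        )


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_label: str = "PD",
    orientation: int = +1,
) -> ROCCurve:
    """Empirical ROC curve with one operating point per distinct score.

    Ties are grouped at a single operating point; the curve always includes
    the (0,0) and (1,1) endpoints.
    """
    s = orientation * np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_binary(y)
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr,
                    positive_label=positive_label, orientation=orientation)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻).

    Computed by midrank counting over all positive–negative pairs, which is
    exactly the area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_binary(y)
    pos = s[y == 1]
    neg = s[y == 0]
    # midranks over the pooled sample give the pair-count statistic in O(n log n)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    n1, n0 = len(pos), len(neg)
    u = r_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stratified_bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC with a percentile CI from class-stratified bootstrap resampling.

    Positives and negatives are resampled with replacement separately so each
    replicate preserves the observed class counts (a degenerate single-class
    replicate is impossible by construction).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_binary(y)
    pos = s[y == 1]
    neg = s[y == 0]
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, n1, n1)]
        n = neg[rng.integers(0, n0, n0)]
        aucs[b] = auc(
            np.concatenate([p, n]),
            np.concatenate([np.ones(n1, int), np.zeros(n0, int)]),
        )
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    point = auc(s, y)
    return AUCResult(
        auc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DeLong paired test
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-positive and per-negative placement values (midrank convention)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i] = mean over negatives of 1[pos_i > neg] + 1/2 1[pos_i = neg]
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same images.  Returns
    (auc_a − auc_b, z, two-sided p) using the placement-value covariance
    estimator and a normal reference.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores and labels must have equal length")
    _check_binary(y)
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    diff = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        if diff == 0:
            return 0.0, 0.0, 1.0
        import warnings

        warnings.warn(
            "zero DeLong variance with nonzero AUC difference; reporting p=0",
            stacklevel=2,
        )
        return float(diff), math.copysign(math.inf, diff), 0.0
    z = diff / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(diff), float(z), float(p)


# ---------------------------------------------------------------------------
# threshold performance
# ---------------------------------------------------------------------------

def _sens_spec(s: np.ndarray, y: np.ndarray, threshold: float) -> tuple[float, float]:
    call = s >= threshold
    sens = call[y == 1].mean()
    spec = (~call[y == 0]).mean()
    return float(sens), float(spec)


def sens_spec_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> ThresholdPerformance:
    """Median sensitivity/specificity at a fixed threshold with bootstrap CIs.

    A positive call is "score >= threshold".  Median and 95% percentile CI
    are taken over class-stratified bootstrap replicates, matching how the
    per-threshold operating characteristics are reported.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_binary(y)
    pos = s[y == 1]
    neg = s[y == 0]
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    sens = np.empty(n_boot)
    spec = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, n1, n1)]
        n = neg[rng.integers(0, n0, n0)]
        sens[b] = (p >= threshold).mean()
        spec[b] = (n < threshold).mean()
    def ci(v: np.ndarray) -> CIFraction:
        lo, hi = np.percentile(v, [2.5, 97.5])
        return CIFraction(float(np.median(v)), float(lo), float(hi))
    return ThresholdPerformance(threshold=threshold, sensitivity=ci(sens),
                                specificity=ci(spec))


def optimal_threshold_range(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float],
    target_sens: float = 0.80,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[ThresholdPerformance]:
    """Sweep a threshold grid; mark thresholds whose sensitivity 95% CI
    contains the target sensitivity (inclusive at both CI bounds)."""
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    out = []
    for i, thr in enumerate(grid):
        perf = sens_spec_at_threshold(
            scores, labels, thr, n_boot=n_boot, seed=seed + i
        )
        sel = perf.sensitivity.ci_low <= target_sens <= perf.sensitivity.ci_high
        out.append(ThresholdPerformance(perf.threshold, perf.sensitivity,
                                        perf.specificity, selected=sel))
    return out


# ---------------------------------------------------------------------------
# inter-reader agreement
# ---------------------------------------------------------------------------

def weighted_kappa(
    reads_a: Sequence[str],
    reads_b: Sequence[str],
    scheme: str = "linear",
    categories: Sequence[str] = BTRADS_ORDER,
) -> KappaResult:
    """Weighted kappa for two ordinal read vectors.

    κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij with disagreement weights
    w_ij = |i−j| (linear, default) or (i−j)² (quadratic) over the ordinal
    category positions; E is the chance-agreement table from the marginals.
    Raw observed (exact-match) agreement is returned alongside.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    if len(reads_a) != len(reads_b) or len(reads_a) == 0:
        raise ValueError("read vectors must be non-empty and equal length")
    pos = {c: i for i, c in enumerate(categories)}
    try:
        ia = np.array([pos[str(r)] for r in reads_a])
        ib = np.array([pos[str(r)] for r in reads_b])
    except KeyError as e:
        raise ValueError(f"unknown category {e.args[0]!r}") from None
    k = len(categories)
    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    idx = np.arange(k)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    w = d if scheme == "linear" else d**2
    def kap(wts: np.ndarray) -> float:
        denom = (wts * expected).sum()
        if denom == 0:
            return 1.0
        return float(1.0 - (wts * obs).sum() / denom)
    return KappaResult(
        kappa_weighted=kap(w),
        kappa_unweighted=kap((d > 0).astype(float)),
        observed_agreement=float(np.trace(obs) / n),
        weight_scheme=scheme,
    )


# ---------------------------------------------------------------------------
# group comparisons (thin wrappers; scipy provides the statistics)
# ---------------------------------------------------------------------------

def friedman_test(block_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank ANOVA over a blocks × methods matrix of paired values."""
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 methods")
    if np.ptp(x, axis=1).max() == 0:  # scipy rejects all-constant rows
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*(x[:, j] for j in range(x.shape[1])))
    return float(stat), float(p)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Standard between/within one-way ANOVA F test."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arr = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arr)
    if np.allclose(grand, grand[0]):
        return 0.0, 1.0
    with np.errstate(divide="ignore"):
        f, p = sps.f_oneway(*arr)
    if math.isinf(f):
        return math.inf, 0.0
    return float(f), float(p)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration when both samples have <= 10 observations and no ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: no information either way
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
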