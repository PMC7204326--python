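"""Nonparametric test battery, multiple-testing adjustment and PCA.

Two-group comparisons use the Mann–Whitney U test (independent samples)
or the Wilcoxon signed-rank test (paired samples); three or more groups
use the Kruskal–Wallis rank-sum test. Small samples are handled exactly:
Mann–Whitney switches to the exact null distribution when the combined
sample size is at most 25 and there are no ties, and the signed-rank
test uses the exact sign-flip permutation distribution (computed by
dynamic programming over midranks, so ties in |d| are handled exactly)
whenever at most 20 nonzero differences remain. Larger samples fall back
to the usual normal approximations with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    exact: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    return _ALTERNATIVES[alternative]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann–Whitney U test for two independent samples.

    Exact p by full enumeration of the null distribution when
    ``len(x) + len(y) <= 25`` and the pooled data contain no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size + y.size <= 25) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alt, method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="mann_whitney_u",
        n_per_group=(x.size, y.size),
        exact=use_exact,
    )


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact sign-flip distribution of 2*W+ given doubled midranks.

    Returns counts over sums 0..sum(double_ranks); entry s is the number
    of the 2**n sign patterns whose positive-rank sum (doubled) equals s.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Wilcoxon signed-rank test for two paired samples.

    Zero differences are dropped (Wilcoxon convention); if all
    differences are zero the result is degenerate with p = 1. With at
    most 20 nonzero differences the p-value comes from the exact
    sign-flip permutation distribution (midranks, exact under ties);
    beyond that, normal approximation with tie and continuity
    corrections.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", (x.size, y.size), True, True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 20:
        double_ranks = np.round(2 * ranks).astype(int)
        dist = _signed_rank_distribution(double_ranks)
        total = 2 ** n
        w2 = int(round(2 * w_plus))
        cdf = dist.cumsum()
        p_less = cdf[w2] / total
        p_greater = (total - (cdf[w2 - 1] if w2 > 0 else 0.0)) / total
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            # the sign-flip distribution is symmetric about sum(ranks)/2
            mid = dist.size - 1
            dev = abs(2 * w2 - mid)
            sums2 = 2 * np.arange(dist.size) - mid
            p = dist[np.abs(sums2) >= dev].sum() / total
        return TestResult(w_plus, float(min(1.0, p)), "wilcoxon_signed_rank", (n, n), True)
    res = sps.wilcoxon(
        d, alternative=_ALTERNATIVES[alternative], correction=True, method="approx"
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank", (n, n), False
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank-sum test with tie correction."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrs)
    sizes = tuple(a.size for a in arrs)
    if np.unique(pooled).size == 1:
        # all observations identical: H = 0 by convention
        return TestResult(0.0, 1.0, "kruskal_wallis", sizes, False, True)
    res = sps.kruskal(*arrs)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal_wallis", sizes, False)


def _check_pvals(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr))):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bonferroni_adjust(p: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    arr = _check_pvals(p)
    if arr.size == 0:
        return arr
    return np.minimum(1.0, arr * arr.size)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    arr = _check_pvals(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r * r), float(p)


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_variables, n_components)
    variance_explained: np.ndarray  # fractions, decreasing
    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)


def pca(
    matrix: np.ndarray,
    scale: bool = False,
    orientation: Optional[np.ndarray] = None,
) -> PCAResult:
    """Covariance (or correlation, if ``scale``) PCA via SVD.

    Components are ordered by decreasing variance. Sign convention: each
    component is flipped so its largest-magnitude loading is positive;
    if ``orientation`` (length n_variables) is given, the first
    component is instead flipped so ``loadings[:, 0] @ orientation >= 0``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples and >= 2 variables")
    if np.any(np.isnan(X)):
        raise ValueError("missing values not allowed in PCA input")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = Xc.std(axis=0, ddof=1)
    if scale:
        if np.any(sd == 0):
            raise ValueError("zero-variance column with scale=True")
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2 / max(X.shape[0] - 1, 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    loadings = Vt.T
    scores = U * S
    for j in range(loadings.shape[1]):
        if j == 0 and orientation is not None:
            o = np.asarray(orientation, dtype=float)
            flip = loadings[:, 0] @ o < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(scores=scores, loadings=loadings, variance_explained=frac, mean=mean, sd=sd)
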