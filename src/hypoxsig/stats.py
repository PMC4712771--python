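"""Wilcoxon rank-sum test and the transcriptome-breadth comparison.

The test is implemented in-repo so its tie policy is pinned: midranks for
ties, exact enumeration of all C(n1+n2, n1) rank assignments when the
pooled sample is small (n1+n2 <= 20) and tie-free, otherwise a normal
approximation with tie-corrected variance and continuity correction
(matching R's ``wilcox.test`` behaviour).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .errors import ValidationError

__all__ = ["RankTestResult", "wilcoxon_rank_sum", "breadth_comparison"]

#: Smallest p-value ever reported; p-values are floored here, never 0.
P_FLOOR = np.finfo(float).tiny

EXACT_LIMIT = 20


@dataclass
class RankTestResult:
    """Outcome of a rank-sum comparison.

    ``statistic`` is the rank sum W of the first sample; ``method`` is
    ``"exact"`` (full enumeration) or ``"normal_approx"``.
    """

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    alternative: str = "two_sided"

    def format_p(self, floor: float = 2.2e-16) -> str:
        """Human-readable p, ``"< {floor}"`` below the display floor."""
        if self.p_value < floor:
            return f"< {floor:g}"
        return f"{self.p_value:.4g}"


def _exact_ranksum_counts(n: int, n1: int) -> np.ndarray:
    """Number of size-n1 subsets of ranks 1..n attaining each rank sum.

    counts[s] = #subsets with sum s; classic dynamic programme over the
    ranks, O(n * n1 * max_sum).
    """
    max_sum = n1 * (2 * n - n1 + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    return dp[n1]


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> RankTestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    ``alternative`` is ``two_sided``, ``greater`` (x tends larger) or
    ``less``. Exact p-values are computed by enumerating the rank-sum
    distribution whenever n1+n2 <= 20 and the pooled data are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum requires non-empty samples")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValidationError(f"unknown alternative: {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    W = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_LIMIT and not has_ties:
        counts = _exact_ranksum_counts(n, n1)
        total = counts.sum()
        w = int(round(W))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean_W = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var_W = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var_W <= 0:
            p = 1.0
        else:
            sd = np.sqrt(var_W)
            d = W - mean_W
            if alternative == "greater":
                z = (d - 0.5) / sd
                p = norm.sf(z)
            elif alternative == "less":
                z = (d + 0.5) / sd
                p = norm.cdf(z)
            else:
                z = (abs(d) - 0.5) / sd
                p = 2.0 * norm.sf(max(z, 0.0))
                p = min(1.0, p)
        method = "normal_approx"

    return RankTestResult(
        statistic=W,
        p_value=float(max(p, P_FLOOR)),
        method=method,
        n1=n1,
        n2=n2,
        alternative=alternative,
    )


def breadth_comparison(
    detable_hypoxia: pd.DataFrame,
    detable_cocl2: pd.DataFrame,
    alternative: str = "two_sided",
    paired: bool = False,
):
    """Compare transcriptome-response breadth between two contrasts.

    Takes the per-gene DE tables of the two contrasts, restricts to their
    shared gene universe with finite log2 fold-changes, and compares the
    |log2fc| distributions with an unpaired rank-sum test by default
    (``paired=True`` switches to the signed-rank test on per-gene
    differences). Returns ``(RankTestResult, sorted_abs_l2fc_hypoxia,
    sorted_abs_l2fc_cocl2)``; the sorted vectors are the plotting
    profiles (genes ranked by |log2fc|).
    """
    shared = detable_hypoxia.index.intersection(detable_cocl2.index)
    if len(shared) == 0:
        raise ValidationError("the two DE tables share no genes")
    a = detable_hypoxia.loc[shared, "log2FoldChange"].to_numpy(dtype=float)
    b = detable_cocl2.loc[shared, "log2FoldChange"].to_numpy(dtype=float)
    finite = np.isfinite(a) & np.isfinite(b)
    if not finite.any():
        raise ValidationError("no shared genes with finite fold-changes")
    abs_a, abs_b = np.abs(a[finite]), np.abs(b[finite])
    if paired:
        result = _signed_rank(abs_a, abs_b, alternative)
    else:
        result = wilcoxon_rank_sum(abs_a, abs_b, alternative=alternative)
    return result, np.sort(abs_a)[::-1], np.sort(abs_b)[::-1]


def _signed_rank(x: np.ndarray, y: np.ndarray, alternative: str) -> RankTestResult:
    """Wilcoxon signed-rank on paired differences, normal approximation
    with tie/zero correction (Pratt's zero handling is not used; zeros
    are dropped, as in R's default)."""
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return RankTestResult(0.0, 1.0, "normal_approx", x.size, y.size, alternative)
    r = rankdata(np.abs(d))
    Wp = float(r[d > 0].sum())
    mean_W = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_W = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var_W)
    dd = Wp - mean_W
    if alternative == "greater":
        p = norm.sf((dd - 0.5) / sd)
    elif alternative == "less":
        p = norm.cdf((dd + 0.5) / sd)
    else:
        p = min(1.0, 2.0 * norm.sf(max((abs(dd) - 0.5) / sd, 0.0)))
    return RankTestResult(Wp, float(max(p, P_FLOOR)), "normal_approx",
                          x.size, y.size, alternative)
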