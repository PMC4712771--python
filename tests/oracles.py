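"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: pmfs are
evaluated from log-gamma formulas, tails by direct summation, and rank
statistics by explicit enumeration of assignments.
"""
from fractions import Fraction
from itertools import combinations
from math import comb, exp, inf, lgamma, log

import numpy as np


def nb_logpmf(k: int, mean: float, disp: float) -> float:
    """log NB pmf with variance mean + disp*mean^2, from log-gammas."""
    if disp <= 0.0:
        # Poisson limit
        return -mean + k * log(mean) - lgamma(k + 1) if mean > 0 else (
            0.0 if k == 0 else -inf)
    r = 1.0 / disp
    logp = log(r / (r + mean))
    logq = log(mean / (r + mean))
    return lgamma(k + r) - lgamma(r) - lgamma(k + 1) + r * logp + k * logq


def conditional_exact_p(kA: int, kB: int, meanA: float, dispA: float,
                        meanB: float, dispB: float) -> float:
    """Exhaustive conditional two-sided p over all splits of kA+kB."""
    K = kA + kB
    probs = [exp(nb_logpmf(a, meanA, dispA) + nb_logpmf(K - a, meanB, dispB))
             for a in range(K + 1)]
    total = sum(probs)
    pobs = probs[kA]
    acc = sum(p for p in probs if p <= pobs * (1 + 1e-12))
    return min(1.0, acc / total)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), exact rationals."""
    denom = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(acc)


def bh_stepup(pvals):
    """Literal step-up evaluation of the BH formula."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, m * p[i] / rank))
        adj[i] = running_min
    return adj


def exact_ranksum_p_two_sided(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all assignments.

    Assumes tie-free pooled data; doubles the smaller tail, capped at 1.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    n, n1 = len(pooled), len(x)
    sums = [sum(c) for c in combinations(range(1, n + 1), n1)]
    total = len(sums)
    p_le = sum(s <= w_obs for s in sums) / total
    p_ge = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mc_hypergeom_tail(rng: np.random.Generator, universe_size: int,
                      pathway_size: int, query_size: int, k: int,
                      n_draws: int = 100_000) -> tuple[float, float]:
    """Monte-Carlo estimate of P[X >= k] with its standard error.

    Draws random query subsets via the generator's hypergeometric
    sampler, an independent route from the closed-form tail sum.
    """
    counts = rng.hypergeometric(pathway_size, universe_size - pathway_size,
                                query_size, size=n_draws)
    p = float((counts >= k).mean())
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return p, se
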