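"""Brute-force enumeration oracle for the conditional NB exact test.

Kept independent of the package's implementation: pmfs from log-gamma
formulas, tails by direct summation over every split of the total.
"""
from math import exp, inf, lgamma, log


def nb_logpmf(k: int, mean: float, disp: float) -> float:
    if disp <= 0.0:
        return -mean + k * log(mean) - lgamma(k + 1) if mean > 0 else (
            0.0 if k == 0 else -inf)
    r = 1.0 / disp
    return (lgamma(k + r) - lgamma(r) - lgamma(k + 1)
            + r * log(r / (r + mean)) + k * log(mean / (r + mean)))


def conditional_exact_p(kA: int, kB: int, meanA: float, dispA: float,
                        meanB: float, dispB: float) -> float:
    K = kA + kB
    probs = [exp(nb_logpmf(a, meanA, dispA) + nb_logpmf(K - a, meanB, dispB))
             for a in range(K + 1)]
    total = sum(probs)
    pobs = probs[kA]
    acc = sum(p for p in probs if p <= pobs * (1 + 1e-12))
    return min(1.0, acc / total)
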