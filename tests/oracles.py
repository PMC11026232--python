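"""Independent brute-force oracles used to validate the statistical engines.

Each oracle recomputes a quantity by enumeration or naive search, sharing no
code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
from scipy import stats


def grid_logistic_mle(X: np.ndarray, y: np.ndarray,
                      half_width: float = 6.0, points: int = 11,
                      rounds: int = 18) -> tuple[np.ndarray, float]:
    """Maximise the logistic log-likelihood by iterative grid refinement.

    Full cartesian grid per round, re-centred (and only shrunk when the
    argmax is interior) — no gradients, no IRLS.  Returns (coef, loglik).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    k = X.shape[1]
    centre = np.zeros(k)
    width = np.full(k, half_width)

    def loglik(betas: np.ndarray) -> np.ndarray:
        eta = X @ betas.T  # (n, m)
        return (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)

    for _ in range(rounds):
        axes = [np.linspace(c - w, c + w, points)
                for c, w in zip(centre, width)]
        grid = np.array(list(itertools.product(*axes)))
        ll = loglik(grid)
        best = grid[np.argmax(ll)]
        on_edge = np.any(np.isclose(best, centre - width)
                         | np.isclose(best, centre + width))
        centre = best
        if not on_edge:
            width = width * (2.0 / (points - 1)) * 2.0
    return centre, float(loglik(centre[None, :])[0])


def hwe_enumeration_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration with rational arithmetic.

    Conditional probability of each heterozygote count given the allele
    counts; p = sum of probabilities no larger than the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    rare, common = min(n_a, n_b), max(n_a, n_b)
    if rare == 0:
        return 1.0
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = (common - het) // 2
        # multinomial genotype arrangements × 2^het allele orderings
        weights[het] = (Fraction(factorial(n),
                                 factorial(hom_r) * factorial(het)
                                 * factorial(hom_c))
                        * Fraction(2) ** het)
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    observed = probs[n_het]
    return float(sum(p for p in probs.values() if p <= observed))


def wilcoxon_enumeration_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating every group assignment of ranks."""
    values = list(x) + list(y)
    n1, n = len(x), len(values)
    ranks = stats.rankdata(values)

    def u_stat(indices) -> float:
        return sum(ranks[i] for i in indices) - n1 * (n1 + 1) / 2.0

    observed = u_stat(range(n1))
    us = np.array([u_stat(c)
                   for c in itertools.combinations(range(n), n1)])
    p_le = np.mean(us <= observed)
    p_ge = np.mean(us >= observed)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def simulate_chi2_power(n1: int, n0: int, p1: float, p0: float, alpha: float,
                        n_rep: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo power of the uncorrected two-proportion chi-square test.

    Returns (power estimate, Monte-Carlo standard error).
    """
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1, p1, size=n_rep)
    x0 = rng.binomial(n0, p0, size=n_rep)
    ph1 = x1 / n1
    ph0 = x0 / n0
    pooled = (x1 + x0) / (n1 + n0)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(var > 0, (ph1 - ph0) ** 2 / var, 0.0)
    reject = z2 >= stats.chi2.ppf(1 - alpha, 1)
    p_hat = reject.mean()
    return float(p_hat), float(np.sqrt(p_hat * (1 - p_hat) / n_rep))
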