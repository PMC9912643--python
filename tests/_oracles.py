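"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle sums
exact hypergeometric probabilities with rational arithmetic; the EM oracle
maximizes the two-allele multinomial likelihood on a dense theta grid; the
reference EM below is a plain, unoptimized fixed-point iteration.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the observed
    margins and summing those with probability <= the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return float(sum(p for p in probs if p <= p_obs))


def fisher_margin_pvalues(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Two-sided p for every table with margins (r1, r2) x (c1, .)."""
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)]
    return {
        lo + i: float(sum(p for p in probs if p <= probs[i]))
        for i in range(len(probs))
    }


def em_theta_grid_search(n_a: int, n_b: int, n_shared: int, step: float = 1e-4):
    """Maximize the two-allele multinomial likelihood over a dense theta
    grid.  Shared-class terms are constant in theta and ignored."""
    theta = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.zeros_like(theta)
        if n_a:
            ll += n_a * np.log(theta)
        if n_b:
            ll += n_b * np.log(1.0 - theta)
    return float(theta[np.nanargmax(ll)])


def em_reference(classes: dict[frozenset, int], alleles: list, n_iter: int = 5000):
    """Plain fixed-point EM run to many iterations, no convergence test."""
    idx = {a: i for i, a in enumerate(alleles)}
    theta = np.full(len(alleles), 1.0 / len(alleles))
    total = sum(classes.values())
    for _ in range(n_iter):
        est = np.zeros(len(alleles))
        for subset, count in classes.items():
            members = [idx[a] for a in subset]
            mass = theta[members].sum()
            for m in members:
                est[m] += count * theta[m] / mass
        theta = est / total
    return est
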