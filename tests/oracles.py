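"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the library
routines) used by the implementation: the affine-gap aligner is checked
against a from-scratch Gotoh dynamic program, and the RRA rho/permutation
machinery against the closed-form binomial order-statistic probability plus
exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEG = -1e18


def gotoh_score(ref: str, query: str, match: float = 2.0, mismatch: float = -3.0,
                gap_open: float = -10.0, gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap alignment score by dynamic programming.

    A gap of length L costs gap_open + (L-1) * gap_extend.  Row-vectorized
    Gotoh recursion: the match and delete states depend only on the previous
    row; the insert state is a prefix-max scan within the row.
    """
    n, m = len(ref), len(query)
    q = np.frombuffer(query.encode(), dtype="S1")

    def gap_cost(length: np.ndarray | int) -> np.ndarray | float:
        return gap_open + (np.asarray(length) - 1) * gap_extend

    j = np.arange(1, m + 1)
    # D: ref[i] aligned to query[j]; V: gap in query (delete ref[i]);
    # H: gap in ref (insert query[j])
    prev_best = np.concatenate(([0.0], gap_cost(j)))        # row 0
    prev_V = np.full(m + 1, NEG)
    for i in range(1, n + 1):
        sub = np.where(q == ref[i - 1].encode(), match, mismatch)
        D = np.concatenate(([NEG], prev_best[:-1] + sub))
        V = np.full(m + 1, NEG)
        V[0] = gap_cost(i)
        enter = np.maximum(prev_best[1:] + gap_open, prev_V[1:] + gap_extend)
        V[1:] = enter
        # H via prefix max of (entry score - k * extend)
        E = np.maximum(D, V)
        E[0] = gap_cost(i)            # boundary: all-delete prefix
        run = np.maximum.accumulate(E[:-1] - np.arange(m) * gap_extend)
        H = np.full(m + 1, NEG)
        H[1:] = run + gap_open + (j - 1) * gap_extend
        prev_best = np.maximum(E, H)
        prev_best[0] = gap_cost(i)
        prev_V = V
    return float(prev_best[m])


def order_statistic_tail(r: float, j: int, k: int) -> float:
    """P(j-th order statistic of k uniforms <= r), via the binomial sum.

    Equals P(X >= j) for X ~ Binomial(k, r) -- an independent closed form
    for the Beta(j, k - j + 1) CDF.
    """
    return sum(math.comb(k, i) * r ** i * (1 - r) ** (k - i)
               for i in range(j, k + 1))


def rra_rho(percentiles, alpha: float) -> float:
    """rho for one gene: min order-statistic tail over the alpha-screened prefix."""
    r = sorted(percentiles)
    k = len(r)
    terms = [order_statistic_tail(r[jj - 1], jj, k)
             for jj in range(1, k + 1) if r[jj - 1] <= alpha]
    return min(terms) if terms else 1.0


def rra_exhaustive_p(percentiles, gene_percentiles, alpha: float) -> float:
    """Exhaustive permutation p: fraction of all k-subsets with rho <= observed."""
    k = len(gene_percentiles)
    obs = rra_rho(gene_percentiles, alpha)
    combos = list(itertools.combinations(percentiles, k))
    hits = sum(rra_rho(c, alpha) <= obs + 1e-12 for c in combos)
    return hits / len(combos)
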