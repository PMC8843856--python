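"""Independent brute-force implementations used only to check the package.

These deliberately avoid the package's own code paths: pairwise statistics
come from explicit pair enumeration, Tajima constants from exact rational
arithmetic, and Fisher p-values from an explicit hypergeometric sum.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def pi_brute(matrix: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all unordered haplotype pairs."""
    n = matrix.shape[0]
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(matrix[i] != matrix[j]))
    return total / math.comb(n, 2)


def segregating_sites_brute(matrix: np.ndarray) -> int:
    n = matrix.shape[0]
    colsum = matrix.sum(axis=0)
    return int(np.sum((colsum > 0) & (colsum < n)))


def watterson_brute(S: int, n: int) -> float:
    a1 = sum(Fraction(1, i) for i in range(1, n))
    return float(Fraction(S) / a1)


def tajimas_d_brute(matrix: np.ndarray) -> float:
    """Tajima's D with constants computed in exact rational arithmetic."""
    n = matrix.shape[0]
    S = segregating_sites_brute(matrix)
    if S == 0 or n < 4:
        return math.nan
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = Fraction(
        sum(
            int(np.sum(matrix[i] != matrix[j]))
            for i, j in itertools.combinations(range(n), 2)
        ),
        math.comb(n, 2),
    )
    theta = Fraction(S) / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return float(pi - theta) / math.sqrt(float(var))


def hudson_fst_brute(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Hudson-type Fst by explicit pair enumeration at shared positions."""
    na, nb = pop_a.shape[0], pop_b.shape[0]

    def mean_pairwise(mat_x, mat_y, within):
        total, count = 0, 0
        if within:
            for i, j in itertools.combinations(range(mat_x.shape[0]), 2):
                total += int(np.sum(mat_x[i] != mat_x[j]))
                count += 1
        else:
            for i in range(mat_x.shape[0]):
                for j in range(mat_y.shape[0]):
                    total += int(np.sum(mat_x[i] != mat_y[j]))
                    count += 1
        return total / count

    h_within = 0.5 * (mean_pairwise(pop_a, None, True) + mean_pairwise(pop_b, None, True))
    h_between = mean_pairwise(pop_a, pop_b, False)
    if h_between == 0:
        return math.nan
    return (h_between - h_within) / h_between


def fisher_greater_brute(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p = P(X >= a) under the hypergeometric null,
    computed as an exact rational sum."""
    row1 = a + b
    n = a + b + c + d
    col1 = a + c
    total = math.comb(n, col1)
    p = Fraction(0)
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > c + d:
            continue
        p += Fraction(math.comb(row1, x) * math.comb(c + d, col1 - x), total)
    return float(p)
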