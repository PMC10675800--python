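"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle works in
exact integer arithmetic via math.comb, and the Ward oracle recomputes
within-cluster sums of squares from the raw data matrix by brute force.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

# Tie tolerance of the point-probability rule, as an exact rational 1 + 1e-7.
_TOL_NUM = 10**7 + 1
_TOL_DEN = 10**7


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (integers)."""
    n = a + b + c + d
    r1, n1 = a + b, a + c
    kmin, kmax = max(0, r1 + n1 - n), min(r1, n1)
    m_obs = comb(r1, a) * comb(n - r1, n1 - a)
    total = 0
    for k in range(kmin, kmax + 1):
        m = comb(r1, k) * comb(n - r1, n1 - k)
        if m * _TOL_DEN <= m_obs * _TOL_NUM:
            total += m
    return total / comb(n, n1)


def ess(X: np.ndarray, clusters: list[list[int]]) -> float:
    """Total within-cluster sum of squares of a partition of the rows of X."""
    total = 0.0
    for members in clusters:
        sub = X[members]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def min_merge_increase(X: np.ndarray, clusters: list[list[int]]) -> float:
    """Smallest ESS increase over all single merges of the current partition."""
    base = ess(X, clusters)
    best = np.inf
    for i, j in itertools.combinations(range(len(clusters)), 2):
        merged = [c for k, c in enumerate(clusters) if k not in (i, j)]
        merged.append(clusters[i] + clusters[j])
        best = min(best, ess(X, merged) - base)
    return best


def replay_ward_and_check(tree, X: np.ndarray, atol: float = 1e-8) -> None:
    """Assert each merge of ``tree`` attains the step-wise minimal Ward
    objective, and that heights follow the d2 convention (sqrt of twice the
    ESS increase)."""
    n = tree.n_leaves
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m, (left, right, height, size) in enumerate(tree.merges):
        parts = [clusters[k] for k in sorted(clusters)]
        base = ess(X, parts)
        merged_members = clusters[left] + clusters[right]
        others = [c for k, c in clusters.items() if k not in (left, right)]
        increase = ess(X, others + [merged_members]) - base
        best = min_merge_increase(X, parts)
        assert increase <= best + atol, (
            f"merge {m}: increase {increase} exceeds minimum {best}")
        expected_height = np.sqrt(max(2.0 * increase, 0.0))
        assert abs(height - expected_height) <= atol * (1 + expected_height)
        assert size == len(merged_members)
        del clusters[left], clusters[right]
        clusters[n + m] = merged_members
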