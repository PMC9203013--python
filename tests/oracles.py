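"""Independent brute-force oracles for exact tests (enumeration, no scipy)."""

from __future__ import annotations

import itertools
from math import comb


def binom_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p by summing outcomes no more likely than k."""
    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    ref = pmf[k] * (1 + 1e-12)
    return min(1.0, sum(x for x in pmf if x <= ref))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Table [[a, b], [c, d]]; margins fixed; sums probabilities of all tables
    no more likely than the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ref = prob(a) * (1 + 1e-12)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= ref))


def ranksum_two_sided(a: list[float], b: list[float]) -> float:
    """Two-sided exact rank-sum p over all C(n+m, n) group assignments.

    Assumes no ties.  The null rank-sum distribution is symmetric, so the
    symmetric-distance tail equals the doubled one-sided tail.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(a), len(b)
    w_obs = sum(ranks[v] for v in a)
    center = n * (n + m + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / total


def count_edges_brute(protein_set, edges) -> int:
    """O(k^2) double loop over set members, independent of the fast path."""
    members = sorted(protein_set)
    total = 0
    for i, x in enumerate(members):
        for y in members[i + 1 :]:
            if frozenset((x, y)) in edges:
                total += 1
    return total
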