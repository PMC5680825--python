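"""Independent brute-force reference implementations used by the tests.

Each oracle is written in the most transparent style possible (explicit
loops, exact rational arithmetic where feasible) so that agreement with
the optimized package code is meaningful evidence of correctness.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import accumulate
from math import comb


def binom_two_sided_oracle(k: int, n: int, p: Fraction) -> float:
    """Exact two-sided binomial p-value via rational enumeration.

    Sums Pr(j) over every j whose point probability is <= Pr(k), with
    the comparison done in exact rational arithmetic (so ties, e.g. the
    symmetric p = 1/2 case, are resolved exactly).
    """
    pmf = [comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(n + 1)]
    pk = pmf[k]
    return float(sum(pm for pm in pmf if pm <= pk))


def roh_oracle(calls, positions, min_markers, max_het, min_length):
    """Maximal-interval ROH by exhaustive enumeration.

    ``calls``: 0 hom, 1 het, -1 missing.  Returns half-open index
    intervals (l, r) that satisfy the het allowance, cannot be extended
    in either direction without exceeding it, and pass the marker-count
    and base-pair-span filters.
    """
    m = len(calls)
    het = [1 if c == 1 else 0 for c in calls]
    pre = [0] + list(accumulate(het))
    out = []
    for left in range(m):
        for right in range(left + 1, m + 1):
            h = pre[right] - pre[left]
            if h > max_het:
                break
            if left > 0 and h + het[left - 1] <= max_het:
                continue  # extendable left: not maximal
            if right < m and h + het[right] <= max_het:
                continue  # extendable right: not maximal
            n = right - left
            if n >= min_markers and (
                positions[right - 1] - positions[left] >= min_length
            ):
                out.append((left, right))
    return out


def group_overlapping_oracle(intervals):
    """Partition (start, end) half-open intervals into transitive-overlap
    groups via union-find; returns a list of frozensets of indices."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            si, ei = intervals[i]
            sj, ej = intervals[j]
            if si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def welch_oracle(x, y):
    """Welch two-sample t-test from the textbook formulas: (t, df, p)."""
    from scipy import stats

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def expected_homozygotes_oracle(trios, copies):
    """(E, n, matings) by direct per-trio looping.

    ``trios``: list of (offspring, sire, dam) panel indices;
    ``copies``: per-animal copy counts, -1 when undetermined.
    """
    e = 0.0
    n = 0
    pairs = set()
    for off, sire, dam in trios:
        cs, cd, co = copies[sire], copies[dam], copies[off]
        if cs >= 1 and cd >= 1 and co >= 0:
            e += (cs / 2.0) * (cd / 2.0)
            n += 1
            pairs.add((sire, dam))
    return e, n, len(pairs)
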