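"""Independent brute-force oracles used by the test suite only."""

from fractions import Fraction
from math import comb


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the table [[a, b], [c, d]]
    by exact hypergeometric tail enumeration with rational arithmetic."""
    n1 = a + b
    n2 = c + d
    k = a + c
    n = n1 + n2
    if n1 == 0:
        return 1.0
    hi = min(k, n1)
    denom = comb(n, n1)
    total = sum(Fraction(comb(k, x) * comb(n - k, n1 - x), denom)
                for x in range(a, hi + 1))
    return float(total)


def edit_distance_oracle(s1: str, s2: str) -> int:
    """Plain dynamic-programming Levenshtein distance."""
    prev = list(range(len(s2) + 1))
    for i, c1 in enumerate(s1, 1):
        cur = [i]
        for j, c2 in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (c1 != c2)))
        prev = cur
    return prev[-1]


def connected_component_clusters(keys: list[str], max_dist: int) -> list[set]:
    """All-pairs edit-distance clustering by transitive closure."""
    parent = list(range(len(keys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if edit_distance_oracle(keys[i], keys[j]) <= max_dist:
                parent[find(i)] = find(j)
    clusters: dict[int, set] = {}
    for i in range(len(keys)):
        clusters.setdefault(find(i), set()).add(i)
    return list(clusters.values())
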