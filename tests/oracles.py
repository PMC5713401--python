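"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive implementations (explicit loops, textbook formulas) kept
separate from the package so the two routes cannot share a bug.
"""

import math


def pearson_oracle(x, y):
    """Definitional product-moment correlation, term by term."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    dx = math.sqrt(sum((xi - mx) ** 2 for xi in x))
    dy = math.sqrt(sum((yi - my) ** 2 for yi in y))
    return num / (dx * dy)


def bh_oracle(pvalues):
    """Step-up BH by rank enumeration: adjusted p for the i-th smallest is
    min over ranks j >= i of p_(j) * n / j, capped at 1."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [None] * n
    for rank_pos, i in enumerate(order, start=1):
        candidates = [pvalues[order[j - 1]] * n / j
                      for j in range(rank_pos, n + 1)]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def bfs_components(nodes, edges):
    """Connected components by breadth-first search over an adjacency map.

    ``edges`` is an iterable of (a, b) pairs; isolated nodes form
    singletons. Returns a set of frozensets.
    """
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen = set()
    components = set()
    for start in nodes:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        component = {start}
        while queue:
            current = queue.pop(0)
            for neighbor in adjacency[current]:
                if neighbor not in seen:
                    seen.add(neighbor)
                    component.add(neighbor)
                    queue.append(neighbor)
        components.add(frozenset(component))
    return components


def ari_pair_oracle(labels_a, labels_b):
    """Adjusted Rand index by explicit pair counting over all unordered
    item pairs."""
    n = len(labels_a)
    assert n == len(labels_b)
    n00 = n01 = n10 = n11 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)
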