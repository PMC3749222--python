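"""Independent brute-force oracles used by the tests.

Everything here is written with plain Python data structures (no networkx)
so that it exercises none of the code paths it is used to check.
"""

from __future__ import annotations

import itertools
from typing import Sequence

Hap = tuple[int, ...]


def wdist(a: Hap, b: Hap, w: Sequence[int]) -> int:
    return sum(wi * abs(x - y) for wi, x, y in zip(w, a, b))


def bottleneck_by_threshold(
    nodes: list[Hap], w: Sequence[int]
) -> dict[tuple[Hap, Hap], int]:
    """Bottleneck distance via threshold scan: the smallest delta such that
    the endpoints are connected using only edges of length <= delta."""
    dist = {
        frozenset((u, v)): wdist(u, v, w)
        for u, v in itertools.combinations(nodes, 2)
    }
    out: dict[tuple[Hap, Hap], int] = {}
    thresholds = sorted(set(dist.values()))
    for u, v in itertools.combinations(nodes, 2):
        for delta in thresholds:
            # BFS using only edges <= delta
            seen, stack = {u}, [u]
            while stack:
                cur = stack.pop()
                for other in nodes:
                    if other in seen or other == cur:
                        continue
                    if dist[frozenset((cur, other))] <= delta:
                        seen.add(other)
                        stack.append(other)
            if v in seen:
                out[(u, v)] = delta
                break
    return out


def msn_edges(
    nodes: list[Hap], w: Sequence[int], eps: int = 0
) -> set[frozenset]:
    """Edges of the epsilon-relaxed minimum spanning network."""
    nodes = sorted(set(nodes))
    if len(nodes) < 2:
        return set()
    bneck = bottleneck_by_threshold(nodes, w)
    edges = set()
    for u, v in itertools.combinations(nodes, 2):
        if wdist(u, v, w) <= bneck[(u, v)] + eps:
            edges.add(frozenset((u, v)))
    return edges


def mst_union_by_cycle_property(
    nodes: list[Hap], w: Sequence[int]
) -> set[frozenset]:
    """Union of all MSTs via the cycle property: an edge belongs to some MST
    iff its endpoints are disconnected using only strictly lighter edges."""
    nodes = sorted(set(nodes))
    dist = {
        frozenset((u, v)): wdist(u, v, w)
        for u, v in itertools.combinations(nodes, 2)
    }
    edges = set()
    for e, d in dist.items():
        u, v = tuple(e)
        seen, stack = {u}, [u]
        while stack:
            cur = stack.pop()
            for other in nodes:
                if other in seen or other == cur:
                    continue
                if dist[frozenset((cur, other))] < d:
                    seen.add(other)
                    stack.append(other)
        if v not in seen:
            edges.add(e)
    return edges


def mst_length(nodes: list[Hap], w: Sequence[int]) -> int:
    """Kruskal with a hand-rolled union-find."""
    nodes = sorted(set(nodes))
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0
    edges = sorted(
        (wdist(u, v, w), u, v) for u, v in itertools.combinations(nodes, 2)
    )
    for d, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            total += d
    return total


def median_joining_oracle(
    haplotypes: Sequence[Hap], w: Sequence[int], eps: int = 0
) -> tuple[set[Hap], set[frozenset]]:
    """Definitional median-joining: MSN + connected-triplet medians to a
    fixpoint, then prune degree-<=2 unobserved nodes that do not shorten
    the minimum spanning tree.  Returns (node set, MSN edge set)."""
    observed = sorted(set(map(tuple, haplotypes)))
    nodes: set[Hap] = set(observed)
    while True:
        edges = msn_edges(sorted(nodes), w, eps)
        cands: dict[Hap, int] = {}
        for u, v, x in itertools.combinations(sorted(nodes), 3):
            present = sum(
                1 for e in (frozenset((u, v)), frozenset((u, x)), frozenset((v, x)))
                if e in edges
            )
            if present < 2:
                continue
            m = tuple(sorted(t)[1] for t in zip(u, v, x))
            if m in nodes:
                continue
            cost = wdist(m, u, w) + wdist(m, v, w) + wdist(m, x, w)
            if m not in cands or cost < cands[m]:
                cands[m] = cost
        if not cands:
            break
        lam = min(cands.values())
        nodes.update(m for m, c in cands.items() if c <= lam + eps)

    while True:
        edges = msn_edges(sorted(nodes), w, eps)
        degree = {n: 0 for n in nodes}
        for e in edges:
            for n in e:
                degree[n] += 1
        base = mst_length(sorted(nodes), w)
        removed = None
        for x in sorted(nodes - set(observed)):
            if degree[x] <= 2 and mst_length(sorted(nodes - {x}), w) <= base:
                removed = x
                break
        if removed is None:
            break
        nodes.discard(removed)
    return nodes, msn_edges(sorted(nodes), w, eps)


def reduced_median_retention_oracle(
    binary: list[tuple[int, ...]], w: Sequence[int], r: float
) -> set[tuple[int, ...]]:
    """Closure of triplet majority-medians retained when the best two-edge
    chain costs at most r times the median's star cost."""
    current = set(binary)
    while True:
        added = False
        for u, v, x in itertools.combinations(sorted(current), 3):
            m = tuple(1 if a + b + c >= 2 else 0 for a, b, c in zip(u, v, x))
            if m in current:
                continue
            star = wdist(m, u, w) + wdist(m, v, w) + wdist(m, x, w)
            chain = min(
                wdist(p, a, w) + wdist(p, b, w)
                for p, a, b in ((u, v, x), (v, u, x), (x, u, v))
            )
            if star > 0 and chain <= r * star:
                current.add(m)
                added = True
        if not added:
            break
    return current
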