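"""Median-joining networks with reduced-median preprocessing for Y-STR
haplotypes.

STR loci are treated as ordinal multistate characters with stepwise cost:
the distance between haplotypes a and b is sum_l w_l * |a_l - b_l|, where
the integer locus weights w_l are proportional to the inverse of the locus
repeat variance (fast, variable loci count for less).

The median-joining construction iterates two steps until a fixpoint:

1. build the minimum spanning network (MSN) over the current haplotype set
   — every edge whose length exceeds the bottleneck (single-linkage merge)
   distance of its endpoints by at most epsilon; at epsilon = 0 this is the
   union of all minimum spanning trees;
2. for every connected triplet of the MSN, form the per-locus median vector
   (the middle repeat count, which minimizes linear stepwise cost) and add
   the cheapest such unobserved vectors (connection cost within epsilon of
   the minimum).

Unobserved median vectors of degree <= 2 that no longer shorten the network
are pruned at the end, so surviving medians have degree >= 3.  Iteration
order is fixed (haplotypes sorted lexicographically), making the network
deterministic.

The reduced-median step operates on the binary (threshold) expansion of the
multistate data and retains a candidate median when the cost of the best
two-edge chain through an existing haplotype exceeds the median's star cost
by at most a factor r (default 2): large r keeps every candidate, r = 1
keeps only cost-neutral ones.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

Haplotype = tuple[int, ...]

MAX_WEIGHT = 99


@dataclass(frozen=True)
class LocusWeights:
    """Integer per-locus weights in [1, MAX_WEIGHT]."""

    loci: tuple[str, ...]
    w: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.w):
            raise ValueError("loci and weights differ in length")
        if any(not (1 <= x <= MAX_WEIGHT) for x in self.w):
            raise ValueError(f"weights must lie in [1, {MAX_WEIGHT}]")

    @classmethod
    def uniform(cls, n_loci: int, loci: Sequence[str] | None = None) -> "LocusWeights":
        loci = tuple(loci) if loci else tuple(f"L{i + 1}" for i in range(n_loci))
        return cls(loci=loci, w=(1,) * n_loci)


def compute_weights(
    haplotypes: Sequence[Haplotype],
    loci: Sequence[str] | None = None,
    cap: int = MAX_WEIGHT,
) -> LocusWeights:
    """Inverse-repeat-variance locus weights.

    w_l is proportional to 1/Var_l, scaled so the smallest weight is >= 1,
    rounded to integers and capped; a zero-variance locus gets the cap.
    """
    if len(haplotypes) < 2:
        raise ValueError("need n >= 2 haplotypes to estimate locus variances")
    arr = np.asarray([tuple(h) for h in haplotypes], dtype=float)
    var = arr.var(axis=0, ddof=1)
    if loci is None:
        loci = tuple(f"L{i + 1}" for i in range(arr.shape[1]))
    raw = np.full(arr.shape[1], np.nan)
    nonzero = var > 0
    raw[nonzero] = 1.0 / var[nonzero]
    if nonzero.any():
        lo = raw[nonzero].min()
        if lo < 1.0:
            raw[nonzero] /= lo
    weights = np.full(arr.shape[1], cap, dtype=int)
    weights[nonzero] = np.clip(np.rint(raw[nonzero]).astype(int), 1, cap)
    return LocusWeights(loci=tuple(loci), w=tuple(int(x) for x in weights))


def weighted_distance(a: Haplotype, b: Haplotype, weights: LocusWeights) -> int:
    """Stepwise distance sum_l w_l |a_l - b_l|."""
    return sum(w * abs(x - y) for w, x, y in zip(weights.w, a, b))


def _differing_loci(a: Haplotype, b: Haplotype, weights: LocusWeights) -> tuple[str, ...]:
    return tuple(l for l, x, y in zip(weights.loci, a, b) if x != y)


# ----------------------------------------------------------------------
def _bottleneck_distances(
    nodes: list[Haplotype], dist: dict[tuple[Haplotype, Haplotype], int]
) -> dict[tuple[Haplotype, Haplotype], int]:
    """Max edge on the MST path for every pair (single-linkage merge height)."""
    T = nx.Graph()
    T.add_nodes_from(nodes)
    for (u, v), d in dist.items():
        T.add_edge(u, v, weight=d)
    mst = nx.minimum_spanning_tree(T, weight="weight")
    bneck: dict[tuple[Haplotype, Haplotype], int] = {}
    for src in nodes:
        # DFS over the tree tracking the max edge seen so far
        stack = [(src, 0)]
        seen = {src}
        while stack:
            cur, mx = stack.pop()
            for nb in mst.neighbors(cur):
                if nb in seen:
                    continue
                seen.add(nb)
                m2 = max(mx, mst.edges[cur, nb]["weight"])
                if src < nb:
                    bneck[(src, nb)] = m2
                stack.append((nb, m2))
    return bneck


def minimum_spanning_network(
    nodes: Iterable[Haplotype], weights: LocusWeights, epsilon: int = 0
) -> nx.Graph:
    """Edges whose length is within epsilon of the bottleneck distance.

    At epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    nodes = sorted(set(map(tuple, nodes)))
    G = nx.Graph()
    G.add_nodes_from(nodes)
    if len(nodes) < 2:
        return G
    dist = {
        (u, v): weighted_distance(u, v, weights)
        for u, v in itertools.combinations(nodes, 2)
    }
    bneck = _bottleneck_distances(nodes, dist)
    for (u, v), d in dist.items():
        if d <= bneck[(u, v)] + epsilon:
            G.add_edge(u, v, length=d, diff_loci=_differing_loci(u, v, weights))
    return G


def _total_length(G: nx.Graph) -> int:
    return sum(d["length"] for _, _, d in G.edges(data=True))


def _mst_length(nodes: Iterable[Haplotype], weights: LocusWeights) -> int:
    nodes = sorted(set(nodes))
    if len(nodes) < 2:
        return 0
    T = nx.Graph()
    T.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        T.add_edge(u, v, weight=weighted_distance(u, v, weights))
    mst = nx.minimum_spanning_tree(T, weight="weight")
    return sum(d["weight"] for _, _, d in mst.edges(data=True))


def triplet_median(u: Haplotype, v: Haplotype, w: Haplotype) -> Haplotype:
    """Per-locus middle value — the stepwise-cost-minimizing Steiner point."""
    return tuple(sorted(t)[1] for t in zip(u, v, w))


@dataclass
class HaploNetwork:
    """Median-joining network: observed haplotypes plus median vectors."""

    graph: nx.Graph
    weights: LocusWeights
    epsilon: int
    multiplicity: dict[Haplotype, int]
    groups: dict[Haplotype, Counter]

    @property
    def observed(self) -> list[Haplotype]:
        return sorted(h for h in self.graph.nodes if self.multiplicity.get(h, 0) > 0)

    @property
    def median_vectors(self) -> list[Haplotype]:
        return sorted(h for h in self.graph.nodes if self.multiplicity.get(h, 0) == 0)

    @property
    def total_length(self) -> int:
        return _total_length(self.graph)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for h in sorted(self.graph.nodes):
            groups = self.groups.get(h, Counter())
            rows.append(
                {
                    "haplotype": ",".join(map(str, h)),
                    "multiplicity": self.multiplicity.get(h, 0),
                    "type": "observed" if self.multiplicity.get(h, 0) else "median",
                    "groups": ";".join(f"{g}:{c}" for g, c in sorted(groups.items())),
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "from": ",".join(map(str, u)),
                    "to": ",".join(map(str, v)),
                    "length": d["length"],
                    "loci": ";".join(d["diff_loci"]),
                }
            )
        return pd.DataFrame(rows)

    def write(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)


def median_joining(
    haplotypes: Sequence[Haplotype],
    weights: LocusWeights | None = None,
    epsilon: int = 0,
    groups: Sequence[Hashable] | None = None,
) -> HaploNetwork:
    """Build the weighted median-joining network of the haplotypes.

    `groups` (parallel to `haplotypes`) records the composition of each
    node, e.g. population labels for sector plots.
    """
    if len(haplotypes) < 2:
        raise ValueError("median-joining needs n >= 2 haplotypes")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    haps = [tuple(int(x) for x in h) for h in haplotypes]
    lengths = {len(h) for h in haps}
    if len(lengths) != 1:
        raise ValueError("haplotypes differ in length")
    if weights is None:
        weights = (
            compute_weights(haps)
            if len(set(haps)) > 1
            else LocusWeights.uniform(len(haps[0]))
        )

    multiplicity = Counter(haps)
    group_comp: dict[Haplotype, Counter] = {h: Counter() for h in multiplicity}
    if groups is not None:
        for h, g in zip(haps, groups):
            group_comp[h][g] += 1

    observed = sorted(multiplicity)
    nodes: set[Haplotype] = set(observed)

    # -- grow: add beneficial median vectors until fixpoint ------------
    while True:
        msn = minimum_spanning_network(nodes, weights, epsilon)
        candidates: dict[Haplotype, int] = {}
        node_list = sorted(nodes)
        for u, v, w in itertools.combinations(node_list, 3):
            n_edges = msn.has_edge(u, v) + msn.has_edge(u, w) + msn.has_edge(v, w)
            if n_edges < 2:  # triplet must be connected within the MSN
                continue
            m = triplet_median(u, v, w)
            if m in nodes:
                continue
            cost = (
                weighted_distance(m, u, weights)
                + weighted_distance(m, v, weights)
                + weighted_distance(m, w, weights)
            )
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        nodes.update(
            sorted(m for m, c in candidates.items() if c <= lam + epsilon)
        )

    # -- prune: drop low-degree medians that no longer shorten --------
    while True:
        msn = minimum_spanning_network(nodes, weights, epsilon)
        base = _mst_length(nodes, weights)
        removed = None
        for x in sorted(nodes - set(observed)):
            if msn.degree(x) <= 2 and _mst_length(nodes - {x}, weights) <= base:
                removed = x
                break
        if removed is None:
            break
        nodes.discard(removed)

    graph = minimum_spanning_network(nodes, weights, epsilon)
    return HaploNetwork(
        graph=graph,
        weights=weights,
        epsilon=epsilon,
        multiplicity={h: multiplicity.get(h, 0) for h in graph.nodes},
        groups={h: group_comp.get(h, Counter()) for h in graph.nodes},
    )


# ----------------------------------------------------------------------
# Reduced-median preprocessing (binary expansion of the multistate data)
# ----------------------------------------------------------------------
def _binarize(
    haps: list[Haplotype], weights: LocusWeights
) -> tuple[list[tuple[int, ...]], list[tuple[int, int, int]]]:
    """Threshold expansion: one 0/1 character per locus per unit step.

    Character (locus, threshold) is 1 iff a_locus >= threshold; stepwise
    distances are preserved exactly, each character inheriting its locus
    weight.  Returns (binary vectors, char descriptors (locus, thr, w)).
    """
    chars: list[tuple[int, int, int]] = []
    arr = np.asarray(haps, dtype=int)
    for l in range(arr.shape[1]):
        lo, hi = arr[:, l].min(), arr[:, l].max()
        for thr in range(lo + 1, hi + 1):
            chars.append((l, thr, weights.w[l]))
    binary = [
        tuple(1 if h[l] >= thr else 0 for l, thr, _ in chars) for h in haps
    ]
    return binary, chars


def _debinarize(
    vec: tuple[int, ...], chars: list[tuple[int, int, int]], base: list[int]
) -> Haplotype:
    values = list(base)
    for bit, (l, _thr, _w) in zip(vec, chars):
        values[l] += bit
    return tuple(values)


def reduced_median(
    haplotypes: Sequence[Haplotype],
    weights: LocusWeights | None = None,
    r: float = 2.0,
) -> list[Haplotype]:
    """Reduced-median preprocessing: observed haplotypes plus inferred
    intermediates (a superset of the input, duplicates collapsed).

    A candidate triplet median is retained when chain_cost <= r * star_cost,
    i.e. when routing through an existing haplotype would cost at least
    1/r of going through the median; r -> inf retains every candidate.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    haps = [tuple(int(x) for x in h) for h in haplotypes]
    distinct = sorted(set(haps))
    if len(distinct) < 3:
        return distinct
    if weights is None:
        weights = compute_weights(haps)

    binary, chars = _binarize(distinct, weights)
    arr = np.asarray(distinct, dtype=int)
    base = [int(arr[:, l].min()) for l in range(arr.shape[1])]
    wvec = [w for _, _, w in chars]

    def bdist(a: tuple[int, ...], b: tuple[int, ...]) -> int:
        return sum(w for w, x, y in zip(wvec, a, b) if x != y)

    current: set[tuple[int, ...]] = set(binary)
    while True:
        added = False
        for u, v, w in itertools.combinations(sorted(current), 3):
            m = tuple(1 if x + y + z >= 2 else 0 for x, y, z in zip(u, v, w))
            if m in current:
                continue
            star = bdist(m, u) + bdist(m, v) + bdist(m, w)
            chain = min(
                bdist(a, c) + bdist(c, b)
                for c, a, b in ((u, v, w), (v, u, w), (w, u, v))
            )
            if star > 0 and chain <= r * star:
                current.add(m)
                added = True
        if not added:
            break

    return sorted({_debinarize(vec, chars, base) for vec in current})
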