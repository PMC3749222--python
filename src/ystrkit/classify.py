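"""SNP-tree haplogroup classification and direct-count frequency tables.

A haplogroup tree is a rooted marker-labeled tree in YCC style: each node
(e.g. ``Q1a3a1a``) is defined by one or more biallelic markers (e.g. M3).
A sample's SNP calls (``ancestral`` / ``derived`` / ``untyped`` per marker)
place it at the deepest node whose root path is entirely derived.

Labels follow the node-marker convention ``Q1a3a1a-M3``; a trailing ``*``
marks a *paragroup*: chromosomes derived at the node but ancestral at every
examined downstream marker.  Markers that were never typed block nothing —
hierarchical typing leaves most deep branches untyped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ANCESTRAL = "ancestral"
DERIVED = "derived"
UNTYPED = "untyped"

_STATE_ALIASES = {
    "a": ANCESTRAL, "ancestral": ANCESTRAL, "0": ANCESTRAL,
    "d": DERIVED, "derived": DERIVED, "1": DERIVED,
    "u": UNTYPED, "untyped": UNTYPED, "-": UNTYPED, "": UNTYPED,
}


class InconsistentCallsError(ValueError):
    """Raised when SNP states contradict the tree topology."""


@dataclass(frozen=True)
class SnpCalls:
    """Per-sample marker states, normalized to ancestral/derived/untyped."""

    states: Mapping[str, str]

    def __post_init__(self) -> None:
        norm = {}
        for marker, state in self.states.items():
            key = str(state).strip().lower()
            if key not in _STATE_ALIASES:
                raise ValueError(f"unknown SNP state {state!r} for {marker}")
            norm[marker] = _STATE_ALIASES[key]
        object.__setattr__(self, "states", norm)

    def state(self, marker: str) -> str:
        return self.states.get(marker, UNTYPED)


@dataclass(frozen=True)
class TreeNode:
    name: str
    parent: str | None
    markers: tuple[str, ...]


class HaplogroupTree:
    """Rooted tree of haplogroup nodes, each with defining markers."""

    def __init__(self, nodes: Iterable[TreeNode]):
        self.nodes: dict[str, TreeNode] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise ValueError(f"duplicate node {n.name}")
            self.nodes[n.name] = n
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {len(roots)}")
        self.root = roots[0].name

        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise ValueError(f"{n.name}: unknown parent {n.parent}")
                self._children[n.parent].append(n.name)
            if not n.markers:
                raise ValueError(f"{n.name}: node has no defining marker")

        self.marker_node: dict[str, str] = {}
        for n in self.nodes.values():
            for m in n.markers:
                if m in self.marker_node:
                    raise ValueError(f"marker {m} defined on two nodes")
                self.marker_node[m] = n.name

        # cycle check + depths via root walk
        self._depth: dict[str, int] = {self.root: 0}
        stack = [self.root]
        while stack:
            cur = stack.pop()
            for ch in self._children[cur]:
                self._depth[ch] = self._depth[cur] + 1
                stack.append(ch)
        if len(self._depth) != len(self.nodes):
            raise ValueError("tree contains a cycle or disconnected node")

    # ------------------------------------------------------------------
    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def depth(self, node: str) -> int:
        return self._depth[node]

    def path_from_root(self, node: str) -> list[str]:
        path = [node]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path[::-1]

    def is_descendant(self, node: str, ancestor: str) -> bool:
        """True if `node` is `ancestor` or lies below it."""
        return ancestor in self.path_from_root(node)

    def descendants(self, node: str) -> list[str]:
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self._children[cur])
        return out

    def label(self, node: str, paragroup: bool = False) -> str:
        base = f"{node}-{self.nodes[node].markers[0]}"
        return base + "*" if paragroup else base

    def node_of_label(self, label: str) -> str | None:
        """Invert a ``Node-Marker[*]`` label; None for out-of-tree labels."""
        name = label.rstrip("*").split("-")[0]
        return name if name in self.nodes else None


def load_tree(path: str | Path | None = None) -> HaplogroupTree:
    """Load a tree from a node/parent/markers TSV; default: bundled Q tree."""
    if path is None:
        source = resources.files("ystrkit.data").joinpath("q_tree.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    nodes = []
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[:3] != ["node", "parent", "markers"]:
        raise ValueError("tree file must have columns node, parent, markers")
    for line in lines[1:]:
        name, parent, markers = line.split("\t")[:3]
        nodes.append(
            TreeNode(
                name=name.strip(),
                parent=None if parent.strip() in ("-", "") else parent.strip(),
                markers=tuple(m.strip() for m in markers.split(",") if m.strip()),
            )
        )
    return HaplogroupTree(nodes)


# ----------------------------------------------------------------------
def classify(calls: SnpCalls, tree: HaplogroupTree) -> str:
    """Assign the deepest all-derived node label; ``not-Q`` below the root.

    Raises :class:`InconsistentCallsError` when a derived marker sits below
    an ancestral one on the same root path, when one node's equivalent
    markers disagree, or when two derived nodes lie on different branches.
    """
    unknown = [m for m in calls.states if m not in tree.marker_node]
    if unknown:
        warnings.warn(f"ignoring markers not in tree: {sorted(unknown)}")

    def node_state(node: str) -> str:
        states = {calls.state(m) for m in tree.nodes[node].markers}
        if DERIVED in states and ANCESTRAL in states:
            raise InconsistentCallsError(
                f"conflicting states among equivalent markers of {node}: "
                f"{[(m, calls.state(m)) for m in tree.nodes[node].markers]}"
            )
        if DERIVED in states:
            return DERIVED
        if ANCESTRAL in states:
            return ANCESTRAL
        return UNTYPED

    root_state = node_state(tree.root)
    if root_state == UNTYPED:
        raise ValueError(f"root marker {tree.nodes[tree.root].markers[0]} untyped")
    if root_state == ANCESTRAL:
        return "not-Q"

    derived = sorted(
        (n for n in tree.nodes if node_state(n) == DERIVED),
        key=tree.depth,
    )
    deepest = derived[-1]
    path = tree.path_from_root(deepest)
    # all derived nodes must sit on one root path
    for n in derived:
        if n not in path:
            raise InconsistentCallsError(
                f"derived markers on diverging branches: "
                f"{tree.nodes[n].markers[0]} ({n}) vs "
                f"{tree.nodes[deepest].markers[0]} ({deepest})"
            )
    # no ancestral call above a derived one
    for n in path:
        if node_state(n) == ANCESTRAL:
            raise InconsistentCallsError(
                f"marker {tree.nodes[deepest].markers[0]} derived below "
                f"ancestral {tree.nodes[n].markers[0]}"
            )

    child_states = [node_state(c) for c in tree.children(deepest)]
    paragroup = ANCESTRAL in child_states and DERIVED not in child_states
    return tree.label(deepest, paragroup=paragroup)


# ----------------------------------------------------------------------
@dataclass
class FrequencyTable:
    """Direct-count frequencies of haplogroup labels per population.

    ``counts`` is populations x labels; percentages are taken within each
    population's classified total, rounded to one decimal.
    """

    counts: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def percentages(self) -> pd.DataFrame:
        pct = 100.0 * self.counts.div(self.row_totals, axis=0)
        return pct.round(1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.astype(str)
        pct = self.percentages
        for col in out.columns:
            mask = self.counts[col] > 0
            out.loc[mask, col] = (
                self.counts.loc[mask, col].astype(str)
                + " ("
                + pct.loc[mask, col].map(lambda v: f"{v:.1f}")
                + ")"
            )
            out.loc[~mask, col] = ""
        out.insert(0, "N", self.row_totals)
        out.to_csv(path, sep="\t")


def frequency_table(labels: Sequence[tuple[str, str]]) -> FrequencyTable:
    """Tally (population, label) pairs into a FrequencyTable.

    Row and column order follow first appearance in the input.
    """
    pops = list(dict.fromkeys(p for p, _ in labels))
    cols = list(dict.fromkeys(l for _, l in labels))
    counts = pd.DataFrame(0, index=pops, columns=cols, dtype=int)
    for pop, lab in labels:
        counts.loc[pop, lab] += 1
    counts.index.name = "population"
    return FrequencyTable(counts)


def aggregate_clade(
    table: FrequencyTable, node: str, tree: HaplogroupTree
) -> pd.Series:
    """Per-population count of samples in `node` or any descendant.

    Labels that do not resolve to a tree node (e.g. ``not-Q``) never count.
    """
    if node not in tree.nodes:
        raise ValueError(f"unknown tree node {node}")
    member = tree.descendants(node)
    cols = [
        c for c in table.counts.columns
        if (n := tree.node_of_label(c)) is not None and n in member
    ]
    return table.counts[cols].sum(axis=1)
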