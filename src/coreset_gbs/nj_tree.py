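"""Neighbor-joining trees on Euclidean-transformed dissimilarities.

The tree model is an unrooted leaf-labelled graph with non-negative edge
lengths, backed by :mod:`networkx`.  Newick parsing delegates to scikit-bio;
writing is done here so lengths round-trip at 10 significant digits.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_formats import SquareMatrix

__all__ = [
    "UnrootedTree",
    "NewickParseError",
    "sqrt_transform",
    "neighbor_joining",
    "bootstrap_support",
    "cut_into_groups",
]


class NewickParseError(ValueError):
    """Raised on malformed Newick input; carries the character position."""

    def __init__(self, message: str, position: int | None = None) -> None:
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)
        self.position = position


class UnrootedTree:
    """Unrooted leaf-labelled tree with non-negative edge lengths.

    Internal nodes are unlabeled integers; leaves carry a ``label`` attribute.
    Optional bipartition supports live in :attr:`supports`, keyed by the
    frozenset of leaf labels on one side (the side not containing the
    lexicographically smallest leaf, a canonical choice).
    """

    def __init__(self, graph: nx.Graph) -> None:
        if graph.number_of_nodes() and not nx.is_tree(graph):
            raise ValueError("graph is not a tree")
        labels = [d["label"] for _, d in graph.nodes(data=True) if "label" in d]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for u, v, d in graph.edges(data=True):
            if d.get("length", 0.0) < 0:
                raise ValueError(f"negative edge length on ({u}, {v})")
        self.graph = graph
        self.supports: dict[frozenset, float] = {}

    # -- construction --------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        leaf_labels: Mapping[int, str],
        edges: Iterable[tuple[int, int, float]],
    ) -> "UnrootedTree":
        g = nx.Graph()
        for u, v, length in edges:
            g.add_edge(u, v, length=float(length))
        for node, label in leaf_labels.items():
            g.add_node(node, label=label)
        return cls(g)

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree(self.graph.copy())
        t.supports = dict(self.supports)
        return t

    # -- basic queries -------------------------------------------------
    @property
    def leaf_nodes(self) -> dict[str, int]:
        return {
            d["label"]: n for n, d in self.graph.nodes(data=True) if "label" in d
        }

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.leaf_nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes)

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def terminal_edge_length(self, label: str) -> float:
        node = self.leaf_nodes[label]
        (nbr,) = list(self.graph.neighbors(node))
        return float(self.graph.edges[node, nbr]["length"])

    def internal_edges(self) -> list[tuple[int, int, float]]:
        """Edges whose endpoints are both internal nodes."""
        is_leaf = {n for n, d in self.graph.nodes(data=True) if "label" in d}
        return [
            (u, v, d["length"])
            for u, v, d in self.graph.edges(data=True)
            if u not in is_leaf and v not in is_leaf
        ]

    # -- path lengths --------------------------------------------------
    def distances_from(self, label: str) -> dict[str, float]:
        """Path lengths from one leaf to every other leaf."""
        src = self.leaf_nodes[label]
        dist = nx.single_source_dijkstra_path_length(self.graph, src, weight="length")
        return {
            d["label"]: dist[n]
            for n, d in self.graph.nodes(data=True)
            if "label" in d and d["label"] != label
        }

    def leaf_distance_matrix(self) -> SquareMatrix:
        labels = self.leaf_labels
        n = len(labels)
        values = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = self.distances_from(lab)
            for j, other in enumerate(labels):
                if other != lab:
                    values[i, j] = dist[other]
        values = (values + values.T) / 2.0  # kill FP asymmetry from traversal order
        return SquareMatrix(labels, values)

    # -- bipartitions --------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (one per internal edge).

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest leaf is the canonical representative.
        """
        if self.n_leaves < 4:
            return set()
        all_leaves = frozenset(self.leaf_nodes)
        smallest = min(all_leaves)
        root = next(iter(self.leaf_nodes.values()))
        below: dict[tuple[int, int], frozenset] = {}
        out: set[frozenset] = set()

        def walk(node: int, parent: int | None) -> frozenset:
            data = self.graph.nodes[node]
            if "label" in data:
                return frozenset([data["label"]])
            acc: set[str] = set()
            for child in self.graph.neighbors(node):
                if child == parent:
                    continue
                acc |= walk(child, node)
            result = frozenset(acc)
            if parent is not None and "label" not in self.graph.nodes[parent]:
                side = result if smallest not in result else all_leaves - result
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
            return result

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * self.graph.number_of_nodes() + 100))
        try:
            walk(next(iter(self.graph.neighbors(root))), root)
        finally:
            sys.setrecursionlimit(old)
        return out

    # -- editing -------------------------------------------------------
    def remove_leaf(self, label: str) -> float:
        """Remove a leaf; suppress the resulting degree-2 node.

        Returns the length of the deleted terminal edge.  When the former
        neighbour drops to degree 2, its two incident edges are merged with
        lengths added, preserving all remaining path lengths.
        """
        node = self.leaf_nodes[label]
        (nbr,) = list(self.graph.neighbors(node))
        removed = float(self.graph.edges[node, nbr]["length"])
        self.graph.remove_node(node)
        if self.graph.degree(nbr) == 2 and "label" not in self.graph.nodes[nbr]:
            a, b = list(self.graph.neighbors(nbr))
            merged = self.graph.edges[nbr, a]["length"] + self.graph.edges[nbr, b]["length"]
            self.graph.remove_node(nbr)
            self.graph.add_edge(a, b, length=merged)
        return removed

    # -- Newick --------------------------------------------------------
    def to_newick(self) -> str:
        leaves = self.leaf_nodes
        if len(leaves) == 0:
            return ";"
        if len(leaves) == 1:
            return f"{next(iter(leaves))};"
        if len(leaves) == 2:
            (la, na), (lb, nb) = sorted(leaves.items())
            length = self.graph.edges[na, nb]["length"]
            half = format(length / 2.0, ".10g")
            return f"({la}:{half},{lb}:{half});"
        root = next(
            n for n, d in self.graph.nodes(data=True) if "label" not in d
        )
        all_leaves = set(leaves)

        def subtree(node: int, parent: int) -> tuple[str, frozenset]:
            data = self.graph.nodes[node]
            if "label" in data:
                return data["label"], frozenset([data["label"]])
            parts, below = [], set()
            for child in self.graph.neighbors(node):
                if child == parent:
                    continue
                text, leafset = subtree(child, node)
                length = format(self.graph.edges[node, child]["length"], ".10g")
                parts.append(f"{text}:{length}")
                below |= leafset
            key = frozenset(below)
            if min(all_leaves) in key:
                key = frozenset(all_leaves - key)
            name = ""
            if key in self.supports:
                name = format(self.supports[key], ".10g")
            return f"({','.join(parts)}){name}", frozenset(below)

        parts = []
        for child in self.graph.neighbors(root):
            text, _ = subtree(child, root)
            length = format(self.graph.edges[root, child]["length"], ".10g")
            parts.append(f"{text}:{length}")
        return f"({','.join(parts)});"

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        depth = 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced parentheses", i)
        if depth != 0:
            raise NewickParseError("unbalanced parentheses", len(text) - 1)

        import skbio

        try:
            rooted = skbio.TreeNode.read(io.StringIO(text))
        except Exception as exc:  # skbio.io raises its own hierarchy
            raise NewickParseError(f"could not parse Newick: {exc}") from exc

        g = nx.Graph()
        counter = [0]
        all_leaves = {str(t.name) for t in rooted.tips()}
        raw_supports: dict[frozenset, float] = {}

        def add(node, parent_id: int | None) -> set[str]:
            node_id = counter[0]
            counter[0] += 1
            below: set[str] = set()
            if node.is_tip():
                g.add_node(node_id, label=str(node.name))
                below.add(str(node.name))
            else:
                g.add_node(node_id)
            if parent_id is not None:
                g.add_edge(parent_id, node_id, length=float(node.length or 0.0))
            for child in node.children:
                below |= add(child, node_id)
            # a support label names the clade below this (non-root) node
            if not node.is_tip() and node.name is not None and parent_id is not None:
                try:
                    value = float(node.name)
                except ValueError:
                    pass
                else:
                    if 1 < len(below) < len(all_leaves) - 1:
                        raw_supports[frozenset(below)] = value
            return below

        add(rooted, None)
        # suppress a degree-2 root left by rooted parsing
        for node in list(g.nodes):
            if g.degree(node) == 2 and "label" not in g.nodes[node]:
                a, b = list(g.neighbors(node))
                merged = g.edges[node, a]["length"] + g.edges[node, b]["length"]
                g.remove_node(node)
                g.add_edge(a, b, length=merged)
        tree = cls(g)
        if raw_supports and all_leaves:
            smallest = min(all_leaves)
            for side, value in raw_supports.items():
                if smallest in side:
                    side = frozenset(all_leaves - side)
                tree.supports[side] = value
        return tree


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sqrt_transform(d: SquareMatrix) -> SquareMatrix:
    """Element-wise square root, mapping dissimilarities in [0, 1] onto a
    Euclidean-behaved scale (fixed points 0 and 1)."""
    if (d.values < 0).any():
        raise ValueError("negative entries cannot be sqrt-transformed")
    return SquareMatrix(list(d.labels), np.sqrt(d.values))


def neighbor_joining(d: SquareMatrix) -> UnrootedTree:
    """Classic Saitou–Nei neighbor joining.

    Ties in the rate-corrected selection criterion are broken toward the
    lexicographically smallest (cluster-minimum-label) pair, and negative
    branch-length estimates are clamped to zero, so output is deterministic.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 leaves")
    labels = list(d.labels)
    if n == 2:
        return UnrootedTree.from_edges(
            {0: labels[0], 1: labels[1]}, [(0, 1, float(d.values[0, 1]))]
        )

    g = nx.Graph()
    node_of = {}
    for i, lab in enumerate(labels):
        g.add_node(i, label=lab)
        node_of[i] = i
    next_id = n

    D = d.values.astype(float).copy()
    active = list(range(n))
    # tie-break key per active cluster: smallest leaf label inside it
    tb = {i: labels[i] for i in range(n)}

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        q_ut = q[iu]
        qmin = q_ut.min()
        ties = np.flatnonzero(q_ut == qmin)
        best = min(
            (tuple(sorted((tb[active[iu[0][k]]], tb[active[iu[1][k]]]))),
             int(iu[0][k]), int(iu[1][k]))
            for k in ties
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        new = next_id
        next_id += 1
        g.add_node(new)
        g.add_edge(new, node_of[i], length=float(li))
        g.add_edge(new, node_of[j], length=float(lj))
        node_of[new] = new

        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        tb[new] = min(tb[i], tb[j])
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    g.add_edge(node_of[i], node_of[j], length=float(max(D[i, j], 0.0)))
    return UnrootedTree(g)


def bootstrap_support(geno, n_reps: int, seed: int | None = None) -> UnrootedTree:
    """NJ tree on the full panel with site-bootstrap bipartition supports.

    Each replicate resamples sites with replacement, recomputes IBS
    distances, square-root transforms them, and rebuilds the NJ tree; the
    support of each internal bipartition of the point-estimate tree is the
    fraction of replicates containing it.
    """
    from .popgen_stats import ibs_distance

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = neighbor_joining(sqrt_transform(ibs_distance(geno)))
    parts = point.bipartitions()
    counts = {p: 0 for p in parts}
    m = geno.n_sites
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        rep_tree = neighbor_joining(sqrt_transform(ibs_distance(geno.take_sites(idx))))
        rep_parts = rep_tree.bipartitions()
        for p in parts:
            if p in rep_parts:
                counts[p] += 1
    point.supports = {p: counts[p] / n_reps for p in parts}
    return point


def cut_into_groups(tree: UnrootedTree, k: int) -> dict[str, int]:
    """Partition leaves into ``k`` groups by deleting the k−1 longest
    internal edges; groups are numbered from 1 by decreasing size."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    internal = tree.internal_edges()
    if k - 1 > len(internal):
        raise ValueError(
            f"cannot make {k} groups: tree has only {len(internal)} internal edges"
        )
    cut = sorted(internal, key=lambda e: (-e[2], e[0], e[1]))[: k - 1]
    g = tree.graph.copy()
    for u, v, _ in cut:
        g.remove_edge(u, v)
    comps = []
    for comp in nx.connected_components(g):
        labels = sorted(
            g.nodes[n]["label"] for n in comp if "label" in g.nodes[n]
        )
        if labels:
            comps.append(labels)
    comps.sort(key=lambda labs: (-len(labs), labs[0]))
    return {lab: gi + 1 for gi, labs in enumerate(comps) for lab in labs}
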