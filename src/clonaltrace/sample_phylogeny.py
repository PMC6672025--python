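"""Sample-level phylogeny from somatic SNV sets.

The distance between two samples is the size of the symmetric difference
of their somatic SNV sets, d_ij = |S_i Δ S_j|; the normal sample's set is
empty by definition, so its distance to any tumor collapses to that
tumor's SNV count.  A tree is built over the distance matrix with the
Saitou–Nei neighbor-joining algorithm (Studier–Keppler Q-criterion form,
implemented from scratch) and rooted at the normal sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

NORMAL = "normal"
ROOT = "__root__"


@dataclass
class SampleDistanceMatrix:
    labels: list[str]
    D: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self):
        n = len(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (n, n):
            raise ConfigurationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ConfigurationError("duplicate labels in distance matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        return path


def symmetric_difference_distance(
    sets: Mapping[str, frozenset | set],
    normal_label: str = NORMAL,
) -> SampleDistanceMatrix:
    """Distance matrix d_ij = |S_i Δ S_j| over tumor SNV sets plus normal.

    The normal entry is added (or overwritten) as the empty set, so
    D[i, normal] = |S_i| exactly.
    """
    labels = [l for l in sets if l != normal_label] + [normal_label]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate sample labels")
    full = {l: frozenset(sets[l]) for l in sets if l != normal_label}
    full[normal_label] = frozenset()
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = len(full[labels[i]] ^ full[labels[j]])
            D[i, j] = D[j, i] = d
    return SampleDistanceMatrix(labels=labels, D=D)


def neighbor_joining(dm: SampleDistanceMatrix) -> nx.Graph:
    """Classic neighbor joining over a distance matrix.

    Iteratively joins the pair minimizing
    Q_ij = (n-2) d_ij - sum_k d_ik - sum_k d_jk, with branch lengths from
    the standard two-point formulas.  Exact ties in Q are broken by the
    lexicographically smallest sorted label pair, so the output is
    deterministic.  Returns an unrooted tree as a graph with a ``length``
    attribute on every edge.  Branch lengths are returned as computed
    (possibly negative); see :func:`clamp_negative_lengths`.
    """
    D = np.asarray(dm.D, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if np.abs(np.diag(D)).max(initial=0.0) > 0:
        raise ValueError("distance matrix must have a zero diagonal")

    labels = list(dm.labels)
    tree = nx.Graph()
    tree.add_nodes_from(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to build a tree")
    if len(labels) == 2:
        tree.add_edge(labels[0], labels[1], length=float(D[0, 1]))
        return tree

    # active nodes and their pairwise distances, kept in a dict-of-dict
    dist: dict[Hashable, dict[Hashable, float]] = {
        a: {b: float(D[i, j]) for j, b in enumerate(labels) if b != a}
        for i, a in enumerate(labels)
    }
    active = list(labels)
    next_internal = 1

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                pair = tuple(sorted((str(a), str(b))))
                if q < best_q or (q == best_q and pair < best[2]):
                    best, best_q = (a, b, pair), q
        a, b, _ = best
        la = 0.5 * dist[a][b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dist[a][b] - la
        u = f"NJ{next_internal}"
        next_internal += 1
        tree.add_edge(a, u, length=float(la))
        tree.add_edge(b, u, length=float(lb))
        dist[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            dist[u][c] = duc
            dist[c][u] = duc
        for c in (a, b):
            del dist[c]
            for d in dist.values():
                d.pop(c, None)
        active = [c for c in active if c not in (a, b)] + [u]

    # closed-form three-point termination
    a, b, c = active
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    u = f"NJ{next_internal}"
    tree.add_edge(a, u, length=float(la))
    tree.add_edge(b, u, length=float(lb))
    tree.add_edge(c, u, length=float(lc))
    return tree


def clamp_negative_lengths(tree: nx.Graph) -> nx.Graph:
    """Clamp negative branch lengths to 0, moving the deficit to the sibling edge.

    Standard display practice for NJ trees: when a pendant edge comes out
    negative, the deficit is added to the adjacent edge created at the
    same join so that path lengths through the pair are preserved.
    """
    out = tree.copy()
    for u, v in list(out.edges):
        l = out[u][v]["length"]
        if l < 0:
            deficit = -l
            out[u][v]["length"] = 0.0
            internal = u if out.degree(u) > 1 else v
            neighbors = [w for w in out.neighbors(internal) if w not in (u, v)]
            if neighbors:
                w = sorted(neighbors, key=str)[0]
                out[internal][w]["length"] = out[internal][w]["length"] + deficit
    return out


def root_at_normal(tree, normal_label: str = NORMAL) -> nx.DiGraph:
    """Root the NJ tree on the edge adjacent to the normal leaf.

    A root node is placed at the attachment point of the normal pendant
    edge: the root's two subtrees are the normal leaf (keeping the full
    pendant length) and the rest of the tree, so all path lengths are
    preserved.  Re-rooting an already rooted tree is a no-op.
    """
    if isinstance(tree, nx.DiGraph):
        if ROOT in tree:
            return tree.copy()
        tree = tree.to_undirected()
    if normal_label not in tree:
        raise ConfigurationError(f"tree has no {normal_label!r} leaf")
    neighbors = list(tree.neighbors(normal_label))
    if len(neighbors) != 1:
        raise ConfigurationError(f"{normal_label!r} is not a leaf")
    attach = neighbors[0]
    pendant = tree[normal_label][attach]["length"]

    rooted = nx.DiGraph()
    rooted.add_node(ROOT)
    rooted.add_edge(ROOT, normal_label, length=float(pendant))
    # direct the remaining tree away from the attachment point
    seen = {normal_label, attach}
    stack = [(ROOT, attach, 0.0)]
    while stack:
        parent, node, length = stack.pop()
        rooted.add_edge(parent, node, length=float(length))
        for nb in sorted(tree.neighbors(node), key=str):
            if nb not in seen:
                seen.add(nb)
                stack.append((node, nb, tree[node][nb]["length"]))
    return rooted


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'\t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree, root=None) -> str:
    """Newick string with branch lengths in 6-decimal fixed format."""
    if isinstance(tree, nx.DiGraph):
        root = ROOT if root is None else root
        children = lambda node: sorted(tree.successors(node), key=str)  # noqa: E731
        length = lambda p, c: tree[p][c]["length"]  # noqa: E731
    else:
        if root is None:
            root = sorted((n for n in tree if tree.degree(n) > 1), key=str)[0] \
                if len(tree) > 2 else sorted(tree, key=str)[0]
        parent: dict = {root: None}
        stack = [root]
        while stack:
            node = stack.pop()
            for nb in sorted(tree.neighbors(node), key=str):
                if nb not in parent:
                    parent[nb] = node
                    stack.append(nb)
        children = lambda node: sorted(  # noqa: E731
            (nb for nb in tree.neighbors(node) if parent.get(nb) == node), key=str)
        length = lambda p, c: tree[p][c]["length"]  # noqa: E731

    def render(node) -> str:
        kids = children(node)
        if not kids:
            return _quote(str(node))
        inner = ",".join(f"{render(c)}:{length(node, c):.6f}" for c in kids)
        name = "" if str(node).startswith(("NJ", ROOT)) else _quote(str(node))
        return f"({inner}){name}"

    return render(root) + ";"


def write_newick(tree, path) -> Path:
    path = Path(path)
    path.write_text(to_newick(tree) + "\n")
    return path


def path_lengths_from(tree, source) -> dict[str, float]:
    """Sum of branch lengths from ``source`` to every node."""
    g = tree.to_undirected() if isinstance(tree, nx.DiGraph) else tree
    return nx.single_source_dijkstra_path_length(g, source, weight="length")
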