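"""Independent oracles used by the test suite.

These are deliberately naive re-derivations, kept separate from the
package: a literal Q-matrix neighbor-joining implementation and a dense
grid search for two-item Bradley-Terry posteriors.  They share no code
with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def nj_oracle(labels, D):
    """Literal neighbor joining, recomputed from the Q definition each step.

    Returns a list of edges (u, v, length).  Ties in Q are broken by the
    lexicographically smallest sorted pair of node names, matching the
    documented tie-break of the implementation under test.
    """
    labels = list(labels)
    D = {a: {b: float(D[i][j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    active = list(labels)
    edges = []
    counter = 1
    while len(active) > 3:
        n = len(active)
        best_q, best_pair = None, None
        for a in active:
            for b in active:
                if str(a) >= str(b):
                    continue
                q = (n - 2) * D[a][b] \
                    - sum(D[a][c] for c in active if c != a) \
                    - sum(D[b][c] for c in active if c != b)
                pair = tuple(sorted((str(a), str(b))))
                if best_q is None or q < best_q or (q == best_q and pair < best_pair):
                    best_q, best_pair, join = q, pair, (a, b)
        a, b = join
        ra = sum(D[a][c] for c in active if c != a)
        rb = sum(D[b][c] for c in active if c != b)
        la = 0.5 * D[a][b] + (ra - rb) / (2 * (n - 2))
        lb = D[a][b] - la
        u = f"NJ{counter}"
        counter += 1
        edges.append((a, u, la))
        edges.append((b, u, lb))
        D[u] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[u][c] = d
            D[c][u] = d
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = active
    u = f"NJ{counter}"
    edges.append((a, u, 0.5 * (D[a][b] + D[a][c] - D[b][c])))
    edges.append((b, u, 0.5 * (D[a][b] + D[b][c] - D[a][c])))
    edges.append((c, u, 0.5 * (D[a][c] + D[b][c] - D[a][b])))
    return edges


def tree_splits(edges, leaves):
    """Map each edge to its leaf bipartition (canonical side) and length."""
    import networkx as nx

    g = nx.Graph()
    for u, v, l in edges:
        g.add_edge(u, v, length=l)
    leaves = frozenset(leaves)
    out = {}
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(n for n in nx.node_connected_component(h, u) if n in leaves)
        other = leaves - side
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(map(str, s)))))
        out[key] = g[u][v]["length"]
    return out


def graph_to_edges(tree):
    return [(u, v, tree[u][v]["length"]) for u, v in tree.edges]


def bt_grid_search_2(W, a=1.1, n_grid=400001):
    """Dense grid search of the 2-item BT log-posterior on pi1 + pi2 = 2."""
    pi1 = np.linspace(1e-9, 2 - 1e-9, n_grid)
    pi2 = 2.0 - pi1
    lp = (W[0][1] * (np.log(pi1) - np.log(2.0))
          + W[1][0] * (np.log(pi2) - np.log(2.0))
          + (a - 1.0) * (np.log(pi1) + np.log(pi2)))
    i = int(np.argmax(lp))
    return float(lp[i]), float(pi1[i])


def random_binary_tree_distances(n_leaves, rng):
    """Random unrooted binary tree with positive lengths; returns
    (leaf labels, distance matrix, edge list)."""
    import networkx as nx

    leaves = [f"L{i}" for i in range(n_leaves)]
    g = nx.Graph()
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 3:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        u = f"I{nxt}"
        nxt += 1
        g.add_edge(a, u, length=rng.uniform(0.5, 2.0))
        g.add_edge(b, u, length=rng.uniform(0.5, 2.0))
        nodes.append(u)
    u = f"I{nxt}"
    for a in nodes:
        g.add_edge(a, u, length=rng.uniform(0.5, 2.0))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    D = [[paths[a][b] for b in leaves] for a in leaves]
    return leaves, np.array(D), [(u, v, g[u][v]["length"]) for u, v in g.edges]
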