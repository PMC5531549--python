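"""Independent oracles used by the tests: brute-force topology search and
random additive trees, kept free of any bhlhkit tree code."""

from __future__ import annotations

import itertools

import numpy as np


class SimpleTree:
    """Unrooted tree as an adjacency map with edge lengths."""

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.next_id = 0

    def new_node(self) -> int:
        nid = self.next_id
        self.next_id += 1
        self.adj[nid] = {}
        return nid

    def add_edge(self, a: int, b: int, length: float = 1.0) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def remove_edge(self, a: int, b: int) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    out.append((a, b))
        return out

    def leaf_distances(self, leaves: list[int]) -> np.ndarray:
        n = len(leaves)
        d = np.zeros((n, n))
        for i, src in enumerate(leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, dst in enumerate(leaves):
                d[i, j] = dist[dst]
        return d

    def splits(self, leaves: list[int]) -> set[frozenset[int]]:
        """Non-trivial bipartitions, each as the frozenset of leaf indices
        on one (canonical: not containing leaf 0) side."""
        leaf_index = {leaf: i for i, leaf in enumerate(leaves)}
        out = set()
        for a, b in self.edges():
            side = set()
            stack, seen = [a], {a, b}
            while stack:
                u = stack.pop()
                if u in leaf_index:
                    side.add(leaf_index[u])
                for v in self.adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 0 in side:
                side = set(range(len(leaves))) - side
            if 1 < len(side) < len(leaves) - 1:
                out.add(frozenset(side))
        return out


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary topology by stepwise addition, random branch
    lengths; returns (tree, leaf node ids)."""
    t = SimpleTree()
    leaves = [t.new_node() for _ in range(3)]
    center = t.new_node()
    for leaf in leaves:
        t.add_edge(center, leaf, float(rng.uniform(0.1, 1.0)))
    for _ in range(n_leaves - 3):
        a, b = t.edges()[rng.integers(len(t.edges()))]
        w = t.adj[a][b]
        t.remove_edge(a, b)
        mid = t.new_node()
        frac = float(rng.uniform(0.2, 0.8))
        t.add_edge(a, mid, w * frac)
        t.add_edge(mid, b, w * (1 - frac))
        leaf = t.new_node()
        t.add_edge(mid, leaf, float(rng.uniform(0.1, 1.0)))
        leaves.append(leaf)
    return t, leaves


def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies on n labelled leaves (1, 3, 15, ...),
    built by exhaustive stepwise addition; unit branch lengths."""
    base = SimpleTree()
    leaves = [base.new_node() for _ in range(3)]
    center = base.new_node()
    for leaf in leaves:
        base.add_edge(center, leaf)
    trees = [(base, leaves)]
    for _k in range(3, n_leaves):
        grown = []
        for t, lv in trees:
            for a, b in t.edges():
                import copy

                t2 = copy.deepcopy(t)
                lv2 = list(lv)
                t2.remove_edge(a, b)
                mid = t2.new_node()
                t2.add_edge(a, mid)
                t2.add_edge(mid, b)
                leaf = t2.new_node()
                t2.add_edge(mid, leaf)
                lv2.append(leaf)
                grown.append((t2, lv2))
        trees = grown
    return trees


def least_squares_topology(d: np.ndarray) -> set[frozenset[int]]:
    """Best-fitting topology for a distance matrix by exhaustive
    enumeration + ordinary least-squares branch lengths; returns its
    split set."""
    n = d.shape[0]
    best = None
    for t, leaves in enumerate_topologies(n):
        edges = t.edges()
        edge_index = {e: k for k, e in enumerate(edges)}
        pairs = list(itertools.combinations(range(n), 2))
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            # path from leaf i to leaf j
            src, dst = leaves[i], leaves[j]
            parent = {src: None}
            stack = [src]
            while stack:
                u = stack.pop()
                for v in t.adj[u]:
                    if v not in parent:
                        parent[v] = u
                        stack.append(v)
            node = dst
            while parent[node] is not None:
                p = parent[node]
                e = (min(p, node), max(p, node))
                A[row, edge_index[e]] = 1.0
                node = p
            y[row] = d[i, j]
        coef, residuals, _rank, _sv = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((A @ coef - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, t.splits(leaves))
    return best[1]
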