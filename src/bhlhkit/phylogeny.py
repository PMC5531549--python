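"""Distance-based subfamily inference.

p-distance with pairwise deletion, Poisson multiple-hit correction
d = -ln(1 - p), Saitou-Nei neighbor joining with deterministic
tie-breaking, non-parametric bootstrap over alignment columns, and
extraction of clades with at least 50% support as subfamilies.

Trees are carried as dendropy objects (Newick I/O, bipartition encoding,
midpoint rooting); the NJ algorithm itself is implemented here so that
tie-breaking, negative-branch clamping and determinism are fully
specified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

GAP = "-"

#: Cap for saturated distances (p -> 1). MEGA-style analyses simply fail
#: there; a finite cap keeps NJ defined while flagging the pair.
DEFAULT_MAX_DISTANCE = 5.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over sites ungapped in both sequences
    (pairwise deletion). NaN when no site is comparable."""
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    valid = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == GAP or y == GAP:
            continue
        valid += 1
        if x != y:
            diffs += 1
    if valid == 0:
        return math.nan
    return diffs / valid


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p); inf when saturated."""
    if math.isnan(p):
        return math.nan
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 1:
        return math.inf
    return -math.log(1.0 - p)


def distance_matrix(
    ids: list[str],
    aligned: list[str],
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances from an alignment.

    Saturated or incomparable pairs are capped at ``max_distance`` with a
    warning.
    """
    n = len(ids)
    d = np.zeros((n, n))
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            dist = poisson_correct(p_distance(aligned[i], aligned[j]))
            if math.isnan(dist) or dist > max_distance:
                dist = max_distance
                capped += 1
            d[i, j] = d[j, i] = dist
    if capped:
        warnings.warn(
            f"{capped} saturated/incomparable pairs capped at {max_distance}"
        )
    return DistanceMatrix(ids=list(ids), d=d)


def neighbor_joining(
    m: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive distances.

    The Q criterion is minimized with exact ties broken toward the
    lexicographically smallest pair of cluster labels (the smallest leaf
    name in each cluster), so the output is deterministic and — up to
    floating-point summation order — independent of input order.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch. The result is an unrooted tree (trifurcation at
    the seed node).
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(m.ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for name in m.ids:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    d = m.d.copy()
    active = list(range(n))
    labels = list(m.ids)  # canonical cluster label: smallest member leaf

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # (r[x] + r[y]) first keeps q exactly symmetric in floating point
        q = (k - 2) * sub - (r[:, None] + r[None, :])
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (int(x), int(y)) for x, y in np.argwhere(q == qmin) if x < y
        ]
        ai, aj = min(
            candidates,
            key=lambda xy: tuple(
                sorted((labels[active[xy[0]]], labels[active[xy[1]]]))
            ),
        )
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    # three-point formulas for the final star join
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def patristic_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(ids)
    out = np.zeros((n, n))
    taxa = [tns.get_taxon(name) for name in ids]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out


def _internal_bipartitions(tree: dendropy.Tree) -> set[int]:
    """Normalized split bitmasks of the internal (non-trivial) edges."""
    tree.encode_bipartitions(suppress_unifurcations=False)
    n_taxa = len(tree.taxon_namespace)
    out: set[int] = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node is tree.seed_node:
            continue
        mask = edge.bipartition.split_bitmask
        size = bin(mask).count("1")
        if 1 < size < n_taxa - 1:
            out.add(mask)
    return out


def bootstrap_supports(
    ids: list[str],
    aligned: list[str],
    n_reps: int = 1000,
    seed: int = 0,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Each replicate resamples alignment columns with replacement; the
    support of an internal edge is the percentage of replicate trees
    containing its bipartition. Replicate r consumes exactly the r-th row
    of a pre-drawn (n_reps x L) column-index array from a single seeded
    generator, so results are reproducible and independent of leaf order.
    Supports are stored as ``edge.head_node.label`` (percent) and in
    ``tree.bipartition_support`` keyed by normalized split bitmask.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    L = len(aligned[0])
    tns = dendropy.TaxonNamespace(ids)
    full = neighbor_joining(distance_matrix(ids, aligned, max_distance), tns)
    target = _internal_bipartitions(full)
    hits: dict[int, int] = {mask: 0 for mask in target}
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, L, size=(n_reps, L))
    arr = np.array([list(s) for s in aligned])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            cols = draws[r]
            rep_aligned = ["".join(row) for row in arr[:, cols]]
            rep_tree = neighbor_joining(
                distance_matrix(ids, rep_aligned, max_distance), tns
            )
            for mask in _internal_bipartitions(rep_tree):
                if mask in hits:
                    hits[mask] += 1
    support = {mask: 100.0 * hits[mask] / n_reps for mask in hits}
    for edge in full.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node is tree_root(full):
            continue
        mask = edge.bipartition.split_bitmask
        if mask in support and not edge.head_node.is_leaf():
            edge.head_node.label = f"{support[mask]:g}"
    full.bipartition_support = support
    return full


def tree_root(tree: dendropy.Tree) -> dendropy.Node:
    return tree.seed_node


def _neighbors(node: dendropy.Node):
    """Undirected tree adjacency: (neighbor, connecting edge length)."""
    out = [(c, c.edge.length or 0.0) for c in node.child_nodes()]
    if node.parent_node is not None:
        out.append((node.parent_node, node.edge.length or 0.0))
    return out


def _farthest_leaf(tree: dendropy.Tree, start: dendropy.Node):
    """(leaf, distance, parent-map) for the leaf farthest from ``start``,
    ties broken by taxon label."""
    dist = {start: 0.0}
    parent: dict = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in _neighbors(u):
            if v not in parent:
                parent[v] = u
                dist[v] = dist[u] + w
                stack.append(v)
    leaves = [n for n in dist if n.is_leaf() and n.taxon is not None]
    best = max(leaves, key=lambda n: (dist[n], n.taxon.label))
    return best, dist, parent


def _midpoint_internal_node(tree: dendropy.Tree) -> dendropy.Node:
    """The internal node nearest the tree midpoint.

    Two-sweep diameter walk: the farthest leaf u from an arbitrary leaf,
    then the farthest leaf v from u; the midpoint lies on the u-v path and
    the nearest internal path node is returned (deterministic tie-breaks
    by taxon label / proximity to u)."""
    any_leaf = next(tree.leaf_node_iter(), None)
    if any_leaf is None:
        return tree.seed_node
    u, _, _ = _farthest_leaf(tree, any_leaf)
    v, dist_u, parent_u = _farthest_leaf(tree, u)
    path = []
    node = v
    while node is not None:
        path.append(node)
        node = parent_u[node]
    internal = [n for n in path if not n.is_leaf()]
    if not internal:
        return tree.seed_node
    half = dist_u[v] / 2.0
    return min(internal, key=lambda n: (abs(dist_u[n] - half), dist_u[n]))


def extract_subfamilies(
    tree: dendropy.Tree, min_support: float = 50.0
) -> list[list[str]]:
    """Maximal midpoint-rooted clades whose subtending edge has bootstrap
    support >= ``min_support``; uncovered leaves become singletons.

    The root is placed at the internal node nearest the tree midpoint (a
    basal multifurcation, the way family trees are displayed) rather than
    bisecting the midpoint edge: a bisected root would duplicate one
    split across both root edges and let a supported subfamily's
    complement masquerade as a huge supported clade.

    Requires a tree from :func:`bootstrap_supports` (it carries
    ``bipartition_support``). The returned clusters partition the leaf
    set; cluster order is by first leaf name.
    """
    support: dict[int, float] = getattr(tree, "bipartition_support", None) or {}
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    root = _midpoint_internal_node(rooted)
    if root is not rooted.seed_node:
        rooted.reroot_at_node(root, update_bipartitions=False)
    rooted.encode_bipartitions(suppress_unifurcations=False)

    clusters: list[list[str]] = []
    covered: set[str] = set()
    full_mask = (1 << len(rooted.taxon_namespace)) - 1

    def edge_support(node: dendropy.Node) -> float:
        # rooted-tree leafset masks are unnormalized; the unrooted support
        # table may key either side of the split
        mask = node.edge.bipartition.leafset_bitmask
        return max(support.get(mask, 0.0), support.get(full_mask ^ mask, 0.0))

    def visit(node: dendropy.Node) -> None:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if node is not rooted.seed_node and not node.is_leaf():
            if edge_support(node) >= min_support:
                clusters.append(sorted(leaves))
                covered.update(leaves)
                return
        for child in node.child_nodes():
            visit(child)

    visit(rooted.seed_node)
    for leaf in rooted.leaf_node_iter():
        if leaf.taxon.label not in covered:
            clusters.append([leaf.taxon.label])
    clusters.sort(key=lambda c: c[0])
    return clusters


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    """PHYLIP-style square distance matrix."""
    with open(path, "wt") as fh:
        fh.write(f"{len(m.ids)}\n")
        for name, row in zip(m.ids, m.d):
            fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
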