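"""Distance-based dendrograms: UPGMA, neighbour joining, and locus-bootstrap
support values.

Trees are :class:`dendropy.Tree` objects; leaves carry taxon labels equal to
the distance-matrix labels, internal nodes optionally carry bootstrap
support (percent, as the node label).
"""

from __future__ import annotations

from typing import Callable, Sequence, Union

import dendropy
import numpy as np

from .types import AlleleMatrix, BandMatrix, DataError, DistanceMatrix

TreeData = Union[AlleleMatrix, BandMatrix]


def _new_tree(labels: Sequence[str]) -> tuple[dendropy.TaxonNamespace, dict]:
    tns = dendropy.TaxonNamespace()
    leaves = {}
    for lab in labels:
        taxon = tns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        leaves[lab] = node
    return tns, leaves


def upgma(d: DistanceMatrix) -> dendropy.Tree:
    """UPGMA dendrogram (unweighted pair-group method, arithmetic average).

    Cluster pairs are merged at the smallest average distance; the average
    over all leaf pairs is maintained by size-proportional updating.  Ties
    are broken by the lexicographically smallest (cluster, cluster) label
    pair, where a cluster is named after its smallest leaf label, so results
    are reproducible.  The returned tree is rooted and ultrametric.
    """
    if d.has_infinite():
        raise DataError("UPGMA requires finite distances (infinite entry found)")
    if d.n < 2:
        raise DataError("need at least 2 labels")
    tns, leaf_nodes = _new_tree(d.labels)

    # active clusters: name -> (node, size, height)
    nodes = {lab: leaf_nodes[lab] for lab in d.labels}
    sizes = {lab: 1 for lab in d.labels}
    heights = {lab: 0.0 for lab in d.labels}
    dist = {
        frozenset((a, b)): float(d.values[i, j])
        for i, a in enumerate(d.labels)
        for j, b in enumerate(d.labels)
        if i < j
    }

    while len(nodes) > 1:
        best = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        (a, b), dmin = tuple(sorted(best[0])), best[1]
        h = dmin / 2.0
        parent = dendropy.Node()
        for child in (a, b):
            node = nodes.pop(child)
            node.edge.length = max(0.0, h - heights.pop(child))
            parent.add_child(node)
        na, nb = sizes.pop(a), sizes.pop(b)
        # size-weighted update keeps the mean over all leaf pairs
        for other in list(nodes):
            dao = dist.pop(frozenset((a, other)))
            dbo = dist.pop(frozenset((b, other)))
            dist[frozenset((a, other))] = (na * dao + nb * dbo) / (na + nb)
        del dist[frozenset((a, b))]
        # re-key entries of the merged cluster under name a (min label)
        nodes[a] = parent
        sizes[a] = na + nb
        heights[a] = h

    root = next(iter(nodes.values()))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def neighbor_joining(d: DistanceMatrix, unweighted: bool = False) -> dendropy.Tree:
    """Neighbour-joining tree (Saitou & Nei agglomeration).

    ``unweighted=True`` switches the distance update to the
    cluster-size-weighted average of the original leaves (the UNJ-style
    update); selection and branch-length estimation are unchanged, and only
    the topology should be relied on in that mode.  Negative branch-length
    estimates are clamped to zero.  Returns an unrooted tree.
    """
    if d.has_infinite():
        raise DataError("neighbour joining requires finite distances")
    if d.n < 3:
        raise DataError("need at least 3 labels for neighbour joining")
    tns, leaf_nodes = _new_tree(d.labels)

    labels = list(d.labels)
    nodes = {lab: leaf_nodes[lab] for lab in labels}
    sizes = {lab: 1 for lab in labels}
    dmat = {
        frozenset((a, b)): float(d.values[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def dd(a: str, b: str) -> float:
        return dmat[frozenset((a, b))]

    active = list(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dd(a, o) for o in active if o != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dd(a, b) - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or key < best)
                ):
                    best, best_q = key, q
        a, b = best
        dab = dd(a, b)
        ba = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        bb = dab - ba
        parent = dendropy.Node()
        nodes[a].edge.length = max(0.0, ba)
        nodes[b].edge.length = max(0.0, bb)
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        counter += 1
        new = f"__internal{counter}"
        nodes[new] = parent
        na, nb = sizes[a], sizes[b]
        sizes[new] = na + nb
        for other in active:
            if other in (a, b):
                continue
            if unweighted:
                dnew = (na * (dd(a, other) - ba) + nb * (dd(b, other) - bb)) / (
                    na + nb
                )
            else:
                dnew = 0.5 * (dd(a, other) + dd(b, other) - dab)
            dmat[frozenset((new, other))] = max(0.0, dnew)
        active = [x for x in active if x not in (a, b)] + [new]

    # final star join of the last three clusters
    a, b, c = sorted(active)
    va = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    vb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    vc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    root = dendropy.Node()
    for lab, v in ((a, va), (b, vb), (c, vc)):
        nodes[lab].edge.length = max(0.0, v)
        root.add_child(nodes[lab])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-leaf path lengths keyed by leaf label."""
    out = {}
    for leaf in tree.leaf_node_iter():
        depth, node = 0.0, leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = depth
    return out


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = list(leaf_depths(tree).values())
    return max(depths) - min(depths) <= tol


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest leaf is used as the canonical key, making the
    encoding rooting-independent.
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted topological equality via bipartition sets."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    return l1 == l2 and bipartitions(t1) == bipartitions(t2)


def path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return float(pdm.patristic_distance(ta, tb))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _resample_loci(data: TreeData, rng: np.random.Generator) -> TreeData:
    if isinstance(data, AlleleMatrix):
        loci = data.loci
        if len(loci) < 2:
            raise DataError("bootstrap needs at least 2 loci")
        draw = rng.integers(0, len(loci), size=len(loci))
        new_loci = [f"{loci[j]}.b{k}" for k, j in enumerate(draw)]
        return AlleleMatrix(list(data.individuals), new_loci, data.calls[:, draw, :])
    loci = data.loci
    if len(loci) < 2:
        raise DataError("bootstrap needs at least 2 loci")
    draw = rng.integers(0, len(loci), size=len(loci))
    bands, cols = [], []
    for k, j in enumerate(draw):
        for idx in data.band_indices(loci[j]):
            bands.append((f"{loci[j]}.b{k}", data.bands[idx][1]))
            cols.append(idx)
    return BandMatrix(list(data.individuals), bands, data.scores[:, cols])


def bootstrap_support(
    data: TreeData,
    builder: Callable[[TreeData], dendropy.Tree],
    n_reps: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """Attach locus-bootstrap support values to the tree ``builder(data)``.

    Loci are resampled with replacement ``n_reps`` times; support for each
    internal edge of the reference tree is the percentage of replicate trees
    containing the same leaf bipartition, stored as the internal node label.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref = builder(data)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(ref)}
    for _ in range(n_reps):
        rep = builder(_resample_loci(data, rng))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(l.taxon.label for l in ref.leaf_node_iter())
    anchor = min(all_leaves)
    for node in ref.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.label = str(int(round(100.0 * counts[side] / n_reps)))
    return ref
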