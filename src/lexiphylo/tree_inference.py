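"""Distance-based tree building (BIONJ) and rooting utilities.

BIONJ is the variance-weighted variant of neighbor joining: at each
agglomeration the reduced distances are a convex combination of the two
joined rows, with the mixing weight chosen to minimize the variance of the
new estimates (Gascuel's first-order model, variance proportional to the
distance).  With the mixing weight fixed at 1/2 the algorithm reduces to
classic neighbor joining.  Trees are dendropy objects throughout.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .language_distance import DistanceMatrix

logger = logging.getLogger(__name__)


def bionj_tree(dm: DistanceMatrix, variance_weighting: bool = True
               ) -> dendropy.Tree:
    """Build an unrooted binary tree from a distance matrix.

    Negative branch-length estimates are clamped to zero (logged); ties in
    the agglomeration criterion break lexicographically on taxon labels so
    the output is reproducible.  On additive matrices the tree's path
    lengths reproduce the input distances.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains undefined entries")

    taxa_ns = dendropy.TaxonNamespace(list(map(str, dm.taxa)))
    tree = dendropy.Tree(taxon_namespace=taxa_ns)
    nodes = []
    for label in dm.taxa:
        nd = dendropy.Node(taxon=taxa_ns.get_taxon(str(label)))
        nodes.append(nd)
    # sort keys: smallest leaf label in each cluster, for tie-breaking
    keys = [str(t) for t in dm.taxa]
    D = dm.values.astype(float).copy()
    V = D.copy()  # first-order variance model: var proportional to distance
    active = list(range(n))
    clamped_total = 0.0

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                lo, hi = sorted((keys[i], keys[j]))
                cand = (q, lo, hi, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, _, i, j = best
        bi_len = D[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        bj_len = D[i, j] - bi_len
        if bi_len < 0:
            clamped_total += -bi_len
            bj_len, bi_len = bj_len + bi_len, 0.0
        if bj_len < 0:
            clamped_total += -bj_len
            bi_len, bj_len = bi_len + bj_len, 0.0
            bi_len = max(bi_len, 0.0)
        # BIONJ mixing weight
        if variance_weighting and V[i, j] > 0:
            lam = 0.5 + sum(V[j, k] - V[i, k]
                            for k in active if k not in (i, j)) / (
                2 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi_len
        nodes[j].edge.length = bj_len
        for k in active:
            if k in (i, j):
                continue
            dk = lam * (D[i, k] - bi_len) + (1 - lam) * (D[j, k] - bj_len)
            vk = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * V[i, j]
            D[i, k] = D[k, i] = dk
            V[i, k] = V[k, i] = vk
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # final three-way join (closed-form three-point formulas)
    i, j, k = active
    center = dendropy.Node()
    li = (D[i, j] + D[i, k] - D[j, k]) / 2
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        if ln < 0:
            clamped_total += -ln
            ln = 0.0
        center.add_child(nodes[idx])
        nodes[idx].edge.length = ln
    if clamped_total > 0:
        logger.info("clamped %.6g of negative branch length to zero",
                    clamped_total)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining (BIONJ with the mixing weight fixed at 1/2)."""
    return bionj_tree(dm, variance_weighting=False)


def root_by_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root at the outgroup's attachment node, then remove the outgroup."""
    t = tree.clone(depth=1)
    leaf = None
    for lf in t.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    if len(t.leaf_nodes()) < 3:
        raise ValueError("tree too small to root by outgroup")
    attach = leaf.parent_node
    t.reroot_at_node(attach, update_bipartitions=False,
                     suppress_unifurcations=False)
    attach.remove_child(leaf)
    t.prune_leaves_without_taxa(suppress_unifurcations=False)
    t.is_rooted = True
    t.update_bipartitions(suppress_unifurcations=False)
    return t


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    If the midpoint falls exactly on a node, the tree is rooted at that
    node; otherwise a root node is inserted on the midpoint edge.
    """
    t = tree.clone(depth=1)
    leaves = t.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    total = sum(e.length or 0.0 for e in t.edges())
    if total == 0:
        logger.warning("zero-length tree; rooting at an arbitrary node")
        t.is_rooted = True
        return t
    # deepest leaf pair, deterministic tie-break on labels
    pdm = t.phylogenetic_distance_matrix()
    best = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = pdm.distance(a.taxon, b.taxon)
            lo, hi = sorted((a.taxon.label, b.taxon.label))
            cand = (-d, lo, hi, a, b)
            if best is None or cand[:3] < best[:3]:
                best = cand
    length, u, v = -best[0], best[3], best[4]
    # node path u -> v through their MRCA
    anc_u = [u] + list(u.ancestor_iter())
    anc_v = [v] + list(v.ancestor_iter())
    in_u = set(id(n) for n in anc_u)
    mrca = next(n for n in anc_v if id(n) in in_u)
    up = anc_u[:anc_u.index(mrca)]       # u ... child-of-mrca
    down = anc_v[:anc_v.index(mrca)]     # v ... child-of-mrca
    path_nodes = up + [mrca] + list(reversed(down))
    target = length / 2.0
    cum = 0.0
    for k in range(len(path_nodes) - 1):
        n1, n2 = path_nodes[k], path_nodes[k + 1]
        child = n1 if n1.parent_node is n2 else n2
        elen = child.edge.length or 0.0
        if cum + elen >= target - 1e-12:
            offset = target - cum  # distance from n1 along this edge
            if abs(offset) < 1e-12:
                t.reroot_at_node(n1, suppress_unifurcations=True)
            elif abs(elen - offset) < 1e-12:
                t.reroot_at_node(n2, suppress_unifurcations=True)
            else:
                # length2 is the sub-edge toward the original child
                toward_child = elen - offset if child is n2 else offset
                t.reroot_at_edge(child.edge, length1=elen - toward_child,
                                 length2=toward_child,
                                 suppress_unifurcations=True)
            break
        cum += elen
    t.is_rooted = True
    t.update_bipartitions(suppress_unifurcations=False)
    return t


def read_tree(path, rooted=None) -> dendropy.Tree:
    kwargs = {}
    if rooted is not None:
        kwargs["rooting"] = "force-rooted" if rooted else "force-unrooted"
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True, **kwargs)


def write_tree(tree: dendropy.Tree, path):
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
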