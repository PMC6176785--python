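"""Testing for punctuated evolution on rooted trees.

If a disproportionate share of change happens at lineage splits, leaves that
accumulated more branching events on their root-to-tip path should also show
more change: regressing the number of branching nodes on the root-to-tip
path length (with phylogenetic generalized least squares under a
Brownian-motion covariance) should give a significantly positive slope.
Because uneven taxon sampling inflates node counts where branch lengths are
short (the node-density artifact), the curvilinear delta-test is applied
first; only artifact-free trees enter the regression, and significance over
a set of families is decided with Holm-Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .language_distance import DistanceMatrix

logger = logging.getLogger(__name__)

MIN_FAMILY_TAXA = 10


def nearest_outgroup(family_taxa, dm: DistanceMatrix) -> str:
    """The non-member with minimal mean distance to the family's members.

    Ties break lexicographically.
    """
    members = set(family_taxa)
    midx = [dm.index(t) for t in members]
    candidates = sorted(t for t in dm.taxa if t not in members)
    if not candidates:
        raise ValueError("no taxa outside the family")
    best, best_val = None, np.inf
    for t in candidates:
        val = float(np.mean(dm.values[dm.index(t), midx]))
        if val < best_val:
            best, best_val = t, val
    return best


def root_to_tip_statistics(tree: dendropy.Tree) -> pd.DataFrame:
    """Per-leaf root-to-tip path length and branching-node count.

    The node count includes every internal node with at least two children
    on the path from the root to the leaf (the root itself counts).
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    rows = []
    for leaf in tree.leaf_node_iter():
        length = 0.0
        count = 0
        node = leaf
        while node.parent_node is not None:
            length += node.edge.length or 0.0
            node = node.parent_node
            if len(node.child_nodes()) >= 2:
                count += 1
        rows.append((leaf.taxon.label if leaf.taxon else None, length, count))
    return pd.DataFrame(rows, columns=["taxon", "path_length", "node_count"])


def _bm_covariance(tree: dendropy.Tree, taxa: list) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()
              if lf.taxon is not None}
    # depth of every node from the root
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    # ancestor chains
    chains = {}
    for t in taxa:
        chain = []
        node = leaves[t]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains[t] = chain
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        seta = set(chains[a])
        C[i, i] = depth[chains[a][0]]
        for j in range(i + 1, n):
            b = taxa[j]
            mrca = next(nd for nd in chains[b] if nd in seta)
            C[i, j] = C[j, i] = depth[mrca]
    return C


def pgls_fit(tree: dendropy.Tree, x, y, taxa: list):
    """GLS of y on x with Brownian-motion residual covariance from the tree."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = _bm_covariance(tree, list(taxa))
    # a star tree gives a diagonal covariance, i.e. ordinary least squares
    if np.allclose(C, 0):
        raise ValueError("zero-length tree: singular covariance")
    d = np.diag(C).copy()
    jitter = 1e-10 * max(d.max(), 1.0)
    C = C + jitter * np.eye(len(d))
    X = sm.add_constant(x)
    model = sm.GLS(y, X, sigma=C)
    return model.fit()


def pgls_slope(tree: dendropy.Tree, x, y, taxa: list) -> tuple:
    """Slope and two-sided p-value of the PGLS regression of y on x."""
    res = pgls_fit(tree, x, y, taxa)
    return float(res.params[1]), float(res.pvalues[1])


@dataclass
class DeltaTestResult:
    delta: float
    se: float
    p_greater_than_1: float
    negative: bool  # True = no node-density artifact detected


def delta_test(tree: dendropy.Tree, alpha: float = 0.05) -> DeltaTestResult:
    """Curvilinear screen for the node-density artifact.

    Fits n = beta * x^delta across leaves (log-log PGLS of node count on
    path length, Brownian-motion covariance).  The test is *negative* (no
    artifact) iff delta is not significantly greater than 1 at level alpha
    (one-sided t-test).
    """
    stats_df = root_to_tip_statistics(tree)
    if len(stats_df) < 5:
        raise ValueError("need at least 5 leaves")
    x = stats_df["path_length"].to_numpy()
    n = stats_df["node_count"].to_numpy()
    if np.all(x == x[0]) or np.all(n == n[0]):
        raise ValueError("degenerate input: constant path lengths or node counts")
    if (x <= 0).any() or (n <= 0).any():
        raise ValueError("log-log fit requires positive lengths and counts")
    res = pgls_fit(tree, np.log(x), np.log(n), list(stats_df["taxon"]))
    delta = float(res.params[1])
    se = float(res.bse[1])
    t = (delta - 1.0) / se
    p = float(stats.t.sf(t, res.df_resid))
    return DeltaTestResult(delta, se, p, bool(p >= alpha))


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni significance flags."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(list(p_values), float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="holm")[0]


@dataclass
class PunctuationResult:
    family: str
    slope: float
    p_value: float
    n_taxa: int
    delta_test_negative: bool
    significant: bool


def punctuation_workflow(families: dict, dm: DistanceMatrix = None,
                         family_members: dict = None, alpha: float = 0.05,
                         min_taxa: int = MIN_FAMILY_TAXA) -> list:
    """Run the punctuation test over per-family trees.

    ``families`` maps family name -> tree.  A rooted tree is used as given
    (all its leaves count as family members).  An unrooted tree must span
    the family plus one outgroup: the outgroup is the leaf outside
    ``family_members[name]`` (or, when ambiguous, the non-member with the
    minimal mean distance to the family in ``dm``); the tree is rooted there
    and the outgroup removed.  Families with fewer than ``min_taxa`` taxa
    are skipped with a warning.  A family shows evidence for punctuated
    evolution iff its delta-test is negative, its PGLS slope is positive,
    and its p-value survives Holm-Bonferroni correction across the
    delta-negative families.
    """
    from .tree_inference import root_by_outgroup

    prepared = []
    for fam, tree in sorted(families.items()):
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if tree.is_rooted:
            rooted = tree
            fam_taxa = leaves
        else:
            if not family_members or fam not in family_members:
                raise ValueError(
                    f"family_members needed to root the unrooted tree for {fam}")
            members = set(family_members[fam])
            extra = [t for t in leaves if t not in members]
            if len(extra) == 1:
                out = extra[0]
            elif dm is not None:
                out = nearest_outgroup([t for t in leaves if t in members], dm)
                if out not in set(leaves):
                    raise ValueError(
                        f"nearest outgroup {out!r} is not a leaf of {fam}'s tree")
            else:
                raise ValueError(
                    f"cannot identify the outgroup for {fam}: {len(extra)} "
                    f"non-member leaves and no distance matrix")
            rooted = root_by_outgroup(tree, out)
            fam_taxa = [t for t in leaves if t != out]
        if len(fam_taxa) < min_taxa:
            logger.warning("family %s has %d taxa (<%d); skipped", fam,
                           len(fam_taxa), min_taxa)
            continue
        stats_df = root_to_tip_statistics(rooted)
        try:
            dres = delta_test(rooted, alpha)
        except ValueError as exc:
            logger.warning("family %s: delta-test degenerate (%s); skipped",
                           fam, exc)
            continue
        slope, p = pgls_slope(rooted, stats_df["path_length"],
                              stats_df["node_count"], list(stats_df["taxon"]))
        prepared.append((fam, slope, p, len(fam_taxa), dres.negative))

    neg = [(i, rec) for i, rec in enumerate(prepared) if rec[4]]
    flags = holm_bonferroni([rec[2] for _, rec in neg], alpha)
    sig_idx = {i for (i, _), fl in zip(neg, flags) if fl}
    results = []
    for i, (fam, slope, p, ntax, dneg) in enumerate(prepared):
        significant = bool(dneg and i in sig_idx and slope > 0)
        results.append(PunctuationResult(fam, slope, p, ntax, dneg, significant))
    return results


def results_table(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family, r.slope, r.p_value, r.n_taxa, r.delta_test_negative,
          r.significant) for r in results],
        columns=["family", "slope", "p_value", "n_taxa",
                 "delta_test_negative", "significant"])
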