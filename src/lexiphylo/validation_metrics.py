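"""Evaluation statistics: B-cubed scores, Generalized Quartet Distance,
cosine character distances, great-circle distances, Mantel test and
correlogram.

The Generalized Quartet Distance compares a (binary) inferred tree with a
possibly multifurcating reference: among the four-taxon subsets the
reference resolves, it is the fraction whose resolution the inferred tree
does not reproduce.  Quartets the reference leaves unresolved are not
counted.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import networkx as nx
import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# B-cubed


def bcubed_scores(predicted: dict, gold: dict) -> tuple:
    """Item-averaged B-cubed precision, recall and F.

    Both arguments map item -> cluster label over the same item set.
    Invariant to cluster relabeling; F is 1 iff the partitions coincide.
    """
    if not predicted:
        raise ValueError("empty item set")
    if set(predicted) != set(gold):
        raise ValueError("partitions must cover the same items")
    pred_clusters: dict = {}
    gold_clusters: dict = {}
    for it, lab in predicted.items():
        pred_clusters.setdefault(lab, set()).add(it)
    for it, lab in gold.items():
        gold_clusters.setdefault(lab, set()).add(it)
    precisions, recalls = [], []
    for it in predicted:
        p_cl = pred_clusters[predicted[it]]
        g_cl = gold_clusters[gold[it]]
        overlap = len(p_cl & g_cl)
        precisions.append(overlap / len(p_cl))
        recalls.append(overlap / len(g_cl))
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


# ---------------------------------------------------------------------------
# quartets


def _topological_distances(tree: dendropy.Tree, labels: list) -> np.ndarray:
    """Leaf-to-leaf path lengths in edge counts, unifurcations suppressed."""
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(id(edge.tail_node), id(edge.head_node))
    leaf_of = {lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()
               if lf.taxon is not None}
    # contract degree-2 nodes so the rooted/unrooted distinction cannot
    # perturb the four-point comparison
    for node in list(g.nodes):
        if g.degree(node) == 2 and node not in leaf_of.values():
            a, b = list(g.neighbors(node))
            g.remove_node(node)
            g.add_edge(a, b)
    n = len(labels)
    out = np.zeros((n, n), dtype=np.int32)
    for i, lab in enumerate(labels):
        dist = nx.single_source_shortest_path_length(g, leaf_of[lab])
        for j, lab2 in enumerate(labels):
            out[i, j] = dist[leaf_of[lab2]]
    return out


def _quartet_splits(D: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    """Resolution of each quartet (a<b<c<d) under the four-point condition.

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, -1 for unresolved.
    """
    a, b, c, d = quartets.T
    s0 = D[a, b] + D[c, d]
    s1 = D[a, c] + D[b, d]
    s2 = D[a, d] + D[b, c]
    S = np.stack([s0, s1, s2], axis=1)
    order = np.argsort(S, axis=1)
    smallest = np.take_along_axis(S, order[:, :1], axis=1)[:, 0]
    second = np.take_along_axis(S, order[:, 1:2], axis=1)[:, 0]
    res = order[:, 0].astype(np.int8)
    res[smallest == second] = -1
    return res


def generalized_quartet_distance(tree: dendropy.Tree,
                                 reference: dendropy.Tree,
                                 mode: str = "auto",
                                 n_samples: int = 100_000,
                                 seed: int = 0,
                                 exact_max_taxa: int = 30) -> float:
    """GQD of ``tree`` against a (possibly multifurcating) ``reference``.

    Both trees are restricted to their shared taxa.  ``mode`` is ``exact``
    (enumerate all C(n,4) quartets), ``sampled`` (uniform sample with a fixed
    seed), or ``auto`` (exact up to ``exact_max_taxa`` taxa).
    """
    labels_t = {lf.taxon.label for lf in tree.leaf_node_iter()}
    labels_r = {lf.taxon.label for lf in reference.leaf_node_iter()}
    shared = sorted(labels_t & labels_r)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared taxa")

    def restrict(t):
        keep = set(shared)
        t = t.clone(depth=1)
        drop = [lf.taxon for lf in t.leaf_node_iter()
                if lf.taxon.label not in keep]
        if drop:
            t.prune_taxa(drop)
        return t

    Dt = _topological_distances(restrict(tree), shared)
    Dr = _topological_distances(restrict(reference), shared)
    n = len(shared)
    if mode == "auto":
        mode = "exact" if n <= exact_max_taxa else "sampled"
    if mode == "exact":
        quartets = np.array(list(itertools.combinations(range(n), 4)),
                            dtype=np.intp)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        cols = rng.random((n_samples, n)).argsort(axis=1)[:, :4]
        quartets = np.sort(cols, axis=1).astype(np.intp)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res_r = _quartet_splits(Dr, quartets)
    resolved = res_r >= 0
    n_resolved = int(resolved.sum())
    if n_resolved == 0:
        raise ValueError("reference tree resolves no sampled quartet")
    res_t = _quartet_splits(Dt, quartets)
    differ = res_t[resolved] != res_r[resolved]
    return float(differ.sum() / n_resolved)


# ---------------------------------------------------------------------------
# character-vector and geographic distances


def cosine_character_distance(v1, v2) -> float:
    """1 - cosine similarity over jointly defined coordinates."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    mask = ~(np.isnan(v1) | np.isnan(v2))
    if not mask.any():
        raise ValueError("no jointly defined characters")
    a, b = v1[mask], v2[mask]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero character vector after masking")
    return float(1.0 - np.dot(a, b) / (na * nb))


def great_circle_distance(p1, p2) -> float:
    """Haversine distance in km on a sphere of mean Earth radius 6371 km."""
    (lat1, lon1), (lat2, lon2) = p1, p2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 360):
            raise ValueError(f"coordinate out of range: {(lat, lon)}")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


# ---------------------------------------------------------------------------
# Mantel statistics


def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _mantel_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("constant matrix: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(dm1, dm2, method: str = "spearman", n_perm: int = 999,
                seed: int = 0, alternative: str = "greater") -> tuple:
    """Mantel permutation test between two symmetric distance matrices.

    The statistic is the (Spearman by default) correlation over the
    off-diagonal upper triangles; the permutation null simultaneously
    permutes the rows and columns of the second matrix.  The p-value is
    (1 + #{r_perm as extreme as r}) / (1 + n_perm).
    """
    m1 = dm1.values if hasattr(dm1, "values") and not isinstance(dm1, np.ndarray) else np.asarray(dm1, float)
    m2 = dm2.values if hasattr(dm2, "values") and not isinstance(dm2, np.ndarray) else np.asarray(dm2, float)
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if not (np.allclose(m1, m1.T) and np.allclose(m2, m2.T)):
        raise ValueError("matrices must be symmetric")
    x = _offdiag_upper(m1)
    r_obs = _mantel_r(x, _offdiag_upper(m2), method)
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _mantel_r(x, _offdiag_upper(m2[np.ix_(perm, perm)]), method)
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)


def mantel_correlogram(dm_ling, dm_geo, bin_edges=None, n_perm: int = 999,
                       seed: int = 0, alpha: float = 0.05,
                       holm: bool = False) -> list:
    """Per-distance-class Mantel statistics against geographic bins.

    For each geographic distance class, the statistic is the (sign-flipped)
    Pearson Mantel correlation between the class-membership indicator matrix
    and the linguistic distances, so positive values mean languages in that
    geographic band are linguistically more similar than average.  Default
    bins are 1,000 km wide, covering the observed range.  Returns a list of
    dicts with bin bounds, r, p and a significance flag (Holm-corrected
    across bins when ``holm=True``).
    """
    geo = dm_geo.values if hasattr(dm_geo, "values") and not isinstance(dm_geo, np.ndarray) else np.asarray(dm_geo, float)
    ling = dm_ling.values if hasattr(dm_ling, "values") and not isinstance(dm_ling, np.ndarray) else np.asarray(dm_ling, float)
    geo, ling = np.asarray(geo, float), np.asarray(ling, float)
    if bin_edges is None:
        top = float(_offdiag_upper(geo).max())
        bin_edges = np.arange(0, top + 1000.0, 1000.0)
    bin_edges = np.asarray(bin_edges, float)
    results = []
    rng = np.random.default_rng(seed)
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        member = ((geo >= lo) & (geo < hi)).astype(float)
        np.fill_diagonal(member, 0.0)
        if _offdiag_upper(member).sum() == 0:
            logger.warning("empty geographic bin [%g, %g); skipped", lo, hi)
            continue
        bin_seed = int(rng.integers(2**31 - 1))
        try:
            r, p = mantel_test(member, ling, method="pearson", n_perm=n_perm,
                               seed=bin_seed, alternative="two-sided")
        except ValueError:
            logger.warning("degenerate bin [%g, %g); skipped", lo, hi)
            continue
        results.append({"lo": float(lo), "hi": float(hi), "r": -r, "p": p})
    if holm:
        from statsmodels.stats.multitest import multipletests
        flags = multipletests([b["p"] for b in results], alpha=alpha,
                              method="holm")[0]
        for b, fl in zip(results, flags):
            b["significant"] = bool(fl)
    else:
        for b in results:
            b["significant"] = b["p"] < alpha
    return results
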