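"""B-cubed, GQD, cosine/geographic distances, and Mantel statistics."""

import itertools
import subprocess
import textwrap

import dendropy
import numpy as np
import pytest

from lexiphylo.synthetic_fixtures import SimulationConfig, simulate_tree
from lexiphylo.validation_metrics import (bcubed_scores,
                                          cosine_character_distance,
                                          generalized_quartet_distance,
                                          great_circle_distance,
                                          mantel_correlogram, mantel_test)


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick",
                             preserve_underscores=True)


class TestBcubed:
    def test_identical_partitions(self):
        part = {1: "a", 2: "a", 3: "b"}
        assert bcubed_scores(part, dict(part)) == (1.0, 1.0, 1.0)

    def test_singletons_vs_one_cluster(self):
        n = 5
        pred = {i: f"s{i}" for i in range(n)}
        gold = {i: "all" for i in range(n)}
        p, r, f = bcubed_scores(pred, gold)
        assert p == pytest.approx(1.0)
        assert r == pytest.approx(1 / n)

    def test_relabeling_invariant(self):
        pred = {1: "x", 2: "x", 3: "y", 4: "z"}
        gold = {1: "a", 2: "b", 3: "b", 4: "c"}
        renamed = {k: v.upper() + "_" for k, v in pred.items()}
        assert bcubed_scores(pred, gold) == bcubed_scores(renamed, gold)

    def test_f_one_iff_identical(self):
        pred = {1: "x", 2: "x", 3: "y"}
        gold = {1: "a", 2: "b", 3: "b"}
        assert bcubed_scores(pred, gold)[2] < 1.0

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError):
            bcubed_scores({1: "a"}, {2: "a"})


def quartet_split_oracle(tree, quartet):
    """Independent oracle: prune a copy to the 4 taxa and read off the
    nontrivial bipartition with dendropy's own encoding."""
    t = tree.clone(depth=1)
    keep = set(quartet)
    t.retain_taxa_with_labels(list(keep))
    t.encode_bipartitions()
    for edge in t.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(tx.label for tx in
                         edge.bipartition.leafset_taxa(t.taxon_namespace))
        side = frozenset(side & keep)
        if len(side) == 2:
            return min(side, keep - side, key=sorted)
    return None  # unresolved


class TestGQD:
    def test_tree_vs_itself_is_zero(self):
        t = simulate_tree(SimulationConfig(n_languages=12, seed=5))
        assert generalized_quartet_distance(t, t) == 0.0

    def test_star_reference_rejected(self):
        star = newick("(A:1,B:1,C:1,D:1,E:1);")
        t = newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        with pytest.raises(ValueError, match="resolve"):
            generalized_quartet_distance(t, star)

    def test_six_taxon_hand_pair_matches_quartet_oracle(self):
        t1 = newick("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        t2 = newick("((A:1,C:1):1,((B:1,D:1):1,(E:1,F:1):1):1);")
        labels = list("ABCDEF")
        differ = total = 0
        for q in itertools.combinations(labels, 4):
            s_ref = quartet_split_oracle(t2, q)
            if s_ref is None:
                continue
            total += 1
            differ += quartet_split_oracle(t1, q) != s_ref
        expected = differ / total
        assert generalized_quartet_distance(t1, t2, mode="exact") == \
            pytest.approx(expected)
        assert total == 15

    def test_partially_resolved_reference_counts_only_resolved(self):
        ref = newick("((A:1,B:1):1,C:1,D:1,E:1);")  # only AB|xy resolved
        t = newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        # every reference-resolved quartet contains the AB cherry; t agrees
        assert generalized_quartet_distance(t, ref) == 0.0
        t_bad = newick("((A:1,C:1):1,(B:1,(D:1,E:1):1):1);")
        assert generalized_quartet_distance(t_bad, ref) > 0.5

    def test_sampled_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        diffs = []
        for seed in range(4):
            t1 = simulate_tree(SimulationConfig(n_languages=10, seed=seed))
            t2 = simulate_tree(SimulationConfig(n_languages=10,
                                                seed=seed + 100))
            exact = generalized_quartet_distance(t1, t2, mode="exact")
            sampled = generalized_quartet_distance(t1, t2, mode="sampled",
                                                   n_samples=4000, seed=9)
            se = np.sqrt(exact * (1 - exact) / 4000) + 1e-9
            assert abs(sampled - exact) <= 4 * se
            diffs.append(abs(sampled - exact))
        assert np.mean(diffs) < 0.05


class TestCosine:
    def test_identical_rows(self):
        v = np.array([1.0, 0.0, 1.0, 1.0])
        assert cosine_character_distance(v, v) == pytest.approx(0.0)

    def test_orthogonal_rows(self):
        assert cosine_character_distance([1, 0, 1, 0], [0, 1, 0, 1]) == \
            pytest.approx(1.0)

    def test_masked_coordinates_ignored(self):
        v1 = np.array([1.0, 0.0, np.nan, 1.0])
        v2a = np.array([1.0, 1.0, 1.0, np.nan])
        v2b = np.array([1.0, 1.0, 0.0, np.nan])
        assert cosine_character_distance(v1, v2a) == \
            pytest.approx(cosine_character_distance(v1, v2b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_character_distance([0.0, 0.0], [1.0, 1.0])


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_distance((10, 20), (10, 20)) == 0.0

    def test_antipodes(self):
        d = great_circle_distance((0, 0), (0, 180))
        assert d == pytest.approx(np.pi * 6371, rel=1e-6)

    def test_symmetric(self):
        a, b = (48.1, 11.5), (-33.9, 151.2)
        assert great_circle_distance(a, b) == pytest.approx(
            great_circle_distance(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance((95, 0), (0, 0))


def random_distance_matrix(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        m = random_distance_matrix(rng, 12)
        r, p = mantel_test(m, m.copy(), n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_statistic_matches_vegan(self, tmp_path):
        """Cross-check the Mantel r against R's vegan on a fixed matrix."""
        rng = np.random.default_rng(3)
        m1 = random_distance_matrix(rng, 10)
        m2 = random_distance_matrix(rng, 10)
        np.savetxt(tmp_path / "m1.csv", m1, delimiter=",")
        np.savetxt(tmp_path / "m2.csv", m2, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m1 <- as.dist(as.matrix(read.csv('{tmp_path}/m1.csv', header=FALSE)))
            m2 <- as.dist(as.matrix(read.csv('{tmp_path}/m2.csv', header=FALSE)))
            r <- mantel(m1, m2, method='spearman', permutations=0)
            cat(sprintf('%.12f', r$statistic))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_vegan = float(out.stdout.strip().split()[-1])
        r_ours, _ = mantel_test(m1, m2, method="spearman", n_perm=9, seed=0)
        assert r_ours == pytest.approx(r_vegan, abs=1e-10)

    def test_taxon_relabeling_invariant(self):
        rng = np.random.default_rng(5)
        m1 = random_distance_matrix(rng, 8)
        m2 = random_distance_matrix(rng, 8)
        perm = rng.permutation(8)
        r1, _ = mantel_test(m1, m2, n_perm=49, seed=2)
        r2, _ = mantel_test(m1[np.ix_(perm, perm)], m2[np.ix_(perm, perm)],
                            n_perm=49, seed=2)
        assert r1 == pytest.approx(r2)

    def test_independent_matrices_p_not_degenerate(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(30):
            m1 = random_distance_matrix(rng, 10)
            m2 = random_distance_matrix(rng, 10)
            ps.append(mantel_test(m1, m2, n_perm=99,
                                  seed=int(rng.integers(1 << 30)))[1])
        frac_small = np.mean(np.array(ps) < 0.5)
        # binomial(30, .5): 3 sigma is about 0.27
        assert 0.2 <= frac_small <= 0.8

    def test_constant_matrix_rejected(self):
        m = np.ones((5, 5))
        np.fill_diagonal(m, 0)
        with pytest.raises(ValueError):
            mantel_test(m, m, n_perm=9)


class TestCorrelogram:
    def geo_and_ling(self, rng, n=40, monotone=True):
        lat = rng.uniform(-40, 40, n)
        lon = rng.uniform(-90, 90, n)
        geo = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                geo[i, j] = geo[j, i] = great_circle_distance(
                    (lat[i], lon[i]), (lat[j], lon[j]))
        if monotone:
            ling = geo / geo.max() + rng.normal(0, 0.02, (n, n))
            ling = (ling + ling.T) / 2
        else:
            ling = random_distance_matrix(rng, n)
        np.fill_diagonal(ling, 0)
        return geo, ling

    def test_monotone_relation_first_bins_positive(self):
        rng = np.random.default_rng(21)
        geo, ling = self.geo_and_ling(rng)
        bins = mantel_correlogram(ling, geo, n_perm=199, seed=3)
        assert bins[0]["r"] > 0
        assert bins[0]["significant"]

    def test_shuffled_linguistic_matrix_mostly_nonsignificant(self):
        rng = np.random.default_rng(22)
        geo, ling = self.geo_and_ling(rng, monotone=False)
        bins = mantel_correlogram(ling, geo, n_perm=199, seed=4)
        assert np.mean([b["significant"] for b in bins]) < 0.4

    def test_empty_bin_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(23)
        geo, ling = self.geo_and_ling(rng, n=15)
        edges = [0, 1000, 2000, 1e6, 2e6]
        with caplog.at_level("WARNING"):
            bins = mantel_correlogram(ling, geo, bin_edges=edges, n_perm=49,
                                      seed=5)
        assert "empty geographic bin" in caplog.text
        assert len(bins) < 4
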