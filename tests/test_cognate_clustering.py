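"""Word-pair features, the cognacy classifier, and label-propagation
clustering."""

import numpy as np
import pandas as pd
import pytest

from lexiphylo.cognate_clustering import (FEATURE_NAMES, WINNING_SUBSET,
                                          FeatureExtractor,
                                          all_feature_subsets,
                                          cluster_collection, cluster_words,
                                          select_feature_subset,
                                          train_cognacy_classifier)
from lexiphylo.pmi_training import train_model
from lexiphylo.sound_model import CONCEPTS_40, asjp_inventory
from lexiphylo.synthetic_fixtures import (SimulationConfig,
                                          simulate_collection,
                                          synthetic_feature_gold)

from .conftest import make_collection, make_model

INV = asjp_inventory()


@pytest.fixture(scope="module")
def near_identical():
    """Three languages, two nearly identical, over complete lists."""
    words = {c: [INV.symbols[i] * 2 + INV.symbols[(i + 1) % 41]]
             for i, c in enumerate(CONCEPTS_40)}
    far = {c: [INV.symbols[(i + 17) % 41] * 3] for i, c in
           enumerate(CONCEPTS_40)}
    return make_collection({"A": dict(words), "B": dict(words), "C": far})


class TestFeatures:
    def test_consistency_and_direction(self, near_identical, diag_model):
        ex = FeatureExtractor(near_identical, diag_model)
        c = CONCEPTS_40[0]
        w = near_identical["A"].entries[c][0]
        f = ex.pair_features(w, w, "A", "B", c)
        assert f["neg_log_p"] == pytest.approx(-np.log(f["calibrated_p"]),
                                               abs=1e-12)
        assert f["neg_log_p"] > 3        # identical words in close languages
        assert f["neg_log_one_minus_d"] < 0.1
        assert f["avg_word_length"] == pytest.approx(3.0)

    def test_concept_correlation_matches_recomputation(self, diag_model):
        coll = make_collection({
            "A": {"dog": ["hund", "dagi"], "sun": ["sol"]},
            "B": {"dog": ["dag"], "sun": ["zon"]},
            "C": {"dog": ["kani"], "sun": ["suno"]},
        })
        ex = FeatureExtractor(coll, diag_model)
        table = pd.concat([ex.concept_pair_table("dog")], ignore_index=True)
        f3 = table["neg_log_p"].to_numpy()
        f4 = table["language_distance"].to_numpy()
        expected = np.corrcoef(f3, np.minimum(f4, 1 - 1e-9))[0, 1]
        assert table["concept_language_correlation"].iloc[0] == \
            pytest.approx(expected)

    def test_same_doculect_rejected(self, near_identical, diag_model):
        ex = FeatureExtractor(near_identical, diag_model)
        c = CONCEPTS_40[0]
        w = near_identical["A"].entries[c][0]
        with pytest.raises(ValueError):
            ex.pair_features(w, w, "A", "A", c)


class TestClassifier:
    @staticmethod
    def separable_table(n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = {name: rng.normal(size=n) for name in FEATURE_NAMES}
        X["neg_log_p"] = y * 4.0 + rng.normal(0, 0.1, n)
        return pd.DataFrame(X), y

    def test_separable_data_fit(self):
        table, y = self.separable_table()
        clf = train_cognacy_classifier(table, y, ("neg_log_p",), seed=0)
        p = clf.predict_proba(table)
        assert ((p > 0.5) == y.astype(bool)).all()
        assert ((p >= 0) & (p <= 1)).all()

    def test_probability_monotone_along_signal_ray(self):
        table, y = self.separable_table()
        clf = train_cognacy_classifier(table, y, ("neg_log_p",), seed=0)
        ray = pd.DataFrame({"neg_log_p": np.linspace(0.0, 4.0, 9)})
        p = clf.predict_proba(ray)
        assert (np.diff(p) > -1e-9).all()
        assert p[-1] > 0.9 > 0.5 > p[0]

    def test_deterministic_given_seed(self):
        table, y = self.separable_table()
        p1 = train_cognacy_classifier(table, y, WINNING_SUBSET,
                                      seed=3).predict_proba(table)
        p2 = train_cognacy_classifier(table, y, WINNING_SUBSET,
                                      seed=3).predict_proba(table)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        table, _ = self.separable_table()
        with pytest.raises(ValueError):
            train_cognacy_classifier(table, np.ones(len(table)), seed=0)

    def test_n_train_subsampling(self):
        table, y = self.separable_table(n=500)
        clf = train_cognacy_classifier(table, y, ("neg_log_p",), n_train=100,
                                       seed=0)
        fitted = clf.pipeline.named_steps["svm"].calibrated_classifiers_[0]
        assert fitted.estimator.shape_fit_[0] == 100


class TestClusterWords:
    def test_no_edges_all_singletons(self):
        items = list("abcde")
        probs = {(a, b): 0.0 for i, a in enumerate(items)
                 for b in items[i + 1:]}
        parts = cluster_words(items, probs, seed=0)
        assert sorted(len(p) for p in parts) == [1] * 5

    def test_two_cliques(self):
        items = list("abcdef")
        probs = {}
        for grp in ("abc", "def"):
            for i, a in enumerate(grp):
                for b in grp[i + 1:]:
                    probs[(a, b)] = 1.0
        parts = cluster_words(items, probs, seed=1)
        assert {frozenset(p) for p in parts} == \
            {frozenset("abc"), frozenset("def")}

    def test_threshold_is_inclusive(self):
        parts = cluster_words(["a", "b"], {("a", "b"): 0.25}, threshold=0.25,
                              seed=0)
        assert len(parts) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        items = [f"w{i}" for i in range(12)]
        probs = {(a, b): float(rng.random()) for i, a in enumerate(items)
                 for b in items[i + 1:]}
        p1 = cluster_words(items, probs, seed=7)
        p2 = cluster_words(items, probs, seed=7)
        assert sorted(map(sorted, p1)) == sorted(map(sorted, p2))


@pytest.fixture(scope="module")
def trained():
    out = simulate_collection(SimulationConfig(n_languages=8, seed=31))
    model = train_model(out.collection)
    return out, model


class TestClusterCollection:
    def test_identical_doculects_co_clustered(self, trained):
        out, model = trained
        twin_words = {c: list(ws) for c, ws in
                      out.collection.doculects[0].entries.items()}
        coll = make_collection({"T1": twin_words, "T2": twin_words,
                                "T3": {c: [w[::-1] if len(w) > 1 else w + "X"]
                                       for c, (w, *_) in twin_words.items()}})
        table, y = _labeled_pairs_from_truth(out, model)
        clf = train_cognacy_classifier(table, y, WINNING_SUBSET, seed=2)
        assign = cluster_collection(coll, model, clf, seed=2)
        merged = assign[assign.doculect.isin(["T1", "T2"])]
        for c, grp in merged.groupby("concept"):
            assert grp["cognate_class"].nunique() == 1

    def test_row_count_equals_word_count(self, trained):
        out, model = trained
        table, y = _labeled_pairs_from_truth(out, model)
        clf = train_cognacy_classifier(table, y, WINNING_SUBSET, seed=2)
        assign = cluster_collection(out.collection, model, clf, seed=2)
        n_words = sum(len(ws) for d in out.collection
                      for ws in d.entries.values())
        assert len(assign) == n_words
        assert (assign["cognate_class"].str.rsplit("_", n=1).str[0]
                == assign["concept"]).all()

    def test_beats_shuffled_baseline(self, trained):
        from lexiphylo.validation_metrics import bcubed_scores
        out, model = trained
        table, y = _labeled_pairs_from_truth(out, model)
        clf = train_cognacy_classifier(table, y, WINNING_SUBSET, seed=2)
        assign = cluster_collection(out.collection, model, clf, seed=2)
        pred = {(r.doculect, r.concept, r.transcription): r.cognate_class
                for r in assign.itertuples(index=False)}
        gold = out.truth_partition()
        f = bcubed_scores(pred, gold)[2]
        rng = np.random.default_rng(0)
        labels = list(gold.values())
        rng.shuffle(labels)
        f_shuffled = bcubed_scores(dict(zip(gold, labels)), gold)[2]
        assert f > f_shuffled + 0.3


def _labeled_pairs_from_truth(out, model):
    """Features + labels for all synonymous pairs of a simulated collection."""
    ex = FeatureExtractor(out.collection, model)
    truth = out.truth_partition()
    tables, labels = [], []
    for c in out.config.concepts:
        t = ex.concept_pair_table(c)
        if not len(t):
            continue
        for r in t.itertuples(index=False):
            labels.append(int(truth[(r.doculect1, c, r.word1)]
                              == truth[(r.doculect2, c, r.word2)]))
        tables.append(t)
    return pd.concat(tables, ignore_index=True), np.asarray(labels)


class TestModelSelection:
    def test_subset_enumeration(self):
        subsets = all_feature_subsets()
        assert len(subsets) == 127
        assert len(set(subsets)) == 127

    def test_single_informative_feature_selected(self):
        pairs, gold = synthetic_feature_gold(
            n_families=6, n_languages=4, n_concepts=5,
            informative=("neg_log_p",), seed=5)
        best, table = select_feature_subset(pairs, gold, n_splits=2,
                                            n_train=400, seed=5)
        assert len(table) == 127
        assert "neg_log_p" in best

    def test_score_table_is_complete(self):
        pairs, gold = synthetic_feature_gold(n_families=4, n_languages=3,
                                             n_concepts=4, seed=6)
        _, table = select_feature_subset(pairs, gold, n_splits=1,
                                         n_train=200, seed=6)
        assert table["mean_bcubed_f"].notna().all()
        assert table["n_features"].between(1, 7).all()

    def test_too_few_families_rejected(self):
        pairs, gold = synthetic_feature_gold(n_families=1, n_languages=4,
                                             n_concepts=3, seed=7)
        with pytest.raises(ValueError):
            select_feature_subset(pairs, gold, n_splits=1, seed=0)
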