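"""Supervised cognate detection and clustering.

For every pair of same-concept words from different doculects, seven features
are computed from the trained PMI model and the calibrated language
distances.  A support-vector machine with an RBF kernel, trained on
gold-standard cognacy judgments and calibrated with Platt scaling, turns the
features into a probability of cognacy.  Per concept, words are clustered by
label propagation on the graph whose edges connect pairs with probability at
or above a threshold (0.25 by default).  A cross-validation harness over all
127 non-empty feature subsets performs model selection by mean B-cubed F.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .alignment import ScoringModel
from .language_distance import LanguageDistanceCalculator, PMIScorer
from .sound_model import WordListCollection

logger = logging.getLogger(__name__)

#: Feature names, in canonical order (the classical f1..f7).
FEATURE_NAMES = (
    "pmi_similarity",            # f1: aggregate PMI of the word pair
    "calibrated_p",              # f2: calibrated p-value of that score
    "neg_log_p",                 # f3: -log f2 ("word similarity")
    "language_distance",         # f4: d(l1, l2)
    "neg_log_one_minus_d",       # f5: -log(1 - d) ("language log-distance")
    "avg_word_length",           # f6: mean word length for the concept
    "concept_language_correlation",  # f7: Pearson r between f3 and f4
)

#: The two-feature subset that won model selection on the real gold data.
WINNING_SUBSET = ("neg_log_p", "neg_log_one_minus_d")

DEFAULT_THRESHOLD = 0.25
DEFAULT_N_TRAIN = 7000
D_CLAMP = 1.0 - 1e-9


class FeatureExtractor:
    """Computes word-pair features over one collection and scoring model."""

    def __init__(self, collection: WordListCollection, model: ScoringModel,
                 calculator: LanguageDistanceCalculator = None):
        self.collection = collection
        self.model = model
        self.calc = calculator or LanguageDistanceCalculator(
            collection, PMIScorer(model))
        self._avg_len: dict = {}
        self._concept_corr: dict = {}

    # -- per-concept statistics -------------------------------------------

    def avg_word_length(self, concept: str) -> float:
        """Mean length (in symbols) of all words for the concept."""
        if concept not in self._avg_len:
            lens = [len(w) for d in self.collection
                    for w in d.entries.get(concept, [])]
            self._avg_len[concept] = float(np.mean(lens)) if lens else np.nan
        return self._avg_len[concept]

    def concept_language_correlation(self, concept: str) -> float:
        """Pearson r between word similarity (f3) and language distance (f4)
        over all cross-doculect word pairs for the concept."""
        if concept not in self._concept_corr:
            f3s, f4s = [], []
            names = self.collection.names
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    for f3, f4 in self._pair_f3_f4(a, b, concept):
                        f3s.append(f3)
                        f4s.append(f4)
            if len(f3s) < 2 or np.std(f3s) == 0 or np.std(f4s) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(f3s, f4s)[0, 1])
            self._concept_corr[concept] = r
        return self._concept_corr[concept]

    def _pair_f3_f4(self, a: str, b: str, concept: str):
        da, db = self.collection[a], self.collection[b]
        if not da.entries.get(concept) or not db.entries.get(concept):
            return
        prof = self.calc.profile(a, b)
        d = min(prof.d, D_CLAMP)
        rows = [i for i, (c, _) in enumerate(prof.words_a) if c == concept]
        cols = [j for j, (c, _) in enumerate(prof.words_b) if c == concept]
        for i in rows:
            for j in cols:
                p = prof.p_of_score(prof.word_scores[i, j])
                yield -np.log(p), d

    # -- per-pair features -------------------------------------------------

    def pair_features(self, w1: str, w2: str, l1: str, l2: str,
                      concept: str) -> dict:
        """The seven features for one same-concept cross-doculect word pair."""
        if l1 == l2:
            raise ValueError("word pair must come from different doculects")
        prof = self.calc.profile(l1, l2)
        # profile rows follow the lexicographically smaller doculect
        if prof.name_a == l1:
            wx, wy = w1, w2
        else:
            wx, wy = w2, w1
        try:
            i = prof.words_a.index((concept, wx))
            j = prof.words_b.index((concept, wy))
        except ValueError:
            raise KeyError(f"word pair not found for concept {concept!r}")
        score = float(prof.word_scores[i, j])
        p = prof.p_of_score(score)
        d = float(min(prof.d, D_CLAMP))
        return {
            "pmi_similarity": score,
            "calibrated_p": p,
            "neg_log_p": float(-np.log(p)),
            "language_distance": float(prof.d),
            "neg_log_one_minus_d": float(-np.log(1.0 - d)),
            "avg_word_length": self.avg_word_length(concept),
            "concept_language_correlation":
                self.concept_language_correlation(concept),
        }

    def concept_pair_table(self, concept: str) -> pd.DataFrame:
        """Features for all cross-doculect word pairs of one concept."""
        rows = []
        names = self.collection.names
        for ia, a in enumerate(names):
            for b in names[ia + 1:]:
                da, db = self.collection[a], self.collection[b]
                for i1, w1 in enumerate(da.entries.get(concept, [])):
                    for i2, w2 in enumerate(db.entries.get(concept, [])):
                        feats = self.pair_features(w1, w2, a, b, concept)
                        feats.update(doculect1=a, doculect2=b, word1=w1,
                                     word2=w2, index1=i1, index2=i2,
                                     concept=concept)
                        rows.append(feats)
        return pd.DataFrame(rows)


def compute_pair_features(w1, w2, l1, l2, concept, model,
                          collection) -> dict:
    """Convenience wrapper around :class:`FeatureExtractor`."""
    return FeatureExtractor(collection, model).pair_features(
        w1, w2, l1, l2, concept)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class CognacyClassifier:
    """A fitted SVM + Platt-scaling pipeline over a feature subset."""

    pipeline: Pipeline
    features: tuple

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.features)].to_numpy()
        cls = list(self.pipeline.classes_)
        return self.pipeline.predict_proba(X)[:, cls.index(1)]


def train_cognacy_classifier(table: pd.DataFrame, labels,
                             features=WINNING_SUBSET,
                             n_train: int = DEFAULT_N_TRAIN,
                             seed: int = 0) -> CognacyClassifier:
    """Fit the RBF-kernel SVM with probability calibration.

    A random sample of at most ``n_train`` labeled pairs is used; features
    are standardized on the training sample before the kernel.
    """
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    X = table.loc[:, list(features)].to_numpy()
    rng = np.random.default_rng(seed)
    if len(labels) > n_train:
        idx = rng.choice(len(labels), size=n_train, replace=False)
        X, labels = X[idx], labels[idx]
        if len(set(labels)) < 2:
            raise ValueError("training sample lost one class; increase n_train")
    min_class = int(np.bincount(labels).min())
    if min_class < 2:
        raise ValueError("need at least 2 training pairs per class")
    # sigmoid calibration on cross-validated decision values = Platt scaling
    svm = SVC(kernel="rbf", random_state=int(rng.integers(2**31 - 1)))
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", CalibratedClassifierCV(svm, method="sigmoid", ensemble=False,
                                       cv=min(5, min_class))),
    ])
    pipe.fit(X, labels)
    return CognacyClassifier(pipe, tuple(features))


# ---------------------------------------------------------------------------
# clustering


def cluster_words(items, probabilities, threshold: float = DEFAULT_THRESHOLD,
                  seed: int = 0) -> list:
    """Partition items by label propagation on the cognacy graph.

    ``probabilities`` maps unordered item pairs to cognacy probabilities;
    items in no pair at or above the threshold end up as singletons.
    Deterministic given the seed (asynchronous random-order label
    propagation).
    """
    G = nx.Graph()
    G.add_nodes_from(items)
    for (a, b), p in probabilities.items():
        if p >= threshold:
            G.add_edge(a, b)
    communities = nx.community.asyn_lpa_communities(G, seed=seed)
    return [set(c) for c in communities]


def cluster_collection(collection: WordListCollection, model: ScoringModel,
                       classifier: CognacyClassifier,
                       threshold: float = DEFAULT_THRESHOLD, seed: int = 0,
                       extractor: FeatureExtractor = None) -> pd.DataFrame:
    """Cluster every concept's words into cognate classes.

    Returns the word list with an appended ``cognate_class`` column; labels
    follow the ``concept_serial`` convention (e.g. ``dog_3``).
    """
    if extractor is None:
        extractor = FeatureExtractor(collection, model)
    rows = []
    for concept in collection.concepts:
        table = extractor.concept_pair_table(concept)
        items = [(d.name, concept, i, w)
                 for d in collection
                 for i, w in enumerate(d.entries.get(concept, []))]
        if not items:
            continue
        probs = {}
        if len(table):
            p = classifier.predict_proba(table)
            for k, row in enumerate(table.itertuples(index=False)):
                key = ((row.doculect1, concept, row.index1, row.word1),
                       (row.doculect2, concept, row.index2, row.word2))
                probs[key] = p[k]
        partition = cluster_words(items, probs, threshold, seed)
        partition = sorted(partition, key=lambda s: min(map(str, s)))
        for serial, cluster in enumerate(partition, start=1):
            for (name, c, i, w) in cluster:
                rows.append((name, c, w, f"{concept}_{serial}"))
    out = pd.DataFrame(rows, columns=["doculect", "concept", "transcription",
                                      "cognate_class"])
    return out.sort_values(["concept", "doculect"], kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# model selection


def all_feature_subsets(features=FEATURE_NAMES) -> list:
    """All 2^k - 1 non-empty feature subsets, in a deterministic order."""
    out = []
    for r in range(1, len(features) + 1):
        out.extend(itertools.combinations(features, r))
    return out


def select_feature_subset(pairs: pd.DataFrame, gold: dict,
                          n_splits: int = 10, n_train: int = DEFAULT_N_TRAIN,
                          n_train_families: int = 6,
                          threshold: float = DEFAULT_THRESHOLD,
                          seed: int = 0) -> tuple:
    """Cross-validated model selection over all 127 feature subsets.

    Parameters
    ----------
    pairs : DataFrame
        One row per labeled same-concept word pair with the seven feature
        columns plus ``item1``, ``item2`` (hashable word identifiers),
        ``family1``, ``family2``, ``concept`` and binary ``cognate``.
    gold : dict
        item -> gold cognate-class label (used for B-cubed scoring).
    n_splits : int
        Number of random family-wise training/test splits.
    n_train : int
        Training pairs sampled per split.

    Returns
    -------
    (best_subset, scores) : (tuple, DataFrame)
        The subset maximizing mean B-cubed F, and the full score table.
    """
    from .validation_metrics import bcubed_scores

    families = sorted(set(pairs["family1"]) | set(pairs["family2"]))
    if len(families) < 2:
        raise ValueError("need at least 2 families for family-wise splits")
    k_train = min(n_train_families, len(families) - 1)
    rng = np.random.default_rng(seed)
    subsets = all_feature_subsets()
    scores = np.zeros((len(subsets), n_splits))
    item_family = {}
    for row in pairs.itertuples(index=False):
        item_family[row.item1] = row.family1
        item_family[row.item2] = row.family2

    for split in range(n_splits):
        train_fams = set(rng.choice(families, size=k_train, replace=False))
        in_train = (pairs["family1"].isin(train_fams)
                    & pairs["family2"].isin(train_fams)).to_numpy()
        in_test = (~pairs["family1"].isin(train_fams)
                   & ~pairs["family2"].isin(train_fams)).to_numpy()
        train_idx = np.flatnonzero(in_train)
        y_train = pairs["cognate"].to_numpy()[train_idx].astype(int)
        if len(set(y_train)) < 2:
            logger.warning("split %d: single-class training data; skipped",
                           split)
            scores[:, split] = np.nan
            continue
        if len(train_idx) > n_train:
            sub = rng.choice(len(train_idx), size=n_train, replace=False)
            train_idx = train_idx[sub]
            y_train = pairs["cognate"].to_numpy()[train_idx].astype(int)
        test = pairs.iloc[np.flatnonzero(in_test)].reset_index(drop=True)
        test_items = sorted({i for i in item_family
                             if item_family[i] not in train_fams},
                            key=str)
        gold_test = {i: gold[i] for i in test_items}
        cluster_seed = int(rng.integers(2**31 - 1))

        for si, subset in enumerate(subsets):
            clf = train_cognacy_classifier(pairs.iloc[train_idx],
                                           y_train, subset,
                                           n_train=n_train, seed=cluster_seed)
            p = clf.predict_proba(test) if len(test) else np.array([])
            predicted = {}
            for concept, grp in test.groupby("concept", sort=True):
                probs = {(r.item1, r.item2): p[i]
                         for i, r in zip(grp.index, grp.itertuples(index=False))}
                citems = sorted({r.item1 for r in grp.itertuples(index=False)}
                                | {r.item2 for r in grp.itertuples(index=False)},
                                key=str)
                for ci, cl in enumerate(cluster_words(citems, probs, threshold,
                                                      cluster_seed)):
                    for it in cl:
                        predicted[it] = f"{concept}_{ci}"
            # items never paired in the test table are singletons
            for it in test_items:
                predicted.setdefault(it, f"single_{it}")
            _, _, fscore = bcubed_scores(predicted, gold_test)
            scores[si, split] = fscore

    mean_f = np.nanmean(scores, axis=1)
    table = pd.DataFrame({
        "subset": [",".join(s) for s in subsets],
        "n_features": [len(s) for s in subsets],
        "mean_bcubed_f": mean_f,
    })
    best = subsets[int(np.argmax(mean_f))]
    return best, table
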