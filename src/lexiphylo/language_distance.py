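"""Calibrated pairwise distances between word lists.

Word-level similarities are aggregated into a language-level dissimilarity in
four steps.  For each concept shared by two languages the similarity is the
maximal score over the synonym cross-product.  The same maximum over the
cross-*concept* pairs (c1 != c2) gives a null sample of similarity scores
between (presumed) non-cognates, against which the synonymous score is
calibrated into a p-value

    p_c = (1 + #{null >= s_c}) / (1 + #null).

The p-values are combined Fisher-style, Z = (sum_c -log p_c - N) / sqrt(N)
over the N shared concepts, and Z is rescaled into a distance

    d = (Zmax - Z) / (Zmax - Zmin),

where the bounds Zmax and Zmin are the closed-form extremes for complete
40-concept lists.  d is a dissimilarity, not a metric distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .alignment import ScoringModel, ldn, pmi_score
from .sound_model import Doculect, SoundInventory, WordListCollection, asjp_inventory

logger = logging.getLogger(__name__)

N_FULL = 40  # complete list length; the Z bounds always use this


@dataclass(frozen=True)
class ZConstants:
    z_max: float
    z_min: float


def z_constants(n_concepts: int = N_FULL) -> ZConstants:
    """Closed-form bounds of the combined Z statistic for complete lists.

    The maximum is attained when every synonymous pair outscores all
    n^2 - n cross-concept pairs, so every p_c sits at its floor
    1/(n^2 - n + 1); the minimum when every p_c equals 1.
    """
    n = n_concepts
    p_floor = 1.0 / (n * n - n + 1)
    z_max = (n * -np.log(p_floor) - n) / np.sqrt(n)
    z_min = (n * -np.log(1.0) - n) / np.sqrt(n)
    return ZConstants(float(z_max), float(z_min))


# ---------------------------------------------------------------------------
# word scorers


class PMIScorer:
    """Similarity = maximal aggregate PMI over licit alignments."""

    def __init__(self, model: ScoringModel):
        self.model = model
        self.inventory = model.inventory

    def single(self, x: str, y: str) -> float:
        return pmi_score(x, y, self.model)

    def matrix(self, batch_x, batch_y) -> np.ndarray:
        (wx, lx), (wy, ly) = batch_x, batch_y
        return _kernels.affine_score_matrix(wx, lx, wy, ly, self.model.pmi,
                                            self.model.gap_open,
                                            self.model.gap_extend)


class LDNScorer:
    """Similarity = 1 - normalized Levenshtein distance (training bootstrap)."""

    def __init__(self, inventory: SoundInventory = None):
        self.inventory = inventory if inventory is not None else asjp_inventory()

    def single(self, x: str, y: str) -> float:
        return 1.0 - ldn(x, y)

    def matrix(self, batch_x, batch_y) -> np.ndarray:
        (wx, lx), (wy, ly) = batch_x, batch_y
        return _kernels.ldn_similarity_matrix(wx, lx, wy, ly)


# ---------------------------------------------------------------------------
# per-pair profile


@dataclass
class PairProfile:
    """All word- and concept-level comparison statistics for one pair."""

    name_a: str
    name_b: str
    concepts_a: list          # defined concepts, in order
    concepts_b: list
    word_scores: np.ndarray   # (n_words_a, n_words_b) similarity matrix
    words_a: list             # (concept, word) in row order
    words_b: list
    concept_scores: np.ndarray  # (n_concepts_a, n_concepts_b) max-pooled
    null_sorted: np.ndarray   # sorted cross-concept scores
    shared: list              # shared concepts
    sims: dict                # concept -> synonymous similarity
    p: dict                   # concept -> calibrated p-value
    z: float
    d: float

    def p_of_score(self, score: float) -> float:
        """Calibrated p-value of an arbitrary word-pair score."""
        return calibrated_p_from_null(score, self.null_sorted)


def calibrated_p_from_null(score: float, null_sorted: np.ndarray) -> float:
    """p = (1 + #{null >= score}) / (1 + #null)."""
    n = len(null_sorted)
    if n == 0:
        raise ValueError("empty null sample")
    ge = n - np.searchsorted(null_sorted, score, side="left")
    return (1.0 + ge) / (1.0 + n)


def language_z(p_values) -> float:
    """Fisher-style combination: Z = (sum -log p - N) / sqrt(N)."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    if n == 0:
        raise ValueError("no shared concepts")
    return float((-np.log(p).sum() - n) / np.sqrt(n))


def language_distance_from_z(z: float, constants: ZConstants = None) -> float:
    if constants is None:
        constants = z_constants()
    return (constants.z_max - z) / (constants.z_max - constants.z_min)


def build_profile(doc_a: Doculect, doc_b: Doculect, scorer,
                  constants: ZConstants = None) -> PairProfile:
    """Compute the full comparison profile for one pair of word lists."""
    if constants is None:
        constants = z_constants()

    def batch(doc):
        concepts, words, starts = [], [], []
        for c in doc.concepts():
            starts.append(len(words))
            concepts.append(c)
            words.extend((c, w) for w in doc.entries[c])
        enc = [scorer.inventory.encode(w) for _, w in words]
        return concepts, words, np.array(starts, dtype=np.intp), _kernels.pad_words(enc)

    ca, wa, sa, ba = batch(doc_a)
    cb, wb, sb, bb = batch(doc_b)
    if not ca or not cb:
        raise ValueError(f"empty word list ({doc_a.name!r} or {doc_b.name!r})")
    W = scorer.matrix(ba, bb)
    # max-pool word scores into concept-pair scores
    rows = np.maximum.reduceat(W, sa, axis=0)
    M = np.maximum.reduceat(rows, sb, axis=1)

    ia = {c: i for i, c in enumerate(ca)}
    ib = {c: i for i, c in enumerate(cb)}
    shared = [c for c in ca if c in ib]
    same = np.zeros(M.shape, dtype=bool)
    for c in shared:
        same[ia[c], ib[c]] = True
    null = M[~same]
    if null.size < 2:
        raise ValueError("fewer than 2 cross-concept pairs for the null sample")
    null_sorted = np.sort(null)

    sims = {c: float(M[ia[c], ib[c]]) for c in shared}
    if shared:
        p = {c: calibrated_p_from_null(sims[c], null_sorted) for c in shared}
        z = language_z(p.values())
        d = language_distance_from_z(z, constants)
    else:
        p, z, d = {}, np.nan, np.nan
    return PairProfile(doc_a.name, doc_b.name, ca, cb, W, wa, wb, M,
                       null_sorted, shared, sims, p, z, d)


# ---------------------------------------------------------------------------
# spec-surface helpers (thin wrappers over the profile machinery)


def concept_similarity(doc_a: Doculect, doc_b: Doculect, concept: str,
                       scorer) -> float:
    """Maximal similarity between any pair of entries for ``concept``."""
    xs, ys = doc_a.entries.get(concept, []), doc_b.entries.get(concept, [])
    if not xs or not ys:
        raise KeyError(f"concept {concept!r} undefined for this pair")
    return max(scorer.single(x, y) for x in xs for y in ys)


def null_similarity_sample(doc_a: Doculect, doc_b: Doculect, scorer) -> list:
    """Max-over-synonym scores for every ordered cross-concept pair."""
    out = []
    for c1 in doc_a.concepts():
        for c2 in doc_b.concepts():
            if c1 == c2:
                continue
            out.append(max(scorer.single(x, y)
                           for x in doc_a.entries[c1]
                           for y in doc_b.entries[c2]))
    if len(out) < 2:
        raise ValueError("fewer than 2 cross-concept pairs")
    return out


def calibrated_p(doc_a: Doculect, doc_b: Doculect, concept: str,
                 scorer, null_sample=None) -> float:
    sim = concept_similarity(doc_a, doc_b, concept, scorer)
    if null_sample is None:
        null_sample = null_similarity_sample(doc_a, doc_b, scorer)
    return calibrated_p_from_null(sim, np.sort(np.asarray(null_sample, float)))


def language_distance(doc_a: Doculect, doc_b: Doculect, scorer,
                      constants: ZConstants = None) -> float:
    """Calibrated distance between two word lists (NaN if no shared concept)."""
    return build_profile(doc_a, doc_b, scorer, constants).d


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric doculect-by-doculect dissimilarities; NaN marks undefined."""

    taxa: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")

    def index(self, name: str) -> int:
        return self.taxa.index(name)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, taxa) -> "DistanceMatrix":
        idx = [self.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_csv(self, path):
        self.to_frame().to_csv(path)

    def to_nexus(self, path, labels=None):
        """Write a Nexus DISTANCES block (triangle=both)."""
        labels = labels if labels is not None else self.taxa
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN taxa;\n")
            fh.write(f"  DIMENSIONS ntax={len(labels)};\n  TAXLABELS\n")
            for t in labels:
                fh.write(f"    {t}\n")
            fh.write("  ;\nEND;\n\nBEGIN distances;\n")
            fh.write(f"  DIMENSIONS ntax={len(labels)};\n")
            fh.write("  FORMAT triangle=both diagonal labels missing=?;\n  MATRIX\n")
            for i, t in enumerate(labels):
                row = " ".join("?" if np.isnan(v) else f"{v:.6f}"
                               for v in self.values[i])
                fh.write(f"    {t} {row}\n")
            fh.write("  ;\nEND;\n")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy())


class LanguageDistanceCalculator:
    """Caches per-pair profiles for a collection under one scorer."""

    def __init__(self, collection: WordListCollection, scorer):
        self.collection = collection
        self.scorer = scorer
        self._profiles: dict = {}

    def profile(self, name_a: str, name_b: str) -> PairProfile:
        key = (name_a, name_b) if name_a <= name_b else (name_b, name_a)
        if key not in self._profiles:
            self._profiles[key] = build_profile(
                self.collection[key[0]], self.collection[key[1]], self.scorer)
        return self._profiles[key]

    def distance(self, name_a: str, name_b: str) -> float:
        return self.profile(name_a, name_b).d

    def distance_matrix(self) -> DistanceMatrix:
        names = self.collection.names
        n = len(names)
        if n < 2:
            raise ValueError("need at least 2 doculects")
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = self.distance(names[i], names[j])
                if np.isnan(d):
                    logger.warning("no shared concepts for %s / %s; "
                                   "distance undefined", names[i], names[j])
                vals[i, j] = vals[j, i] = d
        return DistanceMatrix(names, vals)


def distance_matrix(collection: WordListCollection, model_or_scorer
                    ) -> DistanceMatrix:
    """Full pairwise distance matrix for a collection.

    ``model_or_scorer`` may be a trained :class:`ScoringModel` or any scorer
    object (e.g. :class:`LDNScorer` for the training bootstrap).
    """
    scorer = (PMIScorer(model_or_scorer)
              if isinstance(model_or_scorer, ScoringModel) else model_or_scorer)
    return LanguageDistanceCalculator(collection, scorer).distance_matrix()
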