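"""Learning the PMI scoring model from a word-list collection.

The procedure bootstraps from surface similarity: language pairs whose
LDN-based distance is at most 0.7 are treated as *probably related*; for each
such pair and each shared concept, the synonym pair with the lowest LDN is a
*potential cognate*.  Initial PMI scores come from plain Levenshtein
alignments of the potential cognates; ten rounds of re-alignment with the
current scores (keeping only pairs whose aggregate PMI reaches the threshold
theta) refine them.  The gap penalties and theta are tuned by Nelder-Mead on
the mean distance between probably related languages under the final scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .alignment import GAP, ScoringModel, ldn, levenshtein_align
from .language_distance import (LDNScorer, LanguageDistanceCalculator,
                                PMIScorer)
from .sound_model import (SoundInventory, WordListCollection,
                          estimate_symbol_frequencies)

logger = logging.getLogger(__name__)

RELATED_THRESHOLD = 0.7
N_ITERATIONS = 10
SMOOTHING_K = 0.5


@dataclass
class PotentialCognate:
    pair: tuple       # (doculect_a, doculect_b), a < b
    concept: str
    word_x: str       # from doculect_a
    word_y: str       # from doculect_b


def probably_related_pairs(collection: WordListCollection,
                           threshold: float = RELATED_THRESHOLD,
                           calculator: LanguageDistanceCalculator = None
                           ) -> set:
    """Unordered doculect pairs with LDN-bootstrap distance <= threshold."""
    if len(collection) < 2:
        raise ValueError("need at least 2 doculects")
    if calculator is None:
        calculator = LanguageDistanceCalculator(collection, LDNScorer())
    names = collection.names
    out = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = calculator.distance(a, b)
            if not np.isnan(d) and d <= threshold:
                out.add((a, b) if a < b else (b, a))
    return out


def potential_cognate_pairs(collection: WordListCollection, related: set
                            ) -> list:
    """The lowest-LDN synonym pair per (related pair, shared concept).

    Ties are broken deterministically by synonym order (first listed wins).
    """
    out = []
    for a, b in sorted(related):
        da, db = collection[a], collection[b]
        for c in collection.concepts:
            xs, ys = da.entries.get(c, []), db.entries.get(c, [])
            if not xs or not ys:
                continue
            best = min(((ldn(x, y), i, j)
                        for i, x in enumerate(xs) for j, y in enumerate(ys)),
                       key=lambda t: (t[0], t[1], t[2]))
            out.append(PotentialCognate((a, b), c, xs[best[1]], ys[best[2]]))
    return out


def _pmi_from_counts(counts: np.ndarray, q: np.ndarray,
                     k: float = SMOOTHING_K, q_smoothing: float = SMOOTHING_K
                     ) -> np.ndarray:
    """PMI(a,b) = log[s(a,b)/(q(a)q(b))] with add-k smoothed counts.

    ``counts`` are symmetrized aligned-pair counts.  q is smoothed with the
    same additive constant so symbols absent from the data stay finite.
    """
    n = len(q)
    s = counts + k
    s = s / s.sum()
    qs = q + q_smoothing / n
    qs = qs / qs.sum()
    return np.log(s / np.outer(qs, qs))


def estimate_initial_pmi(potential_cognates: list, inventory: SoundInventory,
                         smoothing: float = SMOOTHING_K) -> np.ndarray:
    """PMI_0 from Levenshtein alignments of the potential cognates.

    Gap columns are excluded from the counts; counts for (a,b) and (b,a) are
    pooled (alignment is undirected).
    """
    if not potential_cognates:
        raise ValueError("no potential cognates")
    n = len(inventory.symbols)
    idx = inventory.index
    counts = np.zeros((n, n))
    for pc in potential_cognates:
        aln = levenshtein_align(pc.word_x, pc.word_y)
        for a, b in aln.columns():
            if a != GAP and b != GAP:
                counts[idx[a], idx[b]] += 1
                counts[idx[b], idx[a]] += 1
    return _pmi_from_counts(counts, inventory.q, smoothing)


def refine_pmi(collection: WordListCollection, potential_cognates: list,
               gap_open: float, gap_extend: float, theta: float,
               inventory: SoundInventory = None, n_iterations: int = N_ITERATIONS,
               smoothing: float = SMOOTHING_K, initial_pmi: np.ndarray = None
               ) -> ScoringModel:
    """Iterative re-estimation of PMI scores (10 rounds by default).

    Round i re-aligns every potential cognate pair with the PMI_{i-1} scores
    and the given gap penalties, keeps pairs whose aggregate PMI is at least
    theta, recounts aligned symbol pairs (gap columns excluded), and applies
    the PMI formula.
    """
    if inventory is None:
        inventory = estimate_symbol_frequencies(collection)
    if initial_pmi is None:
        initial_pmi = estimate_initial_pmi(potential_cognates, inventory,
                                           smoothing)
    n = len(inventory.symbols)
    encoded = [(inventory.encode(pc.word_x), inventory.encode(pc.word_y))
               for pc in potential_cognates]
    buf = np.empty((2 * max(max(len(x), len(y)) for x, y in encoded), 2),
                   dtype=np.int32)
    pmi = initial_pmi
    for it in range(1, n_iterations + 1):
        counts = np.zeros((n, n))
        kept = 0
        for cx, cy in encoded:
            ncols, score = _kernels.affine_align_pairs(
                cx, cy, pmi, gap_open, gap_extend, buf)
            if score < theta:
                continue
            kept += 1
            for k in range(ncols):
                i, j = buf[k, 0], buf[k, 1]
                if i >= 0 and j >= 0:
                    counts[cx[i], cy[j]] += 1
                    counts[cy[j], cx[i]] += 1
        if kept == 0:
            raise RuntimeError(
                f"no potential cognate pair reached theta={theta} in round "
                f"{it}; theta is too high for these data")
        pmi = _pmi_from_counts(counts, inventory.q, smoothing)
    return ScoringModel(inventory, pmi, gap_open, gap_extend, theta)


@dataclass
class OptimizationResult:
    model: ScoringModel
    params: tuple              # (gap_open, gap_extend, theta)
    f_value: float
    trace: list = field(default_factory=list)  # [(params, f), ...]
    converged: bool = True


def _mean_related_distance(collection, model, related) -> float:
    calc = LanguageDistanceCalculator(collection, PMIScorer(model))
    ds = [calc.distance(a, b) for a, b in related]
    ds = [d for d in ds if not np.isnan(d)]
    return float(np.mean(ds))


def optimize_hyperparameters(collection: WordListCollection,
                             init=(-2.5, -1.75, 4.5),
                             inventory: SoundInventory = None,
                             n_iterations: int = N_ITERATIONS,
                             smoothing: float = SMOOTHING_K,
                             max_evaluations: int = 200,
                             f_tolerance: float = 1e-3,
                             related: set = None) -> OptimizationResult:
    """Nelder-Mead search over (gap_open, gap_extend, theta).

    The objective f is the mean calibrated distance between all probably
    related language pairs under the PMI scores refined with the candidate
    hyperparameters.  The probably-related screen and the potential-cognate
    list are computed once from the LDN bootstrap and frozen during the
    search.  Deterministic given the initial point.
    """
    if inventory is None:
        inventory = estimate_symbol_frequencies(collection)
    if related is None:
        related = probably_related_pairs(collection)
    if not related:
        raise ValueError("no probably related pairs; nothing to optimize")
    cognates = potential_cognate_pairs(collection, related)
    initial_pmi = estimate_initial_pmi(cognates, inventory, smoothing)
    trace = []

    def f(params):
        gp1, gp2, theta = params
        try:
            model = refine_pmi(collection, cognates, gp1, gp2, theta,
                               inventory=inventory, n_iterations=n_iterations,
                               smoothing=smoothing, initial_pmi=initial_pmi)
            val = _mean_related_distance(collection, model, related)
        except RuntimeError:
            val = 2.0  # theta filtered out every pair; off the d in [0,1] scale
        trace.append((tuple(params), val))
        return val

    res = minimize(f, np.asarray(init, float), method="Nelder-Mead",
                   options={"maxfev": max_evaluations, "fatol": f_tolerance,
                            "xatol": 1e-2})
    if not res.success:
        logger.warning("Nelder-Mead did not converge within %d evaluations; "
                       "returning best point found", max_evaluations)
    gp1, gp2, theta = res.x
    model = refine_pmi(collection, cognates, gp1, gp2, theta,
                       inventory=inventory, n_iterations=n_iterations,
                       smoothing=smoothing, initial_pmi=initial_pmi)
    return OptimizationResult(model, tuple(res.x), float(res.fun), trace,
                              bool(res.success))


def train_model(collection: WordListCollection, optimize: bool = False,
                gap_open: float = None, gap_extend: float = None,
                theta: float = None, **kwargs) -> ScoringModel:
    """End-to-end training convenience: bootstrap, refine, optionally tune.

    Without ``optimize=True`` the shipped reference gap penalties and theta
    are used (or any explicitly supplied values).
    """
    from .alignment import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, DEFAULT_THETA
    inventory = estimate_symbol_frequencies(collection)
    if optimize:
        return optimize_hyperparameters(collection, inventory=inventory,
                                        **kwargs).model
    related = probably_related_pairs(collection)
    if not related:
        raise ValueError("no probably related pairs in the collection")
    cognates = potential_cognate_pairs(collection, related)
    return refine_pmi(collection, cognates,
                      gap_open if gap_open is not None else DEFAULT_GAP_OPEN,
                      gap_extend if gap_extend is not None else DEFAULT_GAP_EXTEND,
                      theta if theta is not None else DEFAULT_THETA,
                      inventory=inventory, **kwargs)
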