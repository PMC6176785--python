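"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

from lexiphylo.alignment import ScoringModel
from lexiphylo.sound_model import (CONCEPTS_40, Doculect, WordListCollection,
                                   asjp_inventory)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inventory():
    return asjp_inventory()


def make_model(inventory, diag=2.0, off=-1.0, gap_open=-2.5, gap_extend=-1.0,
               theta=0.0, pmi=None):
    """A simple diagonal-dominant scoring model for tests."""
    if pmi is None:
        n = len(inventory.symbols)
        pmi = np.full((n, n), float(off))
        np.fill_diagonal(pmi, float(diag))
    return ScoringModel(inventory, pmi, gap_open, gap_extend, theta)


@pytest.fixture
def diag_model(inventory):
    return make_model(inventory)


def make_collection(entries_by_doculect, family="FAM", genus="GEN",
                    coords=None, concepts=CONCEPTS_40):
    """Build a collection from {name: {concept: [words]}} (words normalized)."""
    docs = []
    for i, (name, entries) in enumerate(entries_by_doculect.items()):
        full = {c: [] for c in concepts}
        for c, ws in entries.items():
            full[c] = list(ws)
        lat, lon = coords[name] if coords else (float(i), float(i))
        fam = family[name] if isinstance(family, dict) else family
        docs.append(Doculect(name, fam, genus, lat, lon, full))
    return WordListCollection(docs, concepts)


# ---------------------------------------------------------------------------
# independent brute-force oracle for licit affine-gap alignment


@lru_cache(maxsize=None)
def licit_structures(lx: int, ly: int) -> tuple:
    """Every licit alignment structure for sequence lengths (lx, ly).

    Moves: 'M' consumes both sequences, 'X' consumes x against a gap,
    'Y' consumes y against a gap.  Licit: 'Y' never directly follows 'X'
    and vice versa.
    """
    results = []

    def rec(i, j, last, acc):
        if i == lx and j == ly:
            results.append(tuple(acc))
            return
        if i < lx and j < ly:
            rec(i + 1, j + 1, "M", acc + ["M"])
        if i < lx and last != "Y":
            rec(i + 1, j, "X", acc + ["X"])
        if j < ly and last != "X":
            rec(i, j + 1, "Y", acc + ["Y"])

    rec(0, 0, "", [])
    return tuple(results)


def score_structure(moves, x, y, score_fn, gap_open, gap_extend) -> float:
    """Aggregate score of one alignment structure with run-aware gaps."""
    total = 0.0
    i = j = 0
    last = ""
    for mv in moves:
        if mv == "M":
            total += score_fn(x[i], y[j])
            i += 1
            j += 1
        else:
            total += gap_extend if mv == last else gap_open
            if mv == "X":
                i += 1
            else:
                j += 1
        last = mv
    return total


def brute_force_score(x, y, score_fn, gap_open, gap_extend) -> float:
    """Maximum aggregate score over exhaustively enumerated licit alignments."""
    return max(score_structure(mv, x, y, score_fn, gap_open, gap_extend)
               for mv in licit_structures(len(x), len(y)))


def brute_force_pmi(x: str, y: str, model: ScoringModel) -> float:
    idx = model.inventory.index

    def score_fn(a, b):
        return model.pmi[idx[a], idx[b]]

    return brute_force_score(x, y, score_fn, model.gap_open, model.gap_extend)
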