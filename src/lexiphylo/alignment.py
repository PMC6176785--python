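"""String comparison: normalized Levenshtein distance and PMI alignment.

The scoring model is a symmetric 41x41 table of pointwise-mutual-information
scores PMI(a,b) = log[s(a,b) / (q(a) q(b))] in log-odds units, together with
affine gap penalties (open, extend) and a cognacy threshold theta used during
training.  Alignment maximizes the aggregate PMI over *licit* alignments —
global alignments in which a gap in one string is never immediately followed
by a gap in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .sound_model import SoundInventory, asjp_inventory

GAP = "-"

#: Reference hyperparameters reported for the full ASJP database
#: (gap open, gap extend, theta); shipped as documented defaults.
DEFAULT_GAP_OPEN = -2.33
DEFAULT_GAP_EXTEND = -1.276
DEFAULT_THETA = 4.401


@dataclass
class ScoringModel:
    """PMI substitution scores plus gap penalties and cognacy threshold."""

    inventory: SoundInventory
    pmi: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    theta: float = DEFAULT_THETA

    def __post_init__(self):
        n = len(self.inventory.symbols)
        self.pmi = np.asarray(self.pmi, dtype=float)
        if self.pmi.shape != (n, n):
            raise ValueError(f"pmi table must be {n}x{n}")
        if not np.allclose(self.pmi, self.pmi.T, atol=1e-9):
            raise ValueError("pmi table must be symmetric")

    def encode(self, word: str) -> np.ndarray:
        return self.inventory.encode(word)

    def save(self, directory):
        """Write the score table as CSV plus a key=value sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.pmi, index=list(self.inventory.symbols),
                     columns=list(self.inventory.symbols)).to_csv(
            directory / "pmi_scores.csv")
        with open(directory / "gap_penalties.csv", "w") as fh:
            fh.write(f"gap_open={self.gap_open}\n")
            fh.write(f"gap_extend={self.gap_extend}\n")
            fh.write(f"theta={self.theta}\n")

    @classmethod
    def load(cls, directory, inventory: SoundInventory = None) -> "ScoringModel":
        directory = Path(directory)
        if inventory is None:
            inventory = asjp_inventory()
        df = pd.read_csv(directory / "pmi_scores.csv", index_col=0)
        if tuple(df.index) != inventory.symbols:
            raise ValueError("score table symbols do not match the inventory")
        params = {}
        with open(directory / "gap_penalties.csv") as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.strip().split("=", 1)
                    params[k] = float(v)
        return cls(inventory, df.to_numpy(), params["gap_open"],
                   params["gap_extend"], params["theta"])


@dataclass
class PairwiseAlignment:
    """A gapped alignment of two words and its aggregate score."""

    aligned_x: str
    aligned_y: str
    score: float

    def columns(self):
        return list(zip(self.aligned_x, self.aligned_y))


def ldn(x: str, y: str) -> float:
    """Levenshtein distance normalized by the longer string's length."""
    if not x or not y:
        raise ValueError("empty sequence")
    if x == y:
        return 0.0
    return levenshtein(x, y) / max(len(x), len(y))


def levenshtein(x: str, y: str) -> int:
    """Unit-cost edit distance (compiled)."""
    cx = np.fromiter(map(ord, x), dtype=np.int32, count=len(x))
    cy = np.fromiter(map(ord, y), dtype=np.int32, count=len(y))
    return int(_kernels.edit_distance(cx, cy))


def levenshtein_align(x: str, y: str) -> PairwiseAlignment:
    """One optimal unit-cost alignment with deterministic traceback.

    Tie preference: substitution > deletion (gap in y) > insertion.
    """
    m, n = len(x), len(y)
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = min(D[i - 1, j - 1] + (x[i - 1] != y[j - 1]),
                          D[i - 1, j] + 1, D[i, j - 1] + 1)
    ax, ay = [], []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (x[i - 1] != y[j - 1]):
            ax.append(x[i - 1]); ay.append(y[j - 1]); i -= 1; j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            ax.append(x[i - 1]); ay.append(GAP); i -= 1
        else:
            ax.append(GAP); ay.append(y[j - 1]); j -= 1
    return PairwiseAlignment("".join(reversed(ax)), "".join(reversed(ay)),
                             -float(D[m, n]))


def pmi_score(x: str, y: str, model: ScoringModel) -> float:
    """Maximal aggregate PMI over all licit alignments (score only)."""
    if not x or not y:
        raise ValueError("empty sequence")
    return float(_kernels.affine_score(model.encode(x), model.encode(y),
                                       model.pmi, model.gap_open,
                                       model.gap_extend))


def pmi_align(x: str, y: str, model: ScoringModel) -> PairwiseAlignment:
    """Maximal-PMI licit alignment with deterministic traceback.

    Tie preference in traceback: match > gap-in-x > gap-in-y; ties do not
    affect the score.
    """
    if not x or not y:
        raise ValueError("empty sequence")
    cx, cy = model.encode(x), model.encode(y)
    out = np.empty((len(x) + len(y), 2), dtype=np.int32)
    ncols, score = _kernels.affine_align_pairs(cx, cy, model.pmi,
                                               model.gap_open,
                                               model.gap_extend, out)
    ax = "".join(x[i] if i >= 0 else GAP for i in out[:ncols, 0])
    ay = "".join(y[j] if j >= 0 else GAP for j in out[:ncols, 1])
    return PairwiseAlignment(ax, ay, float(score))
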