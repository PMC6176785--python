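"""Binary character extraction and phylogenetics-ready export.

Two character systems are extracted from a clustered word-list collection:

* **cognate-class characters** — one column per inferred cognate class; a
  taxon scores 1 if its word list contains a member of the class, 0 if the
  concept is attested but no member is present, and *undefined* if the
  concept is missing from its list;
* **soundclass-concept characters** — one column per (concept, symbol) pair;
  1 if any word for the concept contains the symbol (presence, not count).

Only *variable* characters (both states attested among defined values) are
kept for inference.  Export writes relaxed Phylip plus a two-block binary
partition file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sound_model import WordListCollection

MISSING = "?"


@dataclass
class CharacterMatrix:
    """Taxa-by-characters binary matrix with an explicit undefined state.

    Values are stored as floats: 0.0, 1.0, or NaN for undefined.
    """

    df: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.df.index)

    @property
    def characters(self) -> list:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __eq__(self, other):
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.df.equals(other.df)


def _concept_of_class(label: str) -> str:
    return label.rsplit("_", 1)[0]


def cognate_characters(assignment: pd.DataFrame,
                       collection: WordListCollection) -> CharacterMatrix:
    """One binary character per inferred cognate class.

    ``assignment`` needs columns doculect, concept, transcription,
    cognate_class (labels follow the concept_serial convention).
    """
    classes = sorted(assignment["cognate_class"].unique())
    members: dict = {cl: set() for cl in classes}
    for row in assignment.itertuples(index=False):
        members[row.cognate_class].add(row.doculect)
    taxa = collection.names
    data = np.full((len(taxa), len(classes)), np.nan)
    for j, cl in enumerate(classes):
        concept = _concept_of_class(cl)
        for i, name in enumerate(taxa):
            if collection[name].entries.get(concept):
                data[i, j] = 1.0 if name in members[cl] else 0.0
    return CharacterMatrix(pd.DataFrame(data, index=taxa, columns=classes))


def soundclass_concept_characters(collection: WordListCollection
                                  ) -> CharacterMatrix:
    """One binary character per (concept, symbol) pair with any support."""
    taxa = collection.names
    symbol_sets: dict = {}  # (name, concept) -> set of symbols
    labels = set()
    for d in collection:
        for c, words in d.entries.items():
            if words:
                syms = set().union(*map(set, words))
                symbol_sets[(d.name, c)] = syms
                labels.update(f"{c}:{s}" for s in syms)
    labels = sorted(labels)
    data = np.full((len(taxa), len(labels)), np.nan)
    for j, label in enumerate(labels):
        concept, sym = label.rsplit(":", 1)
        for i, name in enumerate(taxa):
            if collection[name].entries.get(concept):
                data[i, j] = 1.0 if sym in symbol_sets[(name, concept)] else 0.0
    return CharacterMatrix(pd.DataFrame(data, index=taxa, columns=labels))


def filter_variable(matrix: CharacterMatrix, taxa=None) -> CharacterMatrix:
    """Keep characters showing both states among the (sub)sample's defined
    values; column order is preserved."""
    df = matrix.df if taxa is None else matrix.df.loc[list(taxa)]
    has_one = (df == 1.0).any(axis=0)
    has_zero = (df == 0.0).any(axis=0)
    keep = has_one & has_zero
    if not keep.any():
        raise ValueError("no variable characters in the sample")
    return CharacterMatrix(df.loc[:, keep])


def drop_all_undefined(matrix: CharacterMatrix) -> CharacterMatrix:
    keep = matrix.df.notna().any(axis=0)
    return CharacterMatrix(matrix.df.loc[:, keep])


def write_phylip(matrix: CharacterMatrix, path, missing: str = MISSING):
    """Relaxed Phylip: taxon name, whitespace, 0/1/? string."""
    df = matrix.df
    width = max((len(str(t)) for t in df.index), default=1) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(df.index)} {len(df.columns)}\n")
        for taxon, row in df.iterrows():
            states = "".join(missing if np.isnan(v) else str(int(v))
                             for v in row.to_numpy())
            fh.write(f"{str(taxon):<{width}}{states}\n")


def read_phylip(path, missing: str = MISSING) -> CharacterMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        ntax, nchar = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, states = line.split(None, 1)
            states = states.strip()
            if len(states) != nchar:
                raise ValueError(f"row {name}: expected {nchar} states")
            taxa.append(name)
            rows.append([np.nan if c == missing else float(c) for c in states])
    if len(taxa) != ntax:
        raise ValueError("taxon count does not match header")
    return CharacterMatrix(pd.DataFrame(rows, index=taxa,
                                        columns=range(nchar)))


def export_character_files(cc: CharacterMatrix, sc: CharacterMatrix,
                           out_prefix, missing: str = MISSING) -> dict:
    """Write per-system and combined Phylip files plus the partition file.

    The combined matrix is the cognate-class columns followed by the
    soundclass-concept columns; the partition file delimits the two blocks
    by 1-based column ranges in the two-block binary-model dialect.
    Columns with no defined value are dropped before writing.
    """
    if list(cc.taxa) != list(sc.taxa):
        raise ValueError("character matrices must share the same taxa")
    cc, sc = drop_all_undefined(cc), drop_all_undefined(sc)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "cc": Path(f"{prefix}.cc.phy"),
        "sc": Path(f"{prefix}.sc.phy"),
        "cc_sc": Path(f"{prefix}.cc_sc.phy"),
        "part": Path(f"{prefix}.part.txt"),
        "cc_csv": Path(f"{prefix}.cc.csv"),
        "sc_csv": Path(f"{prefix}.sc.csv"),
    }
    write_phylip(cc, paths["cc"], missing)
    write_phylip(sc, paths["sc"], missing)
    combined = CharacterMatrix(pd.concat([cc.df, sc.df], axis=1))
    write_phylip(combined, paths["cc_sc"], missing)
    n_cc, n_sc = len(cc.characters), len(sc.characters)
    with open(paths["part"], "w") as fh:
        fh.write(f"BIN, cognate_classes = 1-{n_cc}\n")
        fh.write(f"BIN, soundclass_concepts = {n_cc + 1}-{n_cc + n_sc}\n")
    cc.df.to_csv(paths["cc_csv"])
    sc.df.to_csv(paths["sc_csv"])
    return paths
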