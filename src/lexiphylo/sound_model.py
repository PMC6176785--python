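"""Sound-class inventory, transcription normalization, and word-list I/O.

Transcriptions are strings over a coarse alphabet of 41 sound classes (the
ASJPcode conventions: 7 vowel classes and 34 consonant classes, each written
as a single ASCII character).  Raw entries may additionally carry diacritics:
post-posed modifier characters (glottalization, nasalization), juxtaposition
markers that fuse the preceding two or three symbols into a single segment,
and aspirated-plosive digraphs.  Normalization strips all of these, so that
every word becomes a plain sequence over the 41 classes.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 40 core concepts used throughout (ASJP 40-item list).
CONCEPTS_40 = (
    "I", "you", "we", "one", "two", "person", "fish", "dog", "louse", "tree",
    "leaf", "skin", "blood", "bone", "horn", "ear", "eye", "nose", "tooth",
    "tongue", "knee", "hand", "breast", "liver", "drink", "see", "hear", "die",
    "come", "sun", "star", "water", "stone", "fire", "path", "mountain",
    "night", "full", "new", "name",
)

WORDLIST_COLUMNS = (
    "doculect", "family", "genus", "latitude", "longitude",
    "concept", "transcription",
)


class NormalizationError(ValueError):
    """Raised when a transcription contains a symbol outside the inventory."""


@dataclass(frozen=True)
class SoundInventory:
    """The sound-class alphabet plus diacritic conventions and frequencies.

    Attributes
    ----------
    symbols : tuple of str
        The 41 single-character sound-class codes, in canonical order.
    delete : frozenset of str
        Modifier characters removed outright.
    combine : dict
        Juxtaposition marker -> number of preceding symbols it fuses
        (the fused segment is represented by its first symbol).
    digraphs : dict
        Two-character sequences reduced to their first symbol (aspiration).
    q : numpy.ndarray
        Occurrence probability per symbol (sums to 1 when estimated;
        all-zero in an untrained inventory).
    """

    symbols: tuple
    delete: frozenset
    combine: dict
    digraphs: dict
    q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.q is None:
            object.__setattr__(self, "q", np.zeros(len(self.symbols)))
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate sound-class symbols")

    @property
    def index(self) -> dict:
        return {s: i for i, s in enumerate(self.symbols)}

    def with_frequencies(self, q: np.ndarray) -> "SoundInventory":
        q = np.asarray(q, dtype=float)
        if q.shape != (len(self.symbols),):
            raise ValueError("q must have one entry per symbol")
        if (q < 0).any():
            raise ValueError("negative occurrence probability")
        return SoundInventory(self.symbols, self.delete, self.combine,
                              self.digraphs, q)

    def encode(self, word: str) -> np.ndarray:
        """Map a normalized word to symbol indices (int32)."""
        idx = self.index
        try:
            return np.fromiter((idx[ch] for ch in word), dtype=np.int32,
                               count=len(word))
        except KeyError as exc:  # pragma: no cover - guarded by normalize
            raise NormalizationError(f"unknown symbol {exc.args[0]!r}") from None


def load_inventory(path=None) -> SoundInventory:
    """Load the inventory/diacritic table from a plain-text config file.

    Without a path, the packaged ASJPcode table is used.
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=None,
                                   interpolation=None)
    if path is None:
        text = (resources.files("lexiphylo") / "data" / "asjp_inventory.cfg").read_text()
    else:
        text = Path(path).read_text()
    cp.read_string(text)
    symbols = tuple(cp["symbols"]["classes"].strip())
    if len(symbols) != 41:
        raise ValueError(f"expected 41 sound classes, got {len(symbols)}")
    dia = cp["diacritics"]
    delete = frozenset(dia.get("delete", "").strip())
    combine = {}
    if dia.get("combine2", "").strip():
        combine[dia["combine2"].strip()] = 2
    if dia.get("combine3", "").strip():
        combine[dia["combine3"].strip()] = 3
    digraphs = {}
    for dg in dia.get("digraphs", "").split():
        if len(dg) != 2:
            raise ValueError(f"digraph entries must be 2 characters: {dg!r}")
        digraphs[dg] = dg[0]
    overlap = delete & set(symbols)
    if overlap:
        raise ValueError(f"deletable diacritics shadow symbols: {overlap}")
    return SoundInventory(symbols, delete, combine, digraphs)


_DEFAULT_INVENTORY = None


def asjp_inventory() -> SoundInventory:
    """The packaged 41-class ASJPcode inventory (cached)."""
    global _DEFAULT_INVENTORY
    if _DEFAULT_INVENTORY is None:
        _DEFAULT_INVENTORY = load_inventory()
    return _DEFAULT_INVENTORY


def normalize_transcription(raw: str, inventory: SoundInventory = None) -> str:
    """Strip diacritics and reduce a raw transcription to sound classes.

    Precedence: whitespace and deletable modifiers are removed first; then
    juxtaposition markers fuse the preceding segment (keeping its first
    symbol); finally digraph reductions are applied left-to-right, repeatedly
    until stable.  The result contains only inventory symbols.

    Raises
    ------
    NormalizationError
        If a character outside the inventory survives stripping; the
        offending character is reported.
    ValueError
        If ``raw`` is empty or normalizes to the empty string.
    """
    if inventory is None:
        inventory = asjp_inventory()
    if not raw:
        raise ValueError("empty transcription")
    chars = [c for c in raw if not c.isspace() and c not in inventory.delete]
    out: list = []
    for c in chars:
        if c in inventory.combine:
            k = inventory.combine[c]
            if len(out) < k:
                raise NormalizationError(
                    f"juxtaposition marker {c!r} without {k} preceding symbols "
                    f"in {raw!r}")
            head = out[-k]
            del out[-k:]
            out.append(head)
        else:
            out.append(c)
    word = "".join(out)
    # digraph reduction to fixpoint (a reduction can create a new digraph)
    changed = True
    while changed:
        changed = False
        i, buf = 0, []
        while i < len(word):
            pair = word[i:i + 2]
            if pair in inventory.digraphs:
                buf.append(inventory.digraphs[pair])
                i += 2
                changed = True
            else:
                buf.append(word[i])
                i += 1
        word = "".join(buf)
    symbol_set = set(inventory.symbols)
    for c in word:
        if c not in symbol_set:
            raise NormalizationError(
                f"unknown symbol {c!r} in transcription {raw!r}")
    if not word:
        raise ValueError(f"transcription {raw!r} normalizes to empty string")
    return word


@dataclass
class Doculect:
    """One documented language variety with its 40-item word list."""

    name: str
    family: str
    genus: str
    latitude: float
    longitude: float
    entries: dict  # concept -> list of normalized transcriptions

    @property
    def taxon_label(self) -> str:
        """FAMILY.GENUS.DOCULECT naming convention, upper case."""
        return f"{self.family}.{self.genus}.{self.name}".upper()

    def concepts(self) -> list:
        """Concepts with at least one entry."""
        return [c for c, ws in self.entries.items() if ws]


@dataclass
class WordListCollection:
    """A set of doculects sharing a fixed concept inventory."""

    doculects: list
    concepts: tuple = CONCEPTS_40

    def __post_init__(self):
        names = [d.name for d in self.doculects]
        if len(set(names)) != len(names):
            raise ValueError("duplicate doculect names")
        cset = set(self.concepts)
        for d in self.doculects:
            extra = set(d.entries) - cset
            if extra:
                raise ValueError(
                    f"doculect {d.name}: concepts outside the inventory: {extra}")

    def __len__(self):
        return len(self.doculects)

    def __iter__(self):
        return iter(self.doculects)

    def __getitem__(self, name: str) -> Doculect:
        for d in self.doculects:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [d.name for d in self.doculects]

    def families(self) -> dict:
        """Mapping family -> list of doculect names."""
        out: dict = {}
        for d in self.doculects:
            out.setdefault(d.family, []).append(d.name)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.doculects:
            for c, words in d.entries.items():
                for w in words:
                    rows.append((d.name, d.family, d.genus, d.latitude,
                                 d.longitude, c, w))
        return pd.DataFrame(rows, columns=list(WORDLIST_COLUMNS))

    def write(self, path, sep="\t"):
        self.to_frame().to_csv(path, sep=sep, index=False)


def parse_wordlists(path, inventory: SoundInventory = None,
                    concepts=CONCEPTS_40) -> WordListCollection:
    """Read a delimited word-list file (TSV default, CSV accepted).

    One synonym per row; header columns doculect, family, genus, latitude,
    longitude, concept, transcription.  Transcriptions are normalized on
    input; empty transcriptions mark the concept as missing; rows with a
    malformed coordinate are rejected with a logged warning.
    """
    if inventory is None:
        inventory = asjp_inventory()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = set(WORDLIST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")

    doculects: dict = {}
    order: list = []
    for row in df.itertuples(index=False):
        name = row.doculect
        try:
            lat, lon = float(row.latitude), float(row.longitude)
        except ValueError:
            logger.warning("row for %s/%s rejected: malformed coordinate %r/%r",
                           name, row.concept, row.latitude, row.longitude)
            continue
        if name not in doculects:
            doculects[name] = Doculect(name, row.family, row.genus, lat, lon,
                                       {c: [] for c in concepts})
            order.append(name)
        if row.concept not in doculects[name].entries:
            raise ValueError(f"unknown concept {row.concept!r} for {name}")
        if row.transcription.strip():
            word = normalize_transcription(row.transcription.strip(), inventory)
            doculects[name].entries[row.concept].append(word)
    return WordListCollection([doculects[n] for n in order], tuple(concepts))


def estimate_symbol_frequencies(collection: WordListCollection,
                                inventory: SoundInventory = None
                                ) -> SoundInventory:
    """Estimate q(a) as relative token frequencies over all entries.

    Symbols never observed get probability 0 (smoothing, where needed, is
    applied downstream in PMI estimation).
    """
    if inventory is None:
        inventory = asjp_inventory()
    if len(collection) == 0:
        raise ValueError("empty collection")
    counts = np.zeros(len(inventory.symbols))
    idx = inventory.index
    for d in collection:
        for words in d.entries.values():
            for w in words:
                for ch in w:
                    counts[idx[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("collection contains no transcriptions")
    return inventory.with_frequencies(counts / total)
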