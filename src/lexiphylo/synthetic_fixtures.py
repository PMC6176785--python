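"""Tree-structured synthetic word-list collections with known ground truth.

A Yule tree is simulated; root words are drawn over the 41-class alphabet;
along each branch, words undergo symbol substitutions (governed by a
ground-truth propensity matrix over sound classes), insertions/deletions,
and concept-level lexical replacements that open a new cognate class.
Optionally an extra burst of change is injected at every split
(punctuational mode).  The generator emits the true tree, the word lists
(in the standard dialect) and the true cognate-class table, so that every
stage of the pipeline can be tested without external data.

What this emulates: related languages share recognizable cognates whose
sound changes are correlated through the propensity matrix, lists may hold
synonyms, and geographic coordinates diffuse along the tree.  What it does
not emulate: realistic phonotactics, borrowing/contact, and documentation
bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .sound_model import (CONCEPTS_40, Doculect, SoundInventory,
                          WordListCollection, asjp_inventory,
                          normalize_transcription)

#: Coarse articulatory groups used to structure the default substitution
#: propensities (sounds substitute preferentially within their group).
SOUND_GROUPS = (
    "ieE3auo",      # vowels
    "pbfvmw",       # labials
    "tdszcnrl8",    # dentals/alveolars
    "SZCjT5y",      # palatals
    "kgxNq",        # velars
    "XG7h!L4",      # uvular/laryngeal/clicks
)

WITHIN_GROUP_WEIGHT = 8.0
CROSS_GROUP_WEIGHT = 1.0


def default_propensity_matrix(inventory: SoundInventory = None) -> np.ndarray:
    """Row-stochastic substitution propensities structured by sound group."""
    if inventory is None:
        inventory = asjp_inventory()
    group_of = {}
    for g, syms in enumerate(SOUND_GROUPS):
        for s in syms:
            group_of[s] = g
    n = len(inventory.symbols)
    P = np.full((n, n), CROSS_GROUP_WEIGHT)
    for i, a in enumerate(inventory.symbols):
        for j, b in enumerate(inventory.symbols):
            if group_of[a] == group_of[b]:
                P[i, j] = WITHIN_GROUP_WEIGHT
        P[i, i] = 0.0  # a substitution always changes the symbol
    return P / P.sum(axis=1, keepdims=True)


def root_symbol_weights(inventory: SoundInventory = None) -> np.ndarray:
    """Mildly skewed occurrence weights for drawing root words."""
    if inventory is None:
        inventory = asjp_inventory()
    n = len(inventory.symbols)
    w = 1.0 / (np.arange(n) + 3.0)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Rates are per unit time along the tree (total root-to-tip depth is
    ``tree_depth``): ``substitution_rate`` per symbol, ``indel_rate`` and
    ``replacement_rate`` per word/concept.  ``burst_size`` adds that much
    extra effective branch length at the start of every branch
    (punctuational mode).  ``synonym_rate`` is the probability that a leaf
    keeps an extra mutated variant of a word as a synonym.
    """

    n_languages: int = 30
    n_concepts: int = 40
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    substitution_rate: float = 0.35
    indel_rate: float = 0.08
    replacement_rate: float = 0.25
    burst_size: float = 0.0
    synonym_rate: float = 0.0
    mean_word_length: float = 4.0
    coord_sigma: float = 15.0  # degrees of Brownian drift per sqrt(unit time)
    family: str = "SIM"
    propensity: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        for name in ("birth_rate", "tree_depth", "substitution_rate",
                     "indel_rate", "replacement_rate", "burst_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_concepts > len(CONCEPTS_40):
            raise ValueError(f"at most {len(CONCEPTS_40)} concepts supported")

    @property
    def concepts(self) -> tuple:
        return CONCEPTS_40[:self.n_concepts]


def simulate_tree(config: SimulationConfig, rng=None) -> dendropy.Tree:
    """Rooted binary ultrametric Yule tree with ``n_languages`` leaves."""
    if config.n_languages < 2:
        raise ValueError("need at least 2 languages")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    t = 0.0
    active = []  # (node, birth_time)
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < config.n_languages:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_final = t + rng.exponential(1.0 / (config.birth_rate * len(active)))
    width = len(str(config.n_languages))
    for node, born in active:
        node.edge.length = t_final - born
    # deterministic leaf naming in preorder
    idx = 1
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = ns.require_taxon(f"L{idx:0{width}d}")
            idx += 1
    if t_final > 0:
        scale = config.tree_depth / t_final
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
    tree.is_rooted = True
    return tree


def _draw_word(rng, inventory, weights, mean_length) -> str:
    length = 2 + rng.poisson(max(mean_length - 2.0, 0.0))
    syms = rng.choice(len(inventory.symbols), size=length, p=weights)
    return "".join(inventory.symbols[i] for i in syms)


def _mutate(word: str, t: float, config, inventory, weights, rng) -> str:
    """Apply substitutions and indels along a branch of effective length t."""
    P = config.propensity
    chars = list(word)
    n_sub = rng.poisson(config.substitution_rate * t * len(chars))
    idx = inventory.index
    for _ in range(n_sub):
        pos = int(rng.integers(len(chars)))
        row = P[idx[chars[pos]]]
        chars[pos] = inventory.symbols[rng.choice(len(row), p=row)]
    n_indel = rng.poisson(config.indel_rate * t)
    for _ in range(n_indel):
        if rng.random() < 0.5 or len(chars) == 1:
            pos = int(rng.integers(len(chars) + 1))
            sym = inventory.symbols[rng.choice(len(weights), p=weights)]
            chars.insert(pos, sym)
        else:
            del chars[int(rng.integers(len(chars)))]
    return "".join(chars)


@dataclass
class SimulationOutput:
    tree: dendropy.Tree
    collection: WordListCollection
    truth: pd.DataFrame  # doculect, concept, transcription, cognate_class
    config: SimulationConfig
    replacement_events: int = 0

    def truth_partition(self) -> dict:
        """(doculect, concept, transcription) -> true cognate class."""
        return {(r.doculect, r.concept, r.transcription): r.cognate_class
                for r in self.truth.itertuples(index=False)}


def evolve_wordlists(tree: dendropy.Tree, config: SimulationConfig,
                     inventory: SoundInventory = None, rng=None
                     ) -> SimulationOutput:
    """Evolve word lists down a rooted tree; emit collection plus truth."""
    if inventory is None:
        inventory = asjp_inventory()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.propensity is None:
        config = replace(config, propensity=default_propensity_matrix(inventory))
    weights = root_symbol_weights(inventory)
    concepts = config.concepts
    class_counter = {c: 1 for c in concepts}
    root_state = {c: (_draw_word(rng, inventory, weights,
                                 config.mean_word_length), 1)
                  for c in concepts}
    root = tree.seed_node
    states = {id(root): root_state}
    coords = {id(root): (0.0, 0.0)}
    replacement_events = 0
    doculects = []
    truth_rows = []

    # genus split: the two root subtrees
    genus_of = {}
    root_children = root.child_nodes()
    for gi, child in enumerate(root_children):
        for nd in child.preorder_iter():
            genus_of[id(nd)] = f"GEN{chr(65 + min(gi, 25))}"

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t_eff = (node.edge.length or 0.0) + config.burst_size
        parent_state = states[id(node.parent_node)]
        state = {}
        for c in concepts:
            word, cid = parent_state[c]
            n_repl = rng.poisson(config.replacement_rate * t_eff)
            replacement_events += int(n_repl)
            if n_repl > 0:
                word = _draw_word(rng, inventory, weights,
                                  config.mean_word_length)
                class_counter[c] += 1
                cid = class_counter[c]
            else:
                word = _mutate(word, t_eff, config, inventory, weights, rng)
            state[c] = (word, cid)
        states[id(node)] = state
        plat, plon = coords[id(node.parent_node)]
        sd = config.coord_sigma * np.sqrt(max(node.edge.length or 0.0, 0.0))
        lat = float(np.clip(plat + rng.normal(0, sd), -60.0, 70.0))
        lon = float(plon + rng.normal(0, sd))
        lon = (lon + 180.0) % 360.0 - 180.0
        coords[id(node)] = (lat, lon)

        if node.is_leaf():
            name = node.taxon.label
            entries = {c: [] for c in CONCEPTS_40}
            for c in concepts:
                word, cid = state[c]
                norm = normalize_transcription(word, inventory)
                entries[c].append(norm)
                truth_rows.append((name, c, norm, f"{c}_{cid}"))
                if rng.random() < config.synonym_rate:
                    syn = normalize_transcription(
                        _mutate(word, 0.2, config, inventory, weights, rng),
                        inventory)
                    entries[c].append(syn)
                    truth_rows.append((name, c, syn, f"{c}_{cid}"))
            doculects.append(Doculect(name, config.family,
                                      genus_of.get(id(node), "GENA"),
                                      lat, lon, entries))

    collection = WordListCollection(doculects, CONCEPTS_40)
    truth = pd.DataFrame(truth_rows, columns=["doculect", "concept",
                                              "transcription",
                                              "cognate_class"])
    return SimulationOutput(tree, collection, truth, config,
                            replacement_events)


def simulate_collection(config: SimulationConfig,
                        inventory: SoundInventory = None) -> SimulationOutput:
    """Convenience: simulate the tree, then evolve word lists on it."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    return evolve_wordlists(tree, config, inventory, rng)


def simulate_gold(n_families: int = 4, config: SimulationConfig = None,
                  seed: int = 0, inventory: SoundInventory = None
                  ) -> pd.DataFrame:
    """Gold-standard table from several independent families.

    Cognate classes are namespaced per family, so cross-family pairs are
    non-cognate by construction.  Columns: doculect, family, genus, latitude,
    longitude, concept, transcription, cognate_class.
    """
    if config is None:
        config = SimulationConfig(n_languages=8)
    rows = []
    for f in range(n_families):
        fam = f"FAM{f + 1}"
        sub = replace(config, seed=seed + 1000 * f, family=fam)
        out = simulate_collection(sub, inventory)
        for d in out.collection:
            truth = out.truth[out.truth["doculect"] == d.name]
            lookup = {(r.concept, r.transcription): r.cognate_class
                      for r in truth.itertuples(index=False)}
            for c in sub.concepts:
                for w in d.entries[c]:
                    rows.append((f"{fam}_{d.name}", fam, d.genus, d.latitude,
                                 d.longitude, c, w,
                                 f"{fam}_{lookup[(c, w)]}"))
    return pd.DataFrame(rows, columns=["doculect", "family", "genus",
                                       "latitude", "longitude", "concept",
                                       "transcription", "cognate_class"])


def gold_to_collection(gold: pd.DataFrame) -> WordListCollection:
    """Assemble a WordListCollection from a gold-standard table."""
    docs: dict = {}
    order = []
    for r in gold.itertuples(index=False):
        if r.doculect not in docs:
            lat = getattr(r, "latitude", 0.0)
            lon = getattr(r, "longitude", 0.0)
            genus = getattr(r, "genus", r.family)
            docs[r.doculect] = Doculect(r.doculect, r.family, genus,
                                        float(lat), float(lon),
                                        {c: [] for c in CONCEPTS_40})
            order.append(r.doculect)
        docs[r.doculect].entries[r.concept].append(r.transcription)
    return WordListCollection([docs[n] for n in order], CONCEPTS_40)


def simulate_change_tree(n_leaves: int, rate_noise_sigma: float = 0.5,
                         burst_size: float = 0.0, depth: float = 1.0,
                         seed: int = 0) -> dendropy.Tree:
    """A rooted tree whose branch lengths measure *change*, not time.

    Time comes from a Yule tree of the given depth; each branch's change is
    its duration times a lognormal rate multiplier (gradual component) plus
    a burst of mean size ``burst_size`` (punctuational component at the
    split that starts the branch), jittered by the same lognormal noise.
    With ``burst_size=0`` the amount of change on a path is unrelated to how
    many splits the path crossed.
    """
    config = SimulationConfig(n_languages=n_leaves, tree_depth=depth,
                              seed=seed)
    rng = np.random.default_rng(seed)
    tree = simulate_tree(config, rng)
    mu = -0.5 * rate_noise_sigma ** 2  # unit-mean rate multipliers
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            rate = float(np.exp(rng.normal(mu, rate_noise_sigma)))
            burst = burst_size * float(np.exp(rng.normal(mu, rate_noise_sigma)))
            edge.length = edge.length * rate + burst
    return tree


def synthetic_feature_gold(n_families: int = 8, n_languages: int = 6,
                           n_concepts: int = 8, n_classes: int = 3,
                           informative=("neg_log_p", "neg_log_one_minus_d"),
                           seed: int = 0) -> tuple:
    """A labeled word-pair feature table where only chosen features carry
    signal (the rest are pure noise), for exercising model selection.

    Returns (pairs, gold): ``pairs`` has the seven feature columns plus
    item1/item2/family1/family2/concept/cognate; ``gold`` maps items to
    their true class labels.
    """
    from .cognate_clustering import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    concepts = CONCEPTS_40[:n_concepts]
    items, gold = [], {}
    for f in range(n_families):
        fam = f"FAM{f + 1}"
        for lg in range(n_languages):
            for c in concepts:
                cls = int(rng.integers(n_classes))
                item = f"{fam}_L{lg}|{c}"
                items.append((item, fam, c, cls))
                gold[item] = f"{fam}_{c}_{cls}"
    rows = []
    by_concept: dict = {}
    for it in items:
        by_concept.setdefault(it[2], []).append(it)
    for c, group in by_concept.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                it1, fam1, _, cls1 = group[i]
                it2, fam2, _, cls2 = group[j]
                cognate = fam1 == fam2 and cls1 == cls2
                feats = {}
                for name in FEATURE_NAMES:
                    if name not in informative:
                        feats[name] = rng.normal()
                if "neg_log_p" in informative:
                    feats["neg_log_p"] = (rng.normal(3.0, 0.7) if cognate
                                          else rng.normal(0.8, 0.7))
                if "neg_log_one_minus_d" in informative:
                    feats["neg_log_one_minus_d"] = abs(
                        rng.normal(0.5, 0.3) if cognate
                        else rng.normal(2.0, 0.6))
                for name in informative:
                    feats.setdefault(name, rng.normal(2.0, 1.0)
                                     if cognate else rng.normal(0.0, 1.0))
                feats.update(item1=it1, item2=it2, family1=fam1,
                             family2=fam2, concept=c, cognate=int(cognate))
                rows.append(feats)
    return pd.DataFrame(rows), gold
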