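# Methods

This note documents the models and procedures implemented in `lexiphylo`,
the parameters that matter, the numerical choices made where the design was
open, what the synthetic generator does and does not emulate, and known
limitations.

## Transcriptions and the sound inventory

Words are sequences over 41 coarse sound classes, each written as one ASCII
character (7 vowel classes, 34 consonant classes — the ASJPcode
conventions).  Raw transcriptions may carry diacritics, which normalization
removes in three passes:

1. whitespace and post-posed modifier characters (`"` glottalization,
   `*` nasalization, `%`) are deleted;
2. juxtaposition markers fuse the preceding segment: `X Y ~ → X`,
   `X Y Z $ → X` (the fused segment is represented by its first symbol);
3. aspirated-plosive digraphs (`ph th kh qh ch Ch Th`) are reduced to their
   first symbol, repeatedly until stable, so that e.g. `th → t` holds also
   when the combining marker was lost upstream.

The whole table ships as an editable plain-text config
(`data/asjp_inventory.cfg`); pass a custom file to
`sound_model.load_inventory` to override any of it.  Normalization is
idempotent and rejects any symbol it cannot resolve, naming the offender.
The digraph rule is deliberately aggressive: a genuine plosive+`h` cluster
is folded into the plosive.  Such clusters are vanishingly rare in
core-vocabulary transcriptions, and the alternative (silently passing
aspiration marks through as segments) is worse for scoring.

Occurrence probabilities q(a) are relative token frequencies over the
collection actually being trained on — not a fixed global table — and
unobserved symbols get q = 0 (see smoothing below).

## Alignment

Similarity between words is the maximal aggregate PMI over *licit* global
alignments: alignments in which a gap in one string is never immediately
followed by a gap in the other.  This is computed exactly by a three-state
affine dynamic program (match, gap-in-x, gap-in-y) with transitions between
the two gap states forbidden.  A gap run costs `gap_open` for its first
column and `gap_extend` for each subsequent column; a length-1 gap therefore
costs `gap_open` alone (documented choice; both penalties are model
parameters).  Traceback ties break match > gap-in-x > gap-in-y, so output
alignments are deterministic; scores are unaffected by the tie rule.  The
inner loops are numba-compiled; a pure-Python traceback aligner is kept as
the reference path, and the test suite checks both against exhaustive
enumeration of all licit alignments for short sequence pairs.

LDN (Levenshtein distance normalized by the longer string) is the
model-free bootstrap similarity; its alignment traceback prefers
substitution > deletion > insertion.

## Learning the scoring model

Training conditions (all configurable; defaults in parentheses):

* probably-related screen: LDN-based language distance ≤ 0.7;
* potential cognates: per related pair and shared concept, the synonym pair
  with the lowest LDN (ties: first listed);
* initial scores: PMI over symmetrized aligned-pair counts from plain
  Levenshtein alignments, gap columns excluded;
* refinement: 10 rounds; round *i* re-aligns all potential cognates with
  the round *i−1* scores and keeps pairs with aggregate PMI ≥ θ;
* smoothing: add-k (k = 0.5) on aligned-pair counts, since raw zero counts
  give −∞ scores; the occurrence probabilities entering the PMI formula are
  smoothed with the same additive constant (k/41 per symbol, renormalized)
  so that symbols absent from the training data stay finite;
* hyperparameters: Nelder–Mead over (gap_open, gap_extend, θ) minimizing
  the mean calibrated distance between probably related pairs, initialized
  at (−2.5, −1.75, 4.5), function tolerance 1e-3, 200-evaluation budget.
  The related set and cognate list are frozen during the search
  (re-screening inside the objective would change its domain).  A θ that
  filters out every pair is penalized with an off-scale objective value
  rather than an exception.

The shipped default parameters (gap_open −2.33, gap_extend −1.276,
θ 4.401) are the values found for a large multi-family reference database;
`train_model` uses them when no optimization is requested.

## Calibrated language distance

p_c = (1 + #{null ≥ s_c}) / (1 + #null), where the null sample contains the
max-over-synonyms score of every ordered cross-concept pair (c₁ ≠ c₂, c₁
from l₁'s defined concepts, c₂ from l₂'s).  Ties count against the
synonymous score (≥), which makes the statistic conservative; note that a
heavily tied similarity measure (e.g. plain LDN on short words) therefore
deflates Σ −log p_c below its nominal Fisher mean — the calibration is meant
for the continuous PMI scores.  Z combines the p-values Fisher-style and is
rescaled by the closed-form bounds computed for complete 40-item lists
(Z_max = (40·log(40²−40+1) − 40)/√40 ≈ 40.18, Z_min = −√40·… ≈ −6.32); the
bounds always use N = 40 regardless of observed list length, the √N in Z
already absorbing incompleteness.  Pairs with no shared concept get NaN
(exported as missing), never a fabricated value.  d is a dissimilarity, not
a metric.

## Cognate clustering

Features per same-concept cross-doculect word pair: (1) alignment score,
(2) its calibrated p-value, (3) −log p, (4) language distance d,
(5) −log(1−d) with d capped at 1−1e-9, (6) mean word length of the concept
across the collection, (7) Pearson correlation between features 3 and 4
over all of the concept's word pairs (cached per concept; 0 when
degenerate).  The classifier is an RBF-kernel SVM behind a standardizing
scaler, calibrated by sigmoid (Platt) scaling on cross-validated decision
values; training samples at most `n_train` (default 7,000) labeled pairs.
Clustering runs per concept: words are nodes, edges connect pairs with
predicted cognacy probability ≥ 0.25, and seeded asynchronous
label-propagation community detection partitions each graph (communities
never span connected components; singletons allowed).  Class labels follow
the `concept_serial` convention.

Model selection enumerates all 127 non-empty feature subsets over
family-wise training/test splits (6 random training families by default, 10
splits) and picks the subset with the best mean B-cubed F.  The harness
operates on a precomputed labeled feature table, so the 127 subsets share
one feature computation; cross-family pairs are labeled non-cognate
throughout, and the training class ratio is the natural ratio in the sample
(configurable only through the input table).

## Characters and export

Cognate-class characters: one binary column per inferred class; undefined
where the underlying concept is missing.  Soundclass-concept characters:
one column per (concept, symbol) with any support; presence, not count.
Only *variable* columns (both states among defined values of the exported
taxon set) are kept, re-filtered per subset.  Export writes relaxed Phylip
(`?` for undefined, configurable) and a two-block binary partition file;
downstream maximum-likelihood inference (with ascertainment correction for
all-variable data) is intentionally left to external engines.

## Trees

BIONJ implemented directly: classic neighbor joining agglomeration with a
first-order variance model (variance proportional to distance) that mixes
the two joined rows with the variance-minimizing weight λ (clamped to
[0,1]; λ = 1/2 when the variance term vanishes, which reduces exactly to
NJ — the test suite checks that limit against an independent NJ
implementation).  Q-criterion ties break lexicographically on taxon labels;
negative branch-length estimates are clamped to zero and logged.  Rooting:
by outgroup (root at the attachment node, outgroup removed) or by midpoint
(root inserted on the longest leaf-to-leaf path; if the midpoint falls
exactly on a node, the tree is rooted at that node).

## Evaluation statistics

* **B-cubed** precision/recall are item-averaged; F is their harmonic mean.
* **GQD**: both trees are restricted to shared taxa; quartet resolutions are
  read off topological (edge-count) distance matrices through the four-point
  condition, with degree-2 nodes contracted first.  The denominator counts
  only quartets the reference resolves; a quartet counts as agreeing only
  if the candidate resolves it identically.  Exact enumeration up to 30
  taxa by default, uniform sampling (100,000 quartets, seeded) above.
* **Mantel**: Spearman by default, permutation p with the +1 correction,
  one-sided by default.  The correlogram uses 1,000 km classes, a Pearson
  statistic against the class-membership indicator, sign-flipped so that
  positive means "linguistically similar at this geographic range", and a
  two-sided permutation p per class; Holm correction across classes is
  available but off by default.
* **Great-circle** distances use the haversine formula on a sphere of mean
  radius 6,371 km.

## Punctuated evolution

Per rooted family tree: root-to-tip path length (sum of branch lengths) and
branching-node count (internal nodes with ≥ 2 children on the path, root
included) per leaf.  PGLS regresses node count on path length with
Brownian-motion residual covariance (shared root-to-MRCA path length from
the same tree, no λ transformation; a star tree reduces to OLS).  The
node-density screen fits the curvilinear law n = β·x^δ as a log–log PGLS
and is *negative* (no artifact) iff δ is not significantly greater than 1
(one-sided t at α).  Evidence for punctuation in a family requires the
conjunction: δ-test negative, slope positive, and p surviving
Holm–Bonferroni across the δ-negative families.  Note that a strong
gradual background added to per-split bursts itself curves the log–log
relation (x = a + b·n gives δ > 1 for a > 0), so the screen is
conservative: cleanly punctuational regimes pass it, mixed regimes may not.

## Synthetic data

The generator emulates the statistical structure the pipeline needs to be
tested against: a Yule tree (unit depth by default), root words drawn from
a mildly skewed symbol distribution (weights ∝ 1/(rank+3), mean length 4),
and three change processes per branch — symbol substitutions (rate 0.35 per
symbol per unit time) governed by a row-stochastic propensity matrix
structured by articulatory group (within-group weight 8, cross-group 1, no
self-substitution), indels (0.08 per word), and lexical replacements (0.25
per concept) that draw a fresh word and open a new cognate class.
Coordinates diffuse as Brownian motion along the tree.  Optional extras:
synonym retention, and a punctuational mode that injects extra change at
every split.  For the punctuation analyses, `simulate_change_tree` converts
a time tree into a change tree: branch change = duration × lognormal rate
multiplier + a lognormally jittered per-split burst.

These defaults were chosen once as a plausible desk-scale analogue of real
core-vocabulary data — deep pairs still share roughly 60% of cognates, and
cognates remain recognizably similar.  What the generator does *not*
emulate: realistic phonotactics, borrowing and contact, documentation bias
in synonym counts, and cross-concept cognacy.  Passing end-to-end tests on
it therefore demonstrate internal correctness and recoverability under the
model's own assumptions, not performance on real lexical data.

Problem sizes used by the shipped end-to-end checks: 30 languages × 40
concepts for tree and cognate recovery (with a separate 4-family gold
simulation for classifier training), 100-leaf trees × 100 replicates for
the punctuation calibration, and reduced training sizes (a few hundred
pairs) for the 127-subset model-selection harness.

## Known limitations

* The PMI table measures global correspondence propensities; 40-item lists
  are far too short to support per-language-pair sound correspondences.
* The calibrated distance is conservative under tied scores and is not a
  metric; BIONJ on it is a similarity tree, not a guaranteed phylogeny.
* Label propagation is stochastic under ties; a fixed seed makes runs
  reproducible but different seeds may split borderline clusters
  differently.
* Maximum-likelihood and Bayesian tree search are out of scope; the package
  produces their input files instead.
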