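# Methods

## Model and assumptions

The core object is a binary classifier over unordered drug pairs. The
working assumption is that two drugs sharing a clinical indication also
resemble each other in *drug-centric* channels — targets, the annotation
sets those targets fall in, structure, target essentiality profiles,
network proximity of targets, and bioassay activity — and that a boosted
tree ensemble can combine these partially redundant channels into one
similarity score. Disease–disease similarity is deliberately never used:
the score must be computable for a molecule with no approved indication.

The classifier is XGBoost with `objective=binary:logistic`,
`base_score=0.5`, exact tree method and a single thread (the last two for
bit-for-bit reproducibility). The reported score is the raw margin before
the logistic transform; `score_to_probability` is the plain sigmoid, so
the network-pruning cutoff 7.4 corresponds to a sharing probability of
0.99939.

## Indication standardization

Mapping free text to disease concepts is treated as *data*, not
algorithm: a synonym vocabulary table maps lexically normalized strings
(lower-case, punctuation stripped — including Unicode apostrophes —
whitespace collapsed, leading severity qualifiers from a configurable
stop-list `advanced/severe/mild/moderate` removed) to concept ids.
Unknown terms map to an explicit `UNMAPPED` sentinel rather than being
dropped. A small published-style fixture of synonym rows with their drug
lists is bundled for tests and examples; one of its rows lists four drugs
against a printed count of three — the fixture preserves the printed drug
list and the discrepancy is documented where it is loaded.

## Feature semantics and numerical choices

- Jaccard of two **empty** sets is *missing*, not 0: absence of annotation
  is no evidence of dissimilarity. Missing cells are median-imputed from
  observed pairs only; a feature with no observed value is a configuration
  error.
- Essentiality similarity averages Pearson correlations over all target
  cross-pairs with ≥ 3 shared non-missing cell lines; constant profiles
  are skipped.
- PPI distance is an unweighted hop count, graphs are treated as
  undirected, a shared target gives 0, and disconnected target sets give a
  missing value.
- `structure_dice` is plain Dice on bit sets. An optional `add_one` flag
  applies the (2|A∩B|+1)/(|A|+|B|+1) smoothing that ChemmineR's `fpSim`
  uses by default; published atom-pair similarity values computed with
  that tool (e.g. tamoxifen vs anastrozole = 0.372 on 1024-bit folded
  atom pairs) are reproduced only under this convention — plain Dice on
  the identical bit sets gives 28/77 ≈ 0.364. Fingerprint dialects are a
  pluggable provider for exactly this reason.
- The KS screen is two-sample, two-sided (`scipy.stats.ks_2samp`); the
  accompanying direction is the sign of the **mean** difference between
  label groups, because several similarity features are zero-inflated and
  have equal group medians while the planted/biological location
  difference is real.
- FP rate at a probability cutoff is reported two ways; the primary
  `fp_fraction` is the false-discovery fraction FP/(FP+TP) among pairs
  called at ≥ cutoff, which is the quantity that matters when confident
  calls seed repurposing candidates; the classical FPR is reported
  alongside.

## Cross-validation, imbalance and leakage

Folds are stratified at the pair level (5-fold, one seed governs
everything); the majority class is downsampled to 1:1 within each
training fold only — evaluation always uses the untouched held-out fold.
Pair-level splitting leaks drug identity (a drug appears in training and
held-out pairs); `group_drugs=True` switches to drug-level folds where a
pair is held out only when both drugs are, training excludes every pair
touching a held-out drug, and straddling pairs are excluded from
evaluation. Pair-level remains the default because it matches the way
such pair classifiers are usually evaluated and uses every pair once.
The default hyperparameter grid is learning rate {0.05, 0.1, 0.3} ×
depth {3, 5, 7} × rounds {100, 300}, ties broken by grid order; grid
search maximizes mean held-out AUC over the same fold assignment.

## Class–disease screen

For class \(K\) and disease area \(D\): group 1 holds scores of pairs
joining a class member to a drug approved for \(D\), group 2 pairs
joining a class member to a drug approved for neither \(D\) nor in
\(K\); pairs internal to \(K\) are excluded from both groups (a pair
must not count as its own evidence) and duplicates are collapsed via the
canonical pair key. The test is `scipy.stats.mannwhitneyu` (exact for
small tie-free groups, tie-corrected normal otherwise); the effect size
is the Hodges–Lehmann estimate, the median of the full between-group
difference grid. BH-FDR is applied across all combinations; ranking
keeps strictly `q < 0.1` and positive shifts, ordered by shift.
"Approved for the disease" means ≥ 1 standardized concept inside the
area; areas are defined by semantic-type codes, case-insensitive
keywords, or explicit concept lists. Sensitivity counts a (class, area)
combination as a true positive when the fraction of class drugs approved
for the area strictly exceeds the chosen cutoff (cutoff 0 therefore
means "at least one approved drug").

## Explanations

Ablation replaces one feature at a time with the per-feature median of
the **full** training table (frozen at train time) and reports
delta = original − ablated on the raw-score scale. Since the vast
majority of pairs share no indication, the cohort median approximates a
"no contribution" value. Global importance is the booster's built-in
importance as normalized **total gain** (the Gain convention of R
xgboost's importance table); unused features score exactly 0.

## Synthetic cohort generator

The generator emulates the statistical regime of real annotation data,
not its content. Defaults: 8 latent diseases × 15 drugs (7,140 pairs,
~14% sharing), a 2,000-gene universe with disjoint 40-gene disease
modules, 4 targets per drug drawn from the drug's module with probability
0.8, 1024-bit fingerprints built from 40-bit disease prototypes with
per-bit replacement noise 0.15 (0 = exact prototype, 0.5 = pure chance),
11 gene-set collections of 30 sets with 2 module-enriched sets per
disease (purity 0.7), a stochastic-block-model PPI aligned to the modules
(within 0.15, between 0.002), 30 cell lines with a per-disease latent
factor explaining 60% of module-gene essentiality variance, per-disease
bioassay pools, 10% multi-indication drugs, and 10% missingness per
resource (fingerprints, bioassay entries, essentiality cells). One
mechanism-named drug class is built per disease (20 drugs, 25% from the
disease); the planted class raises that to 60%, capped so that some
disease drugs always remain outside the class — otherwise the screen has
no disease-approved partners left and degenerates. The structure-noise
default of 0.15 makes structure one of the weaker channels and target
essentiality the dominant one, mirroring the empirical ordering in this
domain where structural similarity is the weakest single discriminator;
it also keeps "the dominant feature" well defined for the
explanation-fidelity check, although under heavy feature correlation the
top-total-gain feature can still differ from the top-ablation feature on
some seeds — that ambiguity is a property of correlated channels, not a
bug.

What the generator does **not** emulate: real chemistry (fingerprints
are synthetic bit sets), realistic class imbalance (~14% positive pairs
vs ~2% on real cohorts), hub structure of real interactomes, correlated
annotation redundancy across collections beyond the shared module origin,
and cohort scale (thousands of drugs). Passing the recovery tests
therefore shows the pipeline's machinery is sound under a known
ground truth, not that a particular real-data performance level will be
attained.

## Problem sizes and determinism

Tests and the acceptance script run the default 120-drug cohort
(featurization ≈ 6 s, a 5-fold CV ≈ 1 s) and a 24-drug cohort for
pipeline/determinism checks; these sizes were chosen so the full suite
stays interactive while keeping enough pairs for stable statistics. All
randomness flows through explicit integer seeds; with a fixed config and
seed the generator's files, the feature table, the scores and the network
exports are byte-identical across runs (single-threaded exact-mode
boosting, sorted iteration everywhere, fixed float formatting on export).

## Known limitations

- Real published performance numbers for this family of models depend on
  proprietary-scale scraped cohorts and are not desk-reproducible; they
  serve only as external context, and this package makes no claim of
  matching them.
- The vocabulary-table approach to indication mapping handles synonyms it
  has seen; it is not an NLP concept mapper.
- The ChemmineR fingerprint provider shells out to Rscript and is
  therefore environment-dependent; the RDKit provider is the pure-Python
  default.
- `class_disease_shift` materializes the full difference grid for the
  Hodges–Lehmann estimate; for very large screens an approximate
  estimator would be needed.
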