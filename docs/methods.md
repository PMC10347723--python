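# Methods

## The problem

Long non-coding RNAs (lncRNAs) touch chromatin at thousands of genomic
sites. Given an RNA–DNA contact map (GRID-seq / RADICL-seq style), the
genome is segmented into non-overlapping 1 kb tiles and, for each lncRNA,
a classifier is trained to distinguish its bound tiles from unbound ones.
The classifier itself is not the end product: the object of interest is
*which families of features* carry the predictive information, because the
families map onto binding mechanisms — triplex-forming sequence potential
points to direct RNA·DNA:DNA contacts, nascent-transcription context points
to transcription-coupled recruitment.

## Labeled examples

**Positives** are the lncRNA's bound tiles. **Negatives** are unbound cis
tiles chosen so that genomic distance to the lncRNA gene cannot separate
the classes:

1. every unbound tile is anchored to its nearest positive (ties → lower
   tile id), and at most `cap = 100` candidates are kept per anchor (the
   nearest ones), which prevents pile-ups next to isolated positives;
2. the positives' distance-to-gene distribution is histogrammed over 50
   log-spaced bins (from one tile width to the chromosome length) and
   converted into per-bin sampling quotas for the candidates
   (largest-remainder rounding; quotas exceeding a bin's supply are
   redistributed to bins with remaining capacity in proportion to the
   positives' mass there); within a bin, candidates are drawn uniformly
   without replacement under the run's seed;
3. `ratio = 5` negatives per positive are drawn (2 for very large maps).

Quota sampling was chosen over weighted-reservoir sampling after measuring
that exponential-keys reservoirs systematically undersample saturated
near-gene bins (achieved KS distance 0.05–0.17 between positive and
negative distance distributions, versus ≈ 0.01 for quotas). A feasibility
constraint follows from supply/demand accounting: per chromosome side the
candidate supply is ~2 tiles per unit tile-distance, so matching is only
achievable when `decay_scale / tile_width > n_positives × (ratio + 1) / 2`.
Study geometries respect this rule; when candidate support cannot cover
the positive support the sampler degrades gracefully (spill into the
nearest supplied bins, uniform fallback with a warning when there is no
overlap at all).

## Cross-validation

Five folds, two modes. *Random* CV stratifies by label. *Block* CV first
groups examples into genomic blocks — a seeded shuffle of the positives is
scanned; each unassigned positive claims its `neighbors_per_seed` nearest
unassigned positives, and every negative joins its anchor's block — then
deals whole blocks to folds, largest block first into the currently
smallest fold (greedy positive-count balancing). Blocks travel together
between train and test, so spatially autocorrelated signal cannot leak
across the split. `neighbors_per_seed` defaults to 49 (blocks of ~50
positives); the synthetic studies use 4 (blocks of ~5) so that each of the
5 folds still receives several independent blocks at the reduced study
size.

## Models

One probability random forest per feature-family subset
(scikit-learn `RandomForestClassifier`): 1000 trees (200 in the synthetic
studies), depth ≤ 10, minimum leaf size 10, `mtry = floor(sqrt(p))`,
minority class upsampled to 1:1 in each training split. Test AUROC is
computed by the midrank Mann–Whitney statistic (ties = half credit), AUPR
by step interpolation. Random seeds for the bootstrap and the upsampling
derive from the ensemble seed and the fold only — not from the family
subset — so paired models across the ensemble share their sampling
randomness (common random numbers), which removes a large part of the
variance from the paired AUROC differences that MPV is built on without
affecting any single model's distribution.

Model sets: with five primary (sequence) families the *sequence-only* set
contains all 2⁵−1 = 31 non-empty subsets on raw features; with five
secondary (context) families the *sequence + context* set contains all
2⁵ = 32 context subsets, each stacked on a 100-component PCA summary of
the full sequence category (fit on the training fold by default;
a whole-data mode exists for compatibility with analyses that fit the
rotation globally).

## MPV, MxPV, complementarity

For family *A<sub>i</sub>* within its category,

V_i = (1 / 2^(n−1)) Σ_{U ∋ A_i} (1/K) Σ_k [ M_k(U) − M_k(U∖A_i) ]

with M_k the block-CV test AUROC on fold k. MxPV replaces the outer mean
with a max. For secondary families the empty-context model is the PC-only
model (it is part of the 32-model set). For primary families the equation
needs M_k(∅), which no one trains; this implementation defines
**M_k(∅) = 0.5**, the featureless random classifier. Two consequences are
worth stating. First, each family's MPV averages exactly 2^(n−1) paired
differences (16 at n = 5). Second, the singleton term (M({A_i}) − 0.5)
carries weight 1/2^(n−1): negligible at n = 5, but half the estimator at
the reduced two-primary-family synthetic schema — which interacts with a
known small-sample artifact, discussed under *Calibration* below.

The *complementarity score* of a family pair is the mean block AUROC of
the pair-trained model minus the better single-family model, trained as a
dedicated three-model set (so pairs may cross the primary/secondary
boundary). It exists precisely because MPV underweights families that are
informative only jointly (XOR-like structure).

A lncRNA is called *transcription-associated* (TA) iff its
transcription-family MPV ≥ 0.01 (inclusive). Group contrasts between TA
and non-TA lncRNAs use one-sided Mann–Whitney tests (exact for groups of
≤ 10).

## Fine-grained importance and association statistics

Each (subset, fold) forest is one model with a test AUROC and a Gini
importance vector. Within the top 20 % of models by AUROC (sequence-only
models for sequence features, sequence+context for context features),
features are ranked by descending Gini (ties → average rank) and the
median rank per feature is reported. The synthetic study widens the cut to
50 % because its sequence-only set has only 3 subsets — a 20 % cut keeps
roughly one k-mer-bearing forest and the median collapses into noise,
an artifact of ensemble size, not of the estimator.

Enrichment uses the signed two-sample Kolmogorov–Smirnov statistic: the
classical D carrying the sign of the ECDF difference at its maximizing
point (ties → smallest x), positive = enriched in bound tiles
(configurable). P-values are two-sided asymptotic; batteries are
BH-adjusted. Spearman correlations use midranks. miRNA seeds (7-mers) are
decomposed into their three overlapping canonical 5-mers; a tile's seed
content is the summed count of those 5-mers, and the lncRNA × miRNA
signed-KS matrix is reported in average-linkage hierarchical-cluster order
(computed on name-sorted input, hence invariant to input order).

## The synthetic data generator

No public desk-scale dataset exercises all of the above, so the generator
plants known structure and the studies measure its recovery.

* **Geometry.** Four chromosomes of 4000 × 1 kb tiles, one lncRNA per
  chromosome, gene at the center; interaction probability
  ∝ exp(−d / 400 kb) — the cis concentration real maps show.
* **Mechanisms.** Each lncRNA binds through one planted route, composed
  multiplicatively with distance:
  p(tile) ∝ exp(−d/decay) · σ(effect_size · s), s ∈ {−1, +1}, effect_size
  = 2 (odds ratio e⁴ ≈ 55 between signal states before distance matching):
  - *transcription*: s = +1 where the transcription latent exceeds its
    chromosome median;
  - *triplex*: s = +1 on tiles carrying a true triplex-target insert
    (below);
  - *xor_pair*: s = +1 where exactly one of the methylation / chromatin
    latents exceeds its median — each track alone is uninformative by
    construction;
  - *noise*: distance only.
* **Context tracks.** Piecewise-constant latents with geometric block
  lengths (mean 10 tiles) plus N(0, 0.05²) track noise; two transcription
  tracks share one latent (a family), methylation and chromatin have one
  track each.
* **Domain structure.** Bound tiles of the track-coupled mechanisms
  (transcription, xor_pair) come in geometric runs (mean 3 tiles) grown
  around law-sampled seed tiles. Real interaction maps are
  domain-structured; the runs give labels spatial autocorrelation *beyond*
  what the features explain, which is exactly what makes random CV
  optimistic relative to block CV. Triplex binding stays site-specific
  (single target tiles), and noise lncRNAs bind by distance only — no
  runs, no signal.
* **Sequence sharing.** A heavy-tailed 5-mer bias (i.i.d. LogNormal(0,1.5)
  weights over the 512 canonical 5-mers, drawn per study seed) shapes the
  lncRNA transcripts (90 % biased-chain segments of a 6 kb transcript),
  the miRNA seed list, the repeat consensus sequences, and the insert
  flanks — so density correlations across these resources exist by
  construction.
* **Triplex plant.** A 45 nt purine element (uniform over all-purine
  5-mers) is carried by the triplex lncRNA's transcript (3 TFO copies) and
  inserted, with 8 % per-base mutation, into 25 % of tiles ("true"
  inserts). Another 40 % of tiles receive *decoy* inserts: fresh random
  purine tracts of the same length. Every insert carries the same 500 nt
  biased-composition flank. At the 5-mer level true and decoy tiles are
  nearly indistinguishable (both are purine tracts with the shared flank
  vocabulary), but only true inserts match the lncRNA's TFOs under the
  built-in scorer's ≤ 1-mismatch-per-15-nt Hoogsteen code — so the triplex
  quartet is by construction a cleaner route to the label than any k-mer
  summary, while bound tiles still share 5-mer content with the transcript
  broadly (what the rank/density correlation analyses measure). This
  mirrors the real situation the scorer exists for: genomes are full of
  purine tracts, and only sequence-matched ones are targets.

What the generator does **not** emulate: read-level noise, mappability and
GC artifacts, trans contacts, overlapping mechanisms within one lncRNA,
cell-type heterogeneity, and realistic repeat or motif landscapes. Passing
the recovery study therefore shows the *pipeline* recovers planted
structure of realistic shape and size; it does not certify performance on
any real map.

## Study sizes and calibration

The replicated recovery study uses 100 positives per lncRNA (600 examples
at 5:1), 200-tree forests, 5-fold block CV, 10 sequence PCs, and 10
replicates; these sizes run the full suite on a single CPU in well under
half an hour. Two calibration facts shaped the study layout:

* **Null CV-AUC at small n.** Cross-validated AUC of a flexible model on
  features independent of the labels is not exactly 0.5 at small n: the
  finite pool anti-correlates train and test composition, and we measure
  E[AUC] ≈ 0.49 (sd 0.037) for the 512-feature k-mer model at 600
  examples, versus no measurable bias in a clean i.i.d. null. Through the
  half-weight singleton term of the two-primary-family schema this would
  leak into the noise-lncRNA MPVs. A second effect persists at any n
  inside one realization: an autocorrelated track can *by chance* align
  with the spatial layout of one interaction map, making it genuinely
  (but meaninglessly) predictive in that realization — cross-validation
  cannot remove this, only averaging over realizations can. The
  no-signal calibration check therefore runs at 4200 examples (700
  positives) and averages the family MPVs over 3 independent study seeds;
  measured seed-averaged MPVs are all within ±0.005.
* **TA-call stability.** The TA threshold (0.01) sits close to the MPV
  noise floor at 600 examples; common random numbers (above) reduce that
  floor enough for per-replicate TA calls on the transcription and triplex
  lncRNAs to be stable.

## Numerical choices

* Coordinates are 0-based half-open throughout; tile–gene distance is the
  minimum gap between intervals (0 if overlapping); trailing partial tiles
  are dropped at tiling, and interactions falling into them are discarded
  with a warning.
* Canonical k-mers: lexicographic min of k-mer and reverse complement
  under A<C<G<T; windows containing non-ACGT are skipped; k odd.
* PWM scores: pseudocount 0.001, uniform background unless supplied, and
  both the threshold DP and the scanner operate on log-odds snapped to a
  0.005 grid, so "score ≥ threshold" is the same event in both. The
  threshold is the smallest grid score with background exceedance
  probability ≤ the target p-value; for short motifs the score
  distribution is atomic and the realized exceedance can sit well below
  the target — that is a property of the distribution, not the DP.
* Sequence PCA drops constant columns, caps components at the numerical
  rank (warning), and fits on training rows by default.
* Ties everywhere break deterministically (lower tile id, smaller name,
  smallest x), and every stochastic step takes an explicit seed; fixed
  seeds reproduce outputs bit for bit.

## Known limitations

* The built-in triplex scorer is an explicit simplification of
  purine-motif triplex search (windows ≥ 15 nt, ≥ 90 % A/G, ≤ 1 mismatch
  per 15 nt); equivalence with dedicated scanners is out of scope — use
  the external-provider path to feed their output in.
* MPV inherits the known blind spot it is documented to have: families
  informative only jointly get near-zero MPV (the XOR construction shows
  this by design); the complementarity score is the intended complement.
* At small study sizes the primary-family MPV estimator leans on the
  M(∅) = 0.5 convention (half its weight at two primary families); at the
  full ten-family schema the convention contributes 1/16 of the weight.
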