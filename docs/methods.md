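# Methods

This note documents the models and procedures implemented in `epifootprint`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention); every operation
consuming intervals asserts `end > start`. The TSS of a stranded feature is
`start` on the plus strand and `end − 1` on the minus strand; a TSS window of
width *w* is `[TSS − w/2, TSS + w/2)`. Region files for TSS classes often
already contain the windows themselves, so any interval whose width equals
the requested window is used as-is and anything else is re-centred on its
TSS. bedGraph gaps are treated as signal 0. Chromatin-state names are
validated against the canonical 15-state mnemonic vocabulary with an
extensible alias table (`RepPC → ReprPC` etc.), since spellings vary across
published segmentations.

## Data slices and normalization

A slice is the regions × samples matrix of base-pair-weighted mean signal
for one mark–ROI pair. The mean (not max or median) is used because slices
summarize *average* signal over a region and bedGraph intervals have unequal
widths; a region on a chromosome absent from a track gets mean 0 rather than
an error (logged once), since sparse tracks are common. Quantile
normalization replaces each column's values by the across-column means of
the order statistics at their ranks; tied values within a column receive the
mean of the reference values over their tied positions (the standard dense
procedure). Consequence worth knowing: with ties, column value multisets are
only approximately identical — exact identity holds for tie-free columns.
Replicates are *not* averaged into slices; replicate handling belongs to the
concordance analysis, which subsamples them.

## Tree concordance

Distance is `1 − Pearson r` between sample columns (range [0, 2]); a
zero-variance column is an error naming the sample. Trees are UPGMA
(unweighted average linkage), implemented directly so ties in the merge
queue break deterministically by the lowest index pair; the implementation
is cross-checked against `scipy.cluster.hierarchy.linkage(method="average")`
on tie-free inputs in the test suite.

Because histone-mark assays have unequal replicate counts, one replicate per
sample is drawn uniformly at random, 50 rounds per mark–ROI combination
(default), yielding one tree per round. Clade identity is the unordered leaf
set of an internal node; singletons and the root are excluded because they
appear in every tree and would only add a constant. The clade-frequency
table pools *all* trees from *all* combinations — concordance is
cross-combination by construction, which is what makes a high score mean
"independently re-discovered structure". A tree's confirmation score is the
unweighted mean of its clades' pooled frequencies; a combination's score is
the mean over its rounds, displayed rounded to one decimal with full
precision retained internally. Bootstrap support for the full-data tree
resamples regions (rows) with replacement and reports plain bootstrap
proportions; multiscale/approximately-unbiased corrections are out of scope.

At desk scale only one combination carries planted signal, so pooled
frequencies — and hence absolute scores — are small (the informative
combination's clades appear in at most 50 of 2,000 trees); the meaningful
output is the *ranking*, which the planted combination tops reproducibly.

## Moderated differential marking

Slices are log2(x + 1)-transformed (signal means are non-negative and
skewed; the linear model assumes roughly Gaussian responses) and quantile
normalized. Per region, signal is regressed on an intercept plus an
in-cluster indicator; the residual variance s² (d = n − 2 df) is shrunk
toward a prior (d₀, s₀²) estimated by moment matching on log s² (digamma /
trigamma inversion, Newton iteration). When the observed spread of log s² is
no wider than sampling noise the inversion has no solution and the model
falls back to full shrinkage (d₀ = ∞) with a log message. The moderated t is
`effect / (s̃ √(1/n₁ + 1/n₂))` with `s̃² = (d₀s₀² + ds²)/(d₀ + d)` on d + d₀
df; setting d₀ = 0 recovers the classical pooled-variance t exactly (tested
to machine tolerance), and the full model is cross-checked against the
Bioconductor reference implementation on a small matrix. All-constant
regions are flagged and assigned p = 1, effect = 0. BH FDR (step-up with
monotonicity) is applied per test family at α = 0.05.

Specificity classes follow the marked-cluster cardinality: a region
significant (any mark) in exactly 1 cluster is `unique`, in 2–3 clusters
`shared_2_3`, in ≥ 4 `nonspecific_marked`, else `unmarked`. Relatedness of
the 2–3 clusters is not enforced by default because "closely related" is not
operationalizable without a cluster grouping; a strict mode restricts
`shared_2_3` to clusters sharing a `group_id`. Summaries report percentages
under both denominators (all regions; regions marked anywhere), since both
are legitimate readings of "fraction specific".

## Footprint clustering

Footprints are per-(stage, mark) blocks of 100-bp-bin base-weighted means
over 3-kb TSS windows (30 bins per block; 150 features for one stage × five
marks, 450 for three stages — asserted). Minus-strand windows are reversed
so bins read 5′→3′. Each block is scaled by its 95th percentile and capped
at 1: percentile capping bounds outlier domination and makes marks
comparable without assuming a common dynamic range. K-means (Euclidean, best
of 10 seeded restarts) partitions windows; labels are reordered by
decreasing cluster size so C1 is always the largest cluster. Defaults: k = 5
for single-stage analyses, k = 6 for three-stage trajectory analyses, both
overridable (the pipeline uses the number of planted archetypes when driven
by the simulator). Chromatin-state fold enrichment per cluster is the ratio
of within-cluster to background state fractions, with zero-background states
reported as fold 0 and flagged.

## State dynamics

A window's state is the one covering the most bases (majority overlap), with
ties broken by canonical state order and zero coverage defaulting to Quies —
the unmarked state is the only sensible fallback for an unannotated window.
A point-lookup mode (state at the window midpoint) is available behind a
flag. Transition matrices count windows over consecutive stage pairs
(15 × 15 = 225 cells; total count equals the number of windows), are
row-normalized (each row sums to 1 or is all-zero), and edges strictly above
the 30% threshold form the reported transition graph. Entropy is Shannon
entropy in bits (base 2, labelled in all outputs) of the per-stage state
distribution; subset entropies (Polycomb = {TssBiv, BivFlnk, EnhBiv, ReprPC,
ReprPCWk} by default, configurable) renormalize within the subset, with the
unnormalized partial sum available behind a flag and empty subsets reported
as 0.

## Enrichment and annotation

TFBS enrichment is a hypergeometric upper-tail test whose unit is the
*site*: background N = all sites of all factors, n = background sites
overlapping the ROI by ≥ 1 bp (each site counted once even if it spans two
ROI intervals), and per factor (K sites, k overlapping) p = P(X ≥ k) via the
numerically stable survival function; the test equals exhaustive subset
enumeration for all N ≤ 12 (tested). BH adjustment across factors is
reported alongside raw p-values. Gene association follows the
basal-plus-extension regulatory-domain rule (basal 5 kb upstream / 1 kb
downstream oriented by strand; both-direction extension to the nearest
neighbouring basal boundary, capped at 500 kb from the TSS); association is
by ≥ 1 bp domain overlap and is monotone in the cap. Nearest-TSS distances
are binned [0, 5 kb), [5 kb, 50 kb), [50 kb, 500 kb], with the left edge
half-open and the last bin closed at 500 kb; farther queries are reported
unassigned. Expression summaries are medians and IQRs of RPKM per footprint
cluster, for the elements themselves and for their associated genes.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the desk-scale study conditions used throughout
the tests: 3 sample clusters × 4 samples × 2 replicates on a 2 × 10 Mb toy
genome, 120 regions per ROI class, log-normal signal (per-region log2
baseline ~ N(3, 1) shared across samples), one informative combination
(H3K4me1 at lincRNA TSS windows) in which 10% of regions per cluster carry a
+2 log2 elevation for in-cluster samples, and replicate noise N(0, 0.25) on
the log2 scale. The log-normal model makes effect sizes interpretable as
log-fold-changes, matching the differential model, and keeps signal
non-negative and heavy-tailed like ChIP coverage. All generators are pure
functions of (config, seed).

State trajectories assign each TSS one of five archetypes —
silencing (TssBiv → ReprPC → Quies), bivalent-retained
(BivFlnk → TssBiv → TssBiv), early activation (EnhBiv → Enh → Enh), late
activation (ReprPCWk → Quies → Enh) and quiescent — allocated
deterministically by cumulative rounding of the mix proportions (default
mix: 40% silencing, 15% each of the others). Each archetype starts in a
*distinct* state on purpose: the phenomenon of interest is the collapse of
combinatorial state diversity during differentiation, and with archetypes
that merely permute states between stages the entropy would be constant by
construction. With the default mix the exact per-stage entropies are
2.171 → 1.871 → 1.406 bits. Per-stage signal tracks are derived from each
window's state through a fixed state → mark emission profile (bivalent
states high in H3K4me3 + H3K27me3, enhancer states high in H3K4me1, and so
on) plus log-scale noise, constant across the window.

What the simulation does *not* emulate: fragment-level read sampling,
mappability and GC bias, within-window spatial signal shape, heterogeneous
tissue composition, and correlated structure across ROI classes. Passing
recovery tests therefore demonstrates that the inference machinery is
correct and well-calibrated under its own model assumptions — not that real
reference-epigenome collections will yield any particular score or fraction.

## Numerical choices and degenerate inputs

Deterministic tie-breaks everywhere randomness is not explicit: UPGMA merges
by lowest index pair, state assignment by canonical order, k-means labels by
decreasing size. A single global seed derives per-stage seeds by hashing the
stage name, so a stage rerun in isolation sees the same randomness as in the
full run; run outputs are checksummed and identical config + seed reproduce
identical checksums. Degenerate inputs have defined behaviour rather than
crashes where a definition exists (empty BED → empty set; all-zero feature
block → zeros; constant region → p = 1 flagged; single-column quantile
normalization → unchanged with a warning) and fail loudly with the offending
item named where none does (zero-variance sample, unknown state, overlapping
bedGraph intervals, mismatched TSS universes).

## Known limitations

Chromatin-state segmentations are consumed, never learned. Bootstrap support
is a plain proportion, not an unbiased multiscale estimate. The differential
model is a two-group comparison only (no covariates, pairing, or trend
fitting). TFBS enrichment treats sites as exchangeable units, ignoring site
width and genomic composition. Ontology/phenotype term enrichment against
external databases and figure rendering are out of scope.
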