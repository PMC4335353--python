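# epifootprint

Tissue-specific epigenetic regulation of regulatory elements — and of lincRNA
transcription start sites in particular — leaves *epigenomic footprints*:
combinations of histone-mark signal whose cell-type specificity can be
quantified without measuring transcription directly. `epifootprint` is a
tested, reusable implementation of that analysis for anyone working with
collections of reference epigenomes (per-sample histone-mark signal tracks,
chromatin-state segmentations, region annotations):

1. **Data slices** — for each of 5 core histone marks (H3K4me1, H3K4me3,
   H3K27me3, H3K9me3, H3K36me3) × 8 region-of-interest classes (lincRNA gene
   bodies and TSS windows, miRNA, gene bodies, exons, 3′UTRs, promoters,
   enhancers), a regions × samples matrix of base-pair-weighted mean signal,
   quantile-normalized between epigenomes.
2. **Tree concordance** — per slice, samples are clustered with
   1 − Pearson-r distance and average linkage (UPGMA). One replicate per
   sample is drawn at random, 50 rounds per combination, giving
   50 × 40 = 2,000 trees. The *confirmation score* of a clade is the fraction
   of all trees containing it; a tree scores the mean over its non-trivial
   clades; a mark–ROI combination scores the mean over its 50 trees. High
   scores flag the combinations whose footprints track cellular identity.
3. **Differential marking** — per region, per cluster, per mark, an
   empirical-Bayes moderated t test of in-cluster vs out-of-cluster samples
   (variance shrinkage across regions, BH FDR < 0.05), then regions are
   classified as uniquely marked (1 cluster), shared (2–3 clusters),
   nonspecifically marked (≥ 4) or unmarked.
4. **Footprint clustering** — multi-mark signal in 100-bp bins across 3-kb
   TSS windows (optionally concatenated over differentiation stages) is
   k-means clustered into footprint archetypes, with chromatin-state fold
   enrichment per cluster.
5. **State dynamics** — 15-state chromatin-state labels per TSS window and
   stage; 15 × 15 stage-to-stage transition matrices (row-normalized, edges
   > 30% reported) and Shannon entropy of the state distribution (all /
   Polycomb / non-Polycomb states) quantify the collapse of chromatin
   diversity during differentiation.
6. **Enrichment & annotation** — hypergeometric TF-binding-site enrichment
   against an all-factors background (≥ 1 bp overlap), basal-plus-extension
   region→gene association (5 kb up, 1 kb down, extension to the nearest
   neighbouring domain capped at 500 kb), nearest-TSS distance binning
   (< 5 kb / 5–50 kb / 50–500 kb) and per-cluster expression summaries.

A planted-truth synthetic-data generator (`epifootprint.synthetic_data`)
produces inputs with the statistical structure the analysis assumes —
clustered samples with replicates, cluster-specific mark elevation,
multi-stage state trajectories, ROI-enriched TF site sets — so every stage is
testable end-to-end without any external data.

## Worked example

Simulate the small preset (3 sample clusters × 4 samples, 2 replicates each,
a 2 × 10 Mb toy genome, H3K4me1-at-lincRNA-TSS planted as the informative
combination) and run every stage:

```bash
epifootprint simulate --seed 7 --out-dir sim
epifootprint all --config sim/run.yaml --out-dir results
```

`results/confirmation_scores.tsv` then starts with:

```
mark      roi_class    score     score_1dp
H3K4me1   lincRNA_TSS  0.037367  0.0
H3K4me1   3UTR         0.035747  0.0
```

The planted combination tops the ranking: its cluster clades recur in all of
its 50 trees while every other combination produces only noise topologies.
(Absolute scores are small at desk scale because the pooled denominator spans
all 2,000 trees and only one combination carries signal.)
`results/entropy_report.tsv` shows the entropy collapse along the simulated
differentiation axis:

```
stage   H_all_bits  H_polycomb_bits  H_nonpolycomb_bits
ESC     2.171       1.837            0.000
HSC     1.871       0.845            0.918
TCell   1.406       0.000            0.937
```

and `results/specificity_summary.tsv` reports, per ROI class, the percentage
of regions marked uniquely / in 2–3 clusters / nonspecifically, under both
denominators (all regions, and regions marked anywhere).

The same analyses are available as library calls; see the module docstrings
in `src/epifootprint/`.

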