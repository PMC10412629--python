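# Methods

## Scope and model

`k9dyn` covers the downstream analysis of stage-resolved H3K9me3
profiles in SCNT versus fertilized mouse embryos: everything from
called peak sets and count matrices onward. Read processing, alignment,
peak calling and track generation are upstream inputs and out of scope.

### Window signal

Peak sets are merged (touching intervals joined) and tiled left-to-
right into 1-kb windows; a final remainder window shorter than 1 kb is
kept so that tiling conserves covered bases exactly — RPKM
normalization removes the length bias of remainder windows. The window
signal is `log2((ChIP_RPKM + p)/(Input_RPKM + p))` with pseudocount
p = 1 applied at the ratio level (to the RPKM values, not raw counts).
All coordinates are 0-based half-open (BED convention); chromosome
names are matched as exact strings.

A region is *marked* by a peak set when some peak overlaps it by at
least half of the region's length **or** at least half of the peak's
length (the reciprocal `-f 0.5 -e -r` semantics). A window is *present*
at a stage when ≥ 50% of its bases are covered by that stage's merged
peaks; presence can alternatively be called from replicate-averaged
signal against a threshold midway between the expected background and
enriched signal levels.

### Reprogramming classification

Windows are classified over the ordered stages CC, 6 hpa, 14 hpa, 2C.
Transitions per consecutive pair follow the truth table
(0,1)=de novo, (1,1)=inherited, (1,0)=erased, (0,0)=absent; labels
partition the windows. The reprogrammed/unreprogrammed call walks
CC-present windows in stage order: loss by 6 hpa → `rpg_6hpa`; loss by
14 hpa → `rpg_14hpa`; retention at 14 hpa → `unrpg_14hpa`, plus
`unrpg_2C` when still present at 2C (the two unreprogrammed labels may
co-occur; the rpg and unrpg families are disjoint). Patterns that
regain presence after a loss satisfy neither definition and are
isolated as `re_established` rather than silently assigned; all 16
presence patterns are frozen against an enumerated decision table in
the tests.

High-CpG promoters are operationalized as promoters (TSS ± 1 kb,
strand-independent, clipped at the chromosome start) marked by the
CpG-island set; the CpG-bias table reports de novo counts and
percentages within each CpG class at one-decimal rounding.

### ZGA cascade

Counts are normalized by median-of-ratios size factors (geometric-mean
pseudo-reference over genes positive in every sample; raw medians
kept). The cascade over fertilized stages oocyte → PN5 → E2C → L2C →
4C is sequential and mutually exclusive, with strict inequalities:

1. oocyte mean > 50 normalized counts → maternal (excluded);
2. PN5 or E2C mean > 100, fold > 2 vs oocyte, q < 0.01 → minor ZGA;
3. remaining genes meeting the same gates at L2C → major ZGA;
4. similarly at 4C → MGA; otherwise none.

q-values come from a negative-binomial Wald test: per-gene dispersion
is moment-estimated per group, pooled, and floored at 0.01; the test
statistic is the log2 fold change of normalized group means
(pseudocount 1) over its delta-method standard error, with BH
adjustment across genes. This is a deliberately simple, documented
stand-in for a full shrinkage-based differential-expression fit —
adequate for gate decisions at the simulated effect sizes, but exact
genome-scale gene counts from shrinkage-based tools are not a target.

Activation degree uses the fertilized/SCNT fold change
`(mean_fert + 1)/(mean_scnt + 1)` at each class's defining stage
(minor: E2C, major: L2C, MGA: 4C — matched-stage comparison): > 4
restricted, < 2 full, otherwise partial. Threshold values refer to
replicate-mean normalized counts.

Repeat families condense per-copy values either by summing counts and
re-normalizing to RPKM over the summed copy length (expression) or by
averaging per-copy levels over the copy number (methylation).

### Lineage-specific domains and rescue

The merged ICM/TE domain signal matrix (domains × samples) is column-
centered and decomposed by SVD with domains as observations. Domains
with |score| > 3 on PC1 or PC2 are selected; each component's sign is
fixed by forcing its largest-magnitude loading positive, making the
selection deterministic. A loading-magnitude threshold of 3 cannot
apply to unit-norm loadings, so the threshold is interpreted on the
per-domain PC scores; it is configurable. Selected domains are
partitioned by k-means (k = 7, k-means++ with 10 restarts, Euclidean
distance on the raw log2 signals, fixed seed).

The rescue statistic averages replicates per condition and lineage,
then computes per-domain Euclidean distances in (ICM, TE) space:
A = ‖SCNT − fert‖, B = ‖OE − fert‖, C = ‖OE − SCNT‖. `repaired` iff
A > B; `rescued` iff repaired and `log2((B + ε)/(C + ε)) < 1` with
ε = 1e-9 (a domain where OE coincides with both endpoints counts as
rescued). `rescued ⊆ repaired` and |A − B| ≤ C ≤ A + B hold by
construction and are tested.

Sample relatedness uses average-linkage hierarchical clustering on
1 − Pearson distance between sample columns, exported as Newick with
ultrametric branch lengths.

### Enrichment statistics

TF-site enrichment tests, per factor, the 2×2 table
`[[k_fert, N_fert − k_fert], [k_scnt, N_scnt − k_scnt]]` where k is
the number of regions of each lineage-specific set overlapped
(reciprocal-50%) by the factor's sites; two-sided Fisher's exact by the
probability-mass rule, BH across factors. The reported fold change is
`log2(((k_fert+1)/N_fert)/((k_scnt+1)/N_scnt))`; the +1 smoothing
enters only the fold change, never the test. ICM and TE are analysed
as separate invocations. Dunn's post hoc after Kruskal–Wallis uses
z-tests on pooled mean ranks with tie-corrected variance and BH
adjustment (the correction method for Dunn is a package choice).
Rank-sum tests are exact below 25 values per group (without ties) and
use the continuity-corrected normal approximation otherwise. Replicate
QC computes pairwise Pearson correlations per (condition, stage,
lineage) over the peak windows and flags pairs below r = 0.90.

## Synthetic cohort

The generator plants ground truth deterministically — each category's
labels go to the first ⌊f·n⌋ entries of a seed-shuffled index list, so
planted fractions are realized as exact counts — and puts noise only in
the observed values. One root seed spawns a keyed substream per
artifact (epigenome, expression, rescue, TF sites), so adding an
artifact never perturbs existing ones; identical seeds give
bit-identical outputs, and writers round to 6 decimals.

Default scale (chosen so the full pipeline runs in about a second):
2 chromosomes × 10 Mb, 5,000 1-kb windows with 2 replicates per stage,
2,000 genes with 3 replicates per stage, 600 blastocyst domains,
20 TF factors (5 enriched).

- **Epigenome**: window classes (rpg_6hpa 25%, rpg_14hpa 15%,
  unrpg_14hpa 10%, unrpg_2C 15%, re_established 5%, never_marked 30%)
  fix the presence pattern over CC/6 hpa/14 hpa/2C; signals are
  N(2.5, sd) where present and N(0, sd) where absent, per replicate.
  The default sd = 0.3 is calibrated so replicate Pearson correlations
  over peak windows land above the 0.90 QC level the real assay
  exhibits (at sd = 0.3 the worst stage gives r ≈ 0.92). Signals are
  stored as ChIP/Input RPKM pairs realizing the drawn value exactly
  (Input fixed at 3 RPKM; a draw below −2 would clip at ChIP = 0, with
  negligible probability at the default sd).
- **Expression**: fertilized per-class stage means (e.g. minor ZGA:
  oocyte 5, PN5/E2C 400; maternal: oocyte 500; MGA: L2C 60, 4C 500)
  keep ≥ 3σ margins from every cascade gate at NB dispersion 0.05 with
  3 replicates. SCNT means divide the fertilized means from the
  defining stage onward by 10 / 3 / 1.2 for planted restricted /
  partial / full degrees. At dispersion 0 counts equal the rounded
  means.
- **Rescue**: fertilized domains are lineage-specific — (4, 0) or
  (0, 4) in (ICM, TE) log2-ratio space — and SCNT sits at the
  indistinct midpoint (2, 2). OE is placed at the fertilized point
  (planted rescued, 33%), 20% of the way from SCNT toward fertilized
  (repaired-not-rescued, 40%; log2(B/C) = 2), or 30% beyond SCNT away
  from fertilized (not repaired, 27%). The high signal of 4 and the
  0.2 step give ≥ 2.7σ margins on both decision boundaries at the
  replicate noise sd = 0.15 with 2 replicates, so recovered fractions
  stay within ±3 percentage points of the planted 73% repaired / 33%
  rescued.
- **TF sites**: enriched factors hit fertilized-specific regions at
  rate 0.5 and SCNT-specific at 0.05; null factors at 0.05 in both. A
  hit drops a 200-bp site at the region midpoint, so overlap counts
  are exact binomials.

What the generator does **not** model: GC/mappability bias, read-level
sampling, spatial autocorrelation of signal along the chromosome,
library-composition effects beyond global size factors, dispersion
trends across the mean, and partially overlapping peak boundaries.
Passing recovery tests therefore demonstrate that the classifiers
implement their definitions correctly and are robust to i.i.d. noise
at realistic levels — not that they are robust to every artefact of
real ChIP data.

## Numerical choices and degenerate inputs

- Thresholds are strict inequalities exactly as stated (> 50, > 100,
  > 2-fold, q < 0.01, > 4, < 2, |score| > 3, log2(B/C) < 1).
- Merge/tiling are exact integer arithmetic; the marked predicate uses
  `≥` on half-lengths.
- All-zero genes get p = 1, log2FC = 0; zero-variance correlation and
  empty region sets raise errors rather than returning NaN silently.
- An all-identical pooled sample gives Kruskal–Wallis H = 0, p = 1 and
  no Dunn pairs.
- A zero-variance domain matrix yields empty PCA selection.
- k-means requires n ≥ k and is deterministic under the seed.

## Problem sizes

The default test suite and the acceptance script run the cohort at the
default scale above (5,000 windows / 2,000 genes / 600 domains /
20 factors, plus a 50-seed null-enrichment replication at reduced
size); the whole suite completes in a few seconds.

## Known limitations

- The NB Wald stand-in lacks dispersion shrinkage and outlier
  handling; q-values near the decision boundary can differ from
  shrinkage-based tools on real data.
- The Fisher enrichment compares fertilized-specific vs SCNT-specific
  overlap proportions; a set-vs-genome-background variant is a
  different (computable) contrast and not the default.
- Degree classification compares fertilized and SCNT at the matched
  defining stage; pooled-stage comparison is not implemented.
- The PCA score threshold of 3 is scale-dependent (log2-ratio units);
  matrices on other scales need a rescaled threshold.
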