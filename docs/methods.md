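# Methods

`cnafid` quantifies how faithfully patient-derived xenografts (PDX)
conserve the somatic copy-number landscape of their originating patient
tumors (PT) across engraftment, serial passaging and lineage splits. This
note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Segment conventions and preparation

The universal currency is a segment profile: per sample, genomic segments
annotated with log2[copy-number ratio] (log2 of total copy number over the
sample baseline; 0 = neutral). Internally all coordinates are 0-based
half-open; the common SEG dialect (1-based inclusive) is converted on
input. Chromosome names are "chr"-less; Y and the mitochondrial contig are
dropped everywhere, X is retained for DNA profiles (it enters pairwise
correlations by default; a flag excludes it) and excluded from
expression-based inference.

Preparation steps, in order:

* **Filtering.** Segments shorter than 1 kb are removed on every platform
  (below the conventional CNA size definition). SNP-array segments must
  additionally be covered by more than ten probes at an average density of
  at least one probe per 5 kb — sparse-probe segments are unreliable.
* **Median re-centering.** Each profile is binned into 10-kb windows and
  the median window value is subtracted, so that profiles are comparable
  across samples regardless of the caller's baseline. Centering
  approximates normalization by sample ploidy but, by construction, cannot
  detect genome-wide ploidy multiplication; all downstream statistics
  share this blind spot.
* **Window binning.** Fixed-width windows (100 kb by default) take the
  value of the overlapping segment with the *largest overlap*; ties go to
  the leftmost segment. The rule is deterministic and
  resolution-preserving; windows with no overlapping segment are absent
  rather than imputed.
* **Gene-level values.** A gene overlapping several segments takes the
  *minimum* log2 ratio — the most conservative estimate for the intact
  gene. Genes overlapping no segment are absent.
* **Aberration level.** Per profile, the 5–95% inter-percentile range
  (IPR) of binned values summarizes how aberrant the genome is; IPR < 0.3
  marks a non-aberrant (genomically quiet) profile. The IPR is preferred
  over variance because a few extreme focal events inflate variance while
  leaving 90% of the genome untouched.
* **Gain/loss labels** use strict thresholds (> 0.1 gain, < −0.1 loss) on
  centered values; descriptive segment-size statistics use the inclusive
  |log2| ≥ 0.1 convention. Both conventions exist in the field; the
  package keeps them where each is standard.

## Pairwise concordance model

Two samples of the same model are compared by ordinary least squares of
gene-level log2 ratios, target on reference:

    y_g = β0 + β1 x_g + ε_g

The regression — rather than thresholded gain/loss calls — absorbs the
systematic differences between samples (centering offsets, stromal
dilution of amplitude, platform dynamic range), so residuals measure
genuine per-gene divergence. Conventions:

* **Orientation.** The reference (predictor) is the PT in PT–PDX pairs,
  the lower-passage sample in PDX–PDX pairs, the first-listed sample
  otherwise. Fixing orientation makes residuals reproducible; the
  asymmetry of the regression is deliberate and tested.
* **Deletion floor.** Values below −3 are rescaled to −3 before fitting;
  extremely negative log values otherwise dominate the fit and the
  correlation.
* **Improved fit.** Genes with |externally studentized residual| > 3 under
  the initial fit are removed and the model refit. Externally studentized
  means the leave-one-out form, computed in closed form
  (r_i/(s_(i)·√(1−h_i)) via t_i = r_i·√((n−p−1)/(n−p−r_i²)), p = 2) and
  verified in the test suite against brute-force leave-one-out refits.
* **Altered genes.** Genes with |raw residual| (log2 units) from the
  improved fit above a threshold: 0.5 by default — low enough to include
  subclonal changes — or 1.0 for the recurrence analysis, where only
  changes with likely functional impact should count. At the 1.0
  threshold, genes at or below the floor in *both* samples are omitted:
  a residual between two saturated values carries no dosage information.
* **Pair validity.** A pair is omitted when its low correlation (< 0.6) is
  explained by a non-aberrant sample (IPR < 0.3): correlation is
  meaningless for a flat profile. A pair is *highly discordant* when both
  samples are clearly aberrant (IPR > 0.5) yet r < 0.6. Samples whose low
  intra-model correlation coincides with r > 0.9 against another model are
  reported as mislabeling candidates, never silently dropped.
* **Range ratio.** The ratio of IPRs (PT in the numerator for PT–PDX
  pairs) measures amplitude dilution; stromal DNA in the PT compresses its
  log-ratio range, so PT/PDX ratios below 1 are the signature of stromal
  contamination rather than genomic divergence.

Cross-platform comparisons of the same tumor run the same regression on
shared 100-kb windows; outlier windows (|studentized residual| > 3) are
mapped back to their source segments to size the discordant events, and
the discordant genome fraction is the outlier-window share of the shared
windows.

Group comparisons (pair types, lineage relations, passage bins,
mutation-status strata) use the Wilcoxon rank-sum test (one- or two-sided
as appropriate) or Kolmogorov–Smirnov for distribution shape; all-tied
degenerate input returns p = 1 with a warning.

## Recurrence, gene sets, drug screen

Recurrence counting is on a *model basis*: a gene altered (|residual| >
1.0) in any pair of a model contributes once to that model, and the
frequency denominator is the number of models contributing at least one
valid pair of the comparison type. This prevents models with many similar
samples from dominating, and avoids deflating frequencies with models
that could not be evaluated.

Gene-set burden: per pair, the proportion of a set's (universe-resolved)
members altered at the 0.5 threshold, compared across pairs against the
protein-coding background proportion by a one-sided rank-sum test.

The drug screen correlates gene-level copy number with drug sensitivity
(AUC) across cell lines, Bonferroni-corrects over the full gene × drug
family (q = p × n_tests, capped at 1; family size is a documented choice),
keeps associations at q < 0.1, and calls them significant only when the
gene's *expression* also correlates with AUC at nominal p < 0.05 in the
same direction — dosage without an expression echo is not considered
actionable. The expression threshold is configurable.

## Expression-based inference (e-karyotyping + PCF)

Chromosomal dosage leaves a footprint in expression along genomic
coordinates. Preprocessing (in order): drop sex-chromosome genes; remove
genes below the floor (1 TPM for RNA-seq, log2 intensity 6 for arrays) in
more than 20% of samples and raise remaining sub-floor values to the
floor; collapse multiple transcripts/probesets per gene to the one with
the highest median across the dataset; remove the 10% most variable genes
(sum of squared deviations from the gene's cross-sample median), since
dosage-unrelated variability masquerades as CNA; then express each tumor
relative to the per-gene median of matched normals (NORM) or of the tumor
cohort itself (TUM, for tumor-only datasets). The variable-gene removal
runs after transcript collapsing.

Segmentation is an exact penalized piecewise-constant fit per chromosome:
minimize Σ within-segment squared error + λ × (number of breakpoints),
solved by the optimal-partitioning dynamic program (O(n²), exact; the
test suite checks it against exhaustive enumeration). Parameters: λ = 12
on MAD-standardized values (standardization makes the penalty comparable
across samples); winsorization at quantile 0.001 first; a segment is
*called* gain/loss only when it has ≥ 30 genes, |mean| ≥ 0.25 (original
scale) and its mean differs from 0 at level 0.01 (two-sided t-test). The
external tool this protocol descends from does not publish its internal
segmentation variant, so this parameter mapping — penalty as a breakpoint
penalty, minimum aberration size as a call requirement rather than a hard
segmentation constraint, threshold as a significance level — is an
approximation and should be read as such.

Calls are bridged back into genomic segments (first-gene start to
last-gene end, clipped to avoid overlap) so expression-inferred profiles
flow through the same comparison machinery as DNA profiles.

## Cohort G scores, rescaling, ΔG and GSEA

Per 100-kb window, the amplification G score is the mean over samples of
max(log2 − t, 0) with event threshold t = 0.1 (frequency × average excess
amplitude in one expression); deletions analogously on −log2. Genes take
the value of the covering bin with the largest overlap. This simplified
score deliberately replaces the full GISTIC background model and peel-off:
the cohort-shift analyses only need G tracks that are *comparable across
cohorts*, not peak calling. Externally produced gene-level G scores can be
imported to run the same downstream analyses.

Significance is empirical: each sample's window vector is cyclically
shifted by a random offset (preserving its amplitude spectrum and segment
structure while destroying positional recurrence), the null G pool is
accumulated over permutations, and per-gene Benjamini–Hochberg q-values
at q < 0.25 mark significant genes.

Stromal DNA dilutes PT amplitudes, so PT cohorts have systematically
compressed G ranges. PDX cohorts are therefore mapped onto the PT scale by
global linear regression of PDX gene-level G on PT gene-level G (amp and
del tracks separately): scaled G = (G − intercept)/slope. Rescaled values
are left unclipped — they can dip marginally below zero — because
clipping would break the idempotence of rescaling; the non-negativity of
G scores applies to scores as computed, not after the affine map.

ΔG vectors (PT→PDX-early, PDX-early→PDX-late) and their correlation probe
progressive, selection-like shifts. One estimator caveat, reproduced and
isolated by the simulator: the middle cohort appears in both ΔG vectors
with opposite signs, so its *measurement* noise induces a structurally
negative correlation even under fully neutral drift. The package's
simulation studies therefore report both the paper-style statistic (at
most slightly negative under neutrality) and a noise-isolated version
computed from an independent re-rendering of the middle cohort (≈ 0 under
neutrality). On real data only the former is computable; its negative bias
means observed near-zero or slightly negative correlations are consistent
with no PDX-specific selection, while only clearly *positive* correlations
would indicate progressive shifts.

Preranked GSEA runs on gene-level G scores: weighted Kolmogorov–Smirnov
enrichment score (weight exponent 1, streaming implementation verified
against the naive running sum), NES by gene-label permutation, FDR from
the pooled normalized permutation null. One extra filter guards against a
genomics-specific artifact: contiguous genes inside a single recurrent
amplicon produce spurious enrichment for positionally clustered gene
sets. A set is accepted only when NES > 1.5, FDR q < 0.05, *and* the
leading-edge genes that are individually significant (G-score q < 0.25)
make up at least 20% of the set.

## The synthetic-data generator

The generator produces ground-truthed cohorts with the statistical
structure the analyses assume:

* **Clonal structure.** A founder clone carries Poisson-distributed
  segmental events (default 30 per full genome) with lengths log-uniform
  over 100 kb–50 Mb and amplitudes from {±0.3, ±0.58, ±1, −3} log2 units
  (one-copy gains/losses around diploid, single-copy steps at tetraploid
  resolution, deep deletion); a minor subclone (default 30% of cells)
  carries additional private events. A small pool of cohort-shared
  ("recurrent") events is carried by 80% of models — needed for any
  analysis that relies on cross-model recurrence.
* **Bulk profiles.** Bulk linear copy number is 2·(1 + Σ f_e(2^a_e − 1))
  over covering events (each event multiplies CN by 2^a in the cells
  carrying it, cellular fraction f_e), floored at 0.05.
* **Lineage tree.** PT → P0 → P1 → P2; each passage adds Poisson(2)
  subclonal drift events with cellular fraction uniform on [0.2, 1]
  (subclonal drift attenuates observable amplitudes, which is what the
  0.5 altered-gene threshold is designed to catch). At the split passage
  the line branches into an independent lineage, so different-lineage
  pairs accumulate roughly twice the drift of equal-distance same-lineage
  pairs.
* **Stroma.** Observed linear CN = (1−f)·CN_tumor + 2f — mixing happens on
  the linear copy scale, then the log is taken (physically correct). PT
  stromal fraction ~ Beta(2, 3) (mean 0.4, the regime that reproduces
  PT/PDX range-ratio medians near 0.6–0.8); PDX samples carry a 5%
  residue.
* **Platform rendering.** Segments below the platform resolution floor
  (SNP 50 kb, WGS 200 kb, WES 1 Mb) are merged into their longer
  neighbor; Gaussian noise (σ 0.05/0.08/0.15) is added per segment mean;
  log2 ratios are clipped to platform dynamic ranges; SNP profiles carry
  probe counts at ~1 probe / 2 kb.
* **Expression.** Tumor log2 expression = per-gene baseline (Normal(5,
  1.5) log2 TPM) + true gene log2 ratio + Normal(0, 0.5) noise; normals
  carry baseline + noise. A configurable 30% of genes are decoupled from
  dosage, emulating the limited fidelity of expression-based inference.

**Scaled miniature.** Tests and the acceptance script run on a ~300 Mb,
8-chromosome genome. The miniature scales event lengths down by the
genome ratio (10 kb–5 Mb) and counts up (120 clonal / 30 subclonal) so the
aberrant genome fraction (~40%) and per-profile statistics match the
full-size configuration; without length scaling a single event could span
17% of the genome and distort centering medians.

**Per-study conditions.** Like any study design, each simulation study
uses conditions matched to the question: the altered-gene recovery study
uses clonal ±1 events (so ground-truth alteration is unambiguous at the
|Δ| ≥ 0.8 definition) under σ = 0.1 gene-level noise; the
expression-calibration study uses chromosome-arm-scale events (2–30 Mb),
because a segmenter requiring ≥ 30 consecutive genes cannot see
sub-megabase focal events by design; the G-score trio study uses WGS-only
cohorts, the platform on which such trio analyses are run in practice.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: whole-genome doubling and ploidy shifts
(invisible to median centering by construction), allele-specific copy
number, breakpoint reuse and chromothripsis-like clustering, realistic
gene-density variation, selection (drift is strictly neutral), batch
effects between centers, and the error structure of real upstream CNA
callers beyond additive segment noise.

## Numerical choices and degenerate inputs

* Window/gene assignment ties always resolve to the leftmost candidate.
* Zero-variance profiles make correlation undefined: pairs are flagged
  invalid rather than erroring.
* Constant expression profiles have MAD 0; the PCF scale falls back to the
  standard deviation and then to 1, so constant input yields one neutral
  segment rather than a division blow-up.
* All simulation randomness flows from explicit seeds through
  `numpy.random.default_rng`; fixed seeds reproduce cohorts bit-for-bit.
* Bonferroni q-values are capped at 1; permutation p-values use the
  (1 + k)/(1 + n) form so they are never exactly 0.

## Known limitations

* The simplified G score has no arm-level/focal decomposition and no
  peak calling; it is built for cross-cohort comparison, not for
  nominating driver loci.
* The PCF parameter mapping is an approximation of an unpublished
  segmentation variant (see above).
* The recurrence denominator convention (models with ≥ 1 valid pair)
  differs from dividing by all models; frequencies are not comparable
  across studies using the other convention.
* Mutation status, tumor-type ontology and gene-set curation are consumed
  as user-supplied labels/files; the package does not derive them.
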