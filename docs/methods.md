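# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical choices that affect results.

## Translational efficiency and its contrasts

TE of a gene in one (genotype, condition, replicate) cell is
(RPF count / RPF size factor) / (RNA count / RNA size factor), with counts
taken over the CDS span. By default mRNA reads are also counted over the CDS
span so numerator and denominator cover the same region; a configuration
switch (`te_cds_only=False`) accepts whole-transcript mRNA counts where a
caller supplies them. Genes with a zero RNA count in any contrasted sample
are excluded (reason `zero_rna`) rather than pseudocounted, keeping TE
well-defined; `te_pseudocount` enables a sensitivity analysis. Genes whose
RPF counts are all zero in one cell are excluded as `zero_rpf` (their log
fold-change is unbounded).

A TE change between two cells is estimated per gene by a log-link
negative-binomial GLM on raw counts over the eight libraries of the two
cells (two assays × two cells × two replicates):

    log mu_ij = log s_j + b0 + b1*[RPF] + b2*[numerator cell] + b3*[RPF x numerator]

`b3` is the log TE ratio (reported as log2), tested with a Wald z against
the standard normal, and BH-adjusted across tested genes. The design is
saturated (four group means), so the point estimate equals the
size-factor-weighted ratio of ratios of group means; the NB machinery
supplies the standard error. An exact permutation alternative
(`method="perm"`) re-assigns samples to cells within each assay (36
relabelings for 2+2 replicates) and is useful for validating the Wald
calibration on small fixtures; with only two replicates per cell its
resolution is limited (minimum two-sided p of 1/36, and coarser when one
assay is uninformative).

The interaction model is one of two defensible readings of a "change in TE"
test (the other being a ratio-of-ratios Wald on precomputed TE values); the
interaction form is used throughout and surfaced in the results object.

### Size factors

Median-of-ratios per assay: for genes with all-positive counts, each
library's counts are divided by the gene's geometric mean across that
assay's libraries; the library factor is the median of those ratios,
rescaled to geometric mean 1. RPF and RNA libraries are normalized
separately (their size factors cancel pairwise in the interaction, so the
split only affects reported per-sample TE values, not contrasts).

### Dispersion

With two replicates per cell a gene contributes four residual degrees of
freedom, far too few for stable gene-wise dispersion estimates, so an
empirical-Bayes device is used:

1. gene-wise method-of-moments estimate pooled over the four assay × cell
   groups: alpha_g = sum(var - mean) / sum(mean^2);
2. a parametric mean–dispersion trend a0 + a1/mean fitted by non-negative
   least squares across genes;
3. shrinkage of the gene-wise estimate toward the trend. The default weight
   is `"auto"`: per gene, w = V_samp / (V_samp + V_prior), where V_samp is
   the analytic sampling variance of the moment estimator evaluated on the
   trend and V_prior is the excess spread of the gene-wise estimates across
   genes. When the data are consistent with a shared dispersion (as in the
   synthetic fixtures) the auto weight approaches 1 and the trend value is
   used, which keeps the Wald z calibrated; genuinely heterogeneous
   dispersions keep gene-wise information. A fixed numeric weight (e.g.
   0.5) can be set via `AnalysisConfig.dispersion_shrink`; in calibration
   experiments on null simulations the fixed weight leaves enough
   estimation noise in the standard errors to inflate the extreme p-value
   tail roughly two-fold, which is why auto is the default.

Dispersions are clipped to [1e-8, 10]. No independent filtering or outlier
replacement is performed — a deliberate simplification relative to the
fuller empirical-Bayes pipelines used for genome-scale data.

## uORF relative ribosome occupancy

RRO is a within-library count ratio (uORF RPF / host CDS RPF), so no size
factors enter the per-sample values. The count filters take "mean RPF counts
in the combined samples" as the arithmetic mean of raw counts over all
samples entering the comparison (four libraries for a 2-vs-2 contrast);
`low_uorf` (mean uORF RPF < 2) takes precedence over `low_cds`
(mean CDS RPF < 32), and the two filters plus `pass` are exhaustive and
mutually exclusive. Whether the published filters used raw or normalized
means is not stated; raw is assumed since the ratio itself is raw.

Differential RRO reuses the interaction GLM with (uORF count, CDS count)
playing the roles of (RPF, RNA) and unit size factors (depth cancels within
a library). Group TE summaries use the two-sided Mann–Whitney U test
against all tested mRNAs including the group, matching the convention of
comparing a group to "all mRNAs"; a disjoint-background option exists.

## Pause scores

Footprint 3′-end counts are shifted 18 nt upstream (`shift_nt`), placing the
first codon of a tripeptide in the E site and the third in the A site.
For the tripeptide at codon k the 9-nt span starts at `cds_start + 3k`;
occurrences whose ±50-nt (`window_nt`) flanks would leave the CDS are
excluded. The numerator is the mean rpm over the whole 9-nt span (an
A-site-codon-only mode exists, `pause_numerator="a_site"`); the background
is the mean rpm of the flanks with the motif span excluded by default
(including it attenuates large pauses; both choices are configuration
switches because either convention appears in the field). Occurrences with
a zero flank mean are skipped and counted, not scored as infinite. A
motif's mean score averages its surviving occurrences; motifs with fewer
than 100 window-safe occurrences across annotated CDSs (not raw genomic
k-mer counts) are flagged `included=False`.

Two exact invariants hold and are tested: a flat track gives every score 1
(to float precision), and scores are invariant to any global rescaling of
the track.

## Conditional-dependence classifier

The diagnostic pattern is operationalized as explicit thresholds on the four
contrasts c1 = mutant/WT under SM, c2 = SM/untreated in the mutant,
c3 = SM/untreated in WT, c4 = mutant/WT untreated:

    conditional_dependent  iff  c1 <= -0.5, c2 <= -0.5, c3 >= -0.25, c4 >= -0.25, and q1 < 0.25

The original gene set was picked by heat-map inspection; fixed thresholds
make the rule reproducible and monotone (strengthening the pattern never
un-labels a gene). The FDR gate applies only to the discovery contrast c1,
mirroring how the candidate set was defined. The overlap of the labelled
set with uORF gene sets is tested with a one-sided hypergeometric upper
tail over the translated-mRNA universe; with the published set sizes
(17 drawn, 514 successes, universe 5482, overlap 3) this gives p = 0.209,
matching the printed two-decimal value, which is why the hypergeometric
form was adopted for the unnamed test.

## Polysome-gradient TE reconstruction

Per pooled fraction i with ribosome weight r_i (1 for 80S, 2 for disomes, …):

    a_i = 2^-(CT_target - CT_18S)                 (18S-relative abundance)
          * (pooled volume / 300 uL) * (25 uL / RT-input volume)
          * (A260 share of fraction / 18S share of fraction)
          * (mean mono+poly A260 across gradients / this gradient's total)

    TE  = sum_i r_i a_i / (input_target / input_ACT1)

The 2^-CT method is read as 2^-ΔCT against 18S measured in the same
fraction (a raw mode exists for sensitivity checks). The 18S share is
computed from the volume-corrected 2^-CT(18S) amounts, which makes the
recovery factor self-consistent with the qPCR measurements. The two volume
corrections are applied literally as stated, and both factors are available
per fraction for auditing, because they would double-count if the
extraction aliquot equalled the pooled volume. Input abundances carry the
1/5-of-extract scale, which cancels in the ACT1 ratio. Missing CTs exclude
the affected fraction with a warning rather than voiding the gradient; a
missing input CT voids only that target's estimate.

ΔTE summaries pair TE(+SM)/TE(−SM) within replicate index and compare the
two strains' ratio sets with a two-sided Welch t-test (the unequal-variance
form is the safer default when only "Student's t-test" is specified);
degenerate identical samples return p = 1.

## Synthetic data: what it emulates, and what it does not

- **Counts.** RNA counts are NB with variance μ + αμ²; RPF counts multiply
  in the cell's TE, composed from factorial log2 effects (genotype,
  condition, interaction) relative to untreated WT. A dispersion of exactly
  0 is implemented as the deterministic limit (counts = rounded means) so
  that zero-noise fixtures are exact oracles. uORF counts are separate NB
  draws with mean true_rro × the host's RPF mean, keeping RRO ground truth
  exact rather than carving reads out of CDS counts. The factorial truth
  model implies c1 − c4 = c2 − c3 across the four contrasts; planted
  conditional profiles therefore use interaction −1 (c1 = c2 = −1,
  c3 = c4 = 0).
- **Tracks.** Uniform density within each CDS (weighted by gene abundance),
  multiplied by the pause factor over planted motif spans, multinomially
  sampled to the requested depth (or returned exactly).
- **Gradients.** CT values are back-computed through the exact inverse of
  the reconstruction chain under mass conservation (ACT1-normalized input
  equals the summed target across fractions), so the true TE must lie in
  [1, max ribosome weight] and is recovered to < 1e-9 relative error at
  zero noise. Gaussian CT noise is added to target CTs only (reference
  measurements are treated as noiseless).

Not emulated: raw reads and alignment artifacts, positional biases along
CDSs (ramps, codon-level dwell variation beyond planted motifs), uORF reads
overlapping CDS starts, mRNA isoforms, batch effects, or primer-efficiency
deviations in qPCR. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to those
artifacts.

### Simulation sizes and noise levels

Chosen once as the package's standard study conditions:

- Null/FDR calibration: 2000 genes, base mean 200, dispersion 0.05, two
  replicates per cell (dispersion 0.05 is a conservative replicate-quality
  assumption for a null stress test).
- Effect recovery: 500 genes at 1e5 expected reads per gene region,
  dispersion 0.002, effects N(0, 0.5²); power read off genes with
  |log2ΔTE| ≥ 1. The low dispersion reflects the near-technical agreement
  of high-quality yeast profiling replicates; with two replicates per cell
  the interaction SD is ≈ sqrt(2·(α + 1/μ))/ln2 log2 units, so recovery
  precision is dispersion-limited, not depth-limited, at this depth.
- Classifier: 2000 genes, base mean 2000, dispersion 0.002, 20 planted
  profiles at twice the thresholds.
- Pause: 100 genes of 200–400 codons, 150 planted PPG occurrences, 1e5
  reads.

## Numerical choices

- GLM fits: IRLS to tolerance 1e-10, ≤ 200 iterations; a moment fallback
  (ratio of group means, infinite SE) guards non-convergence.
- BH: step-up with explicit monotonicity enforcement; stable sort.
- Floats in result TSVs carry 6 significant digits (round-trip relative
  error < 1e-5).
- Tie handling in Mann–Whitney uses scipy's tie-corrected normal
  approximation (exact tails for small untied groups).
- Strict inequalities for fold selections (>1.41-fold means log2 effect
  strictly above log2 1.41).

## Known limitations

- P-site offsets are a single configurable constant, not calibrated per
  read length.
- The Wald test's normal reference is slightly anticonservative in extreme
  tails when dispersions are heterogeneous and replicates few; the
  permutation mode provides an exact but low-resolution check.
- Differential RRO treats uORF and CDS counts as independent NB draws; on
  real data they share a transcript and fragment-assignment boundary
  effects could correlate them.
- The polysome chain assumes equal mono+polysome content per A260 of input
  extract across strains, as the gradient-recovery normalization requires.
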