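# Methods

This note records the models, conventions and design choices behind each
stage of `hdquant`, and what the synthetic-data tests do and do not
establish about real data.

## Somatic instability indices

A capillary-electrophoresis trace of a PCR across an expanded CAG tract is
reduced to a peak table (fragment size in bp, height in arbitrary
fluorescence units). Fragment sizes are converted to integer repeat-unit
changes Δ relative to the inherited allele by
Δ = round((size − anchor_bp) / bp_per_repeat), with bp_per_repeat fixed at
3.0 and the anchor taken from the inherited-allele size measured in
tail/ear DNA. Peaks with height below a threshold fraction (default 0.10)
of the tallest peak are discarded, surviving heights are normalised to sum
to one, and

- expansion index = Σ_{Δ>0} w_Δ · Δ (≥ 0),
- contraction index = Σ_{Δ<0} w_Δ · Δ (≤ 0),
- instability index = expansion + contraction (an identity, exact by
  construction).

Choices the cited index procedure leaves open, and what this package does:

- **Threshold**: 0.10 of the tallest peak by default, exposed as a
  parameter, because sensitivity to it should be reportable.
- **Reference allele**: the inherited allele (not the modal somatic peak)
  anchors Δ = 0; a `reference="modal"` switch re-anchors to the tallest
  peak.
- **The inherited-allele peak is counted** in the normalising sum; no
  guard band around Δ = 0 is applied.
- **Stutter is not deconvolved**: stutter peaks passing the threshold
  contribute like any peak. The simulator quantifies the resulting bias
  (below).
- Peaks rounding to the same Δ are height-summed; a missing anchor peak
  (none within 1.5 bp) is flagged, not fatal.

**Peak calling.** Traces are lightly smoothed (Gaussian, 0.1 bp s.d. —
several-fold narrower than a peak) before local-maximum detection with a
prominence gate relative to the global maximum (default 5%); apex
positions come from quadratic interpolation on the smoothed trace, apex
heights from a local least-squares quadratic on the raw trace so narrow
peaks are not attenuated by the detection filter.

## Trace simulation

`simulate_fla` places one Gaussian peak (0.35 bp s.d.) per repeat-change
value, centred at inherited_bp + Δ·3 bp, with height proportional to the
probability mass of Δ; minus-one-repeat PCR stutter satellites carry a
configurable fraction (`stutter_decay`) of their parent's height, and
white noise is added per scan point. Ground-truth indices are the analytic
expectations over the Δ distribution, recorded before stutter and noise.

The stock mosaic cluster (`biased_delta_distribution`) is a discretised
Gaussian truncated at two standard deviations around its mean. Truncation
at 2 s.d. keeps every peak above 13.5% of the modal height — above the 10%
analysis threshold — so the noise-free height-weighted index equals the
distribution mean and recovery can be assessed against an exactly attained
target. Under 15%/unit stutter the index acquires a deterministic downward
bias of about s/(1+s) ≈ 0.13 repeat units (mass shifted one unit down and
renormalised); the recovery suite observes a mean absolute error of ≈ 0.13
at a baseline noise of 1% of the modal peak height, i.e. the error budget
is dominated by the un-deconvolved stutter, not by noise. Real traces add
size-calibration error, peak-shape asymmetry and heteroscedastic baselines
that the simulator does not model; noise parameters are free knobs, not
estimates of instrument behaviour.

## Marker selection and composition estimation

Single-cell counts are summed per annotated cell type (after merging fine
labels into coarse classes; the stock merge map pools dMSN/iMSN into MSN,
interneuron and progenitor subtypes into "other_neuron", and vascular/
ependymal types into "other"), separately per condition. A pseudocount
(default 1) is added to every gene and each column is scaled to one
million. No gene-length term is applied by default — the natural reading
for UMI counts — but supplying `gene_lengths` switches to classical
length-normalised TPM.

For each gene the reference-condition pseudobulk row is normalised to a
probability vector p over the N cell types, and

    H(p) = −Σ p_i log2 p_i,    s(p) = 1 − H(p)/log2 N,

so s = 1 for a perfectly type-restricted gene and s = 0 for uniform
expression. Markers for a cell type are genes whose argmax abundance
(home type, first-index tie-break) is that type, detected in every bulk
sample, with home expression ≥ 50 TPM (inclusive) and s > 0.40 (strict),
ranked by s descending with ties broken by home TPM then gene name, capped
at 20. A gene can mark only its home type, which prevents one gene serving
two panels.

Composition of a bulk library for cell type c is the mean over c's markers
of TPM divided by the marker's mean TPM across the reference-group
samples; reference samples therefore average to exactly 1. The estimator
is linear in mixture weight. Group summaries use two-sided t intervals on
per-sample composition values (n − 1 df; the study design has n = 3 per
group), with a CI-overlap flag against a designated reference group.

**Known bias.** With markers of finite specificity, depleting a cell type
to a fraction f of its reference share yields an expected composition
slightly above f, because a marker's non-home expression rises with the
compensating types. With the synthetic reference's ~30-fold markers
(home fraction ≈ 0.91), true f = 0.5 yields ≈ 0.56. This bleed-through is
a property of marker-panel composition estimation generally; panels of
more exclusive markers shrink it.

## DEG calling and set accounting

A gene is differentially expressed when |log2FC| > 0.5 **and** BH-adjusted
q < 0.05, both strict, so boundary values are not called. BH adjustment
(step-up, q_(i) = min_{j≥i} p_(j)·m/j capped at 1) runs over each
contrast's full p-value vector independently; genes with missing p are
excluded from m. DEG sets from two contrasts over a shared universe are
partitioned per direction into unique and shared components by exact set
algebra. Rescue of a fixed gene set is summarised by zero-centred
histograms (default bin width 0.25 log2 units) of log2FC against the
reference group, with mean |log2FC| as the distance-from-reference
statistic. The DE model fit itself is consumed as input; the bundled DE
simulator scores genes with a two-sample Welch t-test on Gaussian
log-expression — a calibration stand-in for generating p-values with known
ground truth, not a count-model DE engine.

## CAG-run scanning and enrichment

A run is the literal contiguous substring (CAG)^k at any offset; the
default call requires k ≥ 3, the shortest tract able to form a slipped
hairpin. Phase rotations (AGC/GCA) lacking the full 9-mer do not count, N
breaks runs, and the complementary CTG motif is only scanned behind
`both_strands`. Enrichment of runs among DEGs uses a two-sided Fisher's
exact test (probability-mass rule) on the DEG × CAG 2×2 table over the
scanned universe; the odds ratio reported is the sample odds ratio
(a·d)/(b·c), infinite when only b·c vanishes and undefined (NaN) when both
products do. The scanner takes whatever FASTA it is given; defining the
protein-coding sequence universe of a genome is out of scope, so genome-
level counts depend on the annotation supplied.

## Imaging metrics

The nuclear mRNA-retention score of a nucleus is
(nucleus intensity / nucleus area) / (image intensity / image area):
1 means the nucleus matches the image's baseline signal density, higher
values indicate nuclear accumulation. No background subtraction is
applied. Percent-positive metrics and nuclei densities are computed per
image, aggregated to per-mouse means, and summarised per group both over
images (the plotting unit in the source figures) and over mice (the
biological replicate); the package computes both and does not adjudicate
which is the independent unit. Aggregate/abnormal-envelope calls are
boolean inputs from upstream classification, never computed here.

## Association statistics

Pearson r with the two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df;
affine-invariant up to sign. The association table covers every
tissue × index × phenotype combination pairwise-complete, reporting n per
row and flagging untestable rows (n < 3 or zero variance); p-values are
unadjusted by default with an optional BH column.

Group comparisons of indices use a one-tailed Mann-Whitney U test. Without
ties the p-value is exact from the null U distribution (for n_a·n_b ≤ 400).
With ties, midranks are used and the exact permutation p is computed by
enumeration when feasible, applying the **mid-p rule**: assignments whose U
equals the observed value contribute half their mass. This removes the
conservativeness midrank ties otherwise induce and yields p = 0.5 for the
fully tied symmetric case. Larger tied problems fall back to the normal
approximation with tie-corrected variance and continuity correction. The
test direction must be stated; for treated-vs-vehicle instability the
conventional alternative is treated < vehicle.

## Problem sizes and reproducibility

Every generator takes an explicit seed and identical seed + config
reproduces output bit-for-bit; ground truths are stored alongside the data
and never recomputed from the noisy realisation. The test and acceptance
suites use: 100 traces per recovery sweep; a 600-gene × 4-type single-cell
reference with ~120 cells per type/condition; 50 bulk-mixture seeds at
n = 3 per group; 200 global-null DE replicates of 500 genes; 10⁴ nuclei per
retention check; and exhaustive Mann-Whitney enumeration for group sizes
≤ 8. These sizes give Monte-Carlo error comfortably below the tolerances
asserted.

## Limitations

Synthetic recovery shows the estimators are correct under their own
generative assumptions (Gaussian peaks, negative-binomial counts,
lognormal noise); it cannot validate upstream steps the package consumes
as input — fragment sizing, cell-type annotation, DE model fit, image
segmentation — nor the biological fidelity of those assumptions.
Reproducing the published marker panel or DEG totals requires the deposited
reference single-cell dataset and supplementary DE tables, which are
external inputs; the package reproduces the published set-accounting
arithmetic from the printed counts and validates every procedure against
simulation ground truth and independent oracles.
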