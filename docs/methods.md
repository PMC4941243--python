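# Methods

## Model and procedure

The package implements a mass-univariate genotype-by-diagnosis
interaction analysis of ALFF (amplitude of low-frequency fluctuations)
maps, followed by Monte-Carlo cluster-extent inference with a two-level
multiplicity correction and an ROI network analysis. The statistical
assumptions are the standard ones of SPM-style mass-univariate practice:
voxels are modelled independently, errors are Gaussian with pooled
variance across genotype×group cells (the "ANOVA" is realised as a
regression partial F — the original description gives no cell-means
detail, and the regression form is the standard operationalisation), and
cluster inference assumes a stationary Gaussian random field of known
smoothness.

### ALFF

The spectral dialect is FFT-centric: no taper, transform length equal to
the (post-discard) series length, band 0.01–0.08 Hz inclusive on both
edges, band-pass realised by selecting frequency bins. Per-bin amplitude
is `sqrt(2)·|X_k|/N`, so the squared one-sided amplitudes of a zero-mean
signal sum to its mean square (a Parseval identity the tests assert at
1e-8 relative). ALFF is the mean amplitude over band bins; it is
homogeneous of degree 1 in signal amplitude and invariant to linear
trends after detrending. Raw ALFF (not mALFF/zALFF) enters the GLM.

One caveat the tests document: with no taper, an off-bin out-of-band tone
leaks a few percent of *amplitude* into the band through the rectangular
window, although its band *energy* fraction stays below 1 %. Bin-aligned
tones show the clean ≤1 % amplitude rejection.

Smoothing order is ambiguous in common pipelines (smoothing is usually a
preprocessing step); the default here smooths the 4D data before ALFF
(the simulator does this), with `alff_smooth_fwhm_mm` available to smooth
the ALFF map instead.

### Interaction GLM

Design columns: intercept, group (0 control / 1 aMCI), age, gender
(0/1), education, genotype code (1 recessive or 2 genotypic columns),
and group×genotype product column(s); the grey-matter covariate is
voxelwise (each subject's GM probability at the voxel under test),
isolating functional effects not attributable to local anatomy. The
interaction partial F compares full vs. interaction-free fits with
df1 = rank difference, df2 = n − rank(full). Numerically, the scan is
vectorised by projecting data and the GM column onto the orthogonal
complement of the common design (an SVD basis, robust to aliased genotype
columns), reducing the voxelwise covariate to a rank-1 update; the
single-voxel path uses lstsq with explicit rank bookkeeping, and the two
agree to 1e-8 relative (tested). Degenerate voxels (rank-deficient
reduced model, zero residual variance) are flagged invalid via p = 1. A
subject without a GM map is mean-imputed with a warning.

### Cluster inference

The Monte-Carlo extent simulation draws Gaussian white noise on the
grid, smooths to the configured FWHM, standardises over the mask,
thresholds the upper tail at the primary voxel p (0.005), and records
the largest connected component; the extent threshold is the smallest
size whose null exceedance probability is ≤ α. Connectivity defaults to
18 (faces+edges, the closest match to a 5 mm clustering radius on a
3 mm grid); 6 and 26 are selectable. F maps are one-sided, so only the
upper tail is thresholded. Smoothness is the *configured* FWHM rather
than residual-estimated; `alff.estimate_fwhm` (lag-1 autocorrelation
inversion) is provided for reporting. Because an F statistic computed
from smooth per-subject maps is locally rougher than the smoothed
Gaussian fields the simulation assumes, the stage-1 family-wise rate
measured on pure-noise statistic maps comes out below the nominal 0.05
(conservative; the calibration suite asserts the ≤ α + 3 SE bound). The
packaged fixed default extent is 48 voxels = 1296 mm³ at 3 mm, used when
simulation is skipped (`extent_mode: fixed`); the exact mask behind that
printed value is not recoverable, so re-simulation on an arbitrary mask
legitimately yields a different extent.

Stage 1 (`pass_S`): within each gene the per-SNP α is Bonferroni-divided
by the gene's SNP count; with a simulated null distribution a cluster's
corrected p is its null tail probability, while in fixed-extent mode the
size rule stands in for the unadjusted α and the approximation is
recorded in the ledger. Stage 2 (`pass_SG`): with k stage-1-surviving
SNPs the voxel threshold tightens to 0.005/k and the same extent rule is
re-applied; a stage-1 cluster inherits `pass_SG` when its peak voxel sits
in a surviving stage-2 component, which enforces `pass_SG ⊆ pass_S`.

### Network analysis

Nodes are the `pass_S` clusters — the full supra-threshold component when
maps are available, or 6 mm spheres around the published peaks when
working from the packaged 31-ROI table (the original choice is unstated).
Edges are `atanh(r)` of ROI-mean series correlations, clipped at
|r| = 1 − 1e-7; negative weights are kept with their sign (node strength
sums signed weights), and the r-thresholds {0.3, 0.5, 0.7} are applied to
|r| (the thresholds are named as correlation coefficients; whether r or z
was thresholded originally is unstated). "Unidirectional weighted
network" is read as an undirected weighted complete graph — C(31,2) = 465
confirms that reading. Group edge tests are pooled two-sample t-tests on
z weights, swept over p ∈ {0.05, 0.01, 0.005, 0.001} uncorrected as in
the reference analysis, with a Bonferroni column added for reference
only. Strength–behaviour correlations are Pearson (or partial via
residualisation on covariates, df = n − 2 − k), with uncorrected and
Bonferroni p both reported. The hemispheric summary uses the laterality
index (|L| − |R|)/(|L| + |R|) on signed strength sums, which stays in
[−1, 1] even when strengths are negative.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 43 aMCI / 30 controls;
demographics, gender ratios (27:16, 17:13) and neuropsychological
z-scores drawn from the published group means/SDs; HWE genotypes for the
33-SNP panel; TR 3 s, 142 volumes (7 min 6 s) with the first 8 discarded;
8 mm smoothing; grey-matter probability maps in [0, 1] (a shared
anatomical pattern plus individual variation, logistic-squashed), with an
optional single withheld GM map mirroring the one missing anatomical
scan. The validation grid is 24×28×24 at 3 mm with a central ellipsoid
mask — large enough for cluster inference to be meaningful, small enough
for the suites to run on one CPU; the full MNI grid adds nothing to
validation. The baseline signal is 10 sinusoids with frequencies uniform
in 0.01–0.08 Hz and random per-voxel phases, normalised to unit variance,
guaranteeing energy in the analysed band; white noise (default SD 1, the
same scale as the signal) and a small random linear trend (SD 0.05 per
voxel) are added, and the 4D data are smoothed spatially. Injected
effects multiply the baseline amplitude by
`1 + effect_size · group · genotype_code` inside spherical blobs, with
the code chosen by the same MAF rule the mapping stage applies (empirical
MAF, recessive below 0.31), so recovery is an identity test. Because the
published allele frequencies are not available, the default panel assigns
MAFs evenly spaced over [0.12, 0.48] in panel order, covering both model
branches; effect sizes are free parameters of the simulation, not
estimates of the study's effects, whose amplitudes are unpublished.

Not emulated: head motion time courses (motion exclusion consumes a
precomputed per-subject summary against the 3 mm / 3° rule), slice
timing, physiological noise, scanner drift beyond the linear term,
spatial normalisation, and any anatomical realism in the mask or GM
fields. Passing tests therefore demonstrate statistical correctness and
calibration of the analysis chain, not robustness to real-data artefacts.

## Seeds and determinism

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams (genotypes, phenotypes, one per
subject series, one per GM map), so any stage can be regenerated in
isolation; the pipeline's two-pass design (ALFF first, ROI series after
cluster inference) relies on bit-identical regeneration instead of
keeping 4D volumes in memory. Reports and serialized ground truth are
byte-stable under a fixed (config, seed).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band | 0.01–0.08 | Hz | the low-frequency range whose amplitude defines ALFF |
| tr_s / n_volumes / n_discard | 3.0 / 142 / 8 | s / – / – | acquisition protocol being emulated |
| smooth_fwhm_mm | 8 | mm | preprocessing smoothness; also the cluster-simulation smoothness |
| voxel_p / alpha | 0.005 / 0.05 | – | primary threshold and cluster-level FWE target |
| extent_vox | 48 (=1296 mm³) | voxels | packaged fixed extent when simulation is skipped |
| maf_exclusion / maf_model_cutoff | 0.05 / 0.31 | – | SNP QC; genotypic-vs-recessive switch (q² ≤ 0.10) |
| connectivity | 18 | – | cluster adjacency (≈5 mm radius at 3 mm voxels) |
| r_thresholds | 0.3, 0.5, 0.7 | – | network edge retention sweep |
| edge_p_thresholds | .05, .01, .005, .001 | – | group edge-difference sweep |
| noise_sd | 1.0 | a.u. | white-noise scale relative to unit-variance signal |
| effect_size | per blob | – | multiplicative interaction amplitude modulation |

## Numerical choices and degenerate inputs

Band edges inclusive; monomorphic SNPs return HWE p = 1 by convention
and are uncodable (error) — with two observed genotype classes a
genotypic request falls back to a 1-df linear contrast with a warning.
MAF exactly at the 0.31 boundary selects the genotypic model. Complete LD
is exact (r² = 1 on minor-allele-count vectors) with a keep-first-in-
panel tie-break. Cluster peak ties break to the lowest linear voxel
index. Zero-variance ROI series produce zero-weight edges with a
warning; degenerate edges are skipped (and logged) in group tests;
constant behaviour scores are rejected. The 2×2 gender test is computed
without continuity correction in both the plain Pearson and the
(N−1)/N-adjusted (Mantel–Haenszel) form — the adjusted form is the one
that reproduces the published gender p of 0.601. Neuropsychological
z-scores are generated directly on the z scale; when standardising raw
scores the reference is the full-sample mean/SD (the reference population
is otherwise unspecified).

## Problem sizes used by the validation suites

Voxelwise null calibration: 2000 independent voxels, n = 73, nominal
p = 0.005, 3-binomial-SE band. Cluster FWE: 200 pure-noise replicate
statistic maps on the 24×28×24 grid against a 1000-iteration Monte-Carlo
extent. Recovery: 20 seeded full-pipeline runs, one blob (radius 3
voxels, effect size 1.0) on rs429358, n = 43/30, requiring the F peak
inside the blob and a stage-1-surviving cluster peaking there in ≥ 90 %
of runs. These sizes were chosen so each suite is statistically
meaningful at desk scale.

## Known limitations

Stationary cluster inference only (the optional local-smoothness
rescaling of the non-stationary variant is not implemented); no
Gaussian-random-field analytic p-values, TFCE, or permutation FWE; no
haplotype phasing, imputation, or population-structure correction; no
graph metrics beyond strength; subject-level published results (peak F
values, the 15/33 significant-SNP split, specific behaviour
correlations) are not reproducible without the original raw data — the
package reproduces the *analytic* worked examples and validates the
*procedure* on ground-truth simulations instead.
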