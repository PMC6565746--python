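# Methods

## The measurement problem

Nuclear DNA content scales with ploidy class (2n, 4n, 8n...), and
stoichiometric DNA stains (DAPI in fixed imaging, propidium iodide or
Vybrant in cytometry) emit integrated signal proportional to DNA content.
None of the three data modalities carries per-cell ground truth, so every
stage here is validated by *parameter recovery*: a generator plants a known
composition, the pipeline recovers it, and the error is the figure of
merit. The generators are first-class, tested code — their contracts (exact
signal stoichiometry, planted QC failures, hidden event classes) are what
make the recovery experiments meaningful.

## Imaging model and the FI statistic

Synthetic scenes place non-overlapping ellipsoidal nuclei (default
semi-axes 2.5 x 3 x 3 µm, roughly a cardiac interstitial nucleus) in a
voxel grid with the acquisition geometry of a 40x confocal z-stack
(0.071 µm lateral, 0.426 µm axial, ~21 slices). Photon emission is
Poisson with expectation normalised so that each nucleus' expected
integrated count equals (ploidy/2) x photon_scale x V2n exactly, where V2n
is the analytic 2n ellipsoid volume in voxel units; Gaussian read noise
(sd 2) and a flat Poisson background (rate 5 against a 2n density of 100)
are added, and intensities clip at zero. Two signal models are provided
because they bracket the biology:

* **density** (default): volume fixed, voxel density ∝ ploidy. The
  widest-plane FI statistic is then exactly proportional to ploidy.
* **volume**: density fixed, volume ∝ ploidy. The 3-D integral still
  scales as ploidy but the widest-plane statistic scales as the equatorial
  cross-section, i.e. ploidy^(2/3) — a 4n/2n FI ratio of 2^(2/3) ≈ 1.587.
  The tests assert both ratios analytically; the 3-D integrated intensity
  is the bias-free comparator.

No point-spread-function blur is applied by default (an optional Gaussian
blur flag exists): the statistic operates on already-reconstructed stacks.
Segmentation is Otsu thresholding **on log intensities** followed by 3-D
connected components and a minimum-volume filter (20 µm³). The log
transform matters: with mixed-ploidy foregrounds the linear-intensity Otsu
threshold can split between the 2n and 4n brightness classes rather than
between background and foreground, deleting every dim nucleus; on the log
scale background/foreground separation dominates. Automated segmentation
replaces manual ROI drawing for reproducibility; the FI statistic itself
(widest-plane mean x pixel area, ties to the smaller z) is unchanged.

A flat background inflates both FI classes additively and pulls the 4n/2n
ratio from 2 toward (2s+b)/(s+b); measurement therefore exposes an
optional background-median subtraction (off by default, matching the
convention of reporting raw intensity statistics; the recovery pipelines
do not need it because the ratio windows are wide relative to the bias at
the default signal-to-background of 20:1).

Marker positivity (c-kit, tryptase, cardiomyocyte channels) is scored on
the nucleus mask dilated by 2 voxels: positive when the mean marker
intensity exceeds 3x the channel's background median. Inclusion rules are
conjunctions such as `ckit+ AND tryptase-` (the mast-cell exclusion used
in infarcted tissue).

## Calibration and classification

FI units are arbitrary, so classification is anchored on a known-ploidy
reference: the median (default) or KDE mode of a reference population's FI,
halved if the anchor population is tetraploid. Ratio windows at 1.5 and 3
— the geometric midpoints between 1x/2x and 2x/4x — assign classes, with
boundaries belonging to the upper class. A 3-component Gaussian mixture on
log FI (means initialised at the calibrated 1x/2x/4x positions) is provided
as a cross-check classifier; at CV ≤ 5 % the two agree on ≥ 99 % of nuclei.
Compositions are averaged per replicate (scene or experiment) with SEM =
sd/√n across replicates, matching mean ± SEM reporting per experiment
rather than per cell; pooled counts are reported alongside.

## Cytometry model and gating

Singlet areas are lognormal with unit mean around class positions 1x/2x/4x
of the diploid channel position (default CV 5 %; the source experiments do
not state their peak CVs, so this is an exposed parameter at a typical
instrument value). Pulse width is proportional to area with 5 % noise.
Doublets are sums of two singlet areas with the width of one singlet —
area is additive across coincident cells, transit width is not — which is
exactly what makes width-versus-area gating work. Debris is uniform on
(0.05, 0.28)x the diploid position, i.e. strictly sub-G1. Gating removes
events below 0.3x the dominant KDE peak as debris, then flags doublets
where log(area/width) exceeds the remaining events' median by more than
3 robust (MAD-based) SDs *and* by at least 0.3 log units; the absolute
floor sits far below the log 2 ≈ 0.69 excess of a true doublet but above
the reach of measurement noise, so clean samples are not eroded
(validated: ≥ 90 % of injected doublets caught, ≤ 2 % of singlets
misflagged, and pure-singlet tables pass untouched).

Peaks are located by Gaussian KDE on log area with Silverman bandwidth
(scale-free); the most prominent peak anchors the DNA scale (halved for a
tetraploid culture control), with an error when the two tallest peaks are
within 10 % of each other's density. An explicit external reference can be
supplied instead, reproducing the use of a tetraploid control sample to
set gates for fresh isolates; both anchorings classify well-separated
mixtures identically for ≥ 99 % of events.

## scRNA-seq model and pipeline

The count generator draws negative-binomial UMIs (gene-level dispersion
0.5) over 8000 genes: lognormal baseline expression, per-type marker genes
(4 fibroblast, 5 endothelial, 1 lymphocyte) enriched 30-fold, a broader
150-gene expression program per type enriched 4-fold (distinct lineages
differ transcriptome-wide, not only at defining markers — this is what
makes PCA embeddings separate types), 13 mitochondrial genes (prefix
`mt-`) whose summed share tracks a per-cell Beta(6,194) target (mean 3 %),
and lognormal library sizes (mean 6000, CV 30 %, yielding a median ~2700
detected genes). Mitochondrial genes are sampled Poisson rather than NB so
that a cell's realised mitochondrial fraction stays close to its planted
target — the property that makes planted QC outcomes deterministic.
Low-quality cells (5 % by default) are planted half with a 0.06x library
(≈ 330 detected genes, far below the 1000-gene cut) and half with a 25 %
mitochondrial share.

The pipeline: cells filtered first (gene count and mitochondrial fraction
computed on the input matrix; the 10 % mito cut is strict), then genes by
the 3-cell minimum on surviving cells, in one pass (a fixpoint iteration
is available behind the same interface but the single pass matches the
stated filter). Normalisation is counts-per-10,000 + log1p. Variable genes
use 20 equal-width bins on log mean expression with a within-bin z-score
of dispersion (variance/mean of exponentiated log-normalised expression);
equal-width rather than quantile bins, because quantile bins pack all
high-expression genes into one bin where genuine structure genes normalise
each other away; zero-dispersion genes are never selected. PCA runs on
z-scored (clipped at ±10) variable genes with a deterministic sign
convention (largest-|loading| entry positive). Cell typing assigns the
argmax of mean marker log-expression, `unassigned` when every score is
zero. Differential expression is a per-gene Wilcoxon rank-sum on
log-normalised values with Benjamini–Hochberg correction; "upregulated"
means adjusted p < 0.05 and natural-log fold change > 0.25 (Seurat-v2-like
defaults, configurable); genes with identical raw counts everywhere report
p = 1.

## Reporting statistics

Unpaired two-tailed t-tests (equal-variance by default, Welch optional),
one-way ANOVA with Bonferroni-corrected pairwise post-hoc t-tests, and
two-way ANOVA with interaction via an OLS fit. Stars: * p<0.05, ** p<0.01,
*** p<0.001. Doubling time DT = t·ln2 / ln(n2/n1) (negative DT flagged as
decline), plus a log-linear regression variant for growth series. Relative
expression uses 2^-ΔΔCt.

## Recovery experiment sizes

The acceptance harness uses 4 replicates of 22,000 cytometry events,
300-nucleus imaging runs rendered in scenes of 25 nuclei (each scene one
replicate; 30 planted diploid reference nuclei anchor calibration), and
1036-cell scRNA-seq runs with exact planted type proportions
(largest-remainder rounding) — the per-experiment scales such experiments
typically report, while keeping a full run at a few minutes on one CPU.

## What passing does and does not show

The generators emulate stoichiometric staining, instrument noise, doublet
physics, and droplet count statistics. They deliberately omit: optical
PSF and spectral bleed-through, tissue autofluorescence, S-phase DNA
continuum (an optional bridge flag exists; by default every cell belongs
to one of three classes), cell-cycle phase structure within peaks,
mono- vs multi-nucleation (a nucleus is the unit of measurement),
ambient RNA and barcode-swapping artefacts, and batch effects. Recovery
within tolerance therefore demonstrates correctness of the inference
chain under the stated noise models, not robustness to every failure mode
of real tissue; on real data the manual steps these modules replace
(ROI drawing, gate placement) remain the dominant source of variation.

## Numerical conventions

Voxel order is (z, y, x), 0-based; masks are boolean pixel sets;
intensities are non-negative floats in arbitrary units. Widest-plane ties
break to the smallest z. Window boundaries belong to the upper ploidy
class. All randomness flows through `numpy.random.default_rng(seed)`;
identical seeds give bit-identical outputs across every generator and
pipeline.
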