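# Methods

This note documents the models, estimators and numerical choices behind
`chromoshape`, and what the synthetic benchmark does and does not show.

## Image model and the synthetic generator

A cell is rendered as channels over a common pixel grid (default
65.35 nm/px, 96×96 px), each following the camera model

    counts = Poisson(ideal * PSF + background) + N(0, read_noise), clipped at 0

with an isotropic Gaussian PSF of σ = 120 nm — a simple, invertible
stand-in for a measured widefield/deconvolution kernel of 120–150 nm
resolution.  Z-stacks are modeled as the in-focus plane plus defocused
planes whose PSF σ grows as σ·√(1+(dz/400 nm)²); analysis operates on the
maximum-intensity projection, so full 3-D optics are unnecessary.

The chromosome is a 1-D density f(s) along an arc of radius 0.75 µm
(crescent span drawn from 90–180°, toroid 360°), swept into a ribbon of
transverse Gaussian width 80 nm.  Density models: uniform, exponential
(decay length λ, default 1 µm, emulating the gradual origin-to-terminus
decrease of DNA signal), and a two-level piecewise profile.  Condensed
regions are isotropic Gaussian blobs (width ≥ PSF) carrying stated
fractions of the DNA; the primary blob sits at the arc start (the origin),
where the ParB channel holds one PSF-limited focus.  *ter*, when rendered,
sits at the opposite arc tip with a deliberately dim spot (60% of its
channel) over a diffuse haze, exercising the 15% signal filter.  The
compact class is a single PSF-scale blob; the dispersed/undefined class is
3–6 blobs ≥ 700 nm apart — far enough that the pattern does not read as a
contiguous ribbon, keeping the four class definitions non-overlapping.

The SMC channel follows the DNA density plus an origin-proximal component
(σ = 250 nm along the arc).  Its weight is solved so that the
**PSF-convolved** linear density, averaged over the first 130 nm of arc,
is 1.6× the convolved profile mean: a fold-increase at the origin is a
property of the measured profile, so the generator targets the value a
profile measurement defines, not the unobservable unblurred density.

Photon budgets (DNA 2·10⁵, ParB 3·10⁴, SMC 10⁵, cell body 3·10⁵;
background 20 counts, read noise 3) are not constrained by published
numbers; they are chosen once to put the arc at mid-range SNR (peak pixel
tens of σ above the shot-noise floor, comfortably past the SNR ≥ 10
regime the recovery tests assume).  In the noiseless limit each channel
integrates exactly to its photon budget.

**What the generator does not emulate:** polymer physics (no bead-spring
chromosome), phase-contrast rendering, SIM raw patterns, spectral
crosstalk, uneven illumination, or cell-to-cell brightness variation.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated optical model, not robustness to every
real-microscope artifact.

## Segmentation and screening

Cells are detected on the cell-body channel: Gaussian smoothing (σ = 1 px),
Otsu threshold (quantile thresholding available; both are invariant to
intensity rescaling), hole filling, connected components, minimum area
1 µm².  Roundness is 4π·area/perimeter² with the Crofton perimeter
estimator (a digitized disc scores ≈ 1); the screening default of 0.85 is
this package's choice — the original screening protocol never quantified
its "simple roundness criterion".  A cell is accepted for chromosome
analysis only if exactly one ParB focus appears in its max projection
(one focus = one chromosome).

## Focus detection

Candidate foci are local maxima above `background + 5·noise` (median and
1.4826·MAD over the masked pixels).  Sub-pixel positions come from a
single-pass border-median-subtracted centroid in a window of half-width
⌈2σ⌉ (a fixed-width Gaussian least-squares fit is the alternative);
duplicates within 1 PSF σ merge, keeping the brighter.  Intensities are
then solved **jointly**: non-negative least squares of unit Gaussians at
the detected positions against the background-subtracted cell pixels,
alternated twice with a per-spot re-localization against the image minus
the other spots' models.  This removes the double counting and mutual
position bias that window integration suffers for spots a few σ apart —
two equal spots at 3σ split the signal exactly 50/50 by symmetry.
Noiseless localization bias is ≤ 0.2 px; at SNR ≥ 10 the cross-channel
pair distance at the 126 nm colocalization scale is recovered with ~1 nm
mean absolute error.

`fraction_of_cell_signal` divides a focus's fitted integral by the cell's
background-subtracted total; the 15% filter for dim locus channels acts on
it.  The ori:ter ratio is pooled (Σ ori / Σ ter over cells with ≥ 1
surviving ter focus) by default; whether the original analysis pooled or
averaged per cell is not documented, so the per-cell mean is exposed as an
option.

## Annular backbone and profiles

The arc model is anchored by a circle fit to the above-Otsu DNA pixels:
weighted Taubin algebraic fit followed by three Gauss–Newton steps of the
weighted geometric problem.  Angular statistics (per-bin intensity and
intensity-weighted radius over 72 bins of 5°) use *all* masked pixels after
subtracting the median in-cell background, so the dim chromosome tail is
not clipped by the threshold.  A bin belongs to the angular support when
its intensity exceeds max(0.25·median bin, 0.10·max bin).  Degenerate
patterns — fewer than 3 supported bins, or a fitted radius under 4 px
(a compact blob fits a meaningless tiny circle) — raise a
shape-not-arc-like error and are excluded from profiling, mirroring the
screening of non-arc cells.

Arc length is s = |Δangle|·R from the ParB angle, sampled in both angular
directions in bins of 0.13 µm (2 px) out to a fixed representative length
of 3.5 µm (both config-exposed; the published analysis fixed a
"representative length" without quantifying it, so demograph comparisons
are relative).  Wedge integration runs on a 6×6 sub-pixel grid so wedge
boundaries do not slice whole pixels — on a noiseless uniform torus the
profile is flat to < 2% CV.  Each bin's integral is divided by the bin arc
length ("per unit annular section").  The orientation with more total DNA
becomes the positive axis (`align_and_flip`, idempotent), after which
fold-increase = raw/mean over observed bins (mean 1 per channel).
Profiles are exactly invariant under image mirroring and 90° rotations;
clockwise vs counterclockwise arcs agree to rendering discretization
(~1–2%).

The exponential decay length is estimated by a log-linear fit over
interior observed bins (skipping 1 bin at the ori and 2 at the far end,
where PSF edge bleed dominates); Gaussian blur preserves an exponential's
log-slope away from edges, which is why the estimator is unbiased to
within a few percent.

## Cluster decomposition

The nucleoid pattern is expressed as a sum of fixed-width (PSF σ)
Gaussian spots: greedy matching pursuit subtracts the brightest residual
spot until the **matched-filtered** residual peak (smoothed at the PSF
scale) falls below 3× its robust noise — filtering first is what lets a
blank field stop at zero spots, since the expected maximum of ~25
independent smoothed noise samples stays below 3σ while that of 10⁴ raw
pixels does not.  Each new spot triggers two cyclic refinement sweeps
(re-localize each spot against the residual with the others subtracted),
and a final joint NNLS refit sets all amplitudes; the residual norm is
non-increasing by construction, with a greedy-amplitude fallback if the
refit fails.

Spots group into clusters by single linkage at "one PSF", interpreted as
the PSF FWHM (2.355σ, config-exposed — the unit is ambiguous in prose).
Consequently a *continuous* ribbon of signal chains into a single cluster
by definition; distinct clusters exist exactly when the pattern has
distinguishable gaps.  The benchmark scenario for primary-cluster recovery
therefore places the non-primary DNA in gap-separated blobs (30% at
0.50·L, 25% at 0.90·L, ~0.8 µm gaps ≫ FWHM) rather than a uniform bridge,
which would merge everything into one cluster by the method's own
definition.  The cluster with the largest share of cell signal is primary
(ties broken by proximity to the ParB focus); the origin-proximal DNA
fraction is computed on the background-subtracted image within a Euclidean
disc (center-in pixel test), with a truth-density quadrature counterpart
for validation.

## Demographs

Row order is by decreasing profile contrast, defined as robust Michelson
contrast (q95 − q5)/(q95 + q5) of the fold-increase (std/mean available);
the published ordering statistic is not specified, so cross-ordering
comparisons with published heatmaps are qualitative.  Bins beyond a cell's
chromosome are explicit missing values and are excluded from the
column-wise mean, avoiding zero-padding bias.  Ordering ties break by cell
id, making the matrix invariant to input permutation.

## Shape classification and bootstrap

The blinded human raters of the original shape survey are replaced by a
deterministic rule on intensity-weighted features of the above-Otsu DNA
pixels (all invariant to intensity rescaling):

1. radius of gyration < 300 nm → **compact** (a PSF-scale blob has
   r_g = σ√2 ≈ 170 nm; an 0.75 µm arc scores > 450 nm);
2. otherwise fit a circle; require radius ≥ 250 nm and that the largest
   connected signal component holds ≥ 60% of the signal (a ribbon is one
   piece; scattered blobs are not);
3. contiguous angular coverage ≥ 330° with central hole score ≥ 0.5 →
   **toroid** (hole score = 1 − inner/ridge mean intensity);
4. contiguous coverage in [60°, 330°), radial rms residual ≤ 0.35·R,
   fragmentation ≤ 40°, hole score ≥ 0.3 → **crescent**;
5. anything else → **other** (never an error).

The small-radius guard runs before the toroid test because a compact blob
yields a degenerate tiny fitted circle with nominally 360° coverage.
Thresholds are config-exposed; the defaults were fixed once on a
development simulation and achieve ≥ 95% per-class accuracy on held-out
populations at the default SNR.

`bootstrap_ratio` mirrors the rating protocol: each of n_boot = 25 series
draws picks_per_series = 100 calls without replacement (no cell shown
twice within a series; with replacement, logged, when the population is
smaller), computes toroid/(toroid+crescent), and reports mean ± SE
(sd/√n_boot) across series.  On a fixed 30/70 population the series
variance matches the hypergeometric expectation.  Per-rater variability is
emulated only through this resampling; no inter-rater agreement analysis
is attempted.

## Pipeline, sizes, determinism

`run_pipeline` chains simulate/read → detect → roundness screen →
single-ParB screen → backbone profile → clusters → demograph → shape
calls → bootstrap, logging every exclusion and recording the monotone
screening funnel in a manifest keyed by the config hash.  All randomness
flows from one master seed through `numpy.random.SeedSequence`-derived
per-cell seeds (< 2³¹), so a rerun is bit-identical.

The validation suite and `scripts/acceptance.py` use populations of
40–150 cells per scenario and 50–200 random draws per oracle comparison —
sizes at which every recovered quantity is stable to well under its
tolerance while the whole acceptance run completes in under a minute on
one CPU.

## Known limitations

- The backbone model assumes one circular-arc chromosome per cell; S-shaped
  or multi-lobed patterns are excluded (by design), not traced.
- Profile arc length uses the mean backbone radius; for strongly
  non-circular arcs the length axis is approximate.
- Cluster relative intensities rely on the fixed-width spot model; blobs
  much wider than the PSF are represented by several spots whose summed
  intensity slightly overlaps neighboring clusters.
- No time-lapse support: focus mobility and shape dynamics are out of
  scope.
- The classifier's thresholds are calibrated on the generator's four
  idealized pattern families; real intermediate morphologies will land in
  *other* more often than a human rater would place them.
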