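# Methods

This note documents the models, numerical choices and synthetic-data design
behind chemoscope, and what the package's tests do and do not establish
about real microscopy data.

## Second-order decay fitting

Focus fluorescence under repeated imaging is modelled as

    f(t) = 1 / (k t + 1 / A0)

with rate constant `k` (min⁻¹) and initial fluorescence `A0` (arbitrary
units). The fit minimizes squared residuals of the *untransformed*
intensities over the samples with t in the closed window [2, 12] minutes
(the first minutes after mounting are not usable; at least 4 in-window
samples are required).

Numerics. The problem is reparameterized as (k, b = 1/A0), which removes the
singularity at A0 → ∞ and makes the model exactly linear in reciprocal
space: 1/f = k t + b. The optimizer (trust-region-reflective least squares,
xtol = ftol = gtol = 1e-12) is initialized from an ordinary least-squares
line through the reciprocal trace, weighted by f² so that noisy small-f
samples — whose reciprocals explode — cannot dominate the initialization; a
two-point estimate through the first and last in-window samples is the
fallback and retry start. `k` is unconstrained (a rising trace legitimately
fits k < 0); `b` is constrained positive. A trace for which both starts fail
to converge raises an error carrying the last iterate.

`sd_k` is the per-trace fitting standard deviation of `k`, taken from the
Gauss–Newton covariance at the optimum, cov = RSS/(n−2) · (JᵀJ)⁻¹. The
alternative reading — a per-condition spread — is served separately by the
baseline statistics.

A property worth noting: the second-order law is *not* scale-invariant in
intensity. Multiplying a trace by c maps (k, A0) → (k/c, c·A0), because this
k carries inverse-intensity units (unlike an exponential rate). Rate
constants are therefore only comparable between traces recorded on a common
intensity normalization, which is how the deviance analysis uses them.

## Deviance classification

The buffer (no-ligand) population defines the photobleaching baseline:
AVE_k and SD_k over all buffer fits (sample SD, n−1). A focus is

* **slower** iff k + sd_k < AVE_k − SD_k (decays less than bleaching
  predicts — consistent with renewed reporter formation),
* **faster** iff k − sd_k > AVE_k + SD_k (the mirrored inequality),
* **baseline** otherwise.

Both inequalities are strict; the classes are mutually exclusive and
exhaustive. The faster rule is implemented as the mirror image of the slower
rule; the published formulation of the faster criterion shares its
right-hand side with the slower one, which would classify every non-slower
trace as faster and is retained only behind `rule="printed"` for fidelity
checks.

Per-series proportions of each class are compared across conditions with a
Kruskal–Wallis test (mid-ranks, standard tie correction, chi-square
approximation with g−1 degrees of freedom). Identical pooled values give
H = 0, p = 1; results are flagged when any group has fewer than 5 series,
where the chi-square approximation is unreliable.

## Foci detection and the focus score

The upstream segmentation tool's "focus score" is not publicly specified;
chemoscope defines a fully specified statistic that reproduces its role:

    score = (smoothed peak − local background) / robust cell-noise SD

Candidate spots are local maxima of the lightly smoothed image
(Gaussian, σ = 1 px) inside each cell mask. The local background is the
median of the cell's *interior* pixels (mask eroded by ⌈3·σ_smooth⌉ px, so
the roll-off smoothing creates at the cell boundary does not contaminate the
statistics) outside exclusion disks of radius 2·σ_PSF around candidates; the
noise scale is 1.4826 × the median absolute deviation of the same pixels.
Retention is inclusive at score ≥ 10 (the default threshold). Spot centers
are refined to sub-pixel precision by a background-subtracted 3×3 intensity
centroid around the peak; on the synthetic benchmark this gives a mean
localization error of ≈0.4 px. Whether this score is numerically equivalent
to the original tool's score is unknowable and not claimed; the threshold's
*role* (retain clearly supra-noise spots) is preserved.

Longitudinal position is the signed projection of the spot onto the cell's
pole axis divided by the half-axis length, clamped to [−1, 1]; it is
invariant under rigid motions of the scene. "Polar" means |position| ≥ 0.5
by default — the boundary between the receptor-cluster pole region and the
motor-associated mid-cell region is not defined numerically anywhere
authoritative, so the cutoff is an exposed parameter.

## Colocalization matching

Two channels are matched one-to-one under a strict Euclidean cutoff
(default 2 px = 120 nm, the epifluorescence resolution limit; 3 px = 180 nm
is the common alternative). The matcher maximizes the number of pairs below
the cutoff and, among such matchings, minimizes the total distance
(Hungarian algorithm on the thresholded distance matrix). A pure
ascending-distance greedy pass was considered and rejected: it is not
optimal on chain-displacement configurations, whereas the assignment matcher
provably attains the brute-force optimum on every instance (verified
exhaustively in the tests for up to 4 foci per channel) and coincides with
greedy matching on the well-separated patterns real scenes produce. The
colocalization fraction is matched-A / |A|; it is non-decreasing in the
cutoff and equals 1 for identical lists at any positive cutoff.

## pHluorin calibration and sector profiles

Calibration fits ratio = slope·pH + intercept by OLS on per-cell mean
emission ratios at known pH, using only points inside the linear validity
range [6, 8]; at least 3 in-range points spanning ≥ 1 pH unit are required
and a non-positive slope is rejected as unphysical. Inversion
pH = (ratio − intercept)/slope flags values outside the validity range as
extrapolated (with a 1e-9 boundary tolerance).

Ratio images are I₃₈₆/I₄₇₀ with pixels masked invalid where the denominator
falls below a floor (default ≈5× the background noise SD — some masking rule
is numerically necessary and this one keeps only pixels with meaningful cell
signal). Cell abundance is the Sobel gradient magnitude (3×3 kernels in both
axes, combined in quadrature), whose zone sums scale linearly with the
number of non-overlapping cells.

Sector profiles bin pixels by signed Euclidean distance to the source
border (exact distance transform, negative inside), in zones of 25 px
(2 µm at the 0.08 µm/px magnification of source assays), by default 3 zones
inside and 57 outside. Zone k ≥ 1 covers [(k−1)w, kw) and zone −j covers
(−jw, −(j−1)w], so every in-range pixel belongs to exactly one zone
regardless of source shape. Per-zone means from each measurement (each
imaged side of each replicate counts as one measurement, so 4 replicates
imaged on both sides give n = 8) are aggregated into mean ± ci95 with
ci95 = t₀.₉₇₅,ₙ₋₁ · SD/√n. The cell-accumulation summary sums the zone
abundances whose centers lie within 30 µm outside the border (15 zones at
2 µm).

Two imaging scales coexist in the package: 0.06 µm/px for high-magnification
foci work (2 px = 120 nm) and 0.08 µm/px for the 20× source assays
(25 px = 2 µm). Each module defaults to its own scale; both are parameters.

## Synthetic scenes: what they emulate and what they do not

**Traces.** k ~ Normal(0.05, 0.01²) min⁻¹ truncated at 0; A0 ~
Normal(3, 0.3²) AU; additive Gaussian noise, sd 0.06 AU (2% of mean A0),
truncated at zero (offset-subtracted camera counts); samples every minute
from 0 to 12. At these values the in-window fluorescence declines ≈2.2-fold,
matching the visible decline of real bleaching traces, and the median
relative error of the fitted k is ≈3–4%. Renewal (new split-eGFP formation
in repellent-exposed cells) is a linear additive term; 0.03 AU/min shifts
the mean fitted k by two buffer SDs and is the default effect size for the
nickel-like condition.

**Ratio scenes.** Cells are rotated ellipses (28 × 10 px) placed by an
inhomogeneous Poisson process whose intensity follows the configured
density-vs-distance profile, with overlapping draws dropped; both channels
share placement exactly. The planted pH field decays exponentially from the
source edge, pH(d) = pH_far + (pH_near − pH_far)·e^(−d/λ) with λ = 20 µm by
default; the 470-channel renders cells at a fixed base intensity and the
386-channel at ratio × base, so the noiseless per-cell channel ratio equals
the calibration ratio at the planted pH exactly. Channel noise is additive
Gaussian, default 2% of the cell signal.

**Foci scenes.** Per-cell focus counts are drawn from a distribution on
0–5; each focus is polar with the configured probability (|position| drawn
in [0.6, 0.9], mid-cell in [−0.45, 0.45], transverse offset scaled by the
local ellipse width so centers stay inside the mask); spots are isotropic
Gaussians (σ = 1.5 px). A configurable fraction of channel-A foci is
duplicated into channel B with ≤ 1 px jitter — the planted overlap that the
colocalization benchmark recovers. The colocalization and detection
benchmarks use one focus per cell so they measure matching and detection
fidelity rather than crowding; the polar-partition benchmark uses 1–2 foci
per cell.

Deliberately *not* modelled: diffraction optics (no Airy PSF), shot noise,
uneven illumination, cell motion or division, segmentation errors (cell
masks are ground truth), and out-of-focus light. Passing tests therefore
demonstrate the correctness of the analysis chain on data that obey its
assumptions, not robustness to real-microscope artifacts; in particular
detection figures (recall/precision ≥ 0.95 at ≥ 10× noise) should be read as
upper bounds on real-data performance.

## Simulation sizes

The null-calibration benchmark simulates 500 three-condition experiments
(8 series × 8 foci per condition) and checks the Kruskal–Wallis rejection
rate at α = 0.05; power is estimated from 200 experiments with the 2-SD
renewal effect in one condition. pH-gradient recovery uses 4 replicate
scenes of 620 × 1300 px (40 outside zones, so the far-field plateau is
estimated beyond 60 µm where the planted exponential has decayed to < 5% of
its near-source amplitude). Confidence-band coverage uses 1000 simulated
zones of 4 replicates. These sizes give each stochastic check a comfortable
margin relative to its tolerance while keeping the full run in the minutes
range.

## Known limitations

* The deviance rule inherits the ±1 SD band of the published procedure; it
  is a descriptive classification, not a calibrated hypothesis test per
  focus (≈10–15% of genuine buffer traces fall outside the band by
  construction).
* `sd_k` from the local curvature underestimates uncertainty for strongly
  non-Gaussian residuals (e.g. traces clipped at zero).
* The Kruskal–Wallis p-value uses the chi-square approximation; with fewer
  than ~5 series per group the result carries a `small_sample` flag and
  should be interpreted cautiously.
* Sector profiles assume the source border is well captured by the mask;
  partial-volume pixels at the border are assigned by the distance
  transform's integer-lattice geometry.
* The calibration is linear by construction and valid only on [6, 8]
  (extended ranges must be supplied explicitly); pHluorin's sigmoidal
  behaviour outside that range is out of scope.
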