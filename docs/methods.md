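# Methods

This note documents the models, numerical choices and limitations behind
`qlcis`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Staining-kinetics model

A unit instantaneous release into a well produces the normalized signal

A(t) = [Σ_j w_j e^(−t/τ_decay,j)] · [Σ_k v_k (1 − e^(−t/τ_assoc,k))],

with 1–2 terms per part.  Two association terms model the fast/slow
binding populations of a polyclonal detection antibody; two decay terms
model mixed dissociation/photobleaching time scales.  All printed kernel
variants are special cases of this product form, which is why the package
represents them with a single `AntibodyKinetics` type parameterized by
(n_decay, n_assoc).

Shipped calibrations (time constants in the unit each assay was imaged
in — minutes for mouse IL-5 at ~1-min cycles, hours for the human
cytokines at ~1-h cycles):

| label | decay τ (weight) | association τ (weight) | unit |
|---|---|---|---|
| mouse-IL-5 | 3.4×10⁴ (1.0) | 7.6 (0.599), 84 (0.401) | min |
| human-IL-5 | 2.8×10² (1.0) | 0.27 (1.0) | h |
| human-IL-13 | 0.84 (0.71), 2.1×10² (0.29) | 1.0 (1.0) | h |
| crosstalk-13to5 | τ_decay 2.8×10², β 0.33 | 0.23 (0.23), 25 (0.77) | h |

For the human IL-13 kernel the 0.71/0.29 mixture weights the two *decay*
exponentials (the association side is a single monoclonal term); the
cross-talk kernel χ(Δt) has the same product shape scaled by the
amplitude β = 0.33.

Because the association-term labels are exchangeable (α ↔ 1−α with a tau
swap), every kinetics object is canonicalized by sorting taus ascending
within each part.  Time units are stored on every object and every
evaluation or deconvolution demands matching units, since the calibrations
deliberately mix minutes and hours.

### Fitting

`fit_kinetics` fits Q·A(t) to a microinjection standard curve (a known
bolus Q released at t = 0) by bounded trust-region least squares on
log-taus, with a log-spaced multi-start over the tau decades spanned by
the observed times (default 8 starts).  Association taus are initialized
below decay taus, and a fit whose association tau ends up above its decay
tau is flagged non-converged rather than returned silently: on a curve
that barely spans the decay time scale those parameters trade off and the
fit is not identified.  Degenerate (constant) curves and curves with
fewer than 10 points are refused.

## Deconvolution

On the Δt-binned grid (default Δt = 5 frames; bin i covers frames
[iΔt, (i+1)Δt), A_k ≡ A(k·Δt·frame_interval)), the forward model is
CSS_{t+1} = Σ_{i≤t} DSS_i·A_{t+1−i} and the inverse is the triangular
recursion DSS_t = (CSS_{t+1} − Σ_{i<t} DSS_i·A_{t+1−i}) / A_1.

Numerical choices:

* **Clamping.**  Secretion cannot be negative, so negative intermediates
  are set to 0 and the clamped value propagates into later history sums
  (this damps the noise amplification inherent in the recursion).  The
  total clamped mass is reported per trace.  Intermediates above
  −10⁻¹²·scale are treated as float round-off and zeroed without being
  counted as clamped, so noiseless round trips report exactly zero
  clamped mass.
* **Validity floor.**  A(Δt) ≤ 10⁻¹² raises an error: the kernel is too
  slow for the chosen bin width and the division would be meaningless.
* **NNLS cross-check.**  `method="nnls"` solves the whole-trace
  non-negative least-squares problem instead of the recursion; it is a
  diagnostic, not the default, because the recursion is the procedure the
  assay defines.
* **Cross-talk.**  The IL-13 channel's raw fluorescence carries
  Χ_t = Σ_i DSS_i^{IL-5}·χ(t−t_i) from captured IL-5 (t_i = start of
  release bin i; χ(0) = 0, so the current bin never contributes).  The
  corrected CSS = FI − Χ is floored at 0 before deconvolution, consistent
  with the DSS clamp; the IL-5 channel is always deconvolved first.
* **Smoothing.**  The published description ("temporal integration and
  moving the median") is read as: the Δt binning *is* the temporal
  integration, and smoothing is a centered moving median over DSS bins
  (window 5 bins, shrinking symmetrically at the edges).  A
  cumsum→median→diff variant was rejected because a median filter is
  edge-preserving: a single-bin spike is a step in the cumulative domain
  and would survive.  Smoothed DSS is for calling/visualization only and
  is never re-deconvolved.

## Preprocessing

* **Registration** is integer-pixel only (the assay does not claim
  subpixel stability): FFT cross-correlation restricted to a ±10-pixel
  search window, taking the normalized correlation peak.  A peak below
  0.2 (featureless or pure-noise frames) keeps a zero shift and flags
  low confidence.  Pixels shifted in from outside the frame become NaN,
  never zero.
* **Denoise/bin**: initial-frame background subtraction first, then a
  5-frame rolling median (symmetric window shrinking at the edges — no
  padding, so no signal is fabricated at t = 0), then 5×5 block *mean*
  binning.  Mean rather than sum keeps intensities on the unbinned
  calibration scale; the deconvolution is scale-covariant either way.
* **Coefficient normalization**: empty-well mean per (channel, quadrant,
  chamber, frame) divided by the channel's grand empty-well mean;
  dividing intensities by the coefficient removes multiplicative
  illumination drift exactly and is idempotent.  Strata without empty
  wells fall back to chamber-level coefficients with a warning.
  Coefficients are computed per channel independently.
* **Baseline**: each well's own initial corrected intensity, unless that
  initial is an outlier above Q3 + 1.5·IQR of the initial-intensity
  population (per channel) — autofluorescent contaminants — in which case
  the per-frame mean empty-well intensity is subtracted instead.  The
  rule is one-sided: contaminants only brighten.  With IQR = 0 and all
  initials identical no well exceeds Q3, so the default applies.

## Calling and classification

σ̂ = 1.4826·MAD of empty-well intensity deviations (per channel; in the
pipeline, deviations of each empty well from its own initial value, the
same transformation applied to occupied wells).  MAD = 0 returns σ̂ = 0
with a degenerate flag and positivity calling refuses to run.

Positivity: frames ≥ 3σ̂ are supra-threshold; supra frames separated by
≤ 3 sub-threshold frames belong to one episode (the gap allowance may be
used repeatedly within an episode); a trace is positive iff some episode
contains ≥ 2 supra frames, and the onset is the first frame of the first
qualifying episode.  "Above the threshold" is implemented inclusively
(≥).  The acceptance suite checks this state machine exhaustively against
an independent brute-force restatement on all binary patterns of length
≤ 12.

Classes: silent (not positive), hyperactive (positive and max CSS
≥ 50σ̂), slightly active (otherwise).  A 2-class k-means on log₁₀ max CSS
of positive wells (10 restarts, fixed seed) is reported as a concordance
check only; the 50σ̂ rule is the classifier of record.

Activation curves are Kaplan–Meier estimates (event = onset; never-called
wells censored at the horizon), reported as 1 − S(t).  Group comparisons
use Mann–Whitney (two-sided) or the log-rank test, with
Benjamini–Hochberg adjustment across the comparison family; all-tied
Mann–Whitney input returns p = 1 with a tie warning instead of a
zero-variance failure.

## Localization

Single 2D Gaussian + constant offset, bounded least squares, moment-based
initialization.  If the background-subtracted peak is below `min_peak`
(default: 3σ̂ of the empty-well secretion-image noise floor) no fit is
attempted — below the noise floor a fitted center is meaningless.
Multi-source wells are flagged by residual, not fitted with multiple
peaks.  Displacements are per-frame Euclidean distances to the tracked
cell centroid, summarized as median with quartiles.

## Synthetic experiment generator

The generator emulates: the dish geometry (4 chambers × 996 cubic wells,
80 μm side, 115 μm pitch; each 2×2 well block is one field of view, so
the quadrant alternates with row/column parity), Bernoulli well occupancy
(default 0.5), a three-phenotype population, staining-kinetics forward
convolution, per-(quadrant, chamber, frame) multiplicative illumination
drift (smooth log-random walk clipped to [1/drift_max, drift_max]),
additive Gaussian detection noise, and optionally Gaussian secretion-spot
images near a wandering cell centroid.

Release model (amplitudes in multiples of the detection noise SD):
silent cells release nothing; slightly active cells release an onset
burst of 10× followed by a 0.1×/frame trickle that ceases within a
uniform 10–30 h window; hyperactive cells release a 100× burst and
sustain 2×/frame to the horizon.  Onsets are log-normal (median 4 h,
log-SD 0.6, i.e. bulk within ~1–12 h post stimulation).  Default class
fractions are 0.33/0.50/0.17 (about two-thirds of occupied wells active,
with hyperactive cells the clear minority).  The burst-then-sustain shape
makes the first supra-threshold frame coincide with the true onset while
keeping slightly-active maxima inside the (3σ̂, 50σ̂) band — a modelling
choice, not a fitted description of any real cell population.

What the generator does *not* emulate: intra-well diffusion of secreted
protein (spot shape is phenomenological), capture-antibody saturation,
cell division/migration between wells, focus drift, and non-Gaussian
noise (hot pixels, cosmic rays).  Passing tests therefore demonstrate
correctness of the *analysis* under the stated noise/drift model, not
performance on any particular microscope.

All randomness flows from a single `numpy.random.default_rng` (PCG64)
seed; identical specs and seeds give bit-identical outputs.

## Problem sizes

The acceptance computations use: 500 random trains (lengths 2–200) across
the three staining calibrations for the round-trip check; 100
microinjection replicates of 200 points at 1% noise for calibration
recovery; all 8,188 binary patterns of length ≤ 12 for the calling rule;
a 2,000-well dish (4 chambers × 500 wells, 72 h at 1-h frames, ×2 drift)
for end-to-end phenotype/onset recovery; a 4 × 249-well dish of empty
wells for the drift-normalization residual; and 1,000 noisy 16×16 spot
images at SNR 10 for localization RMSE.  These sizes keep every check
reproducible on a laptop while leaving the per-stratum empty-well counts
(~60) large enough for sub-percent coefficient estimates.

## Known limitations

* The recursion divides by A(Δt); for very fast frame rates relative to
  the association time constants this amplifies noise, which is exactly
  why Δt = 5 frames is the default bin.
* Onset is reported on the CSS frame grid; because a release in bin t
  first appears in the signal at frame t+1, detected onsets
  characteristically lag the true onset by one frame.  Under Gaussian
  noise the gap-tolerant rule can occasionally chain a pre-onset noise
  frame into the onset episode and pull the called onset earlier; in the
  synthetic conditions this affects ~1–2% of detected wells, so onset
  agreement is stated as a ≥ 95%-within-one-frame property, not a
  per-well guarantee.
* The empty-well baseline fallback assumes contaminants brighten a well
  from frame 0; a contaminant arriving mid-run is not corrected.
* Per-pixel deconvolution treats pixels independently; no spatial PSF or
  regularization is applied (deliberately, matching the assay's
  definition of the DSS image).
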