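# qlcis

Analysis of **quantitative live-cell imaging of secretion activity**:
time-resolved fluorescence immunospot assays in which single immune cells
(e.g. group 2 innate lymphoid cells) sit in nanoliter wells on a TIRF
imaging dish and the cytokines they secrete (IL-5, IL-13) are captured and
stained on the well floor, frame after frame, for days.

The package is for experimentalists and analysts who have such time-lapse
data — or want to prototype the analysis before having any — and need to
turn raw per-well fluorescence into *when, how much and where* each cell
secreted.

## What it computes

The measured fluorescence of a well is a **cumulative secretion signal**
(CSS): every past release still contributes through the staining kinetics.
A unit instantaneous release produces the normalized kernel

```
A(t) = [Σ_j w_j e^(−t/τ_decay,j)] · [Σ_k v_k (1 − e^(−t/τ_assoc,k))]
```

(weighted exponential association of the detection antibody × weighted
exponential decay from dissociation and photobleaching).  On a Δt-binned
grid the forward model is the causal convolution
`CSS_{t+1} = Σ_{i≤t} DSS_i · A_{t+1−i}`, and the **deconvoluted secretion
signal** (DSS, the per-bin release amount) is recovered by the triangular
recursion

```
DSS_t = (CSS_{t+1} − Σ_{i<t} DSS_i · A_{t+1−i}) / A_1,   DSS_t ← max(DSS_t, 0)
```

Four staining calibrations ship with the package (mouse IL-5, human IL-5,
human IL-13, and the IL-13→IL-5 cross-reaction kernel χ(Δt), which is
subtracted from the IL-13 channel before its deconvolution).

Around that core the package provides:

* **preprocess** — frame registration, rolling-median denoising, 5×5
  binning; empty-well coefficient normalization of illumination drift per
  (field-of-view quadrant, chamber, frame); baseline subtraction with the
  Q3 + 1.5·IQR outlier fallback.
* **calling** — robust noise floor σ̂ = 1.4826·MAD of empty wells;
  positivity at ≥ 3σ̂ sustained ≥ 2 frames (gaps ≤ 3 frames tolerated);
  onset times; silent / slightly-active / hyperactive classification at
  50σ̂ with a k-means concordance check; Kaplan–Meier activation curves,
  Mann–Whitney / log-rank tests with Benjamini–Hochberg correction.
* **localization** — 2D Gaussian fits of secretion images and
  displacement from the tracked cell centroid.
* **optics** — critical-angle / aperture-limit arithmetic to validate a
  TIRF dish configuration.
* **simulate** — a synthetic experiment generator (dish layout,
  heterogeneous populations, drift, noise, spot images) with ground truth,
  so the full pipeline is testable without a microscope.

## Worked example

`examples/simulate_and_call.py` builds a 2-chamber dish (249 wells per
chamber), simulates a mixed population under ×2 illumination drift and
unit detection noise, and runs the full pipeline:

```
empty-well noise SD (sigma-hat): 1.426
class counts: {'slightly_active': 125, 'silent': 56, 'hyperactive': 42}
phenotype recovery accuracy: 97.8% over 223 occupied wells
```

σ̂ is estimated from the empty wells of the same dish; each occupied well
is called positive if its CSS stays above 3σ̂ for ≥ 2 frames and
hyperactive if its maximum CSS reaches 50σ̂; the accuracy line compares
the calls with the generator's ground truth.  The other example scripts
(`deconvolve_trace.py`, `fit_calibration.py`, `localize_secretion.py`,
`check_optics.py`) each demonstrate one capability the same way.

A thin CLI mirrors the stages:

```
qlcis simulate --seed 7 --out wells.csv
qlcis preprocess --table wells.csv --out css.csv
qlcis deconvolve --table css.csv --calibration human-IL-5 --out dss.csv
qlcis check-optics --n1 1.34 --n2 1.52 --na 1.49
```

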