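# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `cordconn`.

## Signal model of the synthetic cord

Each subject's 4D acquisition (default 40×40 voxels in-plane, 16 slices of
5 mm, 250 volumes at TR 1.89 s) is composed voxel-wise as

```
v(x,t) = baseline(x)
       + a_GM · Σ_h w_h(x) · z_h,seg(x)(t)          gray-matter signal
       + a_card · g_card(x) · c(θc_slice(x)(t))      cardiac confound
       + a_resp · g_resp(x) · r(θr_slice(x)(t))      respiratory confound
       + a_CSF · channel signals (CSF ring)          CSF pulsation
       + a_NS · structured artifacts (non-spinal)    swallowing etc.
       + a_drift · slow drift (per slice)
       [ then optional in-plane Gaussian blur ]
       + thermal noise  N(0, σ²)
```

**Latent horn signals.** For each spinal segment (C6, C7, C8, T1) a 4-vector
process `z(t)` is drawn as standardized AR(1) series (φ = 0.3, a mild BOLD-like
autocorrelation at this TR) coloured by the Cholesky factor of the target
correlation matrix `R_true`. `R_true` is defined on the horn-mean signal,
because every downstream statistic operates on ROI means; this makes
parameter recovery well-defined. The default calibration sets DD = VV = 0.22,
W = 0.02, B = −0.08 (eigenvalues 0.68–1.28, comfortably positive definite).
Segments receive independent draws with the same `R_true` (or per-segment
matrices), so whole-cord ROI means — which pool segments — inherit the same
correlation structure, and intra-segment "fingerprints" are similar across
segments.

**Horn profiles.** The gray-matter probability map is a butterfly of four
truncated-Gaussian horn profiles plus a sub-threshold central-gray bridge,
all windowed by the cord cross-section. Truncation (compact support) is
deliberate: real probabilistic GM maps fall to exactly zero inside white
matter, and an untruncated Gaussian would leak a little of every horn's
signal across the whole cord, mixing ROI time courses even without any
point spread. The bridge contributes GM probability (the "central gray
matter" the mask-building step discards) but carries no latent signal. The
dorsal horns are long and thin and reach toward the dorsal cord surface;
the ventral horns are bulkier and sit deeper, so the 50%-thresholded dorsal
and ventral regions approach to about a one-voxel gap, and the ventral
horns come closer to the midline than the dorsal horns — both features of
the real anatomy that the mask construction rules react to.

**Confounds.** The cardiac trace is a single-peaked pulse waveform
`exp(3(cos 2πφ − 1))` on a beat train whose rate wanders as an AR(1) around
the configured mean (default 70 ± 5 bpm); the respiratory trace is a
sinusoid with slowly drifting rate (16 ± 2 breaths/min) and amplitude. The
voxel-level cardiac/respiratory confounds are Fourier series (orders ≤ 3
and ≤ 2) of the *slice-specific* phases computed from the emitted traces by
the same estimators the analysis uses, so they are phase-locked to the
physiological log by construction and exactly removable by the 32-regressor
set. CSF pulsation lives in a ring standing one voxel off the cord (the
pia); its four angular channels share a common pulsation component
(ρ = 0.5) plus channel-specific flow, at amplitude 2 (percent of the
100-unit baseline) — twice the GM fluctuation amplitude, reflecting that
CSF pulsation, not thermal noise, is the dominant noise source in spinal
fMRI. Non-spinal artifacts are three smooth random spatial patterns outside
the dilated cord+CSF times smooth time courses. Thermal noise defaults to
σ = 0.4 (0.4% of baseline): small relative to the physiological confounds,
which is the regime in which recovering ROI-level correlations is
meaningful. No measured values exist for these confound amplitudes; they
are documented assumptions, chosen once so that the base pipeline behaves
the way real spinal acquisitions do (stable DD/VV under denoising, the CSF
regressor selecting actual CSF voxels).

**Point spread.** The optional in-plane Gaussian blur (σ in voxels, default
0; 1.5 ≈ 3.5 mm FWHM for the mixing experiments) is applied to the
noiseless composite; thermal (receiver) noise is added afterwards, as a
physical PSF acts before detection.

**Determinism.** Every output is a pure function of (config, master seed).
Per-subject seeds are spawned from the master seed via `SeedSequence` and
recorded in the cohort manifest.

## Mask construction

Thresholds are inclusive (≥). The quadrant split uses the per-slice GM
centroid as origin; voxels exactly on a centroid line count as central gray
and are unassigned. The dorsoventral gap rule removes whole rows nearest
the centroid until at least one empty voxel (in-plane Chebyshev distance
≥ 2) separates dorsal from ventral. The left–right equalization computes
minimal Euclidean distances between nearest voxel centres and repeatedly
discards the central-most column band of the closer pair, symmetrically
from its left and right mask; if exact equality is unattainable (it always
is attainable on the shipped geometry) the loop stops before emptying a
horn and warns. COG masks take the in-mask voxel nearest the horn centroid
(ties broken lexicographically by (y, x)), never the rounded centroid,
which may fall outside a concave horn. Segment maps are thresholded at 50%;
overlap voxels go to the higher-probability segment and exact ties to the
more rostral one — a deterministic stand-in for the manual edits used on
real atlases. Nuisance masks: WM = (wm ≥ 0.10) minus a 1-voxel 3×3×3
dilation of (gm ≥ 0.50); NS = the complement of the dilated cord∪CSF,
restricted to the body.

## Nuisance regression and filtering

High-pass filtering is realized as discrete-cosine basis columns
(K = ⌊2·T·TR/cutoff⌋; K = 9 for T = 250, TR = 1.89 s, cutoff 100 s) inside
the same OLS design as the noise regressors, preserving the simultaneity
that avoids spectral misspecification, with a transparent and testable
linear-algebra implementation. The cardiac phase is linear within each
detected beat interval; the respiratory phase uses the empirical CDF of
absolute amplitude (the infinitesimal-bin limit of the amplitude histogram)
signed by the local slope. Heart rate is the 6-beat moving average of
instantaneous BPM interpolated to slice times (the smoothing span is a
fixed documented choice). The task regressor convolves 15-s events with a
standard double-gamma response. The CSF regressor averages the voxels whose
temporal variance reaches the 90th percentile within the cord+CSF region,
per slice. Rank-deficient designs fall back to the minimum-norm solution
with a warning; residuals are orthogonal to the design either way.

Pipeline-variant nuisance regressors (WM mean, first 4 CSF principal
components, first 10 non-spinal principal components, per slice) are
computed on the base residuals. Because all per-slice operations are
linear, regressing them from per-slice horn means and combining slices
weighted by voxel count is exactly equivalent to voxel-wise regression
followed by ROI averaging; the pipeline uses the cheap order. The band-pass
option is a zero-phase 4th-order Butterworth (0.01–0.08 Hz) applied to the
extracted ROI time courses — legitimate because filtering and averaging
commute (verified as a test invariant).

## Connectivity metrics

Series are standardized before the partial metrics, making the
precision-based formula scale-free. PARTIAL inverts the 4×4 sample
correlation matrix (condition number guarded; a singular matrix raises an
error that points to REGPARTIAL). REGPARTIAL applies the graphical lasso
with off-diagonal penalty α = λ/T (λ = 5 by default). The exact penalty
scaling of legacy tools is not recoverable from their descriptions, so the
λ/T convention is fixed here and guarded by the λ→0 ⇒ PARTIAL convergence
test. Group averages of correlations are plain means (no Fisher transform),
accepting the small conservative bias of that estimator. tSNR is computed
as temporal mean over temporal sd on base-denoised data with the mean
added back (residuals are zero-mean by construction); zero-sd voxels map
to 0 with a warning.

## Inference

Sign-flip tests use the one-sample t statistic; flipped statistics reuse
the unflipped sum of squares, so a cohort's entire null distribution is one
matrix product. P-values follow the add-one convention (observed statistic
included), guaranteeing p ∈ (0, 1]; all 2ⁿ patterns are enumerated whenever
2ⁿ ≤ n_flips. Zero-variance statistics map to t = 0, p = 1 (conservative);
a zero-variance *nonzero* mean yields t = ±∞, which orders correctly in all
rankings. FWE correction uses the max statistic over synchronized flips;
NPC computes within-flip per-analysis p-values by ranking each flip's |t|
in the full flip distribution of its analysis and combines them with
Fisher's −2Σln p; the identity flip is row zero. The repeated-measures
ANOVA collapses the factorial grid per factor and applies the
Greenhouse–Geisser ε from the double-centered covariance (ε = 1 for
two-level factors; cross-checked against an independent implementation).
Fingerprint similarity correlates the four intra-segmental indices between
segment pairs per subject, averages within distance class (3/2/1 pairs at
distances 1/2/3), and tests each distance by sign-flip with FWE over the
three distances; subjects with an undefined (constant-pattern) similarity
are dropped from inference with a warning.

## Problem sizes

The shipped test suite runs the full stack on a miniature cohort (8 slices,
80 volumes, 3 subjects) and the acceptance layer on full-size cohorts
(n = 20, 250 volumes) with 10,000 flips; permutation calibration uses 1000
null cohorts of n = 20 with 300–500 flips each, sizes at which the
Monte-Carlo error of a 5% rejection rate is well inside the asserted
[0.03, 0.07] band. The acceptance script completes in about a minute on a
single CPU.

## What the generator does and does not emulate

It emulates: the acquisition geometry and timing; latent inter-horn
correlation structure per segment; slice-phase-locked cardiac and
respiratory confounds; multi-channel CSF pulsation; non-spinal structured
artifacts; drift; thermal noise; point-spread mixing; motion *logs* (two
AR(1) translation traces exercise the motion regressors — no actual
displacement is simulated, as motion correction is out of scope). It does
not emulate: B0 inhomogeneity or z-shimming, coil profiles, registration
error (all maps share one grid), non-Gaussian noise, or neuronal
non-stationarity. Passing tests therefore certify the analysis machinery
and its statistical calibration on data whose generative assumptions are
known to hold — they do not certify performance on real scanner data.

## Mechanism experiments and an honest caveat

With blur σ = 1.5 voxels and a true within-hemicord correlation of zero,
the probabilistic masks — separated dorsoventrally by a single voxel —
show a clearly positive within-hemicord index (≈ +0.06 to +0.13 across
cohorts), reproducing the time-course-mixing interpretation of that
finding, while single-voxel COG masks show ≈ 0 (±0.02). A strict
"COG ≤ 0" expectation is not reproducible in expectation under a truly
zero latent correlation: at ~6 mm dorsoventral separation and 3.5 mm-FWHM
point spread the residual mixing bias is small but positive, so the sign
of the COG group mean at any single seed is near a coin toss centred just
above zero. Observed negative COG values in real data plausibly reflect a
genuinely (slightly) negative underlying correlation or residual
noise-regression structure rather than an unbiased zero.

## Known limitations

- The left–right equalization guarantees exact distance equality only when
  the two pair distances share a value set (true for the shipped geometry
  and typical atlases); otherwise it stops at the closest achievable
  configuration with a warning.
- The graphical-lasso penalty convention (λ/T) is a package choice; other
  implementations scale differently, so λ values are not transferable
  across tools.
- Slice timing assumes ascending acquisition with slices evenly spread
  over the TR.
- The ANOVA reports main effects only (no interactions), matching the
  analysis it implements.
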