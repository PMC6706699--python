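# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `ccpquant`.

## Synthetic data model

The generators exist because the analyses here are only trustworthy if they
recover known answers; every generator therefore returns its planted ground
truth.

**Movies.** Each CCP is a stationary isotropic 2D Gaussian of width
`psf_sigma` (default 1.1 px, the diffraction-limited PSF of a 100×/1.49 NA
TIRF objective on a ~6.45 μm-pixel camera) on a constant photon background
(default 100).  Defaults follow the targeted acquisition regime: 0.5
frames/s (2 s interval), 300 frames (10 min).  Noise is Poisson shot noise
on the noiseless image followed by additive Gaussian read noise (default SD
4), the standard sCMOS approximation; the per-pixel noise floor at
background is `sqrt(background + read²) ≈ 10.8`, so the default amplitude
range (80–250) spans SNR ≈ 7–23.

Event lifetimes follow a two-population mixture: transient assemblies
(fraction 0.4, exponential mean 8 s) and bona fide CCPs (mean 40 s), floored
at 2 frames.  Amplitude profiles: bona fide events rise linearly over the
first 30% of their lifetime, plateau, and fall over the last 20% (the shape
cohort averages display; no published generative form exists, so this is a
modelling choice); the normalized lifetime is sampled at frame midpoints so
short traces never sit on the zero endpoints of the ramps.  Transient
events are flat at half their drawn peak; persistent structures hold a
constant amplitude for every frame of the acquisition.  A slave channel
renders only events drawn slave-positive (Bernoulli with the requested
fraction) at `slave_amplitude_ratio` (default 0.7) times the master
amplitude.

Spots are placed uniformly with pairwise minimum spacing 4σ (plus a 2 px
guard band at the image border so every spot admits a full fit window);
densities that cannot satisfy the spacing raise a crowding error.  Overlap
handling is deliberately out of scope, so detection tests are never
confounded by unresolvable doublets.

**What the generator does not emulate:** evanescent-field depth effects,
camera gain and fixed-pattern noise, photobleaching, stage drift, spot
motion, and overlapping/merging structures.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every property of real movies.

**Titrations** are forward-simulated from the same model functions the
fitters use, plus Gaussian noise; the ITC default design is 20 injections
of 2.43 μl from the syringe into a 170 μl cell.

## Detection

Candidates are local maxima of a difference-of-Gaussians band-pass (σ and
1.6σ) above a permissive threshold (3× the robust MAD-based noise SD of the
DoG image; floored at a tiny fraction of the DoG maximum so noiseless flat
background never yields candidates).  Each candidate is fit by least
squares over an 11×11 window with σ fixed (free-σ refit available); the
unbounded Levenberg–Marquardt solution is accepted when its center stays
within the position tolerance of the seed and refit with box constraints
otherwise.

**Significance.** The null hypothesis is `A ≤ k·σ_res`, where `σ_res` is
the residual SD of the fit; the statistic `(A − k·σ_res)/SE(A)` is referred
to a t distribution with `n_pix − n_params` df.  The offset `k` (default 2)
exists because candidates are *selected* at local maxima: the amplitude at
a noise maximum is biased upward, and a plain `A > 0` test would not hold
the false-positive rate at α.  Requiring the amplitude to clear twice the
local noise restores type-I control (measured ≈ 0 on pure noise) while
costing nothing at the SNR ≥ 5 regime the analyses target.  For pre-linked
track tables whose noise SD is known exactly and where no selection
occurred, per-frame significance is instead an exact one-sided z-test of
`A > 0` at α = 0.05.

Duplicate fits within 1 px are merged keeping the larger amplitude.
Insignificant detections are retained behind a flag, never silently
dropped.  Slave measurements constrain the fitted center within
`slave_search_radius` (default 2 px) of the master position and are paired
1:1, order-preserving, with the masters.

## Normalization

The "distribution" being matched is the empirical quantile table on
percentiles 1–99.  The reference is the per-percentile median across cells
(≥ 3 cells required); each cell's scale is the closed-form MSE minimizer
`s* = ΣQ_ref·Q_cell / ΣQ_cell²`, cross-checked in tests against a grid
search at step 1e-4.  Cells with fewer than 20 detections are refused.
Channels are normalized independently; a caller wanting the master's factor
applied to slaves can do so explicitly.

## Colocalization

Equal-count binning sorts masters by intensity (stable sort, so ties may
straddle bins) into `n_bins` (default 10) bins whose counts differ by at
most one, remainder to the lowest-intensity bins.  The slave significance
flag is computed once upstream with one α, so compared conditions share the
threshold by construction.  Condition comparisons use the Welch
(unequal-variance) two-tailed unpaired t-test.

## Tracking and dynamics

Linking is greedy mutual-nearest-neighbour within `max_displacement`
(default 3 px) with gap closing up to `max_gap` (default 2) frames —
adequate because synthetic scenes are non-crowded by construction; a full
LAP/Kalman tracker is a non-goal.  Classification: persistent ⇔ the track
spans frames 0..n−1; otherwise bona fide iff the track has ≥ 4 frames and
its maximum master amplitude reaches the intensity threshold (default 5×
the per-pixel noise floor); otherwise transient.  Persistent structures are
excluded from lifetime statistics and reported as a density per μm²
(pixel size default 0.0645 μm).

The "p95" lifetime statistic is interpreted as the **mean lifetime of the
tracks at or above the 95th percentile** (the long-lived tail most
sensitive to stalled maturation); the percentile value itself is also
reported.  A track is slave-positive when ≥ 30% of its frames carry
significant slave signal (config-exposed).

Cohort traces resample each track's channel traces onto a common
50-point normalized time axis by linear interpolation; the SE of a
single-track cohort is 0 by convention, and an empty cohort yields an empty
summary rather than an error.

**Timing.** Traces are smoothed with a Gaussian kernel of SD 1.2 samples;
the maximum is localized with sub-sample precision by cubic-spline
interpolation restricted to ±1 sample around the discrete argmax.  The
maximum recruitment rate applies the same localization to the central
difference of the smoothed trace.  Flat traces return their earliest
maximum with a degeneracy flag; a peak that fails to clear 3× a
first-difference noise estimate above the trace median is flagged
unreliable (white-noise traces are flagged in ≥ 90% of trials).

## Binding fits

All fitters are nonlinear least squares with positivity of K_D (and SPR
rate ordering k_fast > k_slow) enforced by log-parameterization, standard
errors from the Jacobian at the optimum, and convergence flags rather than
exceptions on poorly informative data (no saturation, rate degeneracy,
c-value outside [1, 1000]).  The biexponential uses 5 log-spaced rate-ratio
starts and is deterministic given the data; data that are truly
single-exponential are canonicalized so the signal sits on the fast
component.  The SPR amplitude-vs-concentration isotherm is the 1:1 model
without a baseline offset (none is stated for the original analysis; an
offset can be added trivially if needed).

The ITC model is the independent-single-site (Wiseman) isotherm with exact
mass balance: each injection of volume v displaces an equal volume of
pre-injection cell solution (cell-side concentrations diluted by 1 − v/V₀
before titrant addition), the bound-complex concentration solves the
mass-action quadratic exactly, and the heat is ΔH × Δ(bound moles in the
cell).  Tests verify equivalence to an independent integration that tracks
moles explicitly and finds the bound concentration by Brent root-finding,
to 1e-6.  Concentrations are handled in molar internally; every fitted K_D
is reported in the unit of its input concentration axis.

## Problem sizes used in validation

The recovery suite uses 2000 two-channel tracks for the slave-positivity
fractions, 1000–1500 spots for still-image co-occurrence, and 10+10
(3+3 in the fast suite) 128×128 movies of 300 (100) frames for the
persistent-density contrast — sizes at which binomial sampling error is
small against the stated tolerances.

## Known limitations

* The image-route slave-positivity rate is biased low for weak transient
  signals: the k = 2 amplitude margin that buys type-I control costs power
  below ~3× the noise floor.  The track-table route (exact z-test) is
  unbiased and is what the fraction-recovery checks use.
* The tracker does not handle merging, splitting, or crowded fields.
* The detector assumes an isotropic PSF and a locally constant background.
* ITC fitting assumes a fully active cell-side species (no active-fraction
  parameter) and subtracted blanks.
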