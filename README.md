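# ccpquant

Quantitative analysis of clathrin-mediated endocytosis (CME) imaging and of
the binding biophysics that regulates it.

Clathrin-coated pits (CCPs) appear in TIRF microscopy as diffraction-limited
spots that nucleate, grow, and either mature into vesicles or stall.
Deciding *which* proteins are recruited to a pit, *when*, and *how strongly
they bind* requires a chain of statistics that is easy to get subtly wrong:
sub-pixel spot detection with a principled significance test, dependent
("slave") quantification of a second channel at positions defined by a
master channel, cross-cell intensity normalization, equal-count
proportion-vs-intensity curves, lifetime/persistence classification of
tracks, cohort-averaged recruitment profiles with sub-sample peak timing,
and equilibrium/kinetic titration fits.  `ccpquant` implements that chain
as a tested Python library, validated end-to-end on synthetic data with
known ground truth.

It is intended for cell biologists and microscopists analysing live-cell or
fixed-cell CCP data (EGFP-CLCa master channel with AP2 / phospho-AP2 /
NECAP / SNX9 slave channels and the like), and for biophysicists fitting
anisotropy, SPR, or ITC titrations of the underlying interactions.

## The statistics at the core

* **Detection.** Spots are fit as `I(x,y) = A·exp(−((x−x₀)²+(y−y₀)²)/(2σ²)) + c`
  with σ fixed to the PSF width.  A detection is significant when the
  one-sided test of `A > k·σ_res` (statistic `(A − k·σ_res)/SE(A)`, t
  distribution with `n_pix − 4` df) rejects at level α.  Slave channels are
  fit at master positions with the center constrained to a search radius,
  so every master has a paired slave measurement.
* **Normalization.** Each cell's intensity distribution (quantile table,
  percentiles 1–99) is scaled onto the median-across-cells reference by
  `s* = ΣQ_ref·Q_cell / ΣQ_cell²`, the MSE-optimal factor.
* **Colocalization.** Pearson correlation of paired intensities, and the
  proportion of master spots with significant slave signal per equal-count
  master-intensity bin.
* **Track statistics.** Greedy mutual-nearest-neighbour linking with gap
  closing; persistent structures = tracks spanning the whole acquisition
  (reported per μm²); bona fide CCPs = intensity-thresholded trajectories;
  lifetime distributions and the mean lifetime of the top 5%; cohort mean ±
  SE traces; recruitment timing from Gaussian-smoothed traces (kernel SD
  1.2 samples) with cubic-interpolation sub-sample maxima, and maximum
  recruitment rate from central differences.
* **Binding models.** Anisotropy `F = F_f + (F_b − F_f)[L]/(K_d + [L])`;
  SPR dissociation `R(t) = A_f e^{−k_f t} + A_s e^{−k_s t}` (k_f > k_s)
  with a 1:1 amplitude isotherm `A(C) = A_max·C/(K_D + C)`; single-site ITC
  with exact per-injection mass balance and injection-volume displacement;
  NMR chemical-shift perturbation `Δδ = √(Δδ(¹H)² + (Δδ(¹⁵N)/5)²)`.

Every generator in `ccpquant.synthgen` returns the planted ground truth, so
each estimator is scored against known answers.

## Worked example

`examples/01_simulate_and_detect.py` renders 50 spots at SNR ~10 and
detects them:

```
planted spots      : 50
significant spots  : 50
recall             : 1.000
RMS position error : 0.131 px
```

All 50 pits are recovered with sub-pixel accuracy and no false positives —
the amplitude test keeps background noise maxima out.  Binding fits
(`examples/05_binding_fits.py`) on noisy simulated titrations:

```
anisotropy  K_d = 9.81 +/- 0.45 uM (truth 10)
SPR         k_fast = 0.0499 /s, k_slow = 0.0050 /s (truth 0.05, 0.005)
ITC         K_D = 49.1 uM, n = 1.09, dH = -36.7 kJ/mol (truth 55 uM, 1.0, -40)
```

The other examples cover full movie analysis (lifetimes, persistent
density, slave positivity), still-image colocalization, and recruitment
timing.  A thin CLI mirrors the pipeline:
`ccpquant run-all --config cfg.yaml --out results/`.

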