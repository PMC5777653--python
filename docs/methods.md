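# Methods

This note documents the models, conventions and numerical choices behind
`dfcd`, and what the synthetic-data tests do and do not establish.

## Sliding-window degree

For a window of `n` volumes the Pearson correlation is computed between
every pair of masked voxels on exactly those samples (standardized matrix
products; the integer degree counts are tested to match a naive per-pair
recomputation exactly).  A voxel's degree is the count of partners with
`|r|` above the two-sided critical value of a zero-correlation test at
`p = 0.001` with `df = n − 2` — with this convention the null per-pair
exceedance rate is exactly `p`.  A `laterality="positive"` switch counts
only positive correlations (the convention of some degree-centrality
tools); the threshold is the two-sided one in both cases.

* **Window lengths.** Nominal lengths are converted to samples by rounding
  (`n = round(length / TR)`), accepted when within one TR of the nominal
  value: 7.8 s → 24/12/6/3 samples at TR 0.33/0.66/1.32/2.64 s, 13.2 s →
  40/20/10/5, 18.4 s → 56/28/14/7, 26.4 s → 10 at TR 2.64 s.
* **Minimum window.** `n ≥ 3` (df = 1).  The critical value at df = 1 is
  finite (t ≈ 636.6, r_c ≈ 0.9999988): 3-sample windows are legal but
  detect essentially nothing — which is itself the long-TR phenomenon the
  analysis quantifies.
* **Centering.** Window values sit at center time `(i + (n−1)/2)·TR`; for
  even `n` the center is fractional and is *not* snapped to the sample
  grid (time is continuous).
* **Edges and degeneracy.** Only full windows are computed.  A voxel with
  zero variance inside a window has undefined correlations and contributes
  no connections in that window (logged); such windows are otherwise kept.
* **Normalization.** Degrees are divided by the gray-matter mean degree of
  the same window, making the gray-matter mean exactly 1; windows whose
  gray-matter mean is zero are flagged missing (NaN) rather than divided.
  Downstream averages and peak searches are NaN-aware.

## Nuisance model

Confounds follow the common fast-fMRI recipe: six motion parameters, mean
CSF and white-matter signals, the global signal, and eight RETROICOR
regressors (sine/cosine of cardiac and respiratory phase, orders 1–2).
All are removed in one joint OLS regression with an intercept; no temporal
filtering.  The global signal is the gray-matter mean by default
(configurable), since the masking convention is not fixed by the method.
Exactly collinear columns are detected by pivoted QR and dropped with a
warning.  Residuals are orthogonal to every retained column and the
operation is idempotent.

Cardiac phase is the linear fraction of the inter-beat interval; beats are
local maxima of the pulse trace above its median with a 0.25 s minimum
separation (robust on clean traces, configurable).  Respiratory phase uses
amplitude histogram equalization via the empirical CDF, signed by the
breathing direction, so one breath maps to one [0, 2π) cycle and the trace
maximum maps to π.

## Event-locking and percent change

Events are aligned to the window-center grid by nearest sample (no
interpolation); events without full epoch coverage are dropped and logged.
The task convention covers −10…+20 s around onset; the baseline is the
half-open window `[onset − 5 s, onset)` (the onset sample is
post-stimulus).

**Percent-change denominator.** The per-event baseline mean `B_e` is
subtracted per event, but the default percent scale divides by the
*pooled* baseline mean across events.  Dividing each event by its own
`B_e` is biased upward at offsets where the curve has decorrelated from
its baseline (Jensen: `E[1/B] > 1/E[B]`); on a stationary synthetic degree
curve this bias reached tens of percent — larger than the transient being
measured — while the pooled denominator is unbiased and leaves the
arithmetic of constant-baseline cases unchanged.  Per-event division
(`mode="percent_event"`) and subtraction only (`mode="subtract"`) remain
available.

The spontaneous-event (IED) convention covers −20…+30 s and needs no
baseline: the gray-matter-normalized curve has global mean 1, so percent
change is `100·(value − 1)`.

**ROI definition.** The localizer is a single-run GLM (intercept + event
boxcar convolved with the HRF, fine-grid convolution) thresholded at a
configurable t-map quantile (default 0.95).  This deliberately simplifies
a group-level random-effects FWE analysis (threshold t > 7.63 in the
multi-subject setting), which requires many subjects and a spatial model
that are out of scope; the quantile rule recovers the generator's
ground-truth cluster with ≥95% sensitivity at ≤5% false inclusion in the
tested regimes.

## Peak statistics

Peak 1 and peak 2 are the curve maxima in [0, 10) s and [10, 20] s
(configurable; the maxima are reported even when they are not local maxima,
with a flag).  The 4 × 3 repeated-measures ANOVA uses classical univariate
sums of squares with each effect tested against its own effect-by-subject
interaction.  Greenhouse–Geisser epsilon is computed per effect from the
covariance of the subjects' cell scores projected onto an orthonormal
contrast basis (for main effects this equals the textbook epsilon of the
collapsed level covariance; for the interaction the basis is the Kronecker
product of the factor contrasts), clipped to `[1/d, 1]`.  A two-level
factor has epsilon exactly 1.  Corrected p-values use the F distribution at
epsilon-scaled degrees of freedom; uncorrected p-values are also reported
(the uncorrected F test is the exact test under sphericity, and is what the
null-calibration test checks — GG is deliberately conservative there).
Post-hoc paired t-tests default to the 30 single-factor cell pairs of the
4 × 3 design with Bonferroni threshold 0.05/30; the family size is always
recomputed from the comparisons actually supplied.  One source describes
the peak-timing analysis as "three-way" while specifying a 4 × 3 design;
the two-way within-subject model is used throughout.

## Synthetic generator: the stated world

Each voxel's series is

```
baseline + gain·(event boxcar ⊗ HRF)           evoked response
         + cluster spontaneous fluctuation      0.01–0.1 Hz, shared in-cluster
         + (1 + β·g(t))·shared white noise      coupling transient
         + drift + physio sinusoids + motion coupling + voxel noise
```

with all randomness from a single seeded generator.  The HRF is the
canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6, dispersions
1 s), sampled so a coarse grid equals the subsampled fine grid.

* **Coupling transient.** `g(t)` is a Gaussian bump (σ = 4 s,
  `coupling_width`) at each event's hemodynamic peak, scaled per cluster by
  its gain ratio and by `coupling_modulation` (β = 1.5 in the demo
  network).  The transient is deliberately *symmetric and compact*: a
  deterministic evoked waveform alone concentrates within-window variance
  late (where the window spans the response fall and undershoot), which is
  not how event-locked connectivity behaves; a symmetric synchrony bump
  centered at the response peak makes the window-centered degree maximum
  coincide with the hemodynamic peak for every window length.  Both the
  modulation and the shared noise default to zero in the bare
  `NetworkSpec`, so all noiseless limiting cases hold exactly.
* **Demo amplitudes** (chosen a priori for a 3 T-like regime and then
  frozen): baseline 100, evoked visual gain 10 (≈1.2% signal change for a
  500 ms event), voxel noise 1 (tSNR ≈ 100), cluster-shared spontaneous
  fluctuations 0.9, shared noise 0.8.  These place the in-cluster window
  correlation in the *sensitive* (non-saturated) range of the degree
  statistic — consistent with the modest (tens of percent) degree changes
  the method reports in practice; at saturation the degree curve flattens
  into a plateau and peak timing becomes meaningless.
* **Geometry.** A 12×12×4 grid with three cuboid clusters of 18 voxels
  each (≈9% of the mask) — small relative to the background, as a
  functional ROI is small relative to gray matter; otherwise the
  gray-matter normalization cancels the transient it is supposed to
  reference.
* **Physio.** Raw pulse (sharp von-Mises-shaped systolic peaks) and belt
  (sinusoid) traces at 50 Hz; TR-sampled sinusoids of the same frequencies
  and phases are injected into the BOLD, so RETROICOR regressors derived
  from the traces remove the injected contamination (>99% in tests).
* **IED emulation.** 30 min series at TR 0.66 s with sparse strong events
  (duration 0.5–3 s, stronger modulation), analyzed with the 13.2 s /
  20-sample window and the global-mean convention.

**What a green test does not establish.**  The generator produces the
statistical structure the analysis assumes — cluster-shared signals,
event-locked coupling transients, separable nuisance — not realistic
anatomy, spatial autocorrelation, scanner drift, motion artifacts in image
space, or the amplitude calibration of any particular scanner.  Group-level
percentages from the demo world agree with plausible magnitudes only
qualitatively; no quantitative claim about real data follows from them.

## Numerical choices

* Degree counting uses strict `>` against the threshold; with continuous
  data, ties have probability zero and the optimized path matches the
  naive recomputation exactly in tests (V = 50, T = 200).
* OLS uses QR; perfect fits in the localizer produce capped t-values
  (10⁶) rather than infinities.
* Derived seeds come from `numpy.random.SeedSequence` and are masked below
  2³¹.
* Scale: simulations in tests are desk-scale (≤ 576 voxels, ≤ 10 min
  series, ≤ 100 replicates) so the full suite runs in minutes on one CPU;
  all statistical tolerances are 3 Monte-Carlo/binomial standard errors at
  those sizes.

## Known limitations

* No spatial statistics (cluster inference, FWE maps) and no graph metrics
  beyond degree.
* The respiratory-phase histogram equalizer assumes a reasonably
  stationary breathing amplitude distribution.
* The RM-ANOVA requires a complete balanced design; missing cells are an
  error, not imputed.
* Event-locked analysis assumes events are sparse enough that epochs
  rarely overlap their neighbours' transients; heavily overlapping designs
  would need deconvolution, which is out of scope.
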