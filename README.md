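# dfcd — dynamic functional connectivity degree for event-related fMRI

`dfcd` implements sliding-window, voxel-pairwise degree analysis of BOLD
fMRI for *brief* events (sub-second visual stimuli, interictal epileptiform
discharges), together with a ground-truth synthetic BOLD generator so that
every stage of the pipeline is testable without any data download.

## The statistic

The **functional connectivity degree** (FCD) of voxel *v* in a temporal
window of *n* consecutive volumes is

    FCD(v) = #{ u ≠ v : |r(u, v)| > r_c },

where *r(u, v)* is the Pearson correlation of the two voxels' series over
exactly those *n* samples and *r_c* is the two-sided critical value of a
zero-correlation test at p < 0.001,

    r_c = t_c / sqrt(t_c² + df),   t_c = t⁻¹(1 − p/2, df),   df = n − 2,

so that on null data the per-pair exceedance rate is exactly *p*.  The
window slides in steps of one volume; each window's counts are assigned to
its **center** time, and the per-voxel degree is **normalized by the
gray-matter mean** at the same window.  Event-locked epochs of a region's
degree curve are baseline-corrected (mean of the 5 s before onset) and
expressed as percent change; peak amplitude and latency per condition feed
a 4 × 3 (TR × window) within-subject repeated-measures ANOVA with
Greenhouse–Geisser correction and Bonferroni-corrected paired post-hocs
(30 single-factor comparisons, threshold 0.05/30).

Because the degree estimate improves with samples per window, repetition
time matters: at TR 0.66 s a 13.2 s window holds 20 samples (r_c ≈ 0.68),
while at a conventional TR 2.64 s it holds 5 (r_c ≈ 0.99) — degree
transients of brief events are essentially invisible at long TR.  The
synthetic generator reproduces this regime: clusters of voxels share an
HRF-shaped evoked response plus an event-modulated coupling transient,
low-frequency fluctuations, drift, cardiac/respiratory contamination and
motion-coupled noise, with raw physio traces for RETROICOR.

## Worked example

```python
import numpy as np
from dfcd import synth, nuisance, fcd, eventlock, stats

hrf = synth.HrfModel()                       # canonical double-gamma, peak 6 s
net = synth.demo_network()                   # 12x12x4 grid, 3 clusters
events = synth.make_event_train(18, 20, 32, 0.5, 568, seed=7)
sim = synth.generate_bold(net, events, hrf, tr=0.66, total_time=600, seed=7)

conf = nuisance.assemble_confounds(sim.bold, sim.confounds.motion,
                                   sim.confounds.csf, sim.confounds.wm,
                                   sim.confounds.cardiac,
                                   sim.confounds.respiratory)
bold = nuisance.partial_regress(sim.bold, conf)   # 17 confounds + intercept

wspec = fcd.WindowSpec.from_seconds(13.2, bold.tr)
print("samples per window:", wspec.n_samples)
print("r threshold (p<0.001):", round(fcd.correlation_threshold(wspec.n_samples), 4))

degree = fcd.normalize_fcd(fcd.sliding_fcd(bold, None, wspec))
roi, _ = eventlock.glm_localizer(bold, events, hrf, threshold_quantile=0.95)
times, curve = eventlock.extract_region_timecourse(degree, roi)
epochs = eventlock.epoch_percent_change(times, curve, events)
p1, p2 = stats.find_peaks(epochs.offsets, epochs.average)
print(f"peak 1: {p1.amplitude:.1f}% at {p1.latency:.2f} s")
print(f"peak 2: {p2.amplitude:.1f}% at {p2.latency:.2f} s")
```

Output:

```
samples per window: 20
r threshold (p<0.001): 0.6788
peak 1: 31.6% at 6.60 s
peak 2: 18.1% at 10.56 s
```

The 13.2 s window at TR 0.66 s holds 20 samples; the ROI degree rises by
~30% of its pre-stimulus baseline, peaking about 6 s after the 500 ms
stimulus — the hemodynamic delay — with a weaker secondary peak later.

## Command line

A thin CLI wraps the library:

```sh
dfcd simulate --tr 0.66 --total-time 360 --seed 1 --out run/
dfcd denoise  --bold run/bold.nii.gz --motion run/motion.tsv \
              --compartments run/compartments.tsv \
              --cardiac run/cardiac.tsv --respiratory run/respiratory.tsv \
              --out run/resid.nii.gz
dfcd fcd      --bold run/resid.nii.gz --window 13.2 --out run/fcd.nii.gz
dfcd eventlock --fcd run/fcd.nii.gz --events run/events.tsv \
              --labels run/clusters.nii.gz --region 1 --out run/epochs.tsv
dfcd run-all  --seed 1 --out run/all
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the full demonstration pipeline from scratch — simulation of 10
subjects at all four TRs (2.64/1.32/0.66/0.33 s), nuisance regression,
degree maps at the three window lengths, event-locked ROI epochs, peak
tables and the repeated-measures ANOVA with post-hocs — printing the
group-level test results and writing the results object to `--out`.
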