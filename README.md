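# pulseclean

Curation pipeline for simultaneous ECG / PPG / arterial blood pressure
(ABP) waveform records, for researchers building and benchmarking
**cuff-less blood pressure estimation** models.

ICU waveform databases hold millions of hours of simultaneously recorded
lead-II ECG, fingertip photoplethysmogram (PPG) and invasive arterial
pressure. Turning them into a trustworthy benchmark requires: finding the
per-beat landmarks, windowing the signals, rejecting corrupted stretches,
attaching reference SBP/DBP labels, and assembling testing sets that
satisfy the AAMI device-validation protocol. `pulseclean` implements that
whole chain as a reusable library + CLI, together with a synthetic-data
module that emulates the source databases with exact ground truth so every
stage is testable offline.

## What the pipeline does

1. **Record selection** (`waveform_io`) — keep the longest interval in
   which all three channels hold valid samples (≥ 10 s); resample 500 Hz
   records to the common 125 Hz rate with polyphase anti-aliasing.
2. **Fiducial points** (`fiducials`) — ECG R-peaks via Pan-Tompkins
   (band-pass, derivative, squaring, 150 ms integration, adaptive dual
   thresholds, search-back from the running average of 8 R-R intervals);
   PPG/ABP systolic peaks via Elgendi's two-moving-average detector on a
   zero-phase 4th-order Chebyshev-II [0.5, 8] Hz band-passed trace, with
   turning points as the minima between consecutive peaks. ABP amplitudes
   at the systolic peak / following turning point are the beat's SBP/DBP.
3. **Segmentation + QC** (`segment_qc`) — non-overlapping 10-s windows,
   labeled with the mean beat-to-beat SBP/DBP, screened by four rules in
   order: flatline/saturation runs, cardiac-cycle presence, PPG skewness
   SQI (negative skewness in any 5-s window rejects), and lag-aligned
   PPG–ABP Pearson correlation (reject below 0.9) — mutual validation that
   catches corrupted ABP morphology without thresholding BP values.
4. **Post-hoc SQI** (`sqi`) — feasibility rules (heart rate 40–180 bpm,
   max gap ≤ 3 s, max/min interval ratio < 2.2) plus an adaptive
   template-matching SQI (mean Pearson correlation of beat-centered
   windows against their average); quality thresholds 0.66 (ECG) and
   0.86 (PPG).
5. **Benchmarking subsets** (`subsets`) — an AAMI-compliant testing set
   (≥ 85 subjects, 3–14 measurements each, ≥ 255 total, ≥ 5 % SBP ≤ 100,
   ≥ 5 % SBP ≥ 160, ≥ 20 % SBP ≥ 140, ≥ 5 % DBP ≤ 60, ≥ 5 % DBP ≥ 100,
   ≥ 20 % DBP ≥ 85) built by a deterministic constrained sampler, its
   companion calibration set, and subject-balanced training /
   calibration-based / calibration-free splits (e.g. 360 + 40 segments per
   subject at K = 400, 10 % of subjects held out entirely).
6. **Error metrics** (`metrics`) — with error `e_i = BP̂_i − BP_i`:
   ME = mean(e), SDE = sample SD of e (n−1), MAE = mean|e|, RMSE,
   R² = 1 − SS_res/SS_tot, and Pearson R; plus the AAMI model criterion
   |ME| ≤ 5 mmHg and SDE ≤ 8 mmHg.

The `synth` module generates coupled triplets: an asymmetric pulse train
whose per-beat maxima/minima equal the requested SBP/DBP exactly, a PPG
that is the normalized ABP delayed by a configurable inter-signal lag
(up to ±1 s), a spike-train ECG, injectable corruptions (NaN gaps,
flatlines, saturation, noise bursts, morphology inversion), and
multi-subject cohorts with a two-level (between/within-subject) BP model.

## Worked example

```python
import numpy as np
from pulseclean import (SynthParams, generate_triplet, process_record,
                        compute_metrics, aami_model_check)

params = SynthParams(heart_rate=72, duration=60, sbp=118, dbp=68,
                     ppg_abp_lag=0.296, hr_variability=0.02, seed=3)
trip = generate_triplet(params)
segments = process_record(trip.record)
print(f"{len(segments)} segments")
for seg in segments[:3]:
    q = seg.qc
    print(f"  t={seg.start_s:4.0f}s  SBP={seg.sbp_ref:6.1f}  DBP={seg.dbp_ref:5.1f}  "
          f"lag={q.alignment_lag:2d} samples  r={q.ppg_abp_r:.3f}  pass={q.overall_pass}")

rng = np.random.default_rng(0)
ref = rng.normal(120, 22, 500)
est = ref + rng.normal(1.0, 6.0, 500)
m = compute_metrics(ref, est)
print(f"ME={m.me:.2f} mmHg  SDE={m.sde:.2f} mmHg  MAE={m.mae:.2f} mmHg  "
      f"R2={m.r2:.3f}  AAMI pass: {aami_model_check(m)}")
```

prints

```
6 segments
  t=   0s  SBP= 118.0  DBP= 68.0  lag=37 samples  r=1.000  pass=True
  t=  10s  SBP= 118.0  DBP= 68.0  lag=37 samples  r=1.000  pass=True
  t=  20s  SBP= 118.0  DBP= 68.0  lag=37 samples  r=1.000  pass=True
ME=0.59 mmHg  SDE=5.63 mmHg  MAE=4.47 mmHg  R2=0.936  AAMI pass: True
```

The pipeline recovers the generator's reference pressures (118/68 mmHg)
exactly, finds the injected 296 ms PPG–ABP lag (37 samples at 125 Hz)
with perfect aligned correlation, and all clean segments pass QC. The
simulated estimator (1 mmHg bias, 6 mmHg error SD) satisfies the AAMI
model criterion.

## Command line

```bash
pulseclean simulate --config cohort.yaml --out raw/       # synthetic cohort
pulseclean clean    --in raw/ --fs 125 --out cleaned/     # valid intervals + resampling
pulseclean fiducials --in cleaned/ --out fid/             # characteristic points
pulseclean qc       --in cleaned/ --out segs/ --report qc.csv
pulseclean sqi      --in segs/ --report sqi.csv
pulseclean split    --in index.csv --k 400 --seed 7 --out bundle/
pulseclean aami-check --labels labels.csv
pulseclean metrics  --ref ref.csv --est est.csv --aami
```

## Limitations

The synthetic generator emulates signal structure (quasi-periodicity,
amplitude semantics, inter-signal lag, common corruption modes), not
patient physiology; see `docs/methods.md` for the model, the numerical
conventions, and what passing tests do and do not establish about real
ICU recordings.
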