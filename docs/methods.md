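# Methods

This note documents the models, conventions and design choices behind
`pulseclean`, in the order data flows through the pipeline.

## Synthetic signal model

All three channels derive from one quasi-periodic beat grid. Beat-to-beat
intervals are `60/HR × (1 + v·ε)` with `ε ~ N(0,1)` truncated at ±3 and a
fractional variability `v` (default 0.02 for cohorts); one beat onset is
anchored at 35 % of a period after the record start and the grid is
extended a few beats beyond both record edges, so edge beats are whole
and a lagged copy of the waveform needs no padding.

* **ABP** — per cycle, a half-cosine systolic rise from the previous
  diastolic level to the requested SBP at 15 % of the cycle, then a
  quasi-exponential diastolic run-off (time constant 0.3 cycle) pinned to
  the requested DBP at the next onset. Consequences relied on by tests:
  the per-beat maximum *equals* SBP and the turning-point amplitude
  *equals* DBP before noise, and the waveform is right-skewed at every
  heart rate (brief peaks, long run-off). A half-cosine decay was
  rejected because it dwells near the systolic level, driving the pulse
  skewness to ~0 and invalidating the premise of the skewness-SQI rule
  even on clean signals.
* **PPG** — the min–max normalized ABP delayed by an integer number of
  samples (`ppg_abp_lag`, positive = PPG later, supported to ±1 s). This
  makes lag recovery and the PPG–ABP correlation exactly verifiable.
* **ECG** — Gaussian R spikes (σ = 12 ms) at beat onsets with smaller
  P/T bumps. The bumps are deliberate: they keep the baseline strictly
  non-constant (a mathematically flat baseline would trip the flatline
  rule on clean data) and give the QRS detector realistic competition.

Artifacts (NaN gap, flatline, high/low saturation, noise burst,
morphology inversion) are injected *after* synthesis, so returned ground
truth is exact; overlapping artifacts on one channel are rejected.

Cohorts use a two-level BP model: subject mean (SBP, DBP) from a
correlated bivariate normal (defaults 117.8 ± 17.2 / 62.1 ± 10.8 mmHg,
r = 0.6 — values typical of per-subject summaries of large ICU waveform
collections), then per-segment targets `mean + N(0, within-SD)`
(defaults 11.9 / 6.5 mmHg) held constant within each 10-s segment, with
DBP clamped to at least 15 mmHg below SBP. Because every beat in a
segment carries the segment's target, `generate_cohort_labels` (no
waveform synthesis) and the full waveform pipeline produce identical
segment labels on noise-free data; the tests verify this equivalence, and
the acceptance script exploits it to build label pools quickly.

**What the generator does not emulate:** pulse-wave morphology variation
(dicrotic notches, respiratory modulation), arrhythmias, drift between
the PPG and ABP amplitude envelopes, or any physiological coupling
between heart rate and pressure. Passing tests therefore establishes
that the *rules and algorithms are implemented correctly and recover
known structure*, not that their thresholds are clinically optimal.

## Fiducial extraction

* **Pan-Tompkins (ECG)** follows the original stages — 5–15 Hz band-pass,
  derivative, squaring, 150 ms moving-window integration, adaptive dual
  thresholds (`THR1 = NPK + 0.25(SPK − NPK)`, refractory 200 ms), and
  search-back with `THR1/2` when the gap since the last beat exceeds
  1.66× the running mean of the previous 8 intervals. Running it on the
  whole record (not per segment) lets the interval estimate settle. Two
  offline adaptations: all filters are zero-phase (so the integrated
  signal is time-aligned with the ECG and detections refine to the raw
  R-wave maximum), and the threshold levels initialize from global
  candidate statistics (90th percentile of candidate heights / median of
  the integrated signal) rather than the first two seconds, which a
  filter edge transient can poison.
* **Elgendi (PPG/ABP)** uses the published defaults: squared clipped
  signal, moving averages W1 = 111 ms and W2 = 667 ms, offset
  β = 0.02 × mean, candidate blocks at least W1 wide, 300 ms refractory.
  The pre-filter is the canonical pulse-wave Chebyshev-II design: order
  4, 20 dB stop-band, stop-band edges [0.5, 8] Hz, applied
  forward-backward. (A "total order 4" variant with stop edges outside
  the band was evaluated and rejected: its transition bands are so wide
  that a 4 Hz in-band tone is attenuated by half, contradicting the
  filter's stated pass band.) The signal mean is removed before
  filtering so DC rejection is exact and peak indices are
  offset-invariant.
* PPG and ABP share one delineation path; filtering is used for
  **localization only**. Detected peaks are refined to the raw-signal
  local maximum and turning points are raw-signal minima between peaks,
  so SBP/DBP amplitudes are read from the unfiltered ABP. A refined peak
  must be verifiable as a local maximum; record-edge candidates that are
  not are dropped, which is why beat-count tests allow a one-beat
  discrepancy per record edge.

## Segmentation and quality control

Windows are `[k·10·fs, (k+1)·10·fs)` samples, 0-based half-open; a
trailing remainder is discarded. Labels are arithmetic means of the
*valid* beat-to-beat values (SBP > DBP, both finite) whose systolic peak
falls in the window.

Rule order: flatline → cycle → skewness SQI → PPG–ABP correlation. All
flags are recorded even after an early failure; correlation is skipped
(recorded failed, r = NaN) when no complete cycle exists, since
alignment is meaningless without beats. Rejections are tallied by the
first failed rule.

* **Flatline**: a run of more than 3 consecutive bitwise-equal samples at
  the segment-channel extreme, or any equal run longer than 1 s, on any
  channel. Exact equality (not a tolerance) is intentional — monitor
  flatlines repeat literal values, and exactness makes the rule invariant
  to affine rescaling. NaN runs count as non-recording signal.
* **Skewness SQI**: population-form skewness (`m3/m2^1.5`, zero-variance
  → 0) over 5-s windows with 1-s stride (six windows per segment); any
  negative window rejects. Evaluated on the **raw** PPG by default
  (configurable): after a [0.5, 8] Hz band-pass, a high-rate pulse keeps
  only one or two harmonics, its trace is near-sinusoidal and the
  skewness sign is uninformative — clean segments would fail. The raw
  pulse is right-skewed at every rate.
* **Correlation**: the standardized raw PPG and ABP are compared at every
  integer lag within ±1 s using the per-overlap-normalized (Pearson)
  cross-correlation; the maximizing lag is reported (ties resolve to the
  smallest magnitude, non-negative first) and the segment fails below
  r = 0.9. Two deliberate choices: (a) per-lag normalization — an
  unnormalized dot-product cross-correlation aliases to one-beat-off
  lags on quasi-periodic signals at high heart rates; (b) raw channels
  rather than band-passed — Pearson correlation is already offset- and
  scale-invariant, and band-passing 10-s windows with a 0.5 Hz high-pass
  edge injects multi-second filtfilt transients that differ between two
  mutually shifted channels, capping r at ≈ 0.97 even for a perfect copy.

## Post-hoc SQI

Heart rate for the feasibility rules comes from the mean inter-peak
interval (robust to partial edge beats). Template windows of width W
(median beat interval) cover `[peak − ⌊W/2⌋, peak − ⌊W/2⌋ + W)`;
boundary-crossing windows are skipped, not padded, because zero-padding
would bias every window's correlation toward the template's edges. A
zero-variance window contributes r = 0; a degenerate template yields an
undefined SQI (reported as failure). The SQI is invariant to affine
transformation of the whole signal and lies in [−1, 1].

Note the feasibility band [40, 180] bpm is evaluated on the *measured*
rate: cohorts generated exactly at a band edge fail it about half the
time, correctly — validation cohorts should sample interior rates.

## Benchmarking subsets

The published AAMI testing sets of curated ICU benchmarks are manually
selected; only their compliance statistics are reproducible. The sampler
here is deterministic given a seed:

1. every subject with ≥ 3 cleaned segments is eligible; if a
   `max_subjects` cap applies, subjects rank by total tail-rarity score
   (the full-bundle builder caps group C at max(85, a quarter of the
   eligible pool) so enough subjects remain for the balanced splits);
2. each selected subject contributes its 3 highest-scoring segments
   (score = Σ target-proportion / pool-proportion over the six tail
   conditions the segment satisfies, with a seeded 1e-9 jitter as
   tie-break);
3. segments are added one at a time (≤ 14 per subject) toward the most
   deficient tail bin until all proportion targets hold, then toward a
   total of ~5 segments/subject while keeping every proportion at
   target.

Default proportion targets are not the formal 5 %/20 % minima but the
tail-heavy composition typical of curated AAMI testing sets
(≈ 14.6 % SBP ≤ 100, 15.5 % SBP ≥ 160, 38.8 % SBP ≥ 140, 25.8 % DBP ≤ 60,
9.4 % DBP ≥ 100, 27.2 % DBP ≥ 85), so the built set stresses hypo- and
hypertensive ranges the way the published sets do; targets are
parameters. Infeasible pools raise an error naming the first requirement
that cannot be met. All thresholds are inclusive as printed (≤, ≥).

Balancing drops subjects below K segments and subsamples the rest to
exactly K with a seeded generator over sorted subject ids
(machine-independent). The split draws 10 % of subjects (group B) for
calibration-free testing and 10 % of each remaining subject's segments
for calibration-based testing; at K = 400 this is the 360/40 per-subject
split. Bundle invariants (pairwise-disjoint subject groups, segment
disjointness, conservation) are asserted on every build.

## Error metrics

Error is `estimate − reference` (positive ME = over-estimation). SDE is
the sample standard deviation (n−1) of the errors; R² is normalized by
the total sum of squares of the references and is NaN when the
references have zero variance; Pearson R is reported separately because
it stays high under large systematic error and is not itself an error
metric. RMSE is included as the root mean squared raw error. The AAMI
model criterion (|ME| ≤ 5, SDE ≤ 8 mmHg) treats "within" as inclusive;
the bounds are parameters. `track_training_metrics` records per-epoch
ME/SDE/MSE/MAE/R²/R for any estimator callable over the training and
both testing subsets — with a mean-of-training predictor, ME ≈ 0 and
SDE ≈ the SD of training BP, the expected initial regime of a learner.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
60-s records for recovery tests (6 segments each, 50 records across the
40–180 bpm and 95–175 / 50–95 mmHg grids), 500 noise draws for the SQI
limit, 100 seeds for split integrity, and a 400-subject × 30-segment
label cohort (12,000 segments) for subset construction. These sizes give
3-SE statistical resolution on every asserted moment while completing in
well under a minute each.

## Known limitations

* The constrained sampler reproduces the *composition* of a curated AAMI
  testing set, not any particular published selection.
* Record-edge beats can be undetectable in principle (no verifiable
  local maximum); counts agree with ground truth to one beat per edge.
* The skewness-SQI default (raw PPG) and the correlation pre-processing
  (raw channels) are documented choices among defensible variants; both
  are configurable where a flag exists (`ssqi_on_filtered`).
* The HDF5 per-subject container mirrors the layout of MAT v7.3-style
  segment files (groups of datasets with attributes) but is not
  byte-compatible with any proprietary writer.
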