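"""Synthetic coupled ECG/PPG/ABP triplets and multi-subject cohorts.

The generator stands in for ICU waveform databases so that the whole
curation pipeline (fiducial extraction, segmentation, quality control,
subset construction) can be exercised offline against exact ground truth.

Signal model
------------
A common quasi-periodic beat grid drives all three channels.  Each cardiac
cycle spans ``[b_k, b_{k+1})`` (beat-onset samples).  The ABP channel is an
asymmetric pulse per cycle: a fast half-cosine systolic rise from the onset
to the systolic peak (placed 15% into the cycle) followed by a slower
half-cosine diastolic decay.  By construction the per-beat maximum equals
the requested SBP exactly and the per-beat minimum (the turning point at
the next onset) equals the requested DBP exactly, before noise.  The PPG is
the min-max normalized ABP waveform delayed by an integer number of samples
(``ppg_abp_lag``), emulating inter-signal misalignment of up to 500 ms.
The ECG is a train of narrow Gaussian R spikes at the beat onsets with
smaller P and T bumps, so a QRS detector sees one dominant sharp complex
per beat.

Artifacts (NaN gaps, flatlines, saturation, noise bursts, morphology
inversion) are injected *after* clean synthesis, so the returned ground
truth stays exact.  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import Demographics, FiducialSet, WaveformRecord

__all__ = [
    "SynthParams",
    "ArtifactSpec",
    "CohortSpec",
    "TripletResult",
    "generate_triplet",
    "generate_cohort",
    "generate_cohort_labels",
    "cohort_segment_labels",
]

#: fraction of the cardiac cycle taken by the systolic upstroke
_SYSTOLIC_RISE_FRACTION = 0.15
#: first beat onset, as a fraction of one period, so edge beats are whole
_ONSET_OFFSET_FRACTION = 0.35

ARTIFACT_KINDS = (
    "nan_gap",
    "flatline",
    "saturation_high",
    "saturation_low",
    "noise_burst",
    "morphology_skew",
)


@dataclass
class SynthParams:
    """Parameters of one synthetic triplet.

    ``sbp``/``dbp`` may be scalars (constant over the record) or per-beat
    sequences in mmHg.  ``hr_variability`` is the fractional SD of the
    beat-to-beat interval.  ``ppg_abp_lag`` is the signed delay of the PPG
    relative to the ABP in seconds (positive: PPG later), rounded to whole
    samples.
    """

    heart_rate: float = 75.0
    hr_variability: float = 0.0
    sbp: Union[float, Sequence[float]] = 120.0
    dbp: Union[float, Sequence[float]] = 70.0
    ppg_abp_lag: float = 0.0
    noise_sd: float = 0.0
    sampling_rate: int = 125
    duration: float = 60.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate not in (125, 500):
            raise ValueError("sampling_rate must be 125 or 500 Hz")
        if self.hr_variability < 0 or self.noise_sd < 0:
            raise ValueError("hr_variability and noise_sd must be non-negative")
        sbp = np.atleast_1d(np.asarray(self.sbp, dtype=float))
        dbp = np.atleast_1d(np.asarray(self.dbp, dtype=float))
        if sbp.size == dbp.size:
            bad = sbp <= dbp
        else:
            bad = np.less.outer(sbp, dbp) | np.equal.outer(sbp, dbp)
        if np.any(bad):
            raise ValueError("sbp must exceed dbp for every beat")
        if abs(self.ppg_abp_lag) > 1.0:
            raise ValueError("ppg_abp_lag beyond +-1 s is not supported")


@dataclass
class ArtifactSpec:
    """One injected corruption on one channel, in seconds from record start."""

    kind: str
    channel: str
    start: float
    length: float

    def validate(self, duration: float) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.channel not in ("ecg", "ppg", "abp"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.start < 0 or self.length <= 0 or self.start + self.length > duration:
            raise ValueError(
                f"artifact [{self.start}, {self.start + self.length}) s "
                f"outside record of {duration} s"
            )


@dataclass
class TripletResult:
    """A synthetic record together with its exact ground truth."""

    record: WaveformRecord
    fiducials: FiducialSet
    beats: pd.DataFrame  # beat_index, r_sample, systolic_sample, turning_sample, sbp, dbp
    params: SynthParams


def _beat_grid(
    heart_rate: float,
    hr_variability: float,
    duration: float,
    fs: int,
    rng: np.random.Generator,
    pad_s: float = 2.5,
) -> tuple[np.ndarray, int]:
    """Beat-onset samples on an extended grid covering ``[-pad_s, duration+pad_s)``.

    Returns (onset samples relative to record start, index of the first
    onset at/after sample 0).  The extension lets the PPG be a shifted copy
    of the ABP without edge padding artifacts.
    """
    period = 60.0 / heart_rate

    def draw(k: int) -> np.ndarray:
        if hr_variability == 0:
            return np.full(k, period)
        eps = np.clip(rng.standard_normal(k), -3.0, 3.0)
        return period * np.clip(1.0 + hr_variability * eps, 0.3, None)

    # anchor one onset at a fixed phase inside the record, then extend in
    # both directions; this keeps whole-beat counts deterministic
    anchor = _ONSET_OFFSET_FRACTION * period
    shrink = max(0.3, 1.0 - 3.0 * hr_variability)  # worst-case interval shrinkage
    n_fwd = int(np.ceil((duration + pad_s) / (period * shrink))) + 4
    fwd = anchor + np.cumsum(draw(n_fwd))
    n_bwd = int(np.ceil(pad_s / (period * shrink))) + 4
    bwd = anchor - np.cumsum(draw(n_bwd))
    times = np.concatenate((bwd[::-1], [anchor], fwd))
    times = times[(times >= -pad_s - 2 * period) & (times <= duration + pad_s + 2 * period)]
    onsets = np.round(times * fs).astype(np.int64)
    onsets = onsets[np.insert(np.diff(onsets) >= 4, 0, True)]  # drop degenerate cycles
    first_real = int(np.searchsorted(onsets, 0, side="left"))
    return onsets, first_real


def _per_beat(
    values: Union[float, Sequence[float]], n_cycles: int, first_real: int, what: str
) -> np.ndarray:
    """Expand a scalar or per-beat sequence over the extended cycle grid.

    A sequence addresses the record's beats (entry 0 is the first beat
    at/after the record start); pad cycles outside the record reuse the
    nearest entry.
    """
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        return np.full(n_cycles, arr[0])
    n_real = n_cycles - first_real
    if arr.size < n_real:
        raise ValueError(
            f"per-beat {what} sequence has {arr.size} entries, need at least {n_real}"
        )
    idx = np.clip(np.arange(n_cycles) - first_real, 0, arr.size - 1)
    return arr[idx].astype(float)


def _pulse_train(
    onsets: np.ndarray, sbp: np.ndarray, dbp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-cosine pulse train over ``[onsets[0], onsets[-1])``.

    Returns (samples, systolic-peak sample per cycle).  Cycle ``k`` rises
    from the previous diastolic level at ``onsets[k]`` to ``sbp[k]`` at the
    peak, then decays to ``dbp[k]`` at ``onsets[k+1]`` (the turning point).
    """
    base = onsets[0]
    n = int(onsets[-1] - base)
    x = np.empty(n)
    n_cycles = len(onsets) - 1
    peaks = np.empty(n_cycles, dtype=np.int64)
    for k in range(n_cycles):
        b0, b1 = int(onsets[k] - base), int(onsets[k + 1] - base)
        width = b1 - b0
        rise = int(np.clip(round(_SYSTOLIC_RISE_FRACTION * width), 1, width - 2))
        p = b0 + rise
        peaks[k] = p + base
        v0 = dbp[k - 1] if k > 0 else dbp[0]
        up = np.arange(0, rise + 1) / rise
        x[b0 : p + 1] = v0 + (sbp[k] - v0) * 0.5 * (1.0 - np.cos(np.pi * up))
        # quasi-exponential diastolic run-off, pinned to dbp at the next onset
        down = np.arange(1, b1 - p) / (b1 - p)
        tau = 0.3
        decay = (np.exp(-down / tau) - np.exp(-1.0 / tau)) / (1.0 - np.exp(-1.0 / tau))
        x[p + 1 : b1] = dbp[k] + (sbp[k] - dbp[k]) * decay
    return x, peaks


def _ecg_train(onsets: np.ndarray, fs: int) -> np.ndarray:
    """Gaussian R spikes at beat onsets plus smaller P and T bumps."""
    base = onsets[0]
    n = int(onsets[-1] - base)
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    sigma_r = max(0.012 * fs, 1.2)
    sigma_t = 0.06 * fs
    sigma_p = 0.04 * fs
    for k in range(len(onsets) - 1):
        r = float(onsets[k] - base)
        ival = float(onsets[k + 1] - onsets[k])
        x += np.exp(-0.5 * ((t - r) / sigma_r) ** 2)
        x += 0.22 * np.exp(-0.5 * ((t - (r + 0.30 * ival)) / sigma_t) ** 2)
        x += 0.12 * np.exp(-0.5 * ((t - (r + 0.80 * ival)) / sigma_p) ** 2)
    return x


def _inject_artifacts(
    record: WaveformRecord,
    artifacts: Sequence[ArtifactSpec],
    rng: np.random.Generator,
) -> None:
    duration = record.duration_s
    fs = record.sampling_rate
    spans: dict[str, list[tuple[int, int, str]]] = {"ecg": [], "ppg": [], "abp": []}
    for art in artifacts:
        art.validate(duration)
        i0 = int(round(art.start * fs))
        i1 = min(int(round((art.start + art.length) * fs)), record.n_samples)
        for j0, j1, kind in spans[art.channel]:
            if i0 < j1 and j0 < i1:
                raise ValueError(
                    f"overlapping artifacts on {art.channel}: {art.kind} at "
                    f"[{i0}, {i1}) collides with {kind} at [{j0}, {j1})"
                )
        spans[art.channel].append((i0, i1, art.kind))
        x = getattr(record, art.channel)
        if art.kind == "nan_gap":
            x[i0:i1] = np.nan
        elif art.kind == "flatline":
            x[i0:i1] = x[i0]
        elif art.kind == "saturation_high":
            x[i0:i1] = np.nanmax(x)
        elif art.kind == "saturation_low":
            x[i0:i1] = np.nanmin(x)
        elif art.kind == "noise_burst":
            scale = 3.0 * max(np.nanstd(x), 1e-12)
            x[i0:i1] = x[i0:i1] + rng.normal(0.0, scale, i1 - i0)
        elif art.kind == "morphology_skew":
            x[i0:i1] = 2.0 * np.nanmean(x[i0:i1]) - x[i0:i1]


def generate_triplet(
    params: SynthParams,
    artifacts: Sequence[ArtifactSpec] = (),
    *,
    subject_id: str = "S0000",
    record_id: str = "R0",
    demographics: Optional[Demographics] = None,
    _grid: Optional[tuple[np.ndarray, int]] = None,
    _rng: Optional[np.random.Generator] = None,
) -> TripletResult:
    """Generate one coupled ECG/PPG/ABP record with exact ground truth.

    Returns the record, the ground-truth fiducial set (R-peaks, systolic
    peaks, turning points of both pulse channels) and a per-beat table with
    the requested SBP/DBP of every complete cycle inside the record.
    """
    params.validate()
    rng = _rng if _rng is not None else np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))

    if _grid is None:
        pad_s = 2.5 + abs(params.ppg_abp_lag)
        onsets, first_real = _beat_grid(
            params.heart_rate, params.hr_variability, params.duration, fs, rng, pad_s
        )
    else:
        onsets, first_real = _grid

    n_cycles = len(onsets) - 1
    sbp = _per_beat(params.sbp, n_cycles, first_real, "sbp")
    dbp = _per_beat(params.dbp, n_cycles, first_real, "dbp")
    if np.any(sbp <= dbp):
        raise ValueError("sbp must exceed dbp for every beat")

    abp_ext, peaks_ext = _pulse_train(onsets, sbp, dbp)
    ecg_ext = _ecg_train(onsets, fs)
    lo, hi = abp_ext.min(), abp_ext.max()
    ppg_ext = (abp_ext - lo) / max(hi - lo, 1e-12)

    base = int(onsets[0])
    lag_samples = int(round(params.ppg_abp_lag * fs))
    # record frame [0, n) within the extended arrays
    ecg = ecg_ext[-base : -base + n].copy()
    abp = abp_ext[-base : -base + n].copy()
    ppg = ppg_ext[-base - lag_samples : -base - lag_samples + n].copy()
    if len(ecg) < n or len(abp) < n or len(ppg) < n:
        raise RuntimeError("internal padding too short for requested duration")

    if params.noise_sd > 0:
        ecg += rng.normal(0.0, params.noise_sd, n)
        ppg += rng.normal(0.0, params.noise_sd, n)
        abp += rng.normal(0.0, params.noise_sd * float(np.mean(sbp - dbp)), n)

    record = WaveformRecord(
        subject_id=subject_id,
        record_id=record_id,
        sampling_rate=fs,
        ecg=ecg,
        ppg=ppg,
        abp=abp,
        source="synthetic",
        demographics=demographics or Demographics(),
    )
    _inject_artifacts(record, artifacts, rng)

    in_rec = lambda idx: idx[(idx >= 0) & (idx < n)]  # noqa: E731
    r_peaks = in_rec(onsets[:-1])
    abp_sys = in_rec(peaks_ext)
    # turning point between peaks k and k+1 is the onset of cycle k+1
    turn_all = onsets[1:-1]  # candidate turning for peak pair (k, k+1)
    keep = (peaks_ext[:-1] >= 0) & (peaks_ext[1:] < n)
    abp_turn = turn_all[keep]
    ppg_sys = in_rec(peaks_ext + lag_samples)
    ppg_turn = turn_all[(peaks_ext[:-1] + lag_samples >= 0) & (peaks_ext[1:] + lag_samples < n)] + lag_samples

    fiducials = FiducialSet(
        r_peaks=r_peaks,
        ppg_systolic_peaks=ppg_sys,
        ppg_turning_points=ppg_turn,
        abp_systolic_peaks=abp_sys,
        abp_turning_points=abp_turn,
        n_samples=n,
    )

    complete = (
        (onsets[:-1] >= 0) & (peaks_ext < n) & (onsets[1:] < n)
    )  # onset, peak and following turning all inside the record
    idx = np.nonzero(complete)[0]
    beats = pd.DataFrame(
        {
            "beat_index": np.arange(len(idx)),
            "r_sample": onsets[idx],
            "systolic_sample": peaks_ext[idx],
            "turning_sample": onsets[idx + 1],
            "sbp": sbp[idx],
            "dbp": dbp[idx],
        }
    )
    return TripletResult(record=record, fiducials=fiducials, beats=beats, params=params)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """A multi-subject cohort with a two-level blood-pressure model.

    Subject mean SBP/DBP are drawn from a correlated bivariate normal
    (between-subject variation); each 10-s segment's target BP is the
    subject mean plus within-subject normal noise, held constant within the
    segment.  Defaults mirror the per-subject summary statistics of large
    ICU waveform collections (subject-average SBP ~118 +- 17 mmHg, DBP
    ~62 +- 11 mmHg, within-subject SDs ~12 / ~7 mmHg).
    """

    n_subjects: int = 10
    segments_per_subject: Union[int, tuple[int, int]] = 6
    subject_sbp_mean: float = 117.8
    subject_sbp_sd: float = 17.2
    subject_dbp_mean: float = 62.1
    subject_dbp_sd: float = 10.8
    sbp_dbp_corr: float = 0.6
    within_sbp_sd: float = 11.9
    within_dbp_sd: float = 6.5
    min_pulse_pressure: float = 15.0
    hr_mean: float = 75.0
    hr_sd: float = 10.0
    hr_variability: float = 0.02
    ppg_abp_lag_range: tuple[float, float] = (0.0, 0.3)
    noise_sd: float = 0.0
    sampling_rate: int = 125
    age_mean: float = 60.9
    age_sd: float = 15.6
    prop_male: float = 0.56
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        lo, hi = self._segment_range()
        if lo < 1 or hi < lo:
            raise ValueError("segments_per_subject must be a positive count or (low, high)")
        for name in ("subject_sbp_sd", "subject_dbp_sd", "within_sbp_sd", "within_dbp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def _segment_range(self) -> tuple[int, int]:
        if isinstance(self.segments_per_subject, (tuple, list)):
            lo, hi = self.segments_per_subject
            return int(lo), int(hi)
        return int(self.segments_per_subject), int(self.segments_per_subject)


def _draw_subjects(spec: CohortSpec) -> pd.DataFrame:
    """Subject-level draws (means, heart rate, demographics, child seeds)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cov = np.array(
        [
            [spec.subject_sbp_sd**2, spec.sbp_dbp_corr * spec.subject_sbp_sd * spec.subject_dbp_sd],
            [spec.sbp_dbp_corr * spec.subject_sbp_sd * spec.subject_dbp_sd, spec.subject_dbp_sd**2],
        ]
    )
    means = rng.multivariate_normal([spec.subject_sbp_mean, spec.subject_dbp_mean], cov, size=n)
    lo, hi = spec._segment_range()
    counts = rng.integers(lo, hi + 1, size=n) if hi > lo else np.full(n, lo)
    hrs = np.clip(rng.normal(spec.hr_mean, spec.hr_sd, n), 45.0, 170.0)
    lags = rng.uniform(spec.ppg_abp_lag_range[0], spec.ppg_abp_lag_range[1], n)
    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 95.0)
    male = rng.random(n) < spec.prop_male
    # two independent child streams per subject: one for segment BP targets,
    # one for waveform synthesis noise, so label-only and full generation agree
    child_seeds = rng.integers(0, 2**63 - 1, size=2 * n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sbp_mean": means[:, 0],
            "dbp_mean": means[:, 1],
            "n_segments": counts,
            "heart_rate": hrs,
            "ppg_abp_lag": lags,
            "age": ages,
            "gender": np.where(male, "M", "F"),
            "target_seed": child_seeds[0::2],
            "wave_seed": child_seeds[1::2],
        }
    )


def _segment_targets(row: pd.Series, spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(int(row["target_seed"]))
    k = int(row["n_segments"])
    sbp = row["sbp_mean"] + spec.within_sbp_sd * rng.standard_normal(k)
    dbp = row["dbp_mean"] + spec.within_dbp_sd * rng.standard_normal(k)
    sbp = np.clip(sbp, 55.0, 240.0)
    dbp = np.minimum(np.clip(dbp, 25.0, 160.0), sbp - spec.min_pulse_pressure)
    return sbp, dbp


def generate_cohort_labels(spec: CohortSpec) -> pd.DataFrame:
    """Per-segment reference labels of the cohort, without waveform synthesis.

    Returns a table (subject_id, record_id, segment_index, sbp_ref, dbp_ref)
    identical to what the full pipeline recovers from noise-free waveforms,
    because within each segment every beat carries the segment's target BP.
    """
    spec.validate()
    subjects = _draw_subjects(spec)
    rows = []
    for _, row in subjects.iterrows():
        sbp, dbp = _segment_targets(row, spec)
        for s in range(int(row["n_segments"])):
            rows.append((row["subject_id"], f"{row['subject_id']}_R0", s, sbp[s], dbp[s]))
    return pd.DataFrame(
        rows, columns=["subject_id", "record_id", "segment_index", "sbp_ref", "dbp_ref"]
    )


def generate_cohort(spec: CohortSpec) -> list[TripletResult]:
    """Generate full waveform records for every subject of the cohort.

    Each subject contributes one record of ``10 * n_segments`` seconds whose
    per-beat SBP/DBP step between the per-segment targets, so segment-level
    reference labels are known exactly.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    subjects = _draw_subjects(spec)
    results: list[TripletResult] = []
    fs = spec.sampling_rate
    for _, row in subjects.iterrows():
        sbp_t, dbp_t = _segment_targets(row, spec)
        duration = 10.0 * int(row["n_segments"])
        rng = np.random.default_rng(int(row["wave_seed"]))
        pad_s = 2.5 + abs(row["ppg_abp_lag"])
        grid = _beat_grid(row["heart_rate"], spec.hr_variability, duration, fs, rng, pad_s)
        onsets, first_real = grid
        # a cycle belongs to the segment holding its systolic peak; the
        # per-beat sequences address the record's beats (first_real onward)
        real = onsets[first_real:]
        peak_times = (real[:-1] + _SYSTOLIC_RISE_FRACTION * np.diff(real)) / fs
        seg_of_beat = np.clip((peak_times // 10.0).astype(int), 0, len(sbp_t) - 1)
        params = SynthParams(
            heart_rate=row["heart_rate"],
            hr_variability=spec.hr_variability,
            sbp=sbp_t[seg_of_beat],
            dbp=dbp_t[seg_of_beat],
            ppg_abp_lag=row["ppg_abp_lag"],
            noise_sd=spec.noise_sd,
            sampling_rate=fs,
            duration=duration,
        )
        demo = Demographics(age=float(row["age"]), gender=str(row["gender"]))
        results.append(
            generate_triplet(
                params,
                subject_id=row["subject_id"],
                record_id=f"{row['subject_id']}_R0",
                demographics=demo,
                _grid=grid,
                _rng=rng,
            )
        )
    return results


def cohort_segment_labels(cohort: Sequence[TripletResult]) -> pd.DataFrame:
    """Ground-truth per-segment labels of a generated cohort.

    A segment's reference is the mean of the per-beat SBP/DBP of cycles
    whose systolic peak falls inside the segment (the same definition the
    segmentation stage applies to detected beats).
    """
    rows = []
    for trip in cohort:
        fs = trip.record.sampling_rate
        seg = (trip.beats["systolic_sample"] // (10 * fs)).astype(int)
        grouped = trip.beats.groupby(seg)[["sbp", "dbp"]].mean()
        for s, bp in grouped.iterrows():
            rows.append(
                (trip.record.subject_id, trip.record.record_id, int(s), bp["sbp"], bp["dbp"])
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "record_id", "segment_index", "sbp_ref", "dbp_ref"]
    )
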