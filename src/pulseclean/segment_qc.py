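"""10-s segmentation and the four-stage segment cleaning procedure.

Records are divided into non-overlapping 10-s windows tiling the record
from its start (a trailing remainder is discarded).  Each window receives
reference SBP/DBP labels — the arithmetic means of the beat-to-beat values
whose systolic peak falls inside the window — and is then screened by four
rules, in order:

1. **flatline/saturation** — more than 3 consecutive equal samples at the
   segment-channel's minimum or maximum amplitude, or any run of equal
   samples longer than 1 s, rejects the segment (any channel);
2. **cardiac cycle presence** — at least one complete cycle (two systolic
   peaks with a turning point between them, two R-peaks) must be locatable
   on every channel from the extracted characteristic points;
3. **skewness SQI** — the PPG sample skewness over 5-s sliding windows
   must stay non-negative in every window;
4. **PPG-ABP correlation** — after alignment at the lag maximizing their
   cross-correlation (within +-1 s), the Pearson correlation between PPG
   and ABP must reach 0.9; this mutual validation rejects ABP morphology
   corrupted by noise or interference without thresholding BP values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import signal as sp_signal

from .fiducials import bandpass_ppg, detect_fiducials, extract_beat_bp
from .records import FiducialSet, QCReport, Segment, WaveformRecord
from .waveform_io import extract_longest_valid_interval, resample_record

__all__ = [
    "QCConfig",
    "segment_record",
    "flatline_check",
    "cycle_check",
    "sample_skewness",
    "ssqi_check",
    "ppg_abp_correlation_check",
    "run_qc",
    "process_record",
    "clean_dataset",
]


@dataclass
class QCConfig:
    """Tunable thresholds of the cleaning rules (defaults as published)."""

    ssqi_window_s: float = 5.0
    ssqi_stride_s: float = 1.0
    ssqi_on_filtered: bool = False
    max_lag_s: float = 1.0
    corr_threshold: float = 0.9
    flatline_run: int = 3  # "more than 3 consecutive samples"
    flatline_max_s: float = 1.0
    target_fs: int = 125


def segment_record(
    record: WaveformRecord, fiducials: FiducialSet
) -> list[Segment]:
    """Split a record into labeled 10-s segments.

    ``floor(duration / 10 s)`` segments are produced; labels are the means
    of the beat-to-beat SBP/DBP of valid beats whose systolic peak lies in
    the window (NaN when a window holds no complete valid beat).  Local
    fiducial indices are expressed in the segment frame.
    """
    fs = record.sampling_rate
    seg_len = 10 * fs
    n_segments = record.n_samples // seg_len
    beats = extract_beat_bp(
        record.abp, fiducials.abp_systolic_peaks, fiducials.abp_turning_points
    )
    beat_peaks = np.array([b.systolic_sample for b in beats], dtype=np.int64)
    beat_sbp = np.array([b.sbp for b in beats])
    beat_dbp = np.array([b.dbp for b in beats])
    beat_valid = np.array([b.valid for b in beats], dtype=bool)

    segments: list[Segment] = []
    for i in range(n_segments):
        start = i * seg_len
        stop = start + seg_len
        inside = beat_valid & (beat_peaks >= start) & (beat_peaks < stop)
        sbp_ref = float(np.mean(beat_sbp[inside])) if inside.any() else float("nan")
        dbp_ref = float(np.mean(beat_dbp[inside])) if inside.any() else float("nan")
        segments.append(
            Segment(
                subject_id=record.subject_id,
                record_id=record.record_id,
                start_sample=start,
                fs=fs,
                ecg=record.ecg[start:stop].copy(),
                ppg=record.ppg[start:stop].copy(),
                abp=record.abp[start:stop].copy(),
                fiducials=fiducials.shifted(start, seg_len),
                sbp_ref=sbp_ref,
                dbp_ref=dbp_ref,
            )
        )
    return segments


def _equal_runs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start index and length of each maximal run of bitwise-equal samples."""
    if len(x) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    # NaN != NaN, but a NaN gap is a non-recording signal: compare on bits
    change = np.flatnonzero(x[1:] != x[:-1])
    nan = np.isnan(x)
    if nan.any():
        same_nan = nan[1:] & nan[:-1]
        change = np.flatnonzero((x[1:] != x[:-1]) & ~same_nan)
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [len(x)])))
    return starts, lengths


def flatline_check(segment: Segment, config: Optional[QCConfig] = None) -> bool:
    """Pass flag of the flatline/saturation rule (True = keep).

    Fails when any channel holds a run of more than ``flatline_run``
    consecutive equal samples at the segment-channel extremes, or any equal
    run longer than ``flatline_max_s``.  Equality is exact (monitor
    flatlines repeat literal values), which makes the rule invariant to
    affine rescaling of a channel.  NaN runs count as flatlines.
    """
    cfg = config or QCConfig()
    max_run = int(cfg.flatline_max_s * segment.fs)
    for ch in ("ecg", "ppg", "abp"):
        x = getattr(segment, ch)
        starts, lengths = _equal_runs(x)
        if np.any(lengths > max_run):
            return False
        lo, hi = np.nanmin(x), np.nanmax(x)
        head = x[starts]
        at_extreme = np.isin(head, (lo, hi)) | np.isnan(head)
        if np.any(at_extreme & (lengths > cfg.flatline_run)):
            return False
    return True


def cycle_check(segment: Segment) -> bool:
    """Pass iff one complete cardiac cycle is locatable on every channel.

    ECG: at least two R-peaks; PPG and ABP: at least two systolic peaks
    with a turning point strictly between them.
    """
    fid = segment.fiducials
    if fid is None:
        return False
    if len(fid.r_peaks) < 2:
        return False
    for ch in ("ppg", "abp"):
        peaks = getattr(fid, f"{ch}_systolic_peaks")
        turns = getattr(fid, f"{ch}_turning_points")
        if len(peaks) < 2 or len(turns) < 1:
            return False
        if not np.any((turns > peaks[0]) & (turns < peaks[-1])):
            return False
    return True


def sample_skewness(x: np.ndarray) -> float:
    """Population-form sample skewness (standardized third central moment).

    Zero-variance input is defined as skewness 0.
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / m2**1.5)


def ssqi_check(
    segment: Segment, config: Optional[QCConfig] = None
) -> tuple[bool, float]:
    """Skewness SQI rule over 5-s sliding windows of the PPG.

    Returns (pass flag, minimum window skewness).  The segment fails iff
    any window's skewness is negative.  By default the raw PPG trace is
    evaluated: a clean pulse (brief systolic peaks, long diastolic run-off)
    is right-skewed at any heart rate, whereas a narrow band-pass leaves a
    near-sinusoidal trace at high rates whose skewness sign is
    uninformative.  Set ``ssqi_on_filtered=True`` to evaluate the
    band-passed trace instead.
    """
    cfg = config or QCConfig()
    fs = segment.fs
    ppg = bandpass_ppg(segment.ppg, fs) if cfg.ssqi_on_filtered else segment.ppg
    win = int(cfg.ssqi_window_s * fs)
    stride = max(int(cfg.ssqi_stride_s * fs), 1)
    n = len(ppg)
    skews = [
        sample_skewness(ppg[s : s + win]) for s in range(0, n - win + 1, stride)
    ]
    min_skew = float(np.min(skews)) if skews else 0.0
    return min_skew >= 0.0, min_skew


def _standardize(x: np.ndarray) -> Optional[np.ndarray]:
    sd = np.std(x)
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - np.mean(x)) / sd


def ppg_abp_correlation_check(
    segment: Segment, config: Optional[QCConfig] = None
) -> tuple[bool, int, float]:
    """Mutual PPG-ABP validation by lag-aligned Pearson correlation.

    The raw channels are standardized (Pearson correlation is offset- and
    scale-invariant, so morphology is compared without regard to absolute
    pressure; band-passing 10-s windows would instead inject filter edge
    transients of several seconds into the comparison).  They are aligned
    at the integer lag (within ``+-max_lag_s``) maximizing the per-overlap
    normalized cross-correlation; positive lag means the PPG trails the
    ABP, and lag ties resolve to the smallest magnitude, non-negative
    first.  Returns (pass flag, lag in samples, Pearson r on the overlap);
    the segment fails iff r < ``corr_threshold``.  A zero-variance channel
    makes r undefined and fails.
    """
    cfg = config or QCConfig()
    fs = segment.fs
    p = _standardize(segment.ppg)
    a = _standardize(segment.abp)
    if p is None or a is None or not np.all(np.isfinite(p)) or not np.all(np.isfinite(a)):
        return False, 0, float("nan")
    max_lag = int(cfg.max_lag_s * fs)
    n = len(p)

    def corr_at(lag: int) -> float:
        # overlap of a[t] with p[t + lag], normalized per overlap so that
        # quasi-periodic signals do not alias to a one-beat-off lag
        if lag >= 0:
            x, y = a[: n - lag], p[lag:]
        else:
            x, y = a[-lag:], p[: n + lag]
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    best_lag, best_r = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l < 0)):
        r = corr_at(lag)
        if np.isfinite(r) and r > best_r:
            best_lag, best_r = lag, r
    if not np.isfinite(best_r):
        return False, 0, float("nan")
    return best_r >= cfg.corr_threshold, best_lag, float(best_r)


def run_qc(segment: Segment, config: Optional[QCConfig] = None) -> QCReport:
    """Evaluate the four cleaning rules in order and attach the report.

    All flags are recorded even after an early failure, except that the
    correlation stage is skipped (recorded as failed with r = NaN) when the
    cycle rule fails, since alignment is meaningless without located beats.
    Segments containing non-finite samples fail outright.
    """
    cfg = config or QCConfig()
    finite = all(
        np.all(np.isfinite(getattr(segment, ch))) for ch in ("ecg", "ppg", "abp")
    )
    if not finite:
        report = QCReport(fail_reason="invalid_samples")
        segment.qc = report
        return report
    pass_flat = flatline_check(segment, cfg)
    pass_cycle = cycle_check(segment)
    pass_ssqi, min_skew = ssqi_check(segment, cfg)
    if pass_cycle:
        pass_corr, lag, r = ppg_abp_correlation_check(segment, cfg)
        reason = ""
    else:
        pass_corr, lag, r = False, 0, float("nan")
        reason = "correlation skipped: no complete cycle"
    report = QCReport(
        pass_flatline=pass_flat,
        pass_cycle=pass_cycle,
        pass_ssqi=pass_ssqi,
        min_window_skewness=min_skew,
        pass_ppg_abp_corr=pass_corr,
        alignment_lag=lag,
        ppg_abp_r=r,
        fail_reason=reason,
    )
    segment.qc = report
    return report


def process_record(
    record: WaveformRecord, config: Optional[QCConfig] = None
) -> list[Segment]:
    """Full per-record pipeline: valid interval, resampling, fiducials, QC.

    Returns all 10-s segments of the record's longest valid interval with
    labels and QC reports attached (empty when no valid interval of at
    least 10 s exists).
    """
    cfg = config or QCConfig()
    valid = extract_longest_valid_interval(record)
    if valid is None:
        return []
    if valid.sampling_rate != cfg.target_fs:
        valid = resample_record(valid, cfg.target_fs)
    fiducials = detect_fiducials(valid)
    segments = segment_record(valid, fiducials)
    for seg in segments:
        run_qc(seg, cfg)
    return segments


def clean_dataset(
    records: Iterable[WaveformRecord], config: Optional[QCConfig] = None
) -> tuple[list[Segment], dict[str, int]]:
    """Apply the cleaning procedure to a collection of records.

    Returns the kept segments (overall QC pass) and a tally of rejections
    attributed to the first failed rule, with keys ``kept``, ``flatline``,
    ``cycle``, ``ssqi``, ``ppg_abp_corr`` and ``no_valid_interval``
    (records contributing no valid interval at all).
    """
    cfg = config or QCConfig()
    kept: list[Segment] = []
    tally = {
        "kept": 0,
        "flatline": 0,
        "cycle": 0,
        "ssqi": 0,
        "ppg_abp_corr": 0,
        "no_valid_interval": 0,
    }
    for record in records:
        segments = process_record(record, cfg)
        if not segments:
            tally["no_valid_interval"] += 1
            continue
        for seg in segments:
            if seg.qc.overall_pass:
                kept.append(seg)
                tally["kept"] += 1
            else:
                tally[seg.qc.first_failed] += 1
    return kept, tally
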