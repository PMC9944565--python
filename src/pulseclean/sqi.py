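"""Post-hoc signal-quality validation of ECG and PPG segments.

Quality is judged in two stages.  First, feasibility rules on the detected
beat sequence of a 10-s segment:

1. heart rate between 40 and 180 beats/min,
2. maximum peak-to-peak interval within 3 s,
3. max/min peak-to-peak interval ratio below 2.2.

Second, for feasible segments, an adaptive template-matching SQI: beat
windows of width W (the median beat-to-beat interval) are extracted
centered at each peak, averaged into an adaptive template, and the SQI is
the mean Pearson correlation between each window and the template.  Good
quality corresponds to SQI above 0.66 for ECG and 0.86 for PPG.

This module validates cleaned segments; it is not an additional exclusion
stage of the cleaning pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import Segment

__all__ = [
    "SQIResult",
    "feasibility_rules",
    "template_sqi",
    "validate_segment_sqi",
    "ECG_SQI_THRESHOLD",
    "PPG_SQI_THRESHOLD",
]

HR_RANGE_BPM = (40.0, 180.0)
MAX_GAP_S = 3.0
MAX_INTERVAL_RATIO = 2.2
ECG_SQI_THRESHOLD = 0.66
PPG_SQI_THRESHOLD = 0.86


@dataclass
class SQIResult:
    """Outcome of feasibility + template matching for one channel.

    ``sqi`` and ``pass_threshold`` are defined only when the segment is
    feasible (None otherwise).
    """

    feasible: bool
    rule_failed: str  # {"hr_range", "max_gap", "interval_ratio", "none"}
    sqi: Optional[float] = None
    pass_threshold: Optional[bool] = None


def feasibility_rules(
    peaks: np.ndarray, fs: float, duration_s: float = 10.0
) -> tuple[bool, str]:
    """Apply the three beat-sequence feasibility rules in order.

    The heart rate is computed from the mean inter-peak interval (robust to
    partial beats at the window edges).  Returns (pass flag, first violated
    rule or "none").  Fewer than two peaks means no interval and therefore
    no measurable heart rate.
    """
    peaks = np.asarray(peaks)
    if len(peaks) < 2:
        return False, "hr_range"
    intervals = np.diff(peaks) / fs
    hr = 60.0 / float(np.mean(intervals))
    if not (HR_RANGE_BPM[0] <= hr <= HR_RANGE_BPM[1]):
        return False, "hr_range"
    if float(np.max(intervals)) > MAX_GAP_S:
        return False, "max_gap"
    if float(np.max(intervals) / np.min(intervals)) >= MAX_INTERVAL_RATIO:
        return False, "interval_ratio"
    return True, "none"


def template_sqi(signal: np.ndarray, peaks: np.ndarray, fs: float) -> Optional[float]:
    """Adaptive template-matching SQI of one channel.

    W is the median beat-to-beat interval in samples.  A window of
    duration W is extracted centered at each peak (covering
    ``[peak - W//2, peak - W//2 + W)``); windows that would cross the
    segment boundary are skipped rather than padded.  The SQI is the mean
    Pearson correlation between each window and the sample-wise mean
    template; it is invariant to affine transformation of the whole signal
    and always lies in [-1, 1].  Returns None when no peak admits a full
    window or the template is degenerate.
    """
    signal = np.asarray(signal, dtype=float)
    peaks = np.asarray(peaks, dtype=np.int64)
    if len(peaks) < 2:
        return None
    w = int(round(float(np.median(np.diff(peaks)))))
    if w < 2:
        return None
    half = w // 2
    windows = []
    for p in peaks:
        lo = p - half
        if lo >= 0 and lo + w <= len(signal):
            windows.append(signal[lo : lo + w])
    if not windows:
        return None
    stack = np.vstack(windows)
    template = stack.mean(axis=0)
    t_sd = template.std()
    if t_sd == 0:
        return None
    tc = template - template.mean()
    rs = []
    for win in stack:
        w_sd = win.std()
        if w_sd == 0:
            rs.append(0.0)
            continue
        wc = win - win.mean()
        rs.append(float(np.dot(wc, tc) / (len(wc) * w_sd * t_sd)))
    return float(np.clip(np.mean(rs), -1.0, 1.0))


def _channel_result(
    signal: np.ndarray, peaks: np.ndarray, fs: float, threshold: float
) -> SQIResult:
    feasible, rule = feasibility_rules(peaks, fs)
    if not feasible:
        return SQIResult(feasible=False, rule_failed=rule)
    sqi = template_sqi(signal, peaks, fs)
    if sqi is None:
        return SQIResult(feasible=True, rule_failed="none", sqi=None, pass_threshold=False)
    return SQIResult(
        feasible=True, rule_failed="none", sqi=sqi, pass_threshold=bool(sqi > threshold)
    )


def validate_segment_sqi(
    segment: Segment,
    ecg_threshold: float = ECG_SQI_THRESHOLD,
    ppg_threshold: float = PPG_SQI_THRESHOLD,
) -> tuple[SQIResult, SQIResult]:
    """Evaluate both channels of a segment: ECG on R-peaks, PPG on systolic peaks."""
    if segment.fiducials is None:
        raise ValueError("segment has no fiducials attached")
    ecg_result = _channel_result(
        segment.ecg, segment.fiducials.r_peaks, segment.fs, ecg_threshold
    )
    ppg_result = _channel_result(
        segment.ppg, segment.fiducials.ppg_systolic_peaks, segment.fs, ppg_threshold
    )
    return ecg_result, ppg_result
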