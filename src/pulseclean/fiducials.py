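"""Characteristic-point extraction from ECG, PPG and ABP waveforms.

Three detectors are implemented here:

* :func:`detect_r_peaks` — Pan-Tompkins QRS detection with adaptive dual
  thresholds and a search-back mechanism driven by a running average of the
  last 8 R-R intervals.  It is meant to run on the whole record, not on
  individual 10-s segments, so the running heart-rate estimate can settle.
* :func:`detect_pulse_peaks` — Elgendi's two-moving-average systolic peak
  detector for PPG-like pulse waveforms, followed by turning-point location
  (the minimum strictly between each pair of consecutive systolic peaks).
* :func:`extract_beat_bp` — beat-to-beat SBP/DBP values read off the
  *unfiltered* ABP series at the located systolic peaks and turning points.

PPG and ABP share one delineation code path (:func:`delineate_pulse_channel`);
band-pass filtering is used for peak *localization* only, never for reading
pressure amplitudes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import uniform_filter1d

from .records import BeatBP, FiducialSet, WaveformRecord

__all__ = [
    "bandpass_ppg",
    "detect_r_peaks",
    "detect_pulse_peaks",
    "delineate_pulse_channel",
    "extract_beat_bp",
    "detect_fiducials",
]

# Elgendi two-moving-average parameters (published defaults)
W1_S = 0.111  # systolic-window moving average
W2_S = 0.667  # beat-window moving average
BETA = 0.02
PULSE_REFRACTORY_S = 0.300

# Pan-Tompkins parameters (original stages)
QRS_BAND_HZ = (5.0, 15.0)
MWI_WINDOW_S = 0.150
QRS_REFRACTORY_S = 0.200
SEARCHBACK_FACTOR = 1.66
RR_HISTORY = 8


def bandpass_ppg(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Chebyshev-II band-pass at [0.5, 8] Hz.

    The canonical pulse-wave pre-filter: design order 4 with 20 dB
    stop-band attenuation and [0.5, 8] Hz as the stop-band edge pair (the
    standard parameterization of this filter in the PPG literature, which
    keeps 1-4 Hz pulse energy essentially untouched while removing DC,
    sub-0.5 Hz baseline wander and 8 Hz+ noise).  Applied
    forward-backward, so fiducial indices are not delayed.
    """
    if fs <= 16:
        raise ValueError("sampling rate too low for a [0.5, 8] Hz pass band")
    x = np.asarray(x, dtype=float)
    # the stop-band floor leaks ~1% of any offset; remove the mean first so
    # DC rejection is exact and peak indices are offset-invariant
    sos = sp_signal.cheby2(4, 20, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, x - np.mean(x))


def _moving_average(x: np.ndarray, width_s: float, fs: float) -> np.ndarray:
    w = max(int(round(width_s * fs)), 1)
    return uniform_filter1d(x, size=w, mode="nearest")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns R-peak sample indices.

    Stages: band-pass (~5-15 Hz), derivative, squaring, 150 ms moving-window
    integration, adaptive dual thresholds with a 200 ms refractory period,
    and search-back when the gap since the last accepted peak exceeds
    1.66x the running average of the previous 8 R-R intervals.  Flat or
    featureless input yields an empty index array.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    if n < int(1.0 * fs):
        return np.array([], dtype=np.int64)
    finite = np.isfinite(ecg)
    if not finite.all():
        ecg = np.where(finite, ecg, 0.0)
    if np.ptp(ecg) == 0:
        return np.array([], dtype=np.int64)

    sos = sp_signal.butter(3, QRS_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(filtered)
    mwi = _moving_average(deriv**2, MWI_WINDOW_S, fs)

    peaks, _ = sp_signal.find_peaks(mwi, distance=max(int(QRS_REFRACTORY_S * fs), 1))
    if len(peaks) == 0:
        return np.array([], dtype=np.int64)

    # initialize the running signal/noise levels from global candidate
    # statistics (robust to filter edge transients at the record start)
    heights = mwi[peaks]
    spki = float(np.percentile(heights, 90))
    npki = float(np.median(mwi))
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_intervals: list[float] = []
    rejected: list[int] = []

    def running_rr() -> Optional[float]:
        if not rr_intervals:
            return None
        return float(np.mean(rr_intervals[-RR_HISTORY:]))

    for p in peaks:
        level = mwi[p]
        if level > thr1:
            if accepted and (p - accepted[-1]) < QRS_REFRACTORY_S * fs:
                # inside the refractory period: keep the stronger candidate
                if level > mwi[accepted[-1]]:
                    accepted[-1] = int(p)
                continue
            if accepted:
                rr_intervals.append(float(p - accepted[-1]))
            accepted.append(int(p))
            spki = 0.125 * level + 0.875 * spki
        else:
            rejected.append(int(p))
            npki = 0.125 * level + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

        # search-back: a beat is overdue when the gap exceeds 1.66x the
        # running average interval; re-examine rejected candidates with
        # the lowered threshold thr2 = thr1 / 2
        rr = running_rr()
        if rr is not None and accepted and (p - accepted[-1]) > SEARCHBACK_FACTOR * rr:
            window = [c for c in rejected if accepted[-1] < c < p]
            if window:
                best = max(window, key=lambda c: mwi[c])
                if mwi[best] > 0.5 * thr1 and (best - accepted[-1]) > QRS_REFRACTORY_S * fs:
                    rr_intervals.append(float(best - accepted[-1]))
                    accepted.append(int(best))
                    accepted.sort()
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    thr1 = npki + 0.25 * (spki - npki)

    if not accepted:
        return np.array([], dtype=np.int64)

    # refine: the MWI maximum is zero-lag here (zero-phase stages), map each
    # detection to the nearest local maximum of the raw ECG
    half = max(int(0.100 * fs), 2)
    refined_list = []
    for p in accepted:
        lo = max(p - half, 0)
        hi = min(p + half + 1, n)
        q = lo + int(np.argmax(ecg[lo:hi]))
        if 0 < q < n - 1 and ecg[q] >= ecg[q - 1] and ecg[q] >= ecg[q + 1]:
            refined_list.append(q)
    refined = np.unique(np.asarray(refined_list, dtype=np.int64))
    keep = np.insert(np.diff(refined) > QRS_REFRACTORY_S * fs / 2, 0, True)
    return refined[keep]


def _elgendi_blocks(x: np.ndarray, fs: float) -> np.ndarray:
    """Candidate systolic peaks via Elgendi's two moving averages."""
    x = x - np.mean(x)
    z = np.square(np.clip(x, 0.0, None))
    ma_peak = _moving_average(z, W1_S, fs)
    ma_beat = _moving_average(z, W2_S, fs)
    thr1 = ma_beat + BETA * float(np.mean(z))
    above = ma_peak > thr1
    if not above.any():
        return np.array([], dtype=np.int64)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, len(x))
    w1 = int(round(W1_S * fs))
    peaks = []
    for s, e in zip(starts, ends):
        if e - s >= w1:  # block at least one systolic-window wide
            peaks.append(s + int(np.argmax(x[s:e])))
    if not peaks:
        return np.array([], dtype=np.int64)
    # refractory: merge peaks closer than 300 ms, keeping the larger
    out = [peaks[0]]
    for p in peaks[1:]:
        if p - out[-1] < PULSE_REFRACTORY_S * fs:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=np.int64)


def _turning_points(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Minimum of ``x`` strictly between each consecutive peak pair.

    Plateau ties resolve to the first sample.  With fewer than two peaks
    the result is empty.
    """
    if len(peaks) < 2:
        return np.array([], dtype=np.int64)
    turns = np.empty(len(peaks) - 1, dtype=np.int64)
    for k in range(len(peaks) - 1):
        lo, hi = peaks[k] + 1, peaks[k + 1]
        turns[k] = lo + int(np.argmin(x[lo:hi]))
    return turns


def detect_pulse_peaks(
    x: np.ndarray, fs: float, raw: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Systolic peaks and turning points of a pulse waveform.

    ``x`` is the signal used for peak localization (band-passed PPG, or a
    band-passed copy of the ABP).  When ``raw`` is given, each peak is
    refined to the local maximum of ``raw`` near the detected block and the
    turning points are minima of ``raw``, so amplitudes read at the returned
    indices are unfiltered.  Returns ``(systolic_peaks, turning_points)``
    with ``len(turning_points) == len(systolic_peaks) - 1`` (or both empty).
    """
    x = np.asarray(x, dtype=float)
    peaks = _elgendi_blocks(x, fs)
    target = x if raw is None else np.asarray(raw, dtype=float)
    if raw is not None and len(peaks):
        half = max(int(round(W1_S * fs)), 2)
        m = len(target)
        refined = []
        for p in peaks:
            lo = max(p - half, 0)
            hi = min(p + half + 1, m)
            q = lo + int(np.argmax(target[lo:hi]))
            # a boundary argmax is an edge artifact, not a systolic peak
            if 0 < q < m - 1 and target[q] >= target[q - 1] and target[q] >= target[q + 1]:
                refined.append(q)
        peaks = np.unique(np.asarray(refined, dtype=np.int64))
    turns = _turning_points(target, peaks)
    return peaks, turns


def delineate_pulse_channel(
    raw: np.ndarray, fs: float, prefilter: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Locate systolic peaks and turning points of a raw pulse channel.

    One shared code path for PPG and ABP: the channel is band-pass filtered
    for localization (when ``prefilter``), while the returned indices point
    at extrema of the raw series so that amplitudes (e.g. SBP/DBP from ABP)
    are read unfiltered.
    """
    raw = np.asarray(raw, dtype=float)
    loc = bandpass_ppg(raw, fs) if prefilter else raw
    return detect_pulse_peaks(loc, fs, raw=raw)


def extract_beat_bp(
    abp: np.ndarray, systolic_peaks: np.ndarray, turning_points: np.ndarray
) -> list[BeatBP]:
    """Beat-to-beat SBP/DBP from the unfiltered ABP series.

    Each beat pairs a systolic peak with the following turning point; the
    amplitudes at those samples are the beat's SBP and DBP.  The last peak
    (no following turning point) is dropped; beats with SBP <= DBP are
    flagged invalid and must be excluded from reference labels.
    """
    abp = np.asarray(abp, dtype=float)
    beats: list[BeatBP] = []
    for k in range(min(len(systolic_peaks) - 1, len(turning_points))):
        p = int(systolic_peaks[k])
        t = int(turning_points[k])
        sbp = float(abp[p])
        dbp = float(abp[t])
        beats.append(
            BeatBP(
                beat_index=k,
                systolic_sample=p,
                sbp=sbp,
                turning_sample=t,
                dbp=dbp,
                valid=bool(np.isfinite(sbp) and np.isfinite(dbp) and sbp > dbp),
            )
        )
    return beats


def detect_fiducials(record: WaveformRecord) -> FiducialSet:
    """Run all three detectors on a full record."""
    r_peaks = detect_r_peaks(record.ecg, record.sampling_rate)
    ppg_peaks, ppg_turns = delineate_pulse_channel(record.ppg, record.sampling_rate)
    abp_peaks, abp_turns = delineate_pulse_channel(record.abp, record.sampling_rate)
    return FiducialSet(
        r_peaks=r_peaks,
        ppg_systolic_peaks=ppg_peaks,
        ppg_turning_points=ppg_turns,
        abp_systolic_peaks=abp_peaks,
        abp_turning_points=abp_turns,
        n_samples=record.n_samples,
    )
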