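"""Core containers for multi-channel waveform records and labeled segments.

Conventions used throughout the package:

* sample indices are 0-based and windows are half-open ``[start, start + L)``;
* invalid samples are represented as non-finite values (NaN);
* ABP amplitudes are in mmHg, PPG amplitude is unitless (normalized), ECG
  amplitude is in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VALID_SAMPLING_RATES = (125, 500)


@dataclass
class Demographics:
    """Per-subject demographic information.

    Height/weight/BMI are optional because only one of the emulated source
    databases provides them.
    """

    age: Optional[float] = None
    gender: str = "unknown"  # "M", "F" or "unknown"
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F", "unknown"):
            raise ValueError(f"gender must be 'M', 'F' or 'unknown', got {self.gender!r}")
        if (
            self.height_cm is not None
            and self.weight_kg is not None
            and self.bmi is not None
        ):
            expected = self.weight_kg / (self.height_cm / 100.0) ** 2
            if not np.isclose(self.bmi, expected, rtol=0.05):
                raise ValueError(
                    f"bmi={self.bmi:.2f} inconsistent with weight/height "
                    f"(expected {expected:.2f} within 5%)"
                )


@dataclass
class WaveformRecord:
    """One subject-record of synchronized ECG, PPG and ABP samples."""

    subject_id: str
    record_id: str
    sampling_rate: int
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    source: str = "synthetic"  # {"mimic-like", "vitaldb-like", "synthetic"}
    demographics: Demographics = field(default_factory=Demographics)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError(
                "all three channels must have equal length, got "
                f"ecg={len(self.ecg)}, ppg={len(self.ppg)}, abp={len(self.abp)}"
            )
        if self.sampling_rate not in VALID_SAMPLING_RATES:
            raise ValueError(
                f"sampling_rate must be one of {VALID_SAMPLING_RATES}, got {self.sampling_rate}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, stop: int) -> "WaveformRecord":
        """Return a copy restricted to samples ``[start, stop)``."""
        return replace(
            self,
            ecg=self.ecg[start:stop].copy(),
            ppg=self.ppg[start:stop].copy(),
            abp=self.abp[start:stop].copy(),
        )


def _check_indices(name: str, idx: np.ndarray, n_samples: Optional[int]) -> np.ndarray:
    idx = np.asarray(idx, dtype=np.int64)
    if idx.ndim != 1:
        raise ValueError(f"{name} must be a 1-d index array")
    if len(idx) > 1 and np.any(np.diff(idx) <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if n_samples is not None and len(idx) and (idx[0] < 0 or idx[-1] >= n_samples):
        raise ValueError(f"{name} indices out of bounds [0, {n_samples})")
    return idx


@dataclass
class FiducialSet:
    """Sample indices of the per-beat landmarks of each channel.

    Turning points are the minima between consecutive systolic peaks, so a
    channel with ``k`` systolic peaks carries ``k - 1`` turning points, one
    strictly between each consecutive pair.
    """

    r_peaks: np.ndarray
    ppg_systolic_peaks: np.ndarray
    ppg_turning_points: np.ndarray
    abp_systolic_peaks: np.ndarray
    abp_turning_points: np.ndarray
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        self.r_peaks = _check_indices("r_peaks", self.r_peaks, self.n_samples)
        self.ppg_systolic_peaks = _check_indices(
            "ppg_systolic_peaks", self.ppg_systolic_peaks, self.n_samples
        )
        self.ppg_turning_points = _check_indices(
            "ppg_turning_points", self.ppg_turning_points, self.n_samples
        )
        self.abp_systolic_peaks = _check_indices(
            "abp_systolic_peaks", self.abp_systolic_peaks, self.n_samples
        )
        self.abp_turning_points = _check_indices(
            "abp_turning_points", self.abp_turning_points, self.n_samples
        )
        for ch in ("ppg", "abp"):
            peaks = getattr(self, f"{ch}_systolic_peaks")
            turns = getattr(self, f"{ch}_turning_points")
            if len(peaks) >= 2 and len(turns):
                inside = np.searchsorted(peaks, turns)
                if np.any(inside == 0) or np.any(inside == len(peaks)):
                    raise ValueError(f"{ch} turning points must lie between systolic peaks")

    def shifted(self, offset: int, n_samples: Optional[int] = None) -> "FiducialSet":
        """Shift all indices by ``-offset`` and keep those inside ``[0, n_samples)``.

        Used to express record-frame fiducials in a segment's local frame.
        """

        def shift(idx: np.ndarray) -> np.ndarray:
            out = idx - offset
            if n_samples is not None:
                out = out[(out >= 0) & (out < n_samples)]
            return out

        def between(turns: np.ndarray, peaks: np.ndarray) -> np.ndarray:
            # cropping can orphan a turning point outside the retained peak
            # span; keep only those strictly between two retained peaks
            if len(peaks) < 2:
                return turns[:0]
            return turns[(turns > peaks[0]) & (turns < peaks[-1])]

        ppg_peaks = shift(self.ppg_systolic_peaks)
        abp_peaks = shift(self.abp_systolic_peaks)
        return FiducialSet(
            r_peaks=shift(self.r_peaks),
            ppg_systolic_peaks=ppg_peaks,
            ppg_turning_points=between(shift(self.ppg_turning_points), ppg_peaks),
            abp_systolic_peaks=abp_peaks,
            abp_turning_points=between(shift(self.abp_turning_points), abp_peaks),
            n_samples=n_samples,
        )


@dataclass
class BeatBP:
    """Reference blood pressure of one cardiac cycle of the ABP waveform."""

    beat_index: int
    systolic_sample: int
    sbp: float
    turning_sample: int
    dbp: float
    valid: bool = True


@dataclass
class QCReport:
    """Outcome of the four-stage segment cleaning procedure.

    ``overall_pass`` is the conjunction of the four rule flags; the order of
    evaluation is flatline -> cardiac cycle -> skewness SQI -> PPG-ABP
    correlation, and ``first_failed`` names the first rule violated (or
    ``"none"``).
    """

    pass_flatline: bool = False
    pass_cycle: bool = False
    pass_ssqi: bool = False
    min_window_skewness: float = float("nan")
    pass_ppg_abp_corr: bool = False
    alignment_lag: int = 0
    ppg_abp_r: float = float("nan")
    fail_reason: str = ""

    RULE_ORDER = ("flatline", "cycle", "ssqi", "ppg_abp_corr")

    @property
    def overall_pass(self) -> bool:
        return (
            self.pass_flatline
            and self.pass_cycle
            and self.pass_ssqi
            and self.pass_ppg_abp_corr
        )

    @property
    def first_failed(self) -> str:
        for rule in self.RULE_ORDER:
            if not getattr(self, f"pass_{rule}"):
                return rule
        return "none"


@dataclass
class Segment:
    """A 10-s window of all three channels with local fiducials and labels.

    ``sbp_ref``/``dbp_ref`` are the arithmetic means of the beat-to-beat
    SBP/DBP values whose systolic peak falls inside the window; NaN when the
    window holds no complete beat.
    """

    subject_id: str
    record_id: str
    start_sample: int
    fs: int
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    fiducials: Optional[FiducialSet] = None
    sbp_ref: float = float("nan")
    dbp_ref: float = float("nan")
    qc: Optional[QCReport] = None

    def __post_init__(self) -> None:
        n = 10 * self.fs
        for name in ("ecg", "ppg", "abp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} slice must hold exactly {n} samples, got {len(arr)}")
            setattr(self, name, arr)
        if (
            np.isfinite(self.sbp_ref)
            and np.isfinite(self.dbp_ref)
            and self.sbp_ref <= self.dbp_ref
        ):
            raise ValueError("sbp_ref must exceed dbp_ref when labels are defined")

    @property
    def duration_s(self) -> float:
        return 10.0

    @property
    def start_s(self) -> float:
        return self.start_sample / self.fs
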