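"""Record-level I/O: valid-interval extraction, resampling, per-subject files.

Records arrive with invalid placeholder samples (represented in memory as
NaN).  Curation keeps, per record, the single longest interval over which
all three channels are simultaneously valid, provided it lasts at least
10 s.  Records sampled at 500 Hz are decimated to the pipeline's common
125 Hz rate with a polyphase anti-aliasing resampler.

Cleaned segments are stored one-subject-per-file in an HDF5 container
(one group per segment holding the three channel datasets, fiducial index
arrays, labels and QC flags, with demographics as file-level attributes),
plus an optional plain-CSV segment index for cohort-level bookkeeping.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .records import Demographics, FiducialSet, QCReport, Segment, WaveformRecord

__all__ = [
    "longest_valid_interval_bounds",
    "extract_longest_valid_interval",
    "resample_record",
    "write_record_file",
    "read_record_file",
    "write_subject_file",
    "read_subject_file",
    "write_segment_index",
]

MIN_VALID_S = 10.0


def longest_valid_interval_bounds(record: WaveformRecord) -> Optional[tuple[int, int]]:
    """Bounds ``[start, stop)`` of the longest jointly-valid run, or None.

    A sample is valid when all three channels are finite there.  Ties
    between equal-length runs keep the earliest.  Runs shorter than 10 s
    yield None.
    """
    valid = np.isfinite(record.ecg) & np.isfinite(record.ppg) & np.isfinite(record.abp)
    if not valid.any():
        return None
    padded = np.concatenate(([False], valid, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    lengths = stops - starts
    best = int(np.argmax(lengths))  # argmax keeps the earliest maximum
    if lengths[best] < MIN_VALID_S * record.sampling_rate:
        return None
    return int(starts[best]), int(stops[best])


def extract_longest_valid_interval(record: WaveformRecord) -> Optional[WaveformRecord]:
    """The longest interval with no invalid sample in any channel.

    Returns None when no jointly-valid run of at least 10 s exists
    (including the all-invalid case).  Idempotent: applying it to its own
    output returns an identical record.
    """
    bounds = longest_valid_interval_bounds(record)
    if bounds is None:
        return None
    start, stop = bounds
    if start == 0 and stop == record.n_samples:
        return record.slice(0, record.n_samples)
    return record.slice(start, stop)


def resample_record(record: WaveformRecord, target_fs: int) -> WaveformRecord:
    """Resample to ``target_fs`` with polyphase anti-aliasing filtering.

    Only downsampling (or the identity) is supported; the curation pipeline
    normalizes 500 Hz sources down to 125 Hz and never upsamples.
    """
    if target_fs > record.sampling_rate:
        raise ValueError(
            f"upsampling from {record.sampling_rate} to {target_fs} Hz is not supported"
        )
    if target_fs == record.sampling_rate:
        return record.slice(0, record.n_samples)
    ratio = Fraction(int(target_fs), int(record.sampling_rate))
    up, down = ratio.numerator, ratio.denominator
    return dataclasses.replace(
        record,
        sampling_rate=int(target_fs),
        ecg=sp_signal.resample_poly(record.ecg, up, down),
        ppg=sp_signal.resample_poly(record.ppg, up, down),
        abp=sp_signal.resample_poly(record.abp, up, down),
    )


def write_record_file(record: WaveformRecord, path, fiducials: Optional[FiducialSet] = None) -> None:
    """Write one raw record (optionally with fiducial index arrays) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = record.subject_id
        f.attrs["record_id"] = record.record_id
        f.attrs["source"] = record.source
        f.attrs["sampling_rate"] = record.sampling_rate
        f.attrs["gender"] = record.demographics.gender
        for name in ("age", "height_cm", "weight_kg", "bmi"):
            value = getattr(record.demographics, name)
            if value is not None:
                f.attrs[name] = float(value)
        for ch in ("ecg", "ppg", "abp"):
            f.create_dataset(ch, data=getattr(record, ch))
        if fiducials is not None:
            g = f.create_group("fiducials")
            for name in _FIDUCIAL_FIELDS:
                g.create_dataset(name, data=getattr(fiducials, name))


def read_record_file(path) -> tuple[WaveformRecord, Optional[FiducialSet]]:
    """Read a record container written by :func:`write_record_file`."""
    with h5py.File(path, "r") as f:
        for ch in ("ecg", "ppg", "abp"):
            if ch not in f:
                raise ValueError(f"malformed record file: missing field '{ch}'")
        demographics = Demographics(
            age=float(f.attrs["age"]) if "age" in f.attrs else None,
            gender=str(f.attrs.get("gender", "unknown")),
            height_cm=float(f.attrs["height_cm"]) if "height_cm" in f.attrs else None,
            weight_kg=float(f.attrs["weight_kg"]) if "weight_kg" in f.attrs else None,
            bmi=float(f.attrs["bmi"]) if "bmi" in f.attrs else None,
        )
        record = WaveformRecord(
            subject_id=str(f.attrs["subject_id"]),
            record_id=str(f.attrs["record_id"]),
            source=str(f.attrs.get("source", "synthetic")),
            sampling_rate=int(f.attrs["sampling_rate"]),
            ecg=np.asarray(f["ecg"]),
            ppg=np.asarray(f["ppg"]),
            abp=np.asarray(f["abp"]),
            demographics=demographics,
        )
        fiducials = None
        if "fiducials" in f:
            g = f["fiducials"]
            fiducials = FiducialSet(
                **{name: np.asarray(g[name]) for name in _FIDUCIAL_FIELDS},
                n_samples=record.n_samples,
            )
    return record, fiducials


# ---------------------------------------------------------------------------
# Per-subject HDF5 container
# ---------------------------------------------------------------------------

_FIDUCIAL_FIELDS = (
    "r_peaks",
    "ppg_systolic_peaks",
    "ppg_turning_points",
    "abp_systolic_peaks",
    "abp_turning_points",
)
_QC_FIELDS = (
    "pass_flatline",
    "pass_cycle",
    "pass_ssqi",
    "pass_ppg_abp_corr",
)


def write_subject_file(
    segments: Sequence[Segment], demographics: Demographics, path
) -> None:
    """Write one subject's cleaned segments to an HDF5 container.

    All segments must share one subject id.  The round trip through
    :func:`read_subject_file` is lossless for signals (float precision),
    labels, fiducial indices, demographics and QC flags.
    """
    subject_ids = {s.subject_id for s in segments}
    if len(subject_ids) > 1:
        raise ValueError(f"segments span multiple subjects: {sorted(subject_ids)}")
    subject_id = subject_ids.pop() if subject_ids else ""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = subject_id
        f.attrs["n_segments"] = len(segments)
        f.attrs["gender"] = demographics.gender
        for name in ("age", "height_cm", "weight_kg", "bmi"):
            value = getattr(demographics, name)
            if value is not None:
                f.attrs[name] = float(value)
        for i, seg in enumerate(segments):
            g = f.create_group(f"segment_{i:06d}")
            g.attrs["record_id"] = seg.record_id
            g.attrs["start_sample"] = seg.start_sample
            g.attrs["fs"] = seg.fs
            g.attrs["sbp_ref"] = seg.sbp_ref
            g.attrs["dbp_ref"] = seg.dbp_ref
            for ch in ("ecg", "ppg", "abp"):
                g.create_dataset(ch, data=getattr(seg, ch))
            if seg.fiducials is not None:
                for name in _FIDUCIAL_FIELDS:
                    g.create_dataset(name, data=getattr(seg.fiducials, name))
            if seg.qc is not None:
                for name in _QC_FIELDS:
                    g.attrs[name] = bool(getattr(seg.qc, name))
                g.attrs["min_window_skewness"] = seg.qc.min_window_skewness
                g.attrs["alignment_lag"] = seg.qc.alignment_lag
                g.attrs["ppg_abp_r"] = seg.qc.ppg_abp_r


def read_subject_file(path) -> tuple[list[Segment], Demographics]:
    """Read a per-subject container written by :func:`write_subject_file`."""
    with h5py.File(path, "r") as f:
        demographics = Demographics(
            age=float(f.attrs["age"]) if "age" in f.attrs else None,
            gender=str(f.attrs.get("gender", "unknown")),
            height_cm=float(f.attrs["height_cm"]) if "height_cm" in f.attrs else None,
            weight_kg=float(f.attrs["weight_kg"]) if "weight_kg" in f.attrs else None,
            bmi=float(f.attrs["bmi"]) if "bmi" in f.attrs else None,
        )
        subject_id = str(f.attrs.get("subject_id", ""))
        segments: list[Segment] = []
        for key in sorted(k for k in f.keys() if k.startswith("segment_")):
            g = f[key]
            for ch in ("ecg", "ppg", "abp"):
                if ch not in g:
                    raise ValueError(f"malformed segment {key!r}: missing field '{ch}'")
            fiducials = None
            if all(name in g for name in _FIDUCIAL_FIELDS):
                fiducials = FiducialSet(
                    **{name: np.asarray(g[name]) for name in _FIDUCIAL_FIELDS}
                )
            qc = None
            if all(name in g.attrs for name in _QC_FIELDS):
                qc = QCReport(
                    pass_flatline=bool(g.attrs["pass_flatline"]),
                    pass_cycle=bool(g.attrs["pass_cycle"]),
                    pass_ssqi=bool(g.attrs["pass_ssqi"]),
                    pass_ppg_abp_corr=bool(g.attrs["pass_ppg_abp_corr"]),
                    min_window_skewness=float(g.attrs["min_window_skewness"]),
                    alignment_lag=int(g.attrs["alignment_lag"]),
                    ppg_abp_r=float(g.attrs["ppg_abp_r"]),
                )
            segments.append(
                Segment(
                    subject_id=subject_id,
                    record_id=str(g.attrs["record_id"]),
                    start_sample=int(g.attrs["start_sample"]),
                    fs=int(g.attrs["fs"]),
                    ecg=np.asarray(g["ecg"]),
                    ppg=np.asarray(g["ppg"]),
                    abp=np.asarray(g["abp"]),
                    fiducials=fiducials,
                    sbp_ref=float(g.attrs["sbp_ref"]),
                    dbp_ref=float(g.attrs["dbp_ref"]),
                    qc=qc,
                )
            )
    return segments, demographics


def write_segment_index(segments: Sequence[Segment], path) -> pd.DataFrame:
    """Cohort-level CSV index: one row per segment with labels and QC outcome."""
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "record_id": [s.record_id for s in segments],
            "segment_start_s": [s.start_s for s in segments],
            "sbp_ref": [s.sbp_ref for s in segments],
            "dbp_ref": [s.dbp_ref for s in segments],
            "qc_pass": [bool(s.qc.overall_pass) if s.qc else False for s in segments],
        }
    )
    df.to_csv(path, index=False)
    return df
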