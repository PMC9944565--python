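import numpy as np
import pytest

from pulseclean.records import FiducialSet, Segment
from pulseclean.synth import SynthParams, generate_triplet

FS = 125
SEG_LEN = 10 * FS


@pytest.fixture(scope="session")
def clean_triplet():
    """A 60-s clean synthetic record at 72 bpm with a 296 ms PPG lag."""
    params = SynthParams(
        heart_rate=72.0,
        hr_variability=0.02,
        sbp=118.0,
        dbp=68.0,
        ppg_abp_lag=0.296,
        noise_sd=0.0,
        sampling_rate=FS,
        duration=60.0,
        seed=3,
    )
    return generate_triplet(params)


def make_segment(ecg=None, ppg=None, abp=None, fs=FS, fiducials=None, **kwargs):
    """A 10-s segment from explicit channel arrays (zeros by default)."""
    n = 10 * fs
    zeros = np.zeros(n)
    return Segment(
        subject_id=kwargs.pop("subject_id", "S0000"),
        record_id=kwargs.pop("record_id", "R0"),
        start_sample=kwargs.pop("start_sample", 0),
        fs=fs,
        ecg=zeros.copy() if ecg is None else np.asarray(ecg, dtype=float),
        ppg=zeros.copy() if ppg is None else np.asarray(ppg, dtype=float),
        abp=zeros.copy() if abp is None else np.asarray(abp, dtype=float),
        fiducials=fiducials,
        **kwargs,
    )


def segment_of(trip, index=0):
    """Extract one labeled QC'd segment from a synthetic triplet."""
    from pulseclean.segment_qc import run_qc, segment_record

    segs = segment_record(trip.record, trip.fiducials)
    seg = segs[index]
    run_qc(seg)
    return seg


def grid_fiducials(fs=FS, period_s=1.0, n=SEG_LEN, peak_offset=20):
    """A regular synthetic fiducial grid for rule-level tests."""
    step = int(period_s * fs)
    peaks = np.arange(peak_offset, n, step)
    turns = (peaks[:-1] + peaks[1:]) // 2
    return FiducialSet(
        r_peaks=peaks,
        ppg_systolic_peaks=peaks,
        ppg_turning_points=turns,
        abp_systolic_peaks=peaks,
        abp_turning_points=turns,
        n_samples=n,
    )
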