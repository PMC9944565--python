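"""Segmentation, labels, and the four cleaning rules."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from conftest import FS, SEG_LEN, grid_fiducials, make_segment
from pulseclean.segment_qc import (
    QCConfig,
    clean_dataset,
    cycle_check,
    flatline_check,
    ppg_abp_correlation_check,
    run_qc,
    sample_skewness,
    segment_record,
    ssqi_check,
)
from pulseclean.synth import ArtifactSpec, SynthParams, generate_triplet


def pulse_ppg(fs=FS, hr=72.0, seed=0):
    trip = generate_triplet(SynthParams(heart_rate=hr, duration=10, seed=seed))
    return trip.record.ppg


class TestSegmentation:
    def test_floor_division_discards_remainder(self):
        trip = generate_triplet(SynthParams(duration=95, seed=1))
        segs = segment_record(trip.record, trip.fiducials)
        assert len(segs) == 9
        assert segs[-1].start_sample == 8 * SEG_LEN

    def test_constant_bp_labels_exact(self, clean_triplet):
        segs = segment_record(clean_triplet.record, clean_triplet.fiducials)
        for seg in segs:
            assert seg.sbp_ref == pytest.approx(118.0, abs=0.5)
            assert seg.dbp_ref == pytest.approx(68.0, abs=0.5)

    def test_alternating_bp_averages(self):
        # beats alternating SBP 110/130 -> label 120
        n_beats = 80
        sbp = np.where(np.arange(n_beats) % 2 == 0, 110.0, 130.0)
        trip = generate_triplet(
            SynthParams(heart_rate=72, hr_variability=0.0, duration=60, sbp=sbp, dbp=70.0)
        )
        segs = segment_record(trip.record, trip.fiducials)
        for seg in segs:
            assert seg.sbp_ref == pytest.approx(120.0, abs=1.7)  # odd beat counts wobble

    def test_segments_tile_from_record_start(self, clean_triplet):
        segs = segment_record(clean_triplet.record, clean_triplet.fiducials)
        starts = [s.start_sample for s in segs]
        assert starts == [i * SEG_LEN for i in range(len(segs))]


class TestFlatline:
    def _segment(self, ppg):
        return make_segment(ppg=ppg, ecg=pulse_ppg(seed=11), abp=pulse_ppg(seed=12) * 50 + 70)

    def test_four_samples_at_maximum_fails(self):
        ppg = pulse_ppg()
        top = np.argmax(ppg)
        ppg[top : top + 4] = ppg.max()
        assert flatline_check(self._segment(ppg)) is False

    def test_three_samples_at_maximum_passes(self):
        ppg = pulse_ppg()
        hi = ppg.max() + 0.1
        ppg[500:503] = hi
        assert flatline_check(self._segment(ppg)) is True

    def test_midrange_run_longer_than_1s_fails(self):
        ecg = pulse_ppg(seed=2)
        mid = 0.5 * (ecg.min() + ecg.max())
        ecg[100 : 100 + int(1.2 * FS)] = mid
        assert flatline_check(make_segment(ecg=ecg, ppg=pulse_ppg(), abp=pulse_ppg())) is False

    def test_midrange_run_up_to_1s_passes(self):
        ecg = pulse_ppg(seed=2)
        mid = 0.5 * (ecg.min() + ecg.max())
        ecg[100 : 100 + FS] = mid
        assert flatline_check(make_segment(ecg=ecg, ppg=pulse_ppg(), abp=pulse_ppg())) is True

    def test_affine_rescaling_invariance(self):
        ppg = pulse_ppg()
        ppg[700:706] = ppg.max()
        seg_fail = make_segment(ppg=ppg)
        seg_fail2 = make_segment(ppg=2.5 * ppg - 7.0)
        assert flatline_check(seg_fail) == flatline_check(seg_fail2) == False  # noqa: E712
        clean = make_segment(ppg=pulse_ppg(), ecg=pulse_ppg(seed=3), abp=pulse_ppg(seed=4))
        scaled = make_segment(
            ppg=3.0 * clean.ppg + 1.0, ecg=3.0 * clean.ecg + 1.0, abp=3.0 * clean.abp + 1.0
        )
        assert flatline_check(clean) == flatline_check(scaled) == True  # noqa: E712


class TestCycle:
    def test_many_beats_pass(self, clean_triplet):
        seg = segment_record(clean_triplet.record, clean_triplet.fiducials)[1]
        assert cycle_check(seg) is True

    def test_no_abp_peaks_fails(self):
        fid = grid_fiducials()
        fid.abp_systolic_peaks = np.array([], dtype=np.int64)
        fid.abp_turning_points = np.array([], dtype=np.int64)
        assert cycle_check(make_segment(fiducials=fid)) is False

    def test_minimal_single_cycle_passes(self):
        from pulseclean.records import FiducialSet

        fid = FiducialSet(
            r_peaks=np.array([100, 500]),
            ppg_systolic_peaks=np.array([120, 520]),
            ppg_turning_points=np.array([320]),
            abp_systolic_peaks=np.array([110, 510]),
            abp_turning_points=np.array([310]),
            n_samples=SEG_LEN,
        )
        assert cycle_check(make_segment(fiducials=fid)) is True


class TestSkewnessSQI:
    def test_skewness_matches_independent_estimator(self):
        rng = np.random.default_rng(0)
        for x in (rng.normal(size=500), rng.exponential(size=500), pulse_ppg()):
            assert sample_skewness(x) == pytest.approx(
                float(sp_stats.skew(x, bias=True)), abs=1e-12
            )

    def test_zero_variance_window_defined_as_zero(self):
        assert sample_skewness(np.full(100, 2.0)) == 0.0

    def test_right_skewed_pulse_train_passes(self):
        flag, min_skew = ssqi_check(make_segment(ppg=pulse_ppg()))
        assert flag and min_skew > 0

    def test_inverted_ppg_fails(self):
        ppg = pulse_ppg()
        flag_pos, skew_pos = ssqi_check(make_segment(ppg=ppg))
        flag_neg, skew_neg = ssqi_check(make_segment(ppg=-ppg))
        assert flag_pos and not flag_neg
        assert skew_neg == pytest.approx(-skew_pos, abs=1e-9)  # skewness is odd

    def test_reported_minimum_matches_oracle(self):
        rng = np.random.default_rng(5)
        ppg = rng.normal(size=SEG_LEN)
        _, min_skew = ssqi_check(make_segment(ppg=ppg))
        win, stride = 5 * FS, FS
        oracle = min(
            sp_stats.skew(ppg[s : s + win], bias=True)
            for s in range(0, SEG_LEN - win + 1, stride)
        )
        assert min_skew == pytest.approx(float(oracle), abs=1e-12)


class TestCorrelation:
    def test_shifted_copy_recovers_lag(self):
        abp = pulse_ppg(seed=6) * 50 + 70
        ppg = np.roll(abp, 37)
        flag, lag, r = ppg_abp_correlation_check(make_segment(ppg=ppg, abp=abp))
        assert flag and lag == 37
        assert r > 0.99

    def test_noise_ppg_fails(self):
        rng = np.random.default_rng(7)
        abp = pulse_ppg(seed=6) * 50 + 70
        flag, _, r = ppg_abp_correlation_check(
            make_segment(ppg=rng.normal(size=SEG_LEN), abp=abp)
        )
        assert not flag and r < 0.5

    def test_clean_triplet_lag_recovery(self, clean_triplet):
        seg = segment_record(clean_triplet.record, clean_triplet.fiducials)[2]
        flag, lag, r = ppg_abp_correlation_check(seg)
        assert flag
        assert abs(lag - round(0.296 * FS)) <= 1
        assert r > 0.99

    def test_zero_variance_channel_fails_with_nan(self):
        flag, _, r = ppg_abp_correlation_check(
            make_segment(ppg=np.zeros(SEG_LEN), abp=pulse_ppg())
        )
        assert not flag and np.isnan(r)

    def test_swap_symmetry(self):
        abp = pulse_ppg(seed=8) * 40 + 75
        ppg = np.roll(abp, 21)
        f1, lag1, r1 = ppg_abp_correlation_check(make_segment(ppg=ppg, abp=abp))
        f2, lag2, r2 = ppg_abp_correlation_check(make_segment(ppg=abp, abp=ppg))
        assert lag1 == -lag2
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestPipeline:
    def test_clean_cohort_all_kept(self):
        records = [
            generate_triplet(
                SynthParams(heart_rate=hr, duration=30, ppg_abp_lag=0.1,
                            hr_variability=0.02, seed=i)
            ).record
            for i, hr in enumerate((55, 75, 95, 115))
        ]
        kept, tally = clean_dataset(records)
        assert len(kept) == 4 * 3
        assert tally["kept"] == 12
        assert sum(v for k, v in tally.items() if k not in ("kept",)) == 0

    def test_flatlined_segments_all_rejected_by_flatline_rule(self):
        arts = [ArtifactSpec("flatline", "ppg", 10.0 * i + 4.0, 2.0) for i in range(3)]
        trip = generate_triplet(SynthParams(duration=30, seed=9), arts)
        kept, tally = clean_dataset([trip.record])
        assert len(kept) == 0
        assert tally["flatline"] == 3

    def test_rejection_monotone_in_noise(self):
        # increasing noise never increases the correlation pass rate
        rates = []
        for noise in (0.0, 0.15, 0.5):
            passes = 0
            for seed in range(5):
                trip = generate_triplet(
                    SynthParams(duration=30, noise_sd=noise, seed=seed)
                )
                segs = segment_record(trip.record, trip.fiducials)
                for s in segs:
                    flag, _, _ = ppg_abp_correlation_check(s)
                    passes += flag
            rates.append(passes)
        assert rates[0] >= rates[1] >= rates[2]

    def test_run_qc_records_all_flags_and_order(self):
        ppg = pulse_ppg()
        ppg[200:600] = ppg[200]  # >1 s flatline; also destroys cycles locally
        seg = make_segment(ppg=ppg, ecg=pulse_ppg(seed=2), abp=pulse_ppg(seed=3) * 50 + 70)
        seg.fiducials = grid_fiducials()
        report = run_qc(seg)
        assert report.first_failed == "flatline"
        assert report.pass_cycle in (True, False)  # still evaluated
        assert not report.overall_pass

    def test_correlation_skipped_without_cycle(self):
        seg = make_segment(ppg=pulse_ppg(), ecg=pulse_ppg(seed=2), abp=pulse_ppg(seed=3))
        seg.fiducials = None
        report = run_qc(seg)
        assert not report.pass_cycle
        assert not report.pass_ppg_abp_corr
        assert np.isnan(report.ppg_abp_r)
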