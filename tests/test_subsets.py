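"""AAMI compliance checking, constrained sampling, balancing and splits."""

import numpy as np
import pandas as pd
import pytest

from pulseclean.subsets import (
    AAMIRequirements,
    balance_subjects,
    build_aami_sets,
    build_subset_bundle,
    check_aami_compliance,
    k_tradeoff,
    split_train_test,
    validate_bundle,
)
from pulseclean.synth import CohortSpec, generate_cohort_labels


def wide_cohort_labels(seed=42, n_subjects=150, segments=30):
    spec = CohortSpec(
        n_subjects=n_subjects,
        segments_per_subject=segments,
        subject_sbp_mean=125.0,
        subject_sbp_sd=25.0,
        subject_dbp_mean=70.0,
        subject_dbp_sd=15.0,
        within_sbp_sd=12.0,
        within_dbp_sd=7.0,
        seed=seed,
    )
    return generate_cohort_labels(spec)


def brute_force_compliance(labels, req):
    """Independent recount with plain loops (oracle for the vectorized check)."""
    per_subject = {}
    for _, row in labels.iterrows():
        per_subject.setdefault(row["subject_id"], []).append((row["sbp_ref"], row["dbp_ref"]))
    n_total = sum(len(v) for v in per_subject.values())
    count = dict(sbp_le_100=0, sbp_ge_160=0, sbp_ge_140=0, dbp_le_60=0, dbp_ge_100=0, dbp_ge_85=0)
    for v in per_subject.values():
        for sbp, dbp in v:
            count["sbp_le_100"] += sbp <= 100
            count["sbp_ge_160"] += sbp >= 160
            count["sbp_ge_140"] += sbp >= 140
            count["dbp_le_60"] += dbp <= 60
            count["dbp_ge_100"] += dbp >= 100
            count["dbp_ge_85"] += dbp >= 85
    props = {k: 100.0 * c / n_total for k, c in count.items()}
    ok = (
        len(per_subject) >= req.min_subjects
        and min(len(v) for v in per_subject.values()) >= req.min_meas_per_subject
        and n_total >= req.min_total
        and all(props[k] >= req.min_prop(k) for k in props)
    )
    return props, ok


class TestCompliance:
    def test_published_reference_composition_passes(self):
        # a set with 242 subjects x >=3 measurements and tail proportions
        # (14.63/15.52/38.81/25.75/9.40/27.24%) satisfies every requirement
        rng = np.random.default_rng(0)
        n = 1340
        counts = np.full(242, 5)
        counts[: n - 242 * 5] += 1  # 130 subjects with 6, the rest with 5
        subj = np.repeat([f"S{i}" for i in range(242)], counts)
        sbp = np.full(n, 120.0)
        sbp[: int(0.1463 * n)] = 95.0
        sbp[int(0.1463 * n) : int(0.1463 * n) + int(0.1552 * n)] = 165.0
        k140 = int(0.3881 * n) - int(0.1552 * n)
        sbp[int(0.1463 * n) + int(0.1552 * n) : int(0.1463 * n) + int(0.1552 * n) + k140] = 145.0
        dbp = np.full(n, 70.0)
        dbp[: int(0.2575 * n)] = 55.0
        dbp[int(0.2575 * n) : int(0.2575 * n) + int(0.094 * n)] = 105.0
        k85 = int(0.2724 * n) - int(0.094 * n)
        dbp[int(0.2575 * n) + int(0.094 * n) : int(0.2575 * n) + int(0.094 * n) + k85] = 90.0
        perm = rng.permutation(n)
        labels = pd.DataFrame(
            {"subject_id": subj, "sbp_ref": sbp[perm], "dbp_ref": dbp[perm] + sbp[perm] * 0}
        )
        report = check_aami_compliance(labels)
        assert report.overall_pass
        assert report.n_subjects == 242
        assert report.n_total == 1340

    def test_84_subjects_fails_min_subjects(self):
        labels = pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(84)], 10),
                "sbp_ref": np.tile([95.0, 165.0, 150.0, 145.0, 120.0] * 2, 84),
                "dbp_ref": np.tile([55.0, 105.0, 90.0, 88.0, 70.0] * 2, 84),
            }
        )
        report = check_aami_compliance(labels)
        assert not report.flags["min_subjects"]
        assert report.failed_requirements() == ["min_subjects"]

    def test_no_low_dbp_fails(self):
        labels = pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(100)], 5),
                "sbp_ref": np.tile([95.0, 165.0, 150.0, 145.0, 120.0], 100),
                "dbp_ref": np.full(500, 70.0),
            }
        )
        report = check_aami_compliance(labels)
        assert report.proportions["dbp_le_60"] == 0.0
        assert not report.flags["min_prop_dbp_le_60"]

    def test_agrees_with_brute_force_recount(self):
        req = AAMIRequirements()
        rng = np.random.default_rng(3)
        for _ in range(5):
            n_subj = int(rng.integers(80, 120))
            labels = pd.DataFrame(
                {
                    "subject_id": rng.choice([f"S{i}" for i in range(n_subj)], 600),
                    "sbp_ref": rng.normal(130, 30, 600),
                    "dbp_ref": rng.normal(72, 18, 600),
                }
            )
            report = check_aami_compliance(labels, req)
            props, ok = brute_force_compliance(labels, req)
            for k, v in props.items():
                assert report.proportions[k] == pytest.approx(v, abs=1e-9)
            assert report.overall_pass == ok


@pytest.fixture(scope="module")
def pool():
    return wide_cohort_labels()


class TestBuildAAMISets:
    def test_built_set_complies(self, pool):
        test, calib, group_c = build_aami_sets(pool, rng_seed=1)
        report = check_aami_compliance(test)
        assert report.overall_pass
        assert report.max_per_subject <= 14
        assert set(test["subject_id"]) == set(group_c)

    def test_calibration_set_is_exact_remainder(self, pool):
        test, calib, group_c = build_aami_sets(pool, rng_seed=1)
        pool_c = pool[pool["subject_id"].isin(group_c)]
        assert len(test) + len(calib) == len(pool_c)
        key = ["subject_id", "record_id", "segment_index"]
        merged = test.merge(calib, on=key)
        assert len(merged) == 0  # disjoint

    def test_deterministic_given_seed(self, pool):
        a, _, _ = build_aami_sets(pool, rng_seed=5)
        b, _, _ = build_aami_sets(pool, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_pool_names_requirement(self, pool):
        capped = pool.copy()
        capped["sbp_ref"] = capped["sbp_ref"].clip(upper=155.0)  # no SBP >= 160 anywhere
        with pytest.raises(ValueError, match="sbp_ge_160"):
            build_aami_sets(capped, rng_seed=1)


class TestBalancing:
    def test_subsample_to_exactly_k(self):
        pool = pd.DataFrame(
            {
                "subject_id": ["A"] * 1000 + ["B"] * 399,
                "sbp_ref": np.linspace(90, 180, 1399),
                "dbp_ref": np.linspace(50, 100, 1399),
            }
        )
        out = balance_subjects(pool, 400, rng_seed=0)
        counts = out.groupby("subject_id").size()
        assert counts.to_dict() == {"A": 400}  # B dropped (399 < 400)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            balance_subjects(pd.DataFrame({"subject_id": []}), 0)

    def test_tradeoff_exact_counting(self):
        pool = pd.DataFrame(
            {
                "subject_id": ["A"] * 10 + ["B"] * 5 + ["C"] * 2,
                "sbp_ref": 120.0,
                "dbp_ref": 70.0,
            }
        )
        table = k_tradeoff(pool, ks=[1, 3, 6, 11])
        assert dict(zip(table["k"], table["usable_subjects"])) == {1: 3, 3: 2, 6: 1, 11: 0}


class TestSplit:
    def balanced(self, n_subjects=100, k=400):
        return pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i:03d}" for i in range(n_subjects)], k),
                "record_id": "R0",
                "segment_index": np.tile(np.arange(k), n_subjects),
                "sbp_ref": np.random.default_rng(0).normal(120, 20, n_subjects * k),
                "dbp_ref": np.random.default_rng(1).normal(65, 12, n_subjects * k),
            }
        )

    def test_360_40_per_subject_at_k400(self):
        bundle = split_train_test(self.balanced(), rng_seed=0)
        assert len(bundle.subjects_in_group("B")) == 10
        train_counts = bundle.training.groupby("subject_id").size()
        cb_counts = bundle.calib_based_test.groupby("subject_id").size()
        assert set(train_counts) == {360}
        assert set(cb_counts) == {40}
        assert len(bundle.calib_free_test) == 10 * 400

    def test_zero_fractions_put_everything_in_training(self):
        pool = self.balanced(n_subjects=10, k=20)
        bundle = split_train_test(pool, 0.0, 0.0, rng_seed=0)
        assert len(bundle.training) == len(pool)
        assert len(bundle.calib_based_test) == 0
        assert len(bundle.calib_free_test) == 0

    def test_too_few_subjects_rejected(self):
        pool = self.balanced(n_subjects=1, k=10)
        with pytest.raises(ValueError):
            split_train_test(pool, rng_seed=0)

    def test_group_disjointness_over_seeds(self):
        pool = self.balanced(n_subjects=30, k=20)
        for seed in range(25):
            bundle = split_train_test(pool, rng_seed=seed)
            validate_bundle(bundle)  # raises on violation
            a = set(bundle.training["subject_id"])
            assert a == set(bundle.calib_based_test["subject_id"])
            assert not (a & set(bundle.calib_free_test["subject_id"]))

    def test_segment_conservation_full_pipeline(self):
        pool = wide_cohort_labels(seed=7, n_subjects=60, segments=25)
        req = AAMIRequirements(min_subjects=40, min_total=120)
        minimal = {name: req.min_prop(name) for name in
                   ("sbp_le_100", "sbp_ge_160", "sbp_ge_140", "dbp_le_60", "dbp_ge_100", "dbp_ge_85")}
        bundle = build_subset_bundle(
            pool, k=20, req=req, rng_seed=3, aami_target_props=minimal
        )
        n_bundle = sum(
            len(getattr(bundle, name))
            for name in ("training", "calib_based_test", "calib_free_test", "aami_test", "aami_calib")
        )
        group_c = bundle.subjects_in_group("C")
        remaining = pool[~pool["subject_id"].isin(group_c)]
        counts = remaining.groupby("subject_id").size()
        discarded = int((counts[counts >= 20] - 20).sum() + counts[counts < 20].sum())
        assert n_bundle + discarded == len(pool)

    def test_train_and_calib_free_bp_distributions_match(self):
        pool = self.balanced(n_subjects=80, k=50)
        diffs = []
        for seed in range(5):
            bundle = split_train_test(pool, rng_seed=seed)
            diffs.append(
                abs(bundle.training["sbp_ref"].mean() - bundle.calib_free_test["sbp_ref"].mean())
            )
        assert np.mean(diffs) < 2.0
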