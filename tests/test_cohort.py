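"""Cohort rules: eligibility, index stays, readmission windows, contacts."""

import logging

import pandas as pd
import pytest

from readmitnet.cohort import (
    CONTACT_PREFIX,
    CohortConfig,
    ascertain_contacts,
    build_cohort,
    detect_readmission,
    eligible_index_codes,
    enumerate_combinations,
    extract_index,
    select_study_base,
)

from conftest import make_dataset, make_records


def _one_patient(age, events, sex="m", pid=1):
    return make_dataset([{"id": pid, "sex": sex, "age": age, "events": events}])


class TestStudyBase:
    def test_age_exactly_at_floor_is_excluded(self):
        ds = _one_patient(50.0, [(10, "admission", "I25", "main")])
        assert select_study_base(ds, CohortConfig()) == set()

    def test_age_just_above_floor_is_included(self):
        ds = _one_patient(50.01, [(10, "admission", "I25", "main")])
        assert select_study_base(ds, CohortConfig()) == {1}

    def test_admission_after_index_window_is_excluded(self):
        # Index window defaults to the first 3 calendar years (2006-2008).
        ds = _one_patient(72.0, [(1200, "admission", "I25", "main")])
        assert select_study_base(ds, CohortConfig()) == set()

    def test_contact_only_patient_is_excluded(self):
        ds = _one_patient(72.0, [(10, "contact", "radiology")])
        assert select_study_base(ds, CohortConfig()) == set()

    def test_no_age_floor_variant_includes_younger_patients(self):
        ds = make_dataset(
            [
                {"id": 1, "sex": "m", "age": 45.0, "events": [(10, "admission", "I25", "main")]},
                {"id": 2, "sex": "f", "age": 101.0, "events": [(10, "admission", "I25", "main")]},
            ]
        )
        assert select_study_base(ds, CohortConfig(min_age=None, max_age=100.0)) == {1}

    def test_all_satisfying_gives_identity(self, small_world):
        _sim, ds, cfg = small_world
        base = select_study_base(ds, cfg)
        assert base == set(ds.events["patient_id"].unique())


class TestExtractIndex:
    def test_earliest_admission_becomes_index(self):
        ds = _one_patient(
            70.0, [(400, "admission", "E11", "main"), (100, "admission", "I25", "main")]
        )
        rec = extract_index(ds, {1}, CohortConfig())
        assert rec.loc[0, "index_date"] == pd.Timestamp("2006-01-01") + pd.Timedelta(days=100)
        assert rec.loc[0, "index_dx"] == frozenset({"I25"})

    def test_code_range_filter_drops_nonspecific_codes(self):
        ds = _one_patient(
            70.0,
            [(10, "admission", "E11", "main"), (10, "admission", "Z03", "secondary")],
        )
        rec = extract_index(ds, {1}, CohortConfig())
        assert rec.loc[0, "index_dx"] == frozenset({"E11"})

    def test_all_codes_out_of_range_drops_patient(self):
        ds = _one_patient(70.0, [(10, "admission", "Z03", "main")])
        rec = extract_index(ds, {1}, CohortConfig())
        assert len(rec) == 0

    def test_same_day_rows_merge_into_one_stay(self):
        ds = _one_patient(
            70.0,
            [
                (10, "admission", "E11", "main"),
                (10, "admission", "I25", "secondary"),
                (10, "admission", "J44", "secondary"),
            ],
        )
        rec = extract_index(ds, {1}, CohortConfig())
        assert rec.loc[0, "index_dx"] == frozenset({"E11", "I25", "J44"})


class TestEligibleCodes:
    def test_count_below_threshold_is_excluded(self):
        recs = make_records(
            [{"index_dx": {"I25"}}] * 3 + [{"index_dx": {"E11"}}] * 2
        )
        assert eligible_index_codes(recs, CohortConfig(min_index_dx_count=3)) == {"I25"}

    def test_degenerate_threshold_keeps_all(self):
        recs = make_records([{"index_dx": {"I25", "E11"}}, {"index_dx": {"J44"}}])
        cfg = CohortConfig(min_index_dx_count=1)
        assert eligible_index_codes(recs, cfg) == {"I25", "E11", "J44"}

    def test_counts_match_brute_force_scan(self, small_world):
        _sim, ds, cfg = small_world
        records, _, codes = build_cohort(ds, cfg)
        brute = {}
        for dx in records["index_dx"]:
            for c in dx:
                brute[c] = brute.get(c, 0) + 1
        expected = {c for c, n in brute.items() if n >= cfg.min_index_dx_count}
        assert codes == expected


class TestDetectReadmission:
    @pytest.mark.parametrize(
        "delta,expected",
        [(89, False), (90, True), (1050, True), (1051, False)],
    )
    def test_window_boundaries_inclusive(self, delta, expected):
        ds = _one_patient(
            70.0,
            [(0, "admission", "I25", "main"), (delta, "admission", "E11", "main")],
        )
        rec = extract_index(ds, {1}, CohortConfig())
        out = detect_readmission(rec, ds, CohortConfig())
        assert bool(out.loc[0, "readmitted"]) is expected

    def test_earliest_qualifying_supplies_d2(self):
        ds = _one_patient(
            70.0,
            [
                (0, "admission", "I25", "main"),
                (90, "admission", "E11", "main"),
                (200, "admission", "J44", "main"),
            ],
        )
        rec = extract_index(ds, {1}, CohortConfig())
        out = detect_readmission(rec, ds, CohortConfig())
        assert out.loc[0, "readmission_main_dx"] == "E11"
        assert out.loc[0, "readmission_date"] == pd.Timestamp("2006-01-01") + pd.Timedelta(days=90)

    def test_missing_main_diagnosis_drops_record(self, caplog):
        ds = _one_patient(
            70.0,
            [(0, "admission", "I25", "main"), (100, "admission", "E11", "secondary")],
        )
        rec = extract_index(ds, {1}, CohortConfig())
        with caplog.at_level(logging.WARNING):
            out = detect_readmission(rec, ds, CohortConfig())
        assert len(out) == 0
        assert "main diagnosis" in caplog.text


class TestAscertainContacts:
    def _flagged(self, ds, specialty="radiology"):
        cfg = CohortConfig(specialty_list=("radiology",))
        rec = extract_index(ds, {1}, cfg)
        rec = detect_readmission(rec, ds, cfg)
        rec = ascertain_contacts(rec, ds, cfg)
        return bool(rec.loc[0, CONTACT_PREFIX + specialty])

    def test_contact_after_readmission_does_not_count(self):
        ds = _one_patient(
            70.0,
            [
                (0, "admission", "I25", "main"),
                (100, "admission", "E11", "main"),
                (101, "contact", "radiology"),
            ],
        )
        assert self._flagged(ds) is False

    def test_contact_between_index_and_readmission_counts(self):
        ds = _one_patient(
            70.0,
            [
                (0, "admission", "I25", "main"),
                (50, "contact", "radiology"),
                (100, "admission", "E11", "main"),
            ],
        )
        assert self._flagged(ds) is True

    def test_contact_on_index_date_does_not_count(self):
        ds = _one_patient(
            70.0, [(0, "admission", "I25", "main"), (0, "contact", "radiology")]
        )
        assert self._flagged(ds) is False

    @pytest.mark.parametrize("delta,expected", [(1050, True), (1051, False)])
    def test_control_follow_up_boundary_inclusive(self, delta, expected):
        ds = _one_patient(
            70.0, [(0, "admission", "I25", "main"), (delta, "contact", "radiology")]
        )
        assert self._flagged(ds) is expected

    def test_repeat_contacts_stay_binary(self):
        ds = _one_patient(
            70.0,
            [(0, "admission", "I25", "main")]
            + [(d, "contact", "radiology") for d in (30, 60, 90, 120, 150)],
        )
        assert self._flagged(ds) is True

    def test_unknown_specialty_is_ignored(self, caplog):
        ds = _one_patient(
            70.0, [(0, "admission", "I25", "main"), (50, "contact", "homeopathy")]
        )
        cfg = CohortConfig(specialty_list=("radiology",))
        rec = extract_index(ds, {1}, cfg)
        rec = detect_readmission(rec, ds, cfg)
        with caplog.at_level(logging.INFO):
            rec = ascertain_contacts(rec, ds, cfg)
        assert not rec.loc[0, CONTACT_PREFIX + "radiology"]
        assert CONTACT_PREFIX + "homeopathy" not in rec.columns


class TestEnumerateCombinations:
    def test_no_readmissions_gives_empty_list(self):
        recs = make_records([{"readmitted": False}] * 5)
        out = enumerate_combinations(recs, CohortConfig())
        assert len(out) == 0

    @pytest.mark.parametrize("n_cases,included", [(49, False), (50, True)])
    def test_case_threshold_boundary(self, n_cases, included):
        recs = make_records(
            [
                {"sex": "m", "index_dx": {"I25"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 200}
            ]
            * n_cases
        )
        recs["patient_id"] = range(n_cases)
        out = enumerate_combinations(recs, CohortConfig())
        assert (len(out) == 1) is included
        if included:
            assert out.loc[0, ["d1", "d2", "sex", "n_cases"]].tolist() == ["I25", "I21", "m", 50]

    def test_multi_code_patient_contributes_each_combination(self):
        recs = make_records(
            [
                {"sex": "f", "index_dx": {"I25", "E11", "J44"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 300}
            ]
        )
        out = enumerate_combinations(recs, CohortConfig(min_combination_cases=1))
        assert set(out["d1"]) == {"I25", "E11", "J44"}
        assert (out["n_cases"] == 1).all()

    def test_restriction_to_eligible_codes(self):
        recs = make_records(
            [
                {"sex": "f", "index_dx": {"I25", "E11"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 300}
            ]
        )
        out = enumerate_combinations(
            recs, CohortConfig(min_combination_cases=1), eligible_codes={"I25"}
        )
        assert set(out["d1"]) == {"I25"}

    def test_lower_threshold_strictly_enlarges(self, small_world):
        """Lowering the case threshold yields a strict superset when some
        combination count falls between the two thresholds; pick thresholds
        from the observed count distribution to guarantee that."""
        import dataclasses

        _sim, ds, cfg = small_world
        records, _, codes = build_cohort(ds, cfg)
        all_counts = enumerate_combinations(
            records, dataclasses.replace(cfg, min_combination_cases=1), eligible_codes=codes
        )["n_cases"]
        t_lo = int(all_counts.quantile(0.25))
        t_hi = int(all_counts.quantile(0.75))
        assert t_lo < t_hi
        base = enumerate_combinations(
            records, dataclasses.replace(cfg, min_combination_cases=t_hi), eligible_codes=codes
        )
        more = enumerate_combinations(
            records, dataclasses.replace(cfg, min_combination_cases=t_lo), eligible_codes=codes
        )
        base_keys = set(map(tuple, base[["d1", "d2", "sex"]].to_numpy()))
        more_keys = set(map(tuple, more[["d1", "d2", "sex"]].to_numpy()))
        assert base_keys < more_keys


def test_records_unique_and_within_study_base(small_world):
    _sim, ds, cfg = small_world
    base = select_study_base(ds, cfg)
    records, _, _ = build_cohort(ds, cfg)
    assert records["patient_id"].is_unique
    assert set(records["patient_id"]) <= base
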