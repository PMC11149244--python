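import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from ckd_labscan.cohort_builder import (
    MalformedRecordError,
    NoEligibleRecordsError,
    PipelineConfig,
    build_assessments,
    diabetes_flag,
    filter_records,
    pair_urinary,
    read_records,
    select_index_creatinine,
)


class TestFilterRecords:
    def test_toy_counts(self):
        rows = [{} for _ in range(7)]
        rows += [{"setting": "inpatient"}, {"setting": "inpatient"}]
        rows += [{"birth_year": 2003, "collection_date": "2019-06-01"}]  # age 16
        kept, counts = filter_records(make_records(rows))
        assert len(kept) == 7
        assert counts.n_excluded_inpatient == 2
        assert counts.n_excluded_age == 1
        assert counts.telescopes()

    @pytest.mark.parametrize("bad_date", ["2018-05-31", "2021-06-01", "2017-01-01"])
    def test_outside_study_window_excluded(self, bad_date):
        kept, counts = filter_records(make_records([{}, {"collection_date": bad_date}]))
        assert len(kept) == 1
        assert counts.n_excluded_window == 1

    def test_window_edges_inclusive(self):
        kept, counts = filter_records(
            make_records(
                [{"collection_date": "2018-06-01"}, {"collection_date": "2021-05-31"}]
            )
        )
        assert len(kept) == 2
        assert counts.n_excluded_window == 0

    def test_high_grade_dipstick_token_kept(self):
        kept, _ = filter_records(
            make_records([{"test_type": "dipstick", "value": "++++"}])
        )
        assert kept["dipstick_category"].iloc[0] == "above_plusplus"

    def test_bad_values_counted_unparseable(self):
        rows = [
            {},
            {"value": "not-a-number"},
            {"value": "-2.0"},
            {"test_type": "dipstick", "value": "5plus"},
            {"sex": ""},
            {"birth_year": ""},
        ]
        kept, counts = filter_records(make_records(rows))
        assert len(kept) == 1
        assert counts.n_excluded_unparseable == 5
        assert counts.telescopes()

    def test_unit_normalization(self):
        kept, _ = filter_records(
            make_records([{"value": "106.1", "unit": "umol/L"}])
        )
        assert kept["value_num"].iloc[0] == pytest.approx(106.1 / 88.42)

    def test_empty_after_filtering_raises(self):
        with pytest.raises(NoEligibleRecordsError):
            filter_records(make_records([{"setting": "inpatient"}]))

    def test_albumin_conc_kept_but_flagged_unusable(self):
        kept, counts = filter_records(
            make_records([{}, {"test_type": "albumin_conc", "value": "120", "unit": "mg/L"}])
        )
        assert counts.n_albumin_conc_unusable == 1
        assert len(kept) == 2


class TestSelectIndexCreatinine:
    def test_chronologically_first(self):
        recs = make_records(
            [
                {"collection_date": "2019-03-01"},
                {"collection_date": "2018-07-10"},
                {"collection_date": "2020-01-01"},
            ]
        )
        index, later = select_index_creatinine(recs)
        assert str(index["collection_date"].date()) == "2018-07-10"
        assert len(later) == 2

    def test_same_date_tie_broken_by_record_id(self):
        recs = make_records([{"value": "1.5"}, {"value": "0.9"}])  # same date
        index, later = select_index_creatinine(recs)
        assert index["record_id"] == 0 and index["value"] == "1.5"
        assert len(later) == 0  # same-day record is not "later"

    def test_single_record(self):
        recs = make_records([{}])
        index, later = select_index_creatinine(recs)
        assert len(later) == 0

    def test_no_creatinine_raises(self):
        recs = make_records([{"test_type": "acr", "value": "40"}])
        with pytest.raises(NoEligibleRecordsError):
            select_index_creatinine(recs)


def _filtered(rows):
    kept, _ = filter_records(make_records(rows))
    return kept


class TestPairUrinary:
    def _index(self, date="2019-06-01"):
        return _filtered([{"collection_date": date}]).iloc[0]

    def test_nearest_wins(self):
        urinary = _filtered(
            [
                {"test_type": "acr", "value": "40", "collection_date": "2019-09-09"},  # +100
                {"test_type": "acr", "value": "400", "collection_date": "2020-07-05"},  # +400
            ]
        )
        pacr, date, _ = pair_urinary(self._index(), urinary)
        assert pacr.value == 40.0

    def test_nearest_in_time_either_direction(self):
        urinary = _filtered(
            [
                {"test_type": "acr", "value": "10", "collection_date": "2019-05-02"},  # -30
                {"test_type": "acr", "value": "99", "collection_date": "2019-12-18"},  # +200
            ]
        )
        pacr, _, _ = pair_urinary(self._index(), urinary)
        assert pacr.value == 10.0

    def test_none_within_window(self):
        urinary = _filtered(
            [{"test_type": "acr", "value": "40", "collection_date": "2020-07-05"}]
        )
        assert pair_urinary(self._index(), urinary) is None

    def test_window_zero_only_same_day(self):
        urinary = _filtered(
            [
                {"test_type": "acr", "value": "40", "collection_date": "2019-06-02"},
                {"test_type": "acr", "value": "7", "collection_date": "2019-06-01"},
            ]
        )
        pacr, _, _ = pair_urinary(self._index(), urinary, window_days=0)
        assert pacr.value == 7.0

    def test_tie_prefers_later_then_modality(self):
        urinary = _filtered(
            [
                {"test_type": "pcr", "value": "500", "collection_date": "2019-05-22"},  # -10
                {"test_type": "dipstick", "value": "++", "collection_date": "2019-06-11"},  # +10
                {"test_type": "pcr", "value": "150", "collection_date": "2019-06-11"},  # +10
            ]
        )
        pacr, _, _ = pair_urinary(self._index(), urinary)
        # +10 beats -10; among +10 candidates PCR outranks dipstick
        assert pacr.source_modality == "pcr_quantitative"
        assert pacr.value == pytest.approx(32.80, abs=0.01)

    def test_direction_after(self):
        urinary = _filtered(
            [{"test_type": "acr", "value": "10", "collection_date": "2019-05-02"}]
        )
        assert pair_urinary(self._index(), urinary, direction="after") is None
        assert pair_urinary(self._index(), urinary, direction="before") is not None

    def test_albumin_conc_never_pairs(self):
        urinary = _filtered(
            [{"test_type": "albumin_conc", "value": "120", "unit": "mg/L"},
             {"test_type": "creatinine"}]
        )
        assert pair_urinary(self._index(), urinary) is None


class TestDiabetesFlag:
    def _index(self):
        return _filtered([{"collection_date": "2019-06-01"}]).iloc[0]

    def test_hba1c_above_threshold_in_window(self):
        g = _filtered([{"test_type": "hba1c", "value": "6.6", "unit": "%",
                        "collection_date": "2019-08-30"}])
        assert diabetes_flag(self._index(), g) is True

    def test_glucose_exactly_200_is_not_diabetes(self):
        g = _filtered([{"test_type": "glucose", "value": "200", "unit": "mg/dL"}])
        assert diabetes_flag(self._index(), g) is False
        g2 = _filtered([{"test_type": "glucose", "value": "200.5", "unit": "mg/dL"}])
        assert diabetes_flag(self._index(), g2) is True

    def test_out_of_window_ignored(self):
        g = _filtered([{"test_type": "hba1c", "value": "7.2", "unit": "%",
                        "collection_date": "2020-07-15"}])  # +410 d
        assert diabetes_flag(self._index(), g) is False


TOY_TABLE = [
    # patient a: G4 creatinine (egfr ~20.2), paired dipstick "+", diabetic
    {"patient_id": "a", "sex": "female", "birth_year": 1949, "value": "2.5",
     "collection_date": "2019-06-01", "specialty": "nephrology"},
    {"patient_id": "a", "test_type": "dipstick", "value": "+", "collection_date": "2019-07-01"},
    {"patient_id": "a", "test_type": "hba1c", "value": "7.1", "unit": "%",
     "collection_date": "2019-06-15"},
    # patient b: G2 creatinine, paired quantitative ACR 45 -> A2 -> ckd
    {"patient_id": "b", "sex": "male", "birth_year": 1959, "value": "1.2",
     "collection_date": "2019-01-10", "specialty": "cardiology"},
    {"patient_id": "b", "test_type": "acr", "value": "45", "collection_date": "2019-03-01"},
    # patient c: G1 creatinine, unpaired
    {"patient_id": "c", "sex": "female", "birth_year": 1969, "value": "0.7",
     "collection_date": "2020-02-02", "specialty": "obgyn"},
]


class TestBuildAssessments:
    def test_toy_three_patients(self):
        out, counts = build_assessments(make_records(TOY_TABLE))
        assert len(out) == 3
        assert counts.n_paired == 2 and counts.n_unpaired == 1
        a = out.set_index("patient_id")
        assert a.loc["a", "g_stage"] == "G4"
        assert a.loc["a", "ckd_status"] == "ckd"
        assert a.loc["a", "a_category"] == "A2"
        assert bool(a.loc["a", "diabetes"]) is True
        assert a.loc["b", "g_stage"] == "G2"
        assert a.loc["b", "ckd_status"] == "ckd"  # G2 with pACR 45 (A2)
        assert a.loc["c", "ckd_status"] == "indeterminate"
        assert not a.loc["c", "paired"]
        assert a.loc["a", "specialty"] == "nephrology"

    def test_patient_with_only_urinary_tests_counted(self):
        rows = TOY_TABLE + [
            {"patient_id": "d", "test_type": "acr", "value": "50",
             "collection_date": "2019-06-01"}
        ]
        out, counts = build_assessments(make_records(rows))
        assert len(out) == 3
        assert counts.n_patients_no_creatinine == 1

    def test_idempotent_and_order_invariant(self, rng):
        table = make_records(TOY_TABLE)
        base, _ = build_assessments(table)
        again, _ = build_assessments(table)
        pd.testing.assert_frame_equal(base, again)
        shuffled = table.sample(frac=1, random_state=7)  # record_id preserved
        out, _ = build_assessments(shuffled)
        pd.testing.assert_frame_equal(base, out)

    def test_flow_counts_telescope_on_messy_input(self):
        rows = TOY_TABLE + [
            {"setting": "inpatient"},
            {"collection_date": "2017-01-01"},
            {"value": "junk"},
        ]
        _, counts = build_assessments(make_records(rows))
        assert counts.telescopes()
        assert counts.n_excluded_inpatient == 1
        assert counts.n_excluded_window == 1
        assert counts.n_excluded_unparseable == 1

    def test_bulk_matches_scalar_composition(self, rng):
        # random small table: the vectorized bulk path must agree with the
        # per-patient scalar operations composed by hand
        rows = []
        for pid in "abcdefgh":
            n = rng.integers(1, 6)
            for _ in range(n):
                tt = rng.choice(["creatinine", "acr", "pcr", "dipstick", "hba1c", "glucose"])
                value = {
                    "creatinine": f"{rng.uniform(0.5, 3.0):.3f}",
                    "acr": f"{rng.uniform(5, 400):.1f}",
                    "pcr": f"{rng.uniform(20, 2000):.1f}",
                    "dipstick": rng.choice(["negative", "trace", "+", "++", ">++"]),
                    "hba1c": f"{rng.uniform(4.5, 9.0):.2f}",
                    "glucose": f"{rng.uniform(60, 320):.0f}",
                }[tt]
                day = int(rng.integers(0, 1000))
                rows.append(
                    {"patient_id": pid, "test_type": tt, "value": value,
                     "collection_date": str((pd.Timestamp("2018-06-01")
                                             + pd.Timedelta(days=day)).date())}
                )
        kept, _ = filter_records(make_records(rows))
        bulk, _ = build_assessments(kept)
        for pid, group in kept.groupby("patient_id"):
            creats = group[group["test_type"] == "creatinine"]
            row = bulk[bulk["patient_id"] == pid]
            if len(creats) == 0:
                assert len(row) == 0
                continue
            index, _ = select_index_creatinine(group)
            got = row.iloc[0]
            assert got["index_date"] == index["collection_date"]
            pairing = pair_urinary(index, group)
            if pairing is None:
                assert not got["paired"]
            else:
                assert got["paired"]
                assert got["pacr"] == pytest.approx(pairing[0].value, rel=1e-12)
            assert got["diabetes"] == diabetes_flag(index, group)


class TestReadRecords:
    def test_malformed_date_cites_row(self, tmp_path):
        path = tmp_path / "r.csv"
        table = make_records([{}, {}]).drop(columns="record_id")
        table["collection_date"] = ["2019-06-01", "06/01/2019"]
        table.to_csv(path, index=False)
        with pytest.raises(MalformedRecordError, match="row 2"):
            read_records(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "r.csv"
        make_records([{}]).drop(columns=["record_id", "region"]).to_csv(path, index=False)
        with pytest.raises(MalformedRecordError, match="region"):
            read_records(path)

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "r.csv"
        make_records(TOY_TABLE).drop(columns="record_id").to_csv(path, index=False)
        df = read_records(path)
        assert len(df) == len(TOY_TABLE)
        assert "record_id" in df.columns
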