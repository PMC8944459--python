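"""Record building, normalization and deduplication."""

import numpy as np
import pandas as pd
import pytest

from fuzzyicu import (
    THERAPY_LABELS,
    build_domain,
    build_monitoring_records,
    build_therapy_records,
    consecutive_days,
    dedup,
    normalize_records,
)
from fuzzyicu.simulate import DEFAULT_DRUG_VOCABULARY, DEFAULT_MONITORING_SCHEMA


def _days(counts):
    return {ts.day: c for ts, c in counts.items()}


class TestConsecutiveDays:
    def test_single_day(self):
        assert _days(consecutive_days(["2020-01-03"])) == {3: 1}

    def test_run_resets_after_gap(self):
        # brute-force run-length scan over {1,2,3,5}
        counts = consecutive_days(["2020-01-01", "2020-01-02", "2020-01-03", "2020-01-05"])
        assert _days(counts) == {1: 1, 2: 2, 3: 3, 5: 1}

    def test_union_of_two_drugs(self):
        # drug A on {1,2}, drug B on {2,3}: the union {1,2,3} is one run
        union = ["2020-01-01", "2020-01-02", "2020-01-02", "2020-01-03"]
        assert _days(consecutive_days(union)) == {1: 1, 2: 2, 3: 3}

    def test_grace_bridges_short_gaps(self):
        counts = consecutive_days(["2020-01-01", "2020-01-03"], grace=1)
        assert _days(counts) == {1: 1, 3: 2}

    def test_counts_within_runs_start_at_one_and_increment(self):
        rng = np.random.default_rng(5)
        days = sorted(rng.choice(60, size=25, replace=False))
        dates = [pd.Timestamp("2020-01-01") + pd.Timedelta(days=int(d)) for d in days]
        counts = consecutive_days(dates)
        assert set(counts) == set(pd.DatetimeIndex(dates))
        prev_day, prev_count = None, None
        for d in sorted(counts):
            expected = prev_count + 1 if prev_day is not None and (d - prev_day).days == 1 else 1
            assert counts[d] == expected
            prev_day, prev_count = d, counts[d]


class TestBuildTherapyRecords:
    def test_single_administration(self):
        admins = pd.DataFrame({"patient_id": ["p1"], "drug": ["A"], "date": ["2020-01-01"]})
        rec = build_therapy_records(admins, ["A", "B"])
        assert len(rec) == 1
        row = rec.iloc[0]
        assert (row["overall_days"], row["A"], row["B"]) == (1, 1, 0)

    def test_overall_counts_on_union_of_drug_days(self, two_drug_admins):
        rec = build_therapy_records(two_drug_admins, ["A", "B"]).set_index("date")
        day2 = rec.loc[pd.Timestamp("2020-01-02")]
        assert (day2["overall_days"], day2["A"], day2["B"]) == (2, 2, 1)
        day3 = rec.loc[pd.Timestamp("2020-01-03")]
        assert (day3["overall_days"], day3["A"], day3["B"]) == (3, 0, 2)

    def test_full_vocabulary_gives_91_value_columns(self, two_drug_admins):
        admins = two_drug_admins.assign(drug=[DEFAULT_DRUG_VOCABULARY[0], DEFAULT_DRUG_VOCABULARY[0],
                                              DEFAULT_DRUG_VOCABULARY[1], DEFAULT_DRUG_VOCABULARY[1]])
        rec = build_therapy_records(admins, DEFAULT_DRUG_VOCABULARY)
        value_cols = [c for c in rec.columns if c not in ("patient_id", "date")]
        assert len(value_cols) == 91  # overall duration + 90 drugs

    def test_duplicate_rows_collapse(self):
        admins = pd.DataFrame({"patient_id": ["p1"] * 3, "drug": ["A"] * 3, "date": ["2020-01-01"] * 3})
        rec = build_therapy_records(admins, ["A"])
        assert len(rec) == 1 and rec.iloc[0]["A"] == 1

    def test_unknown_drug_listed_in_error(self, two_drug_admins):
        with pytest.raises(ValueError, match=r"unknown drug names: \['B'\]"):
            build_therapy_records(two_drug_admins, ["A"])


class TestBuildMonitoringRecords:
    def _readings(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "timestamp", "parameter", "value"])

    def test_within_hour_median(self):
        r = self._readings([
            ("p1", "2020-01-01T10:05", "heart_rate", 80.0),
            ("p1", "2020-01-01T10:45", "heart_rate", 90.0),
        ])
        rec = build_monitoring_records(r, ["heart_rate"])
        assert len(rec) == 1 and rec.iloc[0]["heart_rate"] == 85.0

    def test_within_hour_last(self):
        r = self._readings([
            ("p1", "2020-01-01T10:45", "heart_rate", 90.0),
            ("p1", "2020-01-01T10:05", "heart_rate", 80.0),
        ])
        rec = build_monitoring_records(r, ["heart_rate"], aggregator="last")
        assert rec.iloc[0]["heart_rate"] == 90.0

    def test_hours_without_readings_emit_no_record(self):
        r = self._readings([("p1", "2020-01-01T10:05", "heart_rate", 80.0)])
        rec = build_monitoring_records(r, ["heart_rate", "spo2"])
        assert rec["hour"].tolist() == [10]
        assert np.isnan(rec.iloc[0]["spo2"])

    def test_full_schema_gives_46_value_columns(self):
        schema = [p.name for p in DEFAULT_MONITORING_SCHEMA]
        r = self._readings([("p1", "2020-01-01T10:05", "heart_rate", 80.0)])
        rec = build_monitoring_records(r, schema)
        assert len([c for c in rec.columns if c not in ("patient_id", "date", "hour")]) == 46

    def test_unknown_parameter_rejected(self):
        r = self._readings([("p1", "2020-01-01T10:05", "blood_type", 0.0)])
        with pytest.raises(ValueError, match="unknown monitoring parameters"):
            build_monitoring_records(r, ["heart_rate"])


class TestNormalizeRecords:
    @pytest.fixture()
    def days_domain(self, therapy_days_domain):
        return therapy_days_domain

    def test_therapy_zeros_stay_absent(self, days_domain):
        rec = pd.DataFrame({"patient_id": ["p1"], "date": ["2020-01-01"], "overall_days": [1], "A": [0]})
        out = normalize_records(rec, {"overall_days": days_domain, "A": days_domain}, zero_is_absent=True)
        assert out.iloc[0]["overall_days"] > 0 and out.iloc[0]["A"] == 0

    def test_long_duration_maps_to_ultra_long(self, days_domain):
        rec = pd.DataFrame({"patient_id": ["p1"], "date": ["2020-01-01"], "overall_days": [25]})
        out = normalize_records(rec, {"overall_days": days_domain}, zero_is_absent=True)
        assert out.iloc[0]["overall_days"] == 5

    def test_monitoring_missing_and_peak(self):
        hr = build_domain(40, 140, 90, 5)
        rec = pd.DataFrame({
            "patient_id": ["p1"], "date": ["2020-01-01"], "hour": [10],
            "heart_rate": [90.0], "spo2": [np.nan],
        })
        out = normalize_records(rec, {"heart_rate": hr, "spo2": hr})
        assert out.iloc[0]["heart_rate"] == 3 and out.iloc[0]["spo2"] == 0

    def test_missing_domain_raises(self, days_domain):
        rec = pd.DataFrame({"patient_id": ["p1"], "date": ["2020-01-01"], "overall_days": [1], "A": [2]})
        with pytest.raises(ValueError, match="no fuzzy domain for columns: \\['A'\\]"):
            normalize_records(rec, {"overall_days": days_domain})


class TestDedup:
    def test_identical_patterns_collapse(self):
        ut = dedup(np.tile([1, 2, 3], (7, 1)))
        assert ut.n_unique == 1 and ut.multiplicity.tolist() == [7]

    def test_multiplicities_and_lexicographic_order(self):
        ut = dedup([(1, 2), (2, 1), (1, 2)])
        assert ut.patterns.tolist() == [[1, 2], [2, 1]]
        assert ut.multiplicity.tolist() == [2, 1]
        assert ut.record_ids.tolist() == [0, 1, 0]

    def test_uniques_never_exceed_records(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 6, size=(50, 3))
        ut = dedup(X)
        assert ut.n_unique <= ut.n_records == 50
        assert int(ut.multiplicity.sum()) == 50

    def test_expansion_reconstructs_the_multiset(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 6, size=(40, 4))
        assert np.array_equal(dedup(X).expand(), X)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 6, size=(60, 4))
        perm = rng.permutation(60)
        a, b = dedup(X), dedup(X[perm])
        assert np.array_equal(a.patterns, b.patterns)
        assert np.array_equal(a.multiplicity, b.multiplicity)
        assert np.array_equal(a.record_ids[perm], b.record_ids)

    def test_stored_uniques_are_pairwise_distinct(self):
        rng = np.random.default_rng(4)
        ut = dedup(rng.integers(0, 3, size=(80, 3)))
        U = ut.patterns
        dist = (U[:, None, :] != U[None, :, :]).sum(axis=2)
        assert np.all(dist[~np.eye(len(U), dtype=bool)] > 0)

    def test_dataframe_input_drops_id_columns(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "date": ["d", "d"], "x": [1, 1], "y": [2, 2]})
        ut = dedup(df)
        assert ut.columns == ("x", "y") and ut.n_unique == 1

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            dedup([[1, 2], [1, 2, 3]])


def test_normalize_then_dedup_commutes_with_row_order(therapy_days_domain):
    rng = np.random.default_rng(6)
    n = 30
    rec = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "date": ["2020-01-01"] * n,
        "overall_days": rng.integers(0, 30, n),
    })
    perm = rng.permutation(n)
    a = dedup(normalize_records(rec, {"overall_days": therapy_days_domain}, zero_is_absent=True))
    b = dedup(normalize_records(rec.iloc[perm].reset_index(drop=True),
                                {"overall_days": therapy_days_domain}, zero_is_absent=True))
    assert np.array_equal(a.patterns, b.patterns)
    assert np.array_equal(a.multiplicity, b.multiplicity)
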