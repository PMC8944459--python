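"""Fuzzy-domain construction: trimming, limit geometry, membership, fuzzification."""

import json

import numpy as np
import pytest

from fuzzyicu import (
    MONITORING_LABELS,
    FuzzyDomain,
    ParameterStats,
    build_domain,
    domain_from_observations,
    fuzzify,
    load_domains,
    membership,
    plot_domain,
    save_domains,
    trim_95,
)
from fuzzyicu.domains import LIMIT_NAMES, round_half_away


class TestTrim95:
    def test_constant_data_is_degenerate_with_full_coverage(self):
        t = trim_95([7.0] * 100, mode="central")
        assert (t.m, t.M, t.coverage, t.degenerate) == (7.0, 7.0, 1.0, True)

    def test_central_trim_cuts_at_observed_values(self):
        # exhaustive cumulative-frequency scan on 1..200: 2.5% reached at 5, 97.5% at 195
        t = trim_95(list(range(1, 201)), mode="central")
        assert (t.m, t.M) == (5.0, 195.0)
        assert t.coverage >= 0.95
        assert t.median_t == 100.0

    def test_upper_trim_keeps_the_value_reaching_the_threshold(self):
        # 4x each of 0..21, 8x 22, singletons above: F(21)=0.88 < 0.95 <= F(22)=0.96
        obs = [v for v in range(22) for _ in range(4)] + [22] * 8 + [25, 27, 29, 31]
        t = trim_95(obs, mode="upper")
        assert (t.m, t.M) == (0.0, 22.0)
        assert t.coverage == pytest.approx(0.96)
        assert all(t.m <= v <= t.M for v in t.value_frequencies)

    def test_retained_stats_recomputed_on_retained_values(self):
        t = trim_95(list(range(1, 201)), mode="central")
        retained = np.arange(5, 196)
        assert t.sd_t == pytest.approx(retained.std(ddof=1))
        assert sum(t.value_frequencies.values()) == retained.size

    def test_errors(self):
        with pytest.raises(ValueError, match="no observations"):
            trim_95([])
        with pytest.raises(ValueError, match="no observations"):
            trim_95([float("nan")])
        with pytest.raises(ValueError, match="trim mode"):
            trim_95([1, 2, 3], mode="sideways")


class TestBuildDomain:
    def test_published_therapy_days_limits(self, therapy_days_domain):
        printed = {
            "VLL": -1.8, "VLH": 3.6, "LL": 1.8, "LH": 9.1, "NL": 7.3,
            "NH": 14.6, "HL": 12.8, "HH": 20.2, "VHL": 18.3, "VHH": 23.8,
        }
        for name, expected in printed.items():
            assert getattr(therapy_days_domain, name) == pytest.approx(expected, abs=0.1)

    def test_symmetric_construction(self):
        d = build_domain(0, 6, 3, 0.5)
        assert (d.NL, d.NH, d.VLL, d.VHH) == (2.0, 4.0, -0.5, 6.5)
        # symmetric about the median: left and right limits mirror
        for left, right in (("VLL", "VHH"), ("LL", "HH"), ("VLH", "VHL"), ("NL", "NH"), ("LH", "HL")):
            assert getattr(d, left) - 3 == pytest.approx(3 - getattr(d, right))

    def test_asymmetric_example_matches_closed_forms(self):
        # independent re-evaluation of each closed-form limit for (10, 70, 30, 5)
        d = build_domain(10, 70, 30, 5)
        expected = (5.0, 15.0, 20.0, 20.0, 25.0, 35.0, 40.0, 60.0, 65.0, 75.0)
        assert tuple(getattr(d, n) for n in LIMIT_NAMES) == pytest.approx(expected)

    def test_overlap_widths_all_equal_h(self, therapy_days_domain):
        d = therapy_days_domain
        for a, b in ((d.LL, d.VLH), (d.NL, d.LH), (d.HL, d.NH), (d.VHL, d.HH)):
            assert b - a == pytest.approx(d.h, abs=1e-9)

    def test_medium_triangle_centered_on_median(self, therapy_days_domain):
        d = therapy_days_domain
        assert (d.NL + d.NH) / 2 == pytest.approx(d.median_t)

    def test_errors(self):
        with pytest.raises(ValueError, match="overlap too wide"):
            build_domain(0, 6, 3, 1.0)
        with pytest.raises(ValueError, match="degenerate range"):
            build_domain(5, 5, 5, 0.1)
        with pytest.raises(ValueError, match="not monotone"):
            build_domain(0, 60, 2, 5)  # median hugging the lower edge
        # clamping pulls the median into the valid interval instead
        d = build_domain(0, 60, 2, 5, clamp_median=True)
        assert d.VLH <= d.NL

    def test_json_round_trip(self, therapy_days_domain, tmp_path):
        save_domains({"overall_days": therapy_days_domain}, tmp_path / "d.json")
        loaded = load_domains(tmp_path / "d.json")["overall_days"]
        assert loaded == therapy_days_domain


class TestMembership:
    def test_beyond_upper_edge_is_fully_very_high(self, therapy_days_domain):
        mu = membership(therapy_days_domain, 25.0)
        assert mu[4] == 1.0

    def test_triangle_foot_at_ll(self, therapy_days_domain):
        mu = membership(therapy_days_domain, therapy_days_domain.LL)
        assert mu[0] == 1.0 and mu[1] == 0.0

    def test_median_peaks_the_medium_triangle(self, therapy_days_domain):
        mu = membership(therapy_days_domain, 11.0)
        assert mu.tolist() == [0.0, 0.0, 1.0, 0.0, 0.0]

    def test_nan_raises(self, therapy_days_domain):
        with pytest.raises(ValueError, match="non-finite"):
            membership(therapy_days_domain, float("nan"))


class TestFuzzify:
    def test_missing_maps_to_none_category(self, therapy_days_domain):
        assert fuzzify(therapy_days_domain, None) == 0
        assert fuzzify(therapy_days_domain, float("nan")) == 0

    def test_below_domain_clamps_to_f1(self, therapy_days_domain):
        assert fuzzify(therapy_days_domain, -5.0) == 1

    def test_overlap_resolved_by_dominant_membership(self, therapy_days_domain):
        # x = 2.4 lies in the F1/F2 overlap with mu1 ~ 0.67 > 0.5
        assert membership(therapy_days_domain, 2.4)[0] == pytest.approx(2 / 3)
        assert fuzzify(therapy_days_domain, 2.4) == 1

    def test_exact_tie_breaks_to_lower_category(self):
        # geometry where the F1 ramp and F2 upslope cross at exactly 0.5
        d = build_domain(0, 24, 8, 2)
        mu = membership(d, 3.0)
        assert mu[0] == mu[1] == 0.5
        assert fuzzify(d, 3.0) == 1

    def test_vectorized_matches_scalar(self, therapy_days_domain):
        xs = np.array([-5.0, 2.4, 11.0, np.nan, 25.0])
        out = fuzzify(therapy_days_domain, xs)
        assert out.tolist() == [1, 1, 3, 0, 5]


class TestDomainFromObservations:
    def test_half_sd_overlap_rule(self):
        rng = np.random.default_rng(3)
        values = rng.normal(80, 10, size=5000)
        d = domain_from_observations("heart_rate", values, mode="central")
        assert d.h == pytest.approx(d.sd_t / 2)
        assert d.labels == MONITORING_LABELS
        assert d.m <= d.median_t <= d.M

    def test_fixed_overlap_rule(self):
        d = domain_from_observations("x", list(range(100)), overlap_rule="fixed:2.0")
        assert d.h == 2.0

    def test_wide_sd_falls_back_to_range_twelfth(self):
        # bimodal: sd/2 exceeds range/6, so the builder substitutes range/12
        values = [0.0] * 50 + [10.0] * 50
        d = domain_from_observations("bimodal", values)
        assert d.h == pytest.approx((d.M - d.m) / 12)
        assert "range_twelfth" in d.overlap_rule

    def test_constant_parameter_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            domain_from_observations("flat", [4.2] * 50)


class TestPlotDomain:
    def test_renders_five_shapes_to_file(self, therapy_days_domain, tmp_path):
        out = tmp_path / "domain.png"
        plot_domain(therapy_days_domain, out)
        assert out.stat().st_size > 0

    def test_shapes_integrate_to_positive_area(self, therapy_days_domain):
        xs = np.linspace(therapy_days_domain.VLL, therapy_days_domain.VHH, 2000)
        mu = membership(therapy_days_domain, xs)
        areas = np.trapezoid(mu, xs, axis=0)
        assert np.all(areas > 0)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            plot_domain("not a domain")


def test_parameter_stats_from_values():
    s = ParameterStats.from_values("days", [1, 2, 3, 4, 100, float("nan")])
    assert (s.n_obs, s.minimum, s.maximum, s.median) == (5, 1.0, 100.0, 3.0)
    assert s.minimum <= s.median <= s.maximum
    with pytest.raises(ValueError, match="no observations"):
        ParameterStats.from_values("empty", [])


def test_report_rounding_is_half_away_from_zero():
    assert round_half_away(14.65) == 14.7
    assert round_half_away(-14.65) == -14.7
    assert round_half_away(20.175, 1) == 20.2
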