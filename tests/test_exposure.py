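"""Unit conversions, distribution shifting, and population impact fractions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pamslt.exposure import (
    ExposureDistribution,
    ExposureError,
    LagSpec,
    RelativeRiskFunction,
    compute_pif,
    lag_pif_series,
    met_minutes_to_activity_hours,
    shift_distribution,
    steps_to_met_minutes,
)


def make_dist(proportions, lowers=None):
    """Small helper: distribution over equal-width bins with given masses."""
    p = np.asarray(proportions, dtype=float)
    n = p.size
    lo = np.arange(n) * 600.0 if lowers is None else np.asarray(lowers, dtype=float)
    hi = np.append(lo[1:], lo[-1] + 600.0)
    mid = (lo + hi) / 2.0
    return ExposureDistribution(lo, hi, mid, p)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "steps, conv, expected",
        [(1404.0, 34.5, 285), (0.0, 34.5, 0), (34.5, 34.5, 7)],
    )
    def test_steps_to_met_minutes(self, steps, conv, expected):
        assert round(steps_to_met_minutes(steps, conv)) == expected

    @pytest.mark.parametrize(
        "met_min, met, expected",
        [(285.0, 3.0, 1.6), (285.0, 4.5, 1.1), (0.0, 3.0, 0.0)],
    )
    def test_met_minutes_to_walking_hours(self, met_min, met, expected):
        assert round(met_minutes_to_activity_hours(met_min, met), 1) == expected

    def test_invalid_conversion_factors_rejected(self):
        with pytest.raises(ValueError):
            steps_to_met_minutes(100.0, 0.0)
        with pytest.raises(ValueError):
            met_minutes_to_activity_hours(100.0, -3.0)
        with pytest.raises(ValueError):
            steps_to_met_minutes(-1.0)


class TestShiftDistribution:
    def test_zero_fraction_is_identity(self):
        dist = make_dist([0.25, 0.25, 0.5])
        out = shift_distribution(dist, 500.0, 0.0)
        np.testing.assert_array_equal(out.proportion, dist.proportion)

    def test_huge_delta_full_fraction_fills_top_bin(self):
        dist = make_dist([0.2, 0.3, 0.5])
        out = shift_distribution(dist, 1e6, 1.0)
        assert out.proportion[-1] == pytest.approx(1.0)
        assert np.all(out.proportion[:-1] == 0.0)

    def test_two_bin_hand_reallocation(self):
        # masses 0.6 at midpoint 0 and 0.4 at 600; shifting half the
        # population by 600 moves 0.3 from the low bin into the high bin
        dist = ExposureDistribution([0.0, 600.0], [600.0, 1200.0], [0.0, 600.0], [0.6, 0.4])
        out = shift_distribution(dist, 600.0, 0.5)
        np.testing.assert_allclose(out.proportion, [0.3, 0.7], atol=1e-15)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            shift_distribution(make_dist([1.0]), -5.0, 0.5)

    @given(
        raw=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        delta=st.floats(0.0, 5000.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_mass_conserved_and_mean_monotone(self, raw, delta, frac):
        p = np.array(raw) / sum(raw)
        dist = make_dist(p)
        out = shift_distribution(dist, delta, frac)
        assert abs(out.proportion.sum() - 1.0) < 1e-12
        # a larger shift never decreases mean exposure
        out2 = shift_distribution(dist, delta * 2.0, frac)
        assert out2.mean() >= out.mean() - 1e-9


class TestComputePif:
    def test_identity_counterfactual_is_zero(self):
        dist = make_dist([0.3, 0.3, 0.4])
        rr = RelativeRiskFunction("chd", 3e-4)
        assert compute_pif(dist, dist, rr) == 0.0

    def test_hand_computed_two_bin_pif(self):
        # RR = (1.0, 0.5), BAU (0.5, 0.5), counterfactual (0, 1):
        # (0.75 - 0.5) / 0.75 = 1/3
        rr = RelativeRiskFunction("toy", math.log(2.0) / 600.0, floor=0.5)
        bau = ExposureDistribution([0, 600], [600, 1200], [0.0, 600.0], [0.5, 0.5])
        cf = bau.replace_proportions([0.0, 1.0])
        assert compute_pif(bau, cf, rr) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_null_relative_risk_gives_zero(self):
        rr = RelativeRiskFunction("null", 0.0)
        bau = make_dist([0.5, 0.5])
        cf = bau.replace_proportions([0.1, 0.9])
        assert compute_pif(bau, cf, rr) == 0.0

    def test_mismatched_bins_rejected(self):
        rr = RelativeRiskFunction("chd", 3e-4)
        with pytest.raises(ExposureError):
            compute_pif(make_dist([0.5, 0.5]), make_dist([0.3, 0.3, 0.4]), rr)

    @given(
        raw_p=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
        raw_q=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
        slope=st.floats(0.0, 1e-3),
    )
    def test_matches_brute_force_expected_risk_sum(self, raw_p, raw_q, slope):
        n = min(len(raw_p), len(raw_q))
        p = np.array(raw_p[:n]) / sum(raw_p[:n])
        q = np.array(raw_q[:n]) / sum(raw_q[:n])
        bau = make_dist(p)
        cf = bau.replace_proportions(q)
        rr = RelativeRiskFunction("x", slope)
        # independent brute-force oracle: explicit python-loop expected risk
        risk_bau = sum(p[i] * float(rr(bau.midpoint[i])) for i in range(n))
        risk_cf = sum(q[i] * float(rr(bau.midpoint[i])) for i in range(n))
        expected = (risk_bau - risk_cf) / risk_bau
        assert compute_pif(bau, cf, rr) == pytest.approx(expected, abs=1e-12)


class TestLagPifSeries:
    def test_constant_series_returns_constant(self):
        lag = LagSpec("chd", 0, 5)
        series = [0.2] * 40
        assert lag_pif_series(series, lag, 20) == pytest.approx(0.2, abs=1e-15)

    def test_pulse_averaged_over_six_offsets(self):
        lag = LagSpec("chd", 0, 5)
        series = [0.12] + [0.0] * 30
        assert lag_pif_series(series, lag, 2) == pytest.approx(0.12 / 6.0, abs=1e-15)

    def test_pulse_outside_cancer_window_is_zero(self):
        lag = LagSpec("colorectal_cancer", 10, 30)
        series = [0.5] + [0.0] * 40
        assert lag_pif_series(series, lag, 5) == 0.0
        assert lag_pif_series(series, lag, 10) == pytest.approx(0.5 / 21.0)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            lag_pif_series([0.1], LagSpec("chd", 0, 5), -1)


class TestRelativeRiskFunction:
    def test_anchored_at_one_and_monotone(self):
        rr = RelativeRiskFunction("chd", 2.8e-4)
        e = np.array([0.0, 75.0, 225.0, 450.0, 900.0, 6000.0])
        vals = rr(e)
        assert vals[0] == 1.0
        assert np.all(np.diff(vals) <= 0)
        assert np.all(vals >= rr.floor)

    def test_degenerate_single_bin_distribution(self):
        dist = ExposureDistribution([0.0], [600.0], [300.0], [1.0])
        assert dist.mean() == 300.0
        assert dist.fraction_below(700.0) == 1.0
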