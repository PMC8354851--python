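"""Height velocity pairing, binning, milestones and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from achondro.curves import AgeWindowScheme, PercentileCurve, velocity_window_scheme
from achondro.reference import ReferenceCurve
from achondro.velocity import (
    VelocityCurve, attainment_age, crossing_age, mean_velocity_curve,
    pairwise_velocities, smooth_velocity_curve, velocity_threshold_age,
    velocity_zero_age,
)


def _stature(ages, values, sid="A"):
    return pd.DataFrame({
        "subject_id": sid, "measure": "length_height", "age_months": ages,
        "value": values, "position": "unknown", "qc_flags": "ok",
    })


def _oracle_pairs(ages, values, min_gap=6.0, max_gap=18.0):
    """Independent enumeration of the greedy non-overlapping pairing rule."""
    order = np.argsort(ages, kind="stable")
    a = np.asarray(ages)[order]
    v = np.asarray(values)[order]
    out, i = [], 0
    while i < len(a) - 1:
        partner = None
        for j in range(i + 1, len(a)):
            gap = a[j] - a[i]
            if gap > max_gap:
                break
            if gap >= min_gap:
                partner = j
                break
        if partner is None:
            i += 1
            continue
        gap = a[partner] - a[i]
        out.append(((a[i] + a[partner]) / 2.0, (v[partner] - v[i]) / gap * 12.0, gap))
        i = partner
    return out


class TestPairwiseVelocities:
    def test_simple_pair(self):
        est = pairwise_velocities(_stature([24.0, 36.0], [80.0, 86.0]))
        assert len(est) == 1
        row = est.iloc[0]
        assert row["velocity"] == pytest.approx(6.0)
        assert row["midpoint_age"] == pytest.approx(30.0)
        assert row["interval_length"] == pytest.approx(12.0)

    def test_short_gap_produces_nothing(self):
        est = pairwise_velocities(_stature([24.0, 28.0], [80.0, 82.0]))
        assert len(est) == 0

    def test_long_gap_produces_nothing(self):
        est = pairwise_velocities(_stature([24.0, 48.0], [80.0, 90.0]))
        assert len(est) == 0

    def test_single_point_empty(self):
        assert len(pairwise_velocities(_stature([24.0], [80.0]))) == 0

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        ages = np.sort(rng.uniform(0, 120, size=n))
        values = 50 + ages * 0.5 + rng.normal(0, 1, n)
        est = pairwise_velocities(_stature(ages, values))
        oracle = _oracle_pairs(ages, values)
        assert len(est) == len(oracle)
        for row, (mid, vel, gap) in zip(est.itertuples(), oracle):
            assert row.midpoint_age == pytest.approx(mid)
            assert row.velocity == pytest.approx(vel)
            assert row.interval_length == pytest.approx(gap)
            assert 6.0 <= row.interval_length <= 18.0

    def test_linear_trajectory_recovers_slope_at_midpoints(self):
        ages = np.arange(0.0, 120.0, 7.0)
        values = 47.0 + 0.5 * ages  # 6 cm/year
        est = pairwise_velocities(_stature(ages, values))
        assert len(est) > 0
        np.testing.assert_allclose(est["velocity"], 6.0, atol=1e-9)
        mids = (ages[:-1] + ages[1:]) / 2.0
        assert set(np.round(est["midpoint_age"], 6)) <= set(np.round(mids, 6))


class TestMeanVelocityCurve:
    def test_flat_curve(self):
        frames = [_stature(np.arange(0, 217, 8.0), 47 + 0.5 * np.arange(0, 217, 8.0), sid=f"S{k}")
                  for k in range(25)]
        est = pairwise_velocities(pd.concat(frames))
        vc = mean_velocity_curve(est, "male", min_n=20)
        m = vc.estimable
        assert m.any()
        np.testing.assert_allclose(vc.mean_velocity[m], 6.0, atol=1e-9)

    def test_min_n_suppression(self):
        est = pairwise_velocities(_stature([24.0, 36.0], [80.0, 86.0]))
        vc = mean_velocity_curve(est, "male", min_n=20)
        assert not vc.estimable.any()


class TestThresholdAges:
    def _linear_curve(self):
        ages = np.arange(0.0, 121.0, 6.0)  # months; velocity in years: 10 - t
        v = 10.0 - ages / 12.0
        return VelocityCurve("male", ages, v, np.full(len(ages), 100))

    def test_linear_threshold_closed_form(self):
        vc = self._linear_curve()
        assert velocity_threshold_age(vc, 1.0) == pytest.approx(9.0, abs=1e-9)
        assert velocity_threshold_age(vc, 0.0) == pytest.approx(10.0, abs=1e-9)

    def test_curve_above_threshold_returns_none(self):
        vc = self._linear_curve()
        assert velocity_threshold_age(vc, -5.0) is None

    def test_crossing_only_after_maximum(self):
        # rises through 2.0 in infancy, peaks, then declines through 2.0
        ages = np.array([0.0, 6.0, 12.0, 24.0, 48.0, 96.0])
        v = np.array([1.0, 3.0, 4.0, 3.0, 2.5, 1.0])
        vc = VelocityCurve("male", ages, v, np.full(6, 100))
        got = velocity_threshold_age(vc, 2.0)
        # linear interp between 48 (2.5) and 96 (1.0): 48 + 16 = 64 months
        assert got == pytest.approx(64.0 / 12.0, abs=1e-9)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            velocity_threshold_age(self._linear_curve(), float("nan"))

    def test_threshold_ordering_monotone(self):
        vc = self._linear_curve()
        assert velocity_threshold_age(vc, 1.0) <= velocity_threshold_age(vc, 0.0)

    def test_zero_age_linear_limb_exact(self):
        vc = self._linear_curve()
        assert velocity_zero_age(vc, fit_range=(0.3, 2.0)) == pytest.approx(10.0, abs=1e-9)

    def test_smoothing_preserves_linear_curve(self):
        vc = self._linear_curve()
        sm = smooth_velocity_curve(vc, lam=0.0)
        np.testing.assert_allclose(sm.mean_velocity, vc.mean_velocity, atol=1e-8)


def _cohort_p95_curve(f):
    ages = np.arange(0.0, 37.0, 1.0)
    vals = f(ages)
    return PercentileCurve("male", "length_height", ages, vals - 2, vals - 1, vals,
                           np.full(len(ages), 100))


def _pct_reference(f5):
    ages = np.arange(0.0, 37.0, 1.0)
    rows = [{"sex": "male", "measure": "length_height", "age_months": a, "kind": "pct",
             "L": np.nan, "M": np.nan, "S": np.nan,
             "p5": f5(a), "p50": f5(a) + 5, "p95": f5(a) + 10} for a in ages]
    return ReferenceCurve(pd.DataFrame(rows))


class TestCrossingAge:
    def test_cohort_already_below_at_birth(self):
        cohort = _cohort_p95_curve(lambda t: 50 + 0.2 * t)
        ref = _pct_reference(lambda t: 52 + 0.5 * t)
        assert crossing_age(cohort, ref, "male") == pytest.approx(0.0, abs=1e-9)

    def test_analytic_intersection(self):
        cohort = _cohort_p95_curve(lambda t: 53 - 0.1 * t)
        ref = _pct_reference(lambda t: 52 + 0.2 * t)
        got = crossing_age(cohort, ref, "male")
        assert got == pytest.approx(10.0 / 3.0, abs=1e-6)

    def test_never_below_returns_none(self):
        cohort = _cohort_p95_curve(lambda t: 60 + 0.5 * t)
        ref = _pct_reference(lambda t: 40 + 0.1 * t)
        assert crossing_age(cohort, ref, "male") is None


class TestAttainmentAge:
    def _exp_curve(self, k=0.11, scale=52.0):
        ages = np.arange(0.0, 61.0, 0.5)
        p50 = scale * (1 - np.exp(-k * ages))
        return PercentileCurve("male", "ofc", ages, p50 - 1, p50, p50 + 1,
                               np.full(len(ages), 100))

    def test_piecewise_linear_closed_form(self):
        """On a ramp-to-plateau curve the attainment age is exact."""
        ages = np.arange(0.0, 61.0, 1.0)
        p50 = np.minimum(ages, 30.0)
        c = PercentileCurve("male", "ofc", ages, p50 - 1, p50, p50 + 1,
                            np.full(len(ages), 100))
        # plateau (mean over final year) = 30, target = 27, reached at 27 months
        assert attainment_age(c, fraction=0.90) == pytest.approx(27.0, abs=1e-9)

    def test_saturating_exponential_near_closed_form(self):
        k = 0.11
        c = self._exp_curve(k=k)
        got = attainment_age(c, fraction=0.90)
        # solve 52(1-e^{-kt}) = 0.9*plateau analytically; the half-month
        # evaluation grid bounds the interpolation error
        m = c.estimable
        tail = c.grid_ages[m] >= c.grid_ages[m][-1] - 12.0
        plateau = c.p50[m][tail].mean()
        expected = -np.log(1 - 0.9 * plateau / 52.0) / k
        assert got == pytest.approx(expected, abs=0.01)

    def test_constant_curve_attains_at_zero(self):
        ages = np.arange(0.0, 61.0, 1.0)
        c = PercentileCurve("male", "ofc", ages, np.full(61, 44.0), np.full(61, 45.0),
                            np.full(61, 46.0), np.full(61, 100))
        assert attainment_age(c, fraction=0.90) == 0.0

    def test_unreachable_fraction_rejected(self):
        c = self._exp_curve()
        with pytest.raises(ValueError):
            attainment_age(c, fraction=1.5)
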