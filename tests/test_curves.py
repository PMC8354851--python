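"""Windowed empirical percentiles, spline smoothing, birth statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from achondro.curves import (
    AgeWindowScheme, birth_stats, empirical_percentiles, smooth_isopleths,
    spline_weight_percentiles, window_for_age,
)
from achondro.reference import (
    ReferenceCurve, ReferenceError, evaluate_reference,
    make_average_stature_reference, read_reference, write_reference,
)


def _pts(ages, values, measure="length_height"):
    return pd.DataFrame({
        "subject_id": "A", "measure": measure, "age_months": ages,
        "value": values, "position": "unknown", "qc_flags": "ok",
    })


class TestWindows:
    @pytest.mark.parametrize("age,expected", [
        (6.0, (5.5, 6.5)),
        (24.0, (23.0, 25.0)),
        (150.0, (144.0, 156.0)),
        (12.0, (11.5, 12.5)),   # 12 belongs to the closed first band
        (36.0, (35.0, 37.0)),
        (120.0, (117.0, 123.0)),
        (0.0, (0.0, 0.5)),      # truncated at birth
    ])
    def test_window_examples(self, age, expected):
        assert window_for_age(age, AgeWindowScheme()) == expected

    def test_age_outside_range_rejected(self):
        with pytest.raises(ValueError):
            window_for_age(250.0, AgeWindowScheme())

    @given(st.floats(min_value=0.0, max_value=216.0, allow_nan=False))
    def test_every_age_maps_to_exactly_one_band(self, age):
        scheme = AgeWindowScheme()
        hits = [i for i, (l, h, _) in enumerate(scheme.bands)
                if ((l <= age <= h) if i == 0 else (l < age <= h))]
        assert len(hits) == 1

    def test_bands_must_be_contiguous(self):
        with pytest.raises(ValueError):
            AgeWindowScheme(bands=((0.0, 12.0, 0.5), (24.0, 36.0, 1.0)))


def _oracle_quantile(values, p):
    """Independent rank-interpolation quantile: rank 1 + (n-1)p."""
    v = sorted(values)
    rank = 1 + (len(v) - 1) * p
    lo = int(np.floor(rank)) - 1
    frac = rank - np.floor(rank)
    if lo + 1 >= len(v):
        return v[-1]
    return v[lo] + frac * (v[lo + 1] - v[lo])


class TestEmpiricalPercentiles:
    def test_constant_window(self):
        pts = _pts(np.full(30, 6.2), np.full(30, 50.0))
        c = empirical_percentiles(pts, "male", "length_height", min_n=20)
        i = list(c.grid_ages).index(6.0)
        assert c.p5[i] == c.p50[i] == c.p95[i] == 50.0

    def test_uniform_0_to_100(self):
        pts = _pts(np.full(101, 6.0), np.arange(101.0))
        c = empirical_percentiles(pts, "male", "length_height", min_n=20)
        i = list(c.grid_ages).index(6.0)
        assert (c.p5[i], c.p50[i], c.p95[i]) == (5.0, 50.0, 95.0)

    def test_min_n_yields_gap(self):
        pts = _pts(np.full(10, 6.2), np.full(10, 50.0))
        c = empirical_percentiles(pts, "male", "length_height", min_n=20)
        i = list(c.grid_ages).index(6.0)
        assert np.isnan(c.p50[i]) and c.n_per_window[i] == 10

    def test_empty_input_empty_curve(self):
        c = empirical_percentiles(_pts([], []), "male", "length_height")
        assert not c.estimable.any()

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 120)
        ages = rng.uniform(5.6, 6.4, size=n)
        values = rng.lognormal(mean=4.0, sigma=0.3, size=n)
        c = empirical_percentiles(_pts(ages, values), "male", "length_height", min_n=20)
        i = list(c.grid_ages).index(6.0)
        for lvl, got in ((0.05, c.p5[i]), (0.50, c.p50[i]), (0.95, c.p95[i])):
            assert got == pytest.approx(_oracle_quantile(values, lvl), rel=1e-12)


class TestSmoothIsopleths:
    def _smooth_curve(self):
        rng = np.random.default_rng(0)
        ages = np.repeat(np.arange(0.0, 217.0, 1.0), 30)
        values = 47.0 + 0.4 * ages + rng.normal(0, 1e-9, len(ages))
        return empirical_percentiles(_pts(ages, values), "male", "length_height", min_n=20)

    def test_zero_penalty_interpolates(self):
        emp = self._smooth_curve()
        sm = smooth_isopleths(emp, lam=0.0)
        m = emp.estimable
        np.testing.assert_allclose(sm.p50[m], emp.p50[m], atol=1e-6)

    def test_non_crossing_enforced(self):
        emp = self._smooth_curve()
        # corrupt one age so p5 > p95 before smoothing
        i = 30
        emp.p5[i], emp.p95[i] = emp.p95[i] + 5.0, emp.p5[i] - 5.0
        sm = smooth_isopleths(emp, lam=0.0)
        m = sm.estimable
        assert (sm.p5[m] <= sm.p50[m] + 1e-9).all()
        assert (sm.p50[m] <= sm.p95[m] + 1e-9).all()

    def test_too_few_ages_rejected(self):
        pts = _pts(np.full(30, 6.2), np.full(30, 50.0))
        emp = empirical_percentiles(pts, "male", "length_height", min_n=20)
        with pytest.raises(ValueError):
            smooth_isopleths(emp)


class TestWeightSplines:
    def _weight_points(self, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ages = np.repeat(np.arange(0.0, 217.0, 1.0), 40)
        median = 3.4 * np.exp(0.012 * ages)
        values = median * np.exp(rng.normal(0, sigma, len(ages)))
        return _pts(ages, values, measure="weight"), median

    def test_constant_weights_flat(self):
        pts, _ = self._weight_points()
        pts["value"] = 10.0
        c = spline_weight_percentiles(pts, "male")
        m = c.estimable
        np.testing.assert_allclose(c.p50[m], 10.0, rtol=1e-6)

    def test_noiseless_lognormal_median_within_1pct(self):
        pts, _ = self._weight_points(sigma=0.0)
        c = spline_weight_percentiles(pts, "male")
        # the final grid age has a one-sided (truncated) window and is
        # biased toward younger ages by construction; assert on interior
        m = c.estimable & (c.grid_ages < 210.0)
        truth = 3.4 * np.exp(0.012 * c.grid_ages[m])
        assert np.max(np.abs(c.p50[m] / truth - 1.0)) < 0.01

    def test_segments_and_composite_continuous(self):
        pts, _ = self._weight_points(sigma=0.05, seed=3)
        left = spline_weight_percentiles(pts, "male", segment="birth_to_3y")
        right = spline_weight_percentiles(pts, "male", segment="three_to_18y")
        comp = spline_weight_percentiles(pts, "male")
        i = list(comp.grid_ages).index(36.0)
        assert abs(left.p50[i] - right.p50[i]) < 0.5   # seam gap small
        assert comp.metadata["seam_gap"] < 0.5
        # composite is the cross-fade at the seam
        assert comp.p50[i] == pytest.approx((left.p50[i] + right.p50[i]) / 2.0, rel=1e-9)

    def test_sparse_segment_rejected(self):
        pts = _pts(np.full(40, 6.0), np.full(40, 6.5), measure="weight")
        with pytest.raises(ValueError):
            spline_weight_percentiles(pts, "male")


class TestBirthStats:
    def _ref(self):
        return make_average_stature_reference()

    def test_degenerate_values(self):
        pts = _pts(np.zeros(25), np.full(25, 47.0))
        bs = birth_stats(pts, "female", "length_height", self._ref())
        assert bs.ci_low == bs.ci_high == bs.mean == 47.0
        assert bs.reference_mean == pytest.approx(49.1)
        assert bs.significantly_different

    def test_ci_formula(self, rng):
        vals = rng.normal(47.28, 2.85, size=400)
        pts = _pts(np.zeros(400), vals)
        bs = birth_stats(pts, "female", "length_height", self._ref())
        half = 1.96 * bs.sd / np.sqrt(bs.n)
        assert bs.ci_low == pytest.approx(bs.mean - half)
        assert bs.ci_high == pytest.approx(bs.mean + half)
        assert bs.significantly_different  # 49.1 far outside CI

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            birth_stats(_pts([0.0], [47.0]), "female", "length_height", self._ref())

    def test_mean_recovery_replicates(self, rng):
        """Estimated birth mean falls within 3 SD/sqrt(n) in >=99% of draws."""
        n, reps, hits = 500, 200, 0
        for _ in range(reps):
            vals = rng.normal(47.28, 2.85, size=n)
            hits += abs(vals.mean() - 47.28) < 3 * 2.85 / np.sqrt(n)
        assert hits / reps >= 0.99


class TestReference:
    def test_lms_identity_at_median(self):
        t = pd.DataFrame([{"sex": "male", "measure": "length_height", "age_months": 0.0,
                           "kind": "lms", "L": 1.0, "M": 50.0, "S": 0.02,
                           "p5": np.nan, "p50": np.nan, "p95": np.nan}])
        ref = ReferenceCurve(t)
        assert evaluate_reference(ref, "male", "length_height", 0.0, 50) == pytest.approx(50.0)

    def test_lms_p95_closed_form(self):
        t = pd.DataFrame([{"sex": "male", "measure": "length_height", "age_months": 0.0,
                           "kind": "lms", "L": 1.0, "M": 50.0, "S": 0.02,
                           "p5": np.nan, "p50": np.nan, "p95": np.nan}])
        ref = ReferenceCurve(t)
        got = evaluate_reference(ref, "male", "length_height", 0.0, 95)
        assert got == pytest.approx(50.0 * (1 + 0.02 * 1.6449), abs=2e-3)

    def test_direct_percentile_interpolation(self):
        rows = [{"sex": "f", "measure": "weight", "age_months": a, "kind": "pct",
                 "L": np.nan, "M": np.nan, "S": np.nan, "p5": p50 - 2, "p50": p50, "p95": p50 + 2}
                for a, p50 in ((120.0, 70.0), (144.0, 74.0))]
        ref = ReferenceCurve(pd.DataFrame(rows))
        assert evaluate_reference(ref, "f", "weight", 132.0, 50) == pytest.approx(72.0)

    def test_age_outside_table_rejected(self):
        ref = make_average_stature_reference()
        with pytest.raises(ReferenceError):
            evaluate_reference(ref, "male", "ofc", 100.0, 50)

    def test_reference_roundtrip(self, tmp_path):
        ref = make_average_stature_reference()
        p = write_reference(ref, tmp_path / "reference.csv")
        back = read_reference(p)
        pd.testing.assert_frame_equal(back.table, ref.table, check_dtype=False)

    def test_bundled_reference_birth_moments(self):
        ref = make_average_stature_reference()
        assert evaluate_reference(ref, "male", "length_height", 0.0, 50) == pytest.approx(49.9)
        assert evaluate_reference(ref, "female", "ofc", 0.0, 50) == pytest.approx(33.9)
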