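"""Sex-specific growth percentile curves by windowed empirical quantiles.

Curve construction is a two-step procedure. First, empirical 5th, 50th and
95th percentiles are computed at each grid age from all values whose age
falls inside an age-dependent window (+-0.5 months up to 12 months, +-1
month to 36 months, +-3 months to 120 months, +-6 months to 216 months);
repeated measures are pooled regardless of subject. Second, each
percentile series is smoothed: penalized smoothing splines (penalty by
generalized cross-validation) through the empirical isopleths for stature
and head circumference, and separate penalized splines for weight on
birth-3 years and 3-18 years (weight skewness grows with age), blended
across a +-3-month seam at 36 months. Non-crossing of the smoothed
percentile levels is enforced by a post-hoc isotonic (sorting) adjustment.

Quantile definition: linear interpolation of order statistics at rank
``1 + (n-1)p`` (numpy's ``method="linear"``). Grid ages whose window holds
fewer than ``min_n`` values yield gaps, not estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from achondro.reference import ReferenceCurve, evaluate_reference

PERCENTILE_LEVELS = (5, 50, 95)


@dataclasses.dataclass
class AgeWindowScheme:
    """Age bands (lo, hi, half-width), all in months, partitioning the grid.

    The first band is closed ``[lo, hi]``; subsequent bands are half-open
    ``(lo, hi]``, matching the ">12 to 36 months" phrasing. The default
    evaluation grid is monthly to 36 months, quarterly to 120 months and
    semiannual to 216 months, so adjacent windows overlap at most 50%.
    """

    bands: tuple = ((0.0, 12.0, 0.5), (12.0, 36.0, 1.0), (36.0, 120.0, 3.0), (120.0, 216.0, 6.0))
    grid: tuple = None

    def __post_init__(self):
        for (l0, h0, w0), (l1, h1, w1) in zip(self.bands, self.bands[1:]):
            if h0 != l1:
                raise ValueError("bands must be contiguous")
        if any(w <= 0 for _, _, w in self.bands):
            raise ValueError("half-widths must be positive")
        if self.grid is None:
            self.grid = tuple(self.default_grid())
        self.grid = tuple(float(g) for g in self.grid)

    @property
    def age_range(self):
        return self.bands[0][0], self.bands[-1][1]

    def default_grid(self):
        lo, hi = self.age_range
        grid = list(np.arange(lo, min(36.0, hi) + 1e-9, 1.0))
        if hi > 36.0:
            grid += list(np.arange(39.0, min(120.0, hi) + 1e-9, 3.0))
        if hi > 120.0:
            grid += list(np.arange(126.0, hi + 1e-9, 6.0))
        return [g for g in grid if lo <= g <= hi]

    def half_width(self, age: float) -> float:
        lo, hi = self.age_range
        if not (lo <= age <= hi):
            raise ValueError(f"age {age} outside scheme range [{lo}, {hi}] months")
        for i, (l, h, w) in enumerate(self.bands):
            if (l <= age <= h) if i == 0 else (l < age <= h):
                return w
        raise ValueError(f"age {age} not covered by any band")

    def window_for_age(self, age: float) -> tuple:
        """Closed window [lo, hi] centered at ``age``, truncated at 0."""
        w = self.half_width(age)
        return max(age - w, 0.0), age + w

    def truncated(self, max_age_months: float) -> "AgeWindowScheme":
        bands = []
        for l, h, w in self.bands:
            if l >= max_age_months:
                break
            bands.append((l, min(h, max_age_months), w))
        grid = tuple(g for g in self.grid if g <= max_age_months)
        return AgeWindowScheme(bands=tuple(bands), grid=grid)


def window_for_age(age: float, scheme: AgeWindowScheme) -> tuple:
    return scheme.window_for_age(age)


def velocity_window_scheme() -> AgeWindowScheme:
    """Window scheme extended to 21 years for velocity binning, so the
    late-adolescent decline (zero velocity past 18 years) stays on-grid."""
    return AgeWindowScheme(
        bands=((0.0, 12.0, 0.5), (12.0, 36.0, 1.0), (36.0, 120.0, 3.0), (120.0, 252.0, 6.0)),
        grid=tuple(list(np.arange(0.0, 36.0 + 1e-9, 1.0))
                   + list(np.arange(39.0, 120.0 + 1e-9, 3.0))
                   + list(np.arange(126.0, 252.0 + 1e-9, 6.0))),
    )


@dataclasses.dataclass
class PercentileCurve:
    """P5/P50/P95 isopleths on an age grid (NaN where not estimable)."""

    sex: str
    measure: str
    grid_ages: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    n_per_window: np.ndarray
    method: str = "empirical"
    spline_segment: str = "not_applicable"
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.grid_ages = np.asarray(self.grid_ages, float)
        for name in ("p5", "p50", "p95"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.grid_ages.shape:
                raise ValueError(f"{name} must match grid length")
            setattr(self, name, arr)
        self.n_per_window = np.asarray(self.n_per_window, int)

    def level(self, percentile: int) -> np.ndarray:
        return {5: self.p5, 50: self.p50, 95: self.p95}[int(percentile)]

    @property
    def estimable(self) -> np.ndarray:
        return ~np.isnan(self.p50)

    def interp(self, percentile: int, ages) -> np.ndarray:
        """Linear interpolation of a level over the estimable grid."""
        m = self.estimable
        if m.sum() < 2:
            raise ValueError("curve has fewer than two estimable grid ages")
        x, y = self.grid_ages[m], self.level(percentile)[m]
        ages = np.asarray(ages, float)
        if (ages < x[0] - 1e-9).any() or (ages > x[-1] + 1e-9).any():
            raise ValueError("requested ages outside the estimable range")
        return np.interp(ages, x, y)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sex": self.sex, "measure": self.measure,
            "age_months": self.grid_ages, "n": self.n_per_window,
            "p5": self.p5, "p50": self.p50, "p95": self.p95,
            "method": self.method, "spline_segment": self.spline_segment,
        })


@dataclasses.dataclass
class BirthStats:
    """Sex-specific birth mean, SD and 95% CI, against a reference mean."""

    sex: str
    measure: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    reference_mean: float
    significantly_different: bool


def empirical_percentiles(points: pd.DataFrame, sex: str, measure: str,
                          scheme: AgeWindowScheme = None, min_n: int = 20) -> PercentileCurve:
    """Windowed empirical P5/P50/P95 for one sex and measure.

    ``points`` must already be cleaned, exclusion-applied and restricted to
    subjects of the given sex; rows of other measures are ignored. At each
    grid age, every value whose age falls in the closed window is pooled
    and order-statistic quantiles with linear interpolation are taken;
    windows with fewer than ``min_n`` values yield NaN.
    """
    if scheme is None:
        scheme = AgeWindowScheme()
    sub = points[points["measure"] == measure]
    ages = pd.to_numeric(sub["age_months"]).to_numpy(float)
    values = pd.to_numeric(sub["value"]).to_numpy(float)
    grid = np.asarray(scheme.grid, float)
    out = {lvl: np.full(len(grid), np.nan) for lvl in PERCENTILE_LEVELS}
    n_per = np.zeros(len(grid), dtype=int)
    for i, g in enumerate(grid):
        lo, hi = scheme.window_for_age(g)
        sel = values[(ages >= lo) & (ages <= hi)]
        n_per[i] = len(sel)
        if len(sel) >= max(min_n, 1):
            q = np.quantile(sel, [l / 100 for l in PERCENTILE_LEVELS], method="linear")
            for lvl, val in zip(PERCENTILE_LEVELS, q):
                out[lvl][i] = val
    return PercentileCurve(sex=sex, measure=measure, grid_ages=grid,
                           p5=out[5], p50=out[50], p95=out[95],
                           n_per_window=n_per, method="empirical",
                           metadata={"min_n": min_n})


def _smooth_series(x, y, lam):
    if len(x) < 5:  # too short to penalize; fall back to the data itself
        return np.asarray(y, float)
    spl = make_smoothing_spline(np.asarray(x, float), np.asarray(y, float), lam=lam)
    return spl(np.asarray(x, float))


def _sort_levels(p5, p50, p95):
    stacked = np.sort(np.vstack([p5, p50, p95]), axis=0)
    return stacked[0], stacked[1], stacked[2]


def smooth_isopleths(curve: PercentileCurve, lam: float = None) -> PercentileCurve:
    """Smooth each empirical percentile series with a penalized spline.

    ``lam`` is the spline penalty; ``None`` selects it by generalized
    cross-validation, ``0`` interpolates the empirical points exactly.
    Non-crossing (p5 <= p50 <= p95) is enforced by sorting the three
    levels at each grid age; the maximum deviation from the empirical
    input is reported in the metadata envelope.
    """
    m = curve.estimable
    if m.sum() < 10:
        raise ValueError(f"only {int(m.sum())} estimable grid ages; need >= 10 to smooth")
    x = curve.grid_ages[m]
    smoothed = {}
    for lvl in PERCENTILE_LEVELS:
        smoothed[lvl] = _smooth_series(x, curve.level(lvl)[m], lam)
    s5, s50, s95 = _sort_levels(smoothed[5], smoothed[50], smoothed[95])
    envelope = max(float(np.max(np.abs(s - curve.level(lvl)[m])))
                   for lvl, s in zip(PERCENTILE_LEVELS, (s5, s50, s95)))
    out = {lvl: np.full(len(curve.grid_ages), np.nan) for lvl in PERCENTILE_LEVELS}
    for lvl, s in zip(PERCENTILE_LEVELS, (s5, s50, s95)):
        out[lvl][m] = s
    return PercentileCurve(
        sex=curve.sex, measure=curve.measure, grid_ages=curve.grid_ages,
        p5=out[5], p50=out[50], p95=out[95], n_per_window=curve.n_per_window,
        method="isopleth_smoothed",
        metadata={**curve.metadata, "lam": lam, "max_deviation": envelope},
    )


WEIGHT_SEAM_MONTHS = 36.0
WEIGHT_BLEND_HALF_WIDTH = 3.0


def spline_weight_percentiles(points: pd.DataFrame, sex: str,
                              scheme: AgeWindowScheme = None,
                              segment: str = "composite",
                              min_n: int = 20, lam: float = None) -> PercentileCurve:
    """Weight-for-age percentiles by segmented penalized splines.

    Windowed empirical percentiles are computed first, then a penalized
    smoothing spline is fitted per percentile level separately on
    birth-3 years and 3-18 years. ``segment`` selects ``"birth_to_3y"``,
    ``"three_to_18y"`` or the default ``"composite"``, which cross-fades
    the two fits linearly over the +-3-month window around 36 months.
    """
    if scheme is None:
        scheme = AgeWindowScheme()
    emp = empirical_percentiles(points, sex, "weight", scheme, min_n=min_n)
    grid = emp.grid_ages
    m = emp.estimable
    left_sel = m & (grid <= WEIGHT_SEAM_MONTHS + WEIGHT_BLEND_HALF_WIDTH)
    right_sel = m & (grid >= WEIGHT_SEAM_MONTHS - WEIGHT_BLEND_HALF_WIDTH)
    need = {"birth_to_3y": left_sel, "three_to_18y": right_sel}
    for name, sel in need.items():
        if segment in (name, "composite") and sel.sum() < 10:
            raise ValueError(f"weight segment {name}: only {int(sel.sum())} estimable grid ages")

    fits = {}
    for name, sel in need.items():
        if segment not in (name, "composite"):
            continue
        x = grid[sel]
        fits[name] = {lvl: _smooth_series(x, emp.level(lvl)[sel], lam) for lvl in PERCENTILE_LEVELS}

    out = {lvl: np.full(len(grid), np.nan) for lvl in PERCENTILE_LEVELS}
    if segment == "composite":
        lo = WEIGHT_SEAM_MONTHS - WEIGHT_BLEND_HALF_WIDTH
        hi = WEIGHT_SEAM_MONTHS + WEIGHT_BLEND_HALF_WIDTH
        w_left = np.clip((hi - grid) / (hi - lo), 0.0, 1.0)
        for lvl in PERCENTILE_LEVELS:
            left_full = np.full(len(grid), np.nan)
            right_full = np.full(len(grid), np.nan)
            left_full[left_sel] = fits["birth_to_3y"][lvl]
            right_full[right_sel] = fits["three_to_18y"][lvl]
            combined = np.where(
                np.isnan(left_full), right_full,
                np.where(np.isnan(right_full), left_full,
                         w_left * np.nan_to_num(left_full) + (1 - w_left) * np.nan_to_num(right_full)))
            out[lvl] = np.where(m, combined, np.nan)
        seam_gap = 0.0
        for lvl in PERCENTILE_LEVELS:
            lf = _project(grid, left_sel, fits["birth_to_3y"][lvl])
            rf = _project(grid, right_sel, fits["three_to_18y"][lvl])
            both = ~np.isnan(lf) & ~np.isnan(rf)
            if both.any():
                seam_gap = max(seam_gap, float(np.max(np.abs(lf[both] - rf[both]))))
        segment_label = "not_applicable"
        meta = {"min_n": min_n, "lam": lam, "seam_gap": seam_gap}
    else:
        sel = need[segment]
        for lvl in PERCENTILE_LEVELS:
            out[lvl][sel] = fits[segment][lvl]
        segment_label = segment
        meta = {"min_n": min_n, "lam": lam}
    p5, p50, p95 = out[5], out[50], out[95]
    est = ~np.isnan(p50)
    p5[est], p50[est], p95[est] = _sort_levels(p5[est], p50[est], p95[est])
    return PercentileCurve(sex=sex, measure="weight", grid_ages=grid,
                           p5=p5, p50=p50, p95=p95, n_per_window=emp.n_per_window,
                           method="penalized_spline", spline_segment=segment_label,
                           metadata=meta)


def _project(grid, sel, values):
    full = np.full(len(grid), np.nan)
    full[sel] = values
    return full


BIRTH_WINDOW = (0.0, 0.5)
Z_95 = 1.96


def birth_stats(points: pd.DataFrame, sex: str, measure: str,
                ref: ReferenceCurve) -> BirthStats:
    """Birth mean, sample SD and 95% normal CI against a reference mean.

    Birth measurements are values at ages in [0, 0.5] months. The CI is
    mean +- 1.96 sd/sqrt(n); the difference is called significant when the
    reference mean falls outside the CI. Requires n >= 2.
    """
    sub = points[points["measure"] == measure]
    ages = pd.to_numeric(sub["age_months"])
    vals = pd.to_numeric(sub["value"])[(ages >= BIRTH_WINDOW[0]) & (ages <= BIRTH_WINDOW[1])]
    n = len(vals)
    if n < 2:
        raise ValueError(f"need >= 2 birth measurements for {sex} {measure}, found {n}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = Z_95 * sd / np.sqrt(n)
    ref_mean = float(evaluate_reference(ref, sex, measure, 0.0, 50))
    return BirthStats(sex=sex, measure=measure, n=n, mean=mean, sd=sd,
                      ci_low=mean - half, ci_high=mean + half,
                      reference_mean=ref_mean,
                      significantly_different=not (mean - half <= ref_mean <= mean + half))
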