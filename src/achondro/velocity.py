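"""Height velocity estimation and derived growth milestones.

A velocity estimate is the difference quotient of two time-ordered
length/height measurements between 6 and 18 months apart, expressed in
cm/year and assigned to the midpoint of the age interval. Pairing is
greedy and non-overlapping: each measurement is paired with the earliest
subsequent measurement 6-18 months later, and the search resumes from
that later measurement. Sex-specific mean velocity curves are obtained by
binning estimates into the same age windows used for percentile curves
(extended past 18 years so the late-adolescent decline to zero velocity
stays on-grid).

Milestones derived here: the age at which the declining velocity curve
crosses a threshold (1 cm/year, 0 cm/year); the age at which a cohort P95
stature curve falls durably below a reference P5 ("divergence age"); and
the age at which the median head circumference reaches a fraction
(default 90%) of its plateau, the plateau being the mean of the median
curve over the final year of its grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from achondro.curves import AgeWindowScheme, PercentileCurve, velocity_window_scheme
from achondro.reference import ReferenceCurve, evaluate_reference

MIN_GAP_MONTHS = 6.0
MAX_GAP_MONTHS = 18.0

VELOCITY_COLUMNS = ["subject_id", "midpoint_age", "velocity", "interval_length"]


@dataclasses.dataclass
class VelocityCurve:
    """Mean height velocity (cm/year) on an age grid in months."""

    sex: str
    grid_ages: np.ndarray
    mean_velocity: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.grid_ages = np.asarray(self.grid_ages, float)
        self.mean_velocity = np.asarray(self.mean_velocity, float)
        self.n = np.asarray(self.n, int)

    @property
    def estimable(self) -> np.ndarray:
        return ~np.isnan(self.mean_velocity)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sex": self.sex, "age_months": self.grid_ages,
                             "mean_velocity": self.mean_velocity, "n": self.n})


@dataclasses.dataclass
class Milestone:
    kind: str      # velocity_reaches_1 | velocity_reaches_0 | cohort_p95_below_ref_p5 | ofc_90pct_attained
    sex: str
    age: float
    unit: str      # "years" or "months"
    basis: str = ""

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def pairwise_velocities(points: pd.DataFrame,
                        min_gap: float = MIN_GAP_MONTHS,
                        max_gap: float = MAX_GAP_MONTHS) -> pd.DataFrame:
    """Greedy non-overlapping velocity estimates per subject.

    ``points`` holds cleaned, exclusion-applied length/height rows for any
    number of subjects. Within a subject (sorted by age), each measurement
    is paired with the earliest subsequent measurement whose age gap lies
    in ``[min_gap, max_gap]`` months; the scan resumes from the paired
    measurement. Velocity is cm/year at the midpoint age.
    """
    sub = points[points["measure"] == "length_height"]
    rows = []
    for sid, g in sub.groupby("subject_id", sort=True):
        ages = pd.to_numeric(g["age_months"]).to_numpy(float)
        vals = pd.to_numeric(g["value"]).to_numpy(float)
        order = np.argsort(ages, kind="mergesort")
        ages, vals = ages[order], vals[order]
        i = 0
        while i < len(ages) - 1:
            j = None
            for cand in range(i + 1, len(ages)):
                gap = ages[cand] - ages[i]
                if gap > max_gap:
                    break
                if gap >= min_gap:
                    j = cand
                    break
            if j is None:
                i += 1
                continue
            gap = ages[j] - ages[i]
            rows.append({
                "subject_id": sid,
                "midpoint_age": (ages[i] + ages[j]) / 2.0,
                "velocity": (vals[j] - vals[i]) / gap * 12.0,
                "interval_length": gap,
            })
            i = j
    return pd.DataFrame(rows, columns=VELOCITY_COLUMNS)


def mean_velocity_curve(estimates: pd.DataFrame, sex: str,
                        scheme: AgeWindowScheme = None, min_n: int = 20) -> VelocityCurve:
    """Bin velocity estimates by midpoint age; arithmetic mean per window."""
    if scheme is None:
        scheme = velocity_window_scheme()
    mid = pd.to_numeric(estimates["midpoint_age"]).to_numpy(float)
    vel = pd.to_numeric(estimates["velocity"]).to_numpy(float)
    grid = np.asarray(scheme.grid, float)
    means = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for i, g in enumerate(grid):
        lo, hi = scheme.window_for_age(g)
        sel = vel[(mid >= lo) & (mid <= hi)]
        counts[i] = len(sel)
        if len(sel) >= max(min_n, 1):
            means[i] = sel.mean()
    return VelocityCurve(sex=sex, grid_ages=grid, mean_velocity=means, n=counts)


def smooth_velocity_curve(vc: VelocityCurve, lam: float = None,
                          min_age_months: float = 24.0) -> VelocityCurve:
    """Penalized-spline smoothing of the binned mean velocity curve.

    Only bins past ``min_age_months`` are smoothed (infancy velocities
    fall an order of magnitude in the first two years; one global penalty
    chosen against that steep segment would leave the childhood and
    adolescent tail - where threshold milestones live - unsmoothed). Bins
    are weighted by their estimate counts; the penalty is chosen by
    generalized cross-validation when ``lam`` is None. Threshold ages read
    off the smoothed curve are far less sensitive to single noisy bins.
    """
    from scipy.interpolate import make_smoothing_spline

    m = vc.estimable & (vc.grid_ages >= min_age_months)
    if m.sum() < 5:
        return vc
    x = vc.grid_ages[m]
    y = vc.mean_velocity[m]
    w = vc.n[m].astype(float)
    spl = make_smoothing_spline(x, y, w=w / w.mean(), lam=lam)
    out = vc.mean_velocity.copy()
    out[m] = spl(x)
    return VelocityCurve(sex=vc.sex, grid_ages=vc.grid_ages, mean_velocity=out, n=vc.n)


def velocity_threshold_age(vc: VelocityCurve, threshold: float) -> float | None:
    """Age (years) at which the declining velocity crosses ``threshold``.

    Only crossings after the curve's global maximum count (infancy
    velocities start far above any threshold of interest); the crossing
    point is linearly interpolated between grid ages. Returns ``None``
    when the curve never falls to the threshold within its grid.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = vc.estimable
    ages = vc.grid_ages[m]
    v = vc.mean_velocity[m]
    if len(v) < 2:
        return None
    start = int(np.argmax(v))
    if v[start] < threshold:
        return None
    for i in range(start, len(v)):
        if v[i] == threshold:
            return float(ages[i] / 12.0)
        if v[i] < threshold:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            return float((ages[i - 1] + frac * (ages[i] - ages[i - 1])) / 12.0)
    return None


def velocity_zero_age(vc: VelocityCurve, fit_range: tuple = (0.3, 2.0)) -> float | None:
    """Age (years) at which growth ceases, from the declining limb.

    Mean pairwise velocities are non-negative by construction near growth
    cessation (stature does not shrink, so once both measurements of a
    pair lie past the plateau their difference quotient is pure noise
    around zero, never systematically below it). A literal zero crossing
    of the binned curve is therefore a noise artifact. Instead, the ages
    where the (smoothed) velocity lies inside ``fit_range`` cm/year -- the
    late linear decline -- are fitted with a count-weighted straight line,
    and its zero intercept is reported. Returns ``None`` when fewer than
    three grid ages fall in the fitting range or the fitted slope is not
    negative.
    """
    m = vc.estimable
    ages = vc.grid_ages[m]
    v = vc.mean_velocity[m]
    n = vc.n[m].astype(float)
    if len(v) < 3:
        return None
    start = int(np.argmax(v))
    sel = slice(start, None)
    in_range = (v[sel] >= fit_range[0]) & (v[sel] <= fit_range[1])
    x = ages[sel][in_range]
    y = v[sel][in_range]
    w = n[sel][in_range]
    if len(x) < 3:
        return None
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    if slope >= 0:
        return None
    return float(-intercept / slope / 12.0)


def crossing_age(cohort_p95: PercentileCurve, ref: ReferenceCurve, sex: str,
                 step_months: float = 0.25) -> float | None:
    """Age (months) at which the cohort P95 falls durably below the reference P5.

    Both curves are evaluated on a shared fine grid from birth over their
    overlapping age range; the answer is the smallest age after which the
    cohort P95 stays below the reference P5 for the rest of the grid,
    linearly interpolated between grid points. Returns 0.0 when the cohort
    is already below at birth and ``None`` when it never stays below.
    """
    m = cohort_p95.estimable
    if m.sum() < 2:
        raise ValueError("cohort curve has fewer than two estimable ages")
    c_lo, c_hi = cohort_p95.grid_ages[m][0], cohort_p95.grid_ages[m][-1]
    r_lo, r_hi = ref.age_range(sex, cohort_p95.measure)
    lo, hi = max(c_lo, r_lo), min(c_hi, r_hi)
    if hi <= lo:
        raise ValueError("cohort and reference age ranges do not overlap")
    grid = np.arange(lo, hi + 1e-9, step_months)
    cohort = cohort_p95.interp(95, grid)
    reference = np.asarray(evaluate_reference(ref, sex, cohort_p95.measure, grid, 5), float)
    diff = cohort - reference
    if diff[-1] >= 0:
        return None
    above = np.flatnonzero(diff >= 0)
    if len(above) == 0:
        return 0.0
    i = above[-1]
    frac = diff[i] / (diff[i] - diff[i + 1])
    return float(grid[i] + frac * (grid[i + 1] - grid[i]))


PLATEAU_SPAN_MONTHS = 12.0


def attainment_age(p50_curve: PercentileCurve, fraction: float = 0.90) -> float:
    """Age (months) at which the median curve reaches ``fraction`` of its plateau.

    The plateau is the mean of the median over the final 12 months of the
    estimable grid. The attainment age is the first age at which the
    median meets ``fraction * plateau``, linearly interpolated.
    """
    m = p50_curve.estimable
    ages = p50_curve.grid_ages[m]
    p50 = p50_curve.p50[m]
    if len(ages) < 2:
        raise ValueError("median curve has fewer than two estimable ages")
    tail = ages >= ages[-1] - PLATEAU_SPAN_MONTHS
    if not tail.any():
        raise ValueError("plateau not estimable: no grid ages in the final year")
    plateau = float(p50[tail].mean())
    target = fraction * plateau
    reached = np.flatnonzero(p50 >= target)
    if len(reached) == 0:
        raise ValueError("median curve never reaches the target fraction of its plateau")
    i = reached[0]
    if i == 0:
        return float(ages[0])
    frac = (target - p50[i - 1]) / (p50[i] - p50[i - 1])
    return float(ages[i - 1] + frac * (ages[i] - ages[i - 1]))
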