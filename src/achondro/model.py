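"""High-level Model/Results interface over the growth-curve pipeline.

``GrowthCurveModel`` is constructed from a :class:`~achondro.registry.Registry`
(or a directory of registry CSVs) and a handful of method options;
``fit()`` runs QC flagging, the cohort exclusion rules, percentile-curve
construction for stature, weight and head circumference in both sexes,
birth statistics against a reference standard, and height-velocity
estimation. The returned :class:`GrowthCurveResults` carries the fitted
curves and their support, the cleaning reports, milestone estimates, a
``summary()`` table, cohort summary tables, and plotting helpers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from achondro.registry import Registry, read_registry, SEXES
from achondro.reference import ReferenceCurve, make_average_stature_reference
from achondro.cleaning import (QCConfig, apply_growth_exclusions, qc_anthropometry,
                               retained_points)
from achondro.curves import (AgeWindowScheme, PercentileCurve, BirthStats, birth_stats,
                             empirical_percentiles, smooth_isopleths,
                             spline_weight_percentiles, velocity_window_scheme)
from achondro.velocity import (Milestone, VelocityCurve, attainment_age, crossing_age,
                               mean_velocity_curve, pairwise_velocities,
                               smooth_velocity_curve, velocity_threshold_age,
                               velocity_zero_age)
from achondro import summaries as _summaries

OFC_MAX_AGE_MONTHS = 60.0   # head-circumference curves run birth through 5 years


class GrowthCurveModel:
    """Growth percentile-curve model for an achondroplasia registry.

    Parameters
    ----------
    registry : Registry
        The cohort to model.
    scheme : AgeWindowScheme, optional
        Window scheme for empirical percentiles (default: the standard
        0-216-month scheme; OFC uses the same scheme truncated at 60
        months, velocities the extension to 252 months).
    qc : QCConfig, optional
        Quality-control thresholds; ``qc.drop_flagged`` controls whether
        flagged points are dropped from curve inputs (default yes).
    reference : ReferenceCurve, optional
        Average-stature standard for birth comparisons and divergence
        milestones (default: the bundled synthetic standard).
    min_n : int
        Minimum values per window for an estimate (default 20).
    lam : float or None
        Spline penalty; None selects by generalized cross-validation.
    """

    def __init__(self, registry: Registry, scheme: AgeWindowScheme = None,
                 qc: QCConfig = None, reference: ReferenceCurve = None,
                 min_n: int = 20, lam: float = None, birth_reference: dict = None):
        self.registry = registry
        self.scheme = scheme or AgeWindowScheme()
        self.qc = qc or QCConfig()
        self.reference = reference or make_average_stature_reference()
        self.min_n = min_n
        self.lam = lam
        self.birth_reference = birth_reference

    @classmethod
    def from_csv_dir(cls, directory, **kwargs) -> "GrowthCurveModel":
        return cls(read_registry(directory), **kwargs)

    def fit(self) -> "GrowthCurveResults":
        flagged, qc_report = qc_anthropometry(self.registry, self.qc)
        excluded, exclusion_report = apply_growth_exclusions(flagged, self.birth_reference)
        points = retained_points(excluded, drop_flagged=self.qc.drop_flagged)
        sex_of = dict(zip(self.registry.subjects["subject_id"], self.registry.subjects["sex"]))
        points = points.assign(sex=points["subject_id"].map(sex_of))

        empirical, curves, births, velocities, raw_velocities = {}, {}, {}, {}, {}
        ofc_scheme = self.scheme.truncated(OFC_MAX_AGE_MONTHS)
        for sex in SEXES:
            pts = points[points["sex"] == sex]
            for measure, scheme in (("length_height", self.scheme), ("ofc", ofc_scheme)):
                emp = empirical_percentiles(pts, sex, measure, scheme, min_n=self.min_n)
                empirical[(sex, measure)] = emp
                try:
                    curves[(sex, measure)] = smooth_isopleths(emp, lam=self.lam)
                except ValueError:
                    curves[(sex, measure)] = emp
            empirical[(sex, "weight")] = empirical_percentiles(
                pts, sex, "weight", self.scheme, min_n=self.min_n)
            try:
                curves[(sex, "weight")] = spline_weight_percentiles(
                    pts, sex, self.scheme, min_n=self.min_n, lam=self.lam)
            except ValueError:
                curves[(sex, "weight")] = empirical[(sex, "weight")]
            for measure in ("length_height", "weight", "ofc"):
                try:
                    births[(sex, measure)] = birth_stats(pts, sex, measure, self.reference)
                except ValueError:
                    pass
            est = pairwise_velocities(pts)
            raw_velocities[sex] = est
            velocities[sex] = mean_velocity_curve(est, sex, velocity_window_scheme(),
                                                  min_n=self.min_n)
        return GrowthCurveResults(
            model=self, curve_points=points, empirical=empirical, curves=curves,
            birth=births, velocity=velocities, velocity_estimates=raw_velocities,
            qc_report=qc_report, exclusion_report=exclusion_report,
        )


@dataclasses.dataclass
class GrowthCurveResults:
    """Fitted percentile curves, velocities, milestones and diagnostics."""

    model: GrowthCurveModel
    curve_points: pd.DataFrame
    empirical: dict
    curves: dict
    birth: dict
    velocity: dict
    velocity_estimates: dict
    qc_report: object
    exclusion_report: object

    def curve(self, sex: str, measure: str) -> PercentileCurve:
        return self.curves[(sex, measure)]

    def birth_stats(self, sex: str, measure: str) -> BirthStats:
        return self.birth[(sex, measure)]

    def milestones(self) -> list:
        """Milestone estimates per sex; entries with unattainable values are skipped.

        Stature milestones (velocity declining through 1 and 0 cm/year) are
        reported in years to two decimals; the divergence age (cohort P95
        durably below reference P5) and the 90% head-circumference
        attainment age in months to one decimal.
        """
        out = []
        for sex in SEXES:
            vc = self.velocity.get(sex)
            if vc is not None and vc.estimable.sum() >= 2:
                smoothed = smooth_velocity_curve(vc, lam=self.model.lam)
                age1 = velocity_threshold_age(smoothed, 1.0)
                if age1 is not None:
                    out.append(Milestone(kind="velocity_reaches_1", sex=sex, age=round(age1, 2),
                                         unit="years", basis="smoothed mean height velocity curve"))
                age0 = velocity_zero_age(smoothed)
                if age0 is not None:
                    out.append(Milestone(kind="velocity_reaches_0", sex=sex, age=round(age0, 2),
                                         unit="years", basis="declining-limb zero intercept"))
            stature = self.curves.get((sex, "length_height"))
            if stature is not None and stature.estimable.sum() >= 2:
                try:
                    age = crossing_age(stature, self.model.reference, sex)
                except ValueError:
                    age = None
                if age is not None:
                    out.append(Milestone(kind="cohort_p95_below_ref_p5", sex=sex,
                                         age=round(age, 1), unit="months",
                                         basis="cohort P95 stature vs reference P5"))
            ofc = self.curves.get((sex, "ofc"))
            if ofc is not None and ofc.estimable.sum() >= 2:
                try:
                    age = attainment_age(ofc, fraction=0.90)
                except ValueError:
                    age = None
                if age is not None:
                    out.append(Milestone(kind="ofc_90pct_attained", sex=sex,
                                         age=round(age, 1), unit="months",
                                         basis="median OFC vs its plateau"))
        return out

    def curves_frame(self) -> pd.DataFrame:
        frames = [c.as_frame() for c in self.curves.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def cohort_summaries(self) -> dict:
        """All six registry summary tables for the underlying cohort."""
        return {tid: fn(self.model.registry) for tid, fn in _summaries.SUMMARIZERS.items()}

    def summary(self):
        """statsmodels-style summary table of the fit."""
        from statsmodels.iolib.table import SimpleTable

        rows = []
        for (sex, measure), bs in sorted(self.birth.items()):
            rows.append([
                f"birth {measure} ({sex})",
                f"{bs.mean:.2f} ± {bs.sd:.2f}",
                f"[{bs.ci_low:.2f}, {bs.ci_high:.2f}]",
                f"{bs.reference_mean:.2f}",
                "yes" if bs.significantly_different else "no",
            ])
        birth_table = SimpleTable(
            rows,
            headers=["quantity", "mean ± SD", "95% CI", "reference mean", "differs"],
            title="Birth anthropometry vs average-stature reference",
        )
        mrows = [[m.kind, m.sex, f"{m.age:g} {m.unit}"] for m in self.milestones()]
        milestone_table = SimpleTable(
            mrows or [["(none estimable)", "", ""]],
            headers=["milestone", "sex", "age"],
            title="Growth milestones",
        )
        n_points = len(self.curve_points)
        meta = SimpleTable(
            [["curve input points", f"{n_points}"],
             ["subjects", f"{len(self.model.registry.subjects)}"],
             ["QC flags", f"{sum(self.qc_report.rule_counts.values())}"],
             ["excluded subjects", f"{self.exclusion_report.rule_counts.get('excluded_subjects', 0)}"]],
            headers=["item", "value"], title="Fit information",
        )
        return "\n".join(str(t) for t in (meta, birth_table, milestone_table))

    def plot_curve(self, sex: str, measure: str, ax=None, show_points: bool = True):
        """Plot P5/P50/P95 with the reference median, optionally raw points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        c = self.curves[(sex, measure)]
        m = c.estimable
        x = c.grid_ages[m]
        if show_points:
            pts = self.curve_points
            pts = pts[(pts["sex"] == sex) & (pts["measure"] == measure)]
            ax.plot(pd.to_numeric(pts["age_months"]), pd.to_numeric(pts["value"]),
                    ".", ms=2, alpha=0.2, color="grey")
        for lvl, style in ((5, "--"), (50, "-"), (95, "--")):
            ax.plot(x, c.level(lvl)[m], style, color="C0", label=f"P{lvl}")
        try:
            from achondro.reference import evaluate_reference
            ref = self.model.reference
            lo, hi = ref.age_range(sex, measure)
            rx = np.linspace(max(lo, x[0]), min(hi, x[-1]), 200)
            ax.plot(rx, evaluate_reference(ref, sex, measure, rx, 50), "-",
                    color="C3", alpha=0.7, label="reference P50")
        except Exception:
            pass
        unit = "kg" if measure == "weight" else "cm"
        ax.set_xlabel("age (months)")
        ax.set_ylabel(f"{measure} ({unit})")
        ax.set_title(f"{measure} for age, {sex}")
        ax.legend(loc="best", fontsize=8)
        return ax

    def plot_velocity(self, sex: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        vc = self.velocity[sex]
        m = vc.estimable
        ax.plot(vc.grid_ages[m] / 12.0, vc.mean_velocity[m], "-", color="C0")
        ax.axhline(1.0, color="grey", lw=0.5)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("height velocity (cm/year)")
        ax.set_title(f"mean height velocity, {sex}")
        return ax
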