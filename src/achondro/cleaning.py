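"""Growth-curve exclusion rules and anthropometry quality control.

Two distinct layers:

* :func:`apply_growth_exclusions` implements the stated cohort rules:
  preterm subjects contribute no points before 24 months (re-entering at
  exactly 24.0 months, boundary inclusive); subjects with limb lengthening,
  growth-hormone treatment or growth-modulating trial participation are
  excluded entirely; subjects of unknown gestation are presumed term when
  every available birth measurement falls within +-2 SD of the published
  sex-specific achondroplasia birth reference, and otherwise treated like
  preterm subjects before 24 months.

* :func:`qc_anthropometry` is a documented stand-in QC layer (the original
  study's cleaning algorithms live in an unavailable supplement): it
  collapses exact duplicates, flags unit-swap suspects (a cm value
  recorded in inches, or kg in pounds, betrayed by the corrected value
  falling back onto the subject's interpolated trajectory), values outside
  hard physiologic bounds, gross within-subject trajectory outliers, and
  stature decreases > 2 cm between consecutive visits before 18 years.
  Flagged points are flagged, not deleted; dropping them for curve
  construction is a config switch (default: drop).
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd

from achondro import registry as reg
from achondro.registry import Registry
from achondro.reference import ACH_BIRTH_REFERENCE

BIRTH_WINDOW_MONTHS = 0.5          # a "birth" measurement is taken in [0, 0.5] months
PRETERM_REENTRY_MONTHS = 24.0      # preterm points re-enter at exactly 24.0 months


@dataclasses.dataclass
class QCConfig:
    """Thresholds for the stand-in QC layer (all config-exposed)."""

    hard_bounds: dict = dataclasses.field(default_factory=lambda: {
        "length_height": (20.0, 220.0), "weight": (0.3, 250.0), "ofc": (20.0, 70.0),
    })
    # residual scale used for trajectory checks: cm for stature/OFC,
    # log-scale for weight
    residual_sd: dict = dataclasses.field(default_factory=lambda: {
        "length_height": 3.0, "ofc": 2.5, "weight": 0.10,
    })
    outlier_mult: float = 4.0      # |residual| beyond this many SD => suspect
    confirm_mult: float = 2.0      # corrected value within this many SD => unit swap
    shrink_tolerance_cm: float = 2.0
    shrink_max_age_months: float = 216.0
    # curvature envelope |f''(t)| <= amp*exp(-t/tau) + floor used to widen
    # the trajectory tolerance where linear interpolation is genuinely
    # inaccurate (growth curves bend hardest in infancy); units are
    # cm/month^2, log-scale for weight
    curvature: dict = dataclasses.field(default_factory=lambda: {
        "length_height": (0.25, 8.0, 0.004), "ofc": (0.25, 9.0, 0.001),
        "weight": (0.04, 6.0, 0.0005),
    })
    flag_trajectory_outliers: bool = True
    drop_flagged: bool = True      # drop flagged points when building curves


# correction factor that undoes a unit swap (inches->cm, pounds->kg)
_UNIT_CORRECTION = {"length_height": 2.54, "ofc": 2.54, "weight": 1 / 2.2046}


@dataclasses.dataclass
class CleaningReport:
    """Accounting of a cleaning pass: every input point is retained,
    flagged-retained or dropped, and counts are conserved per measure."""

    rule_counts: dict = dataclasses.field(default_factory=dict)
    subject_reasons: dict = dataclasses.field(default_factory=dict)
    input_by_measure: dict = dataclasses.field(default_factory=dict)
    dropped_by_measure: dict = dataclasses.field(default_factory=dict)
    retained_by_measure: dict = dataclasses.field(default_factory=dict)
    retained_by_band: dict = dataclasses.field(default_factory=dict)

    def conserved(self) -> bool:
        return all(
            self.input_by_measure.get(m, 0)
            == self.dropped_by_measure.get(m, 0) + self.retained_by_measure.get(m, 0)
            for m in reg.MEASURES
        )

    def to_json(self, indent: int = 2) -> str:
        d = dataclasses.asdict(self)
        d["conserved"] = self.conserved()
        return json.dumps(d, indent=indent, sort_keys=True)


def _count_by_measure(a: pd.DataFrame) -> dict:
    c = a["measure"].value_counts().to_dict()
    return {m: int(c.get(m, 0)) for m in reg.MEASURES}


def presume_term(subject_row, birth_points: pd.DataFrame, ref: dict = None) -> str:
    """Presumed gestation for a subject of unknown gestation.

    Returns ``"term"`` iff the subject has at least one birth measurement
    (age in [0, 0.5] months) and every available birth measurement lies
    within mean +- 2 SD of the sex-specific achondroplasia birth reference
    ``ref`` (``{(sex, measure): (mean, sd)}``); otherwise ``"unknown"``.
    """
    if ref is None:
        ref = ACH_BIRTH_REFERENCE
    sex = subject_row["sex"]
    bp = birth_points[pd.to_numeric(birth_points["age_months"]) <= BIRTH_WINDOW_MONTHS]
    if len(bp) == 0:
        return "unknown"
    for _, row in bp.iterrows():
        key = (sex, row["measure"])
        if key not in ref:
            continue
        mean, sd = ref[key]
        if not (mean - 2 * sd <= float(row["value"]) <= mean + 2 * sd):
            return "unknown"
    return "term"


def apply_growth_exclusions(r: Registry, birth_reference: dict = None) -> tuple:
    """Apply the cohort's growth-curve exclusion rules.

    Returns ``(registry, report)`` where the registry's anthropometry
    contains only curve-eligible points. Idempotent: applying the rules to
    their own output changes nothing.
    """
    if birth_reference is None:
        birth_reference = ACH_BIRTH_REFERENCE
    r = r.canonicalize()
    s = r.subjects.set_index("subject_id", drop=False)
    a = r.anthropometry
    report = CleaningReport(input_by_measure=_count_by_measure(a))

    excluded_subjects = {}
    for _, row in s.iterrows():
        reasons = []
        if row["limb_lengthening"] == "true":
            reasons.append("limb_lengthening")
        if row["gh_treated"] == "true":
            reasons.append("gh_treated")
        if row["trial_participant"] == "true":
            reasons.append("trial")
        if reasons:
            excluded_subjects[row["subject_id"]] = reasons

    preterm_like = set(s.loc[s["gestation"] == "preterm", "subject_id"])
    presumed_term = []
    for sid in s.loc[s["gestation"] == "unknown", "subject_id"]:
        bp = a[(a["subject_id"] == sid)]
        status = presume_term(s.loc[sid], bp, birth_reference)
        if status == "term":
            presumed_term.append(sid)
        else:
            preterm_like.add(sid)

    age = pd.to_numeric(a["age_months"])
    drop_subject = a["subject_id"].isin(excluded_subjects)
    drop_preterm = a["subject_id"].isin(preterm_like) & (age < PRETERM_REENTRY_MONTHS)
    dropped = drop_subject | drop_preterm

    report.rule_counts = {
        "excluded_subject_points": int(drop_subject.sum()),
        "preterm_under_24mo_points": int((drop_preterm & ~drop_subject).sum()),
        "excluded_subjects": len(excluded_subjects),
        "preterm_like_subjects": len(preterm_like),
        "presumed_term_subjects": len(presumed_term),
    }
    report.subject_reasons = {sid: reasons for sid, reasons in sorted(excluded_subjects.items())}
    kept = a[~dropped].reset_index(drop=True)
    report.dropped_by_measure = _count_by_measure(a[dropped])
    report.retained_by_measure = _count_by_measure(kept)
    report.retained_by_band = _retained_by_band(kept, s)

    out = r.copy()
    out.anthropometry = kept
    return out.canonicalize(), report


def _retained_by_band(a: pd.DataFrame, subjects_indexed: pd.DataFrame) -> dict:
    """Point counts per measure and age-at-last-contact band (table shape)."""
    if len(a) == 0:
        return {m: {"lt10y": 0, "10to18y": 0, "ge18y": 0} for m in reg.MEASURES}
    age_last = pd.to_numeric(subjects_indexed["age_last_encounter"])
    band = pd.cut(age_last, [-0.001, 10.0 - 1e-9, 18.0 - 1e-9, np.inf],
                  labels=["lt10y", "10to18y", "ge18y"])
    band_of = dict(zip(subjects_indexed["subject_id"], band.astype(str)))
    out = {}
    for m in reg.MEASURES:
        sub = a[a["measure"] == m]
        counts = sub["subject_id"].map(band_of).value_counts()
        out[m] = {b: int(counts.get(b, 0)) for b in ("lt10y", "10to18y", "ge18y")}
    return out


# ---------------------------------------------------------------------------
# QC layer
# ---------------------------------------------------------------------------


def _neighbor_prediction(t, v, i, use, log_scale: bool):
    """Predict point i from the subject's other usable points.

    Interior points are linearly interpolated between the nearest usable
    neighbours below and above; edge points are linearly extrapolated from
    the two nearest usable points (or copied, if only one exists).
    Returns ``(prediction, (t0, t1), extrapolated)`` with the neighbour
    ages used, or ``None`` when no other point exists.
    """
    others = [j for j in range(len(t)) if j != i and use[j]]
    if not others:
        return None
    y = np.log(v) if log_scale else v
    below = [j for j in others if t[j] < t[i]]
    above = [j for j in others if t[j] > t[i]]
    extrapolated = not (below and above)
    if not extrapolated:
        j0, j1 = max(below, key=lambda j: t[j]), min(above, key=lambda j: t[j])
    else:
        side = sorted(others, key=lambda j: abs(t[j] - t[i]))[:2]
        if len(side) == 1:
            j = side[0]
            return float(y[j]), (t[j], t[j]), True
        j0, j1 = side
    if t[j1] == t[j0]:
        return float((y[j0] + y[j1]) / 2.0), (t[j0], t[j1]), extrapolated
    slope = (y[j1] - y[j0]) / (t[j1] - t[j0])
    return float(y[j0] + slope * (t[i] - t[j0])), (t[j0], t[j1]), extrapolated


def _curvature_allowance(cfg: QCConfig, measure, t_i, t0, t1, extrapolated):
    """Worst-case linear-prediction error for a curve whose second
    derivative is bounded by the configured envelope over the support."""
    amp, tau, floor = cfg.curvature[measure]
    tmin = min(t_i, t0, t1)
    c = amp * math.exp(-tmin / tau) + floor
    d0, d1 = abs(t_i - t0), abs(t_i - t1)
    if extrapolated:
        return 0.5 * c * max(d0, d1) ** 2
    return 0.5 * c * d0 * d1


def _trajectory_pass(t, v, measure, cfg: QCConfig, use):
    """One flagging pass over a subject's series.

    Returns per-point ``(flag_or_None, |residual|_or_None, allowance)``
    where the allowance is the curvature slack added to the threshold.
    """
    log_scale = measure == "weight"
    sd = cfg.residual_sd[measure]
    corr = _UNIT_CORRECTION[measure]
    out = [(None, None, math.inf)] * len(t)
    for i in range(len(t)):
        got = _neighbor_prediction(t, v, i, use, log_scale)
        if got is None:
            continue
        pred, (t0, t1), extrapolated = got
        allow = _curvature_allowance(cfg, measure, t[i], t0, t1, extrapolated)
        yi = math.log(v[i]) if log_scale else v[i]
        resid = abs(yi - pred)
        flag = None
        if resid > cfg.outlier_mult * sd + allow:
            yc = math.log(v[i] * corr) if log_scale else v[i] * corr
            if abs(yc - pred) <= cfg.confirm_mult * sd + allow:
                flag = "unit_swap_suspect"
            elif cfg.flag_trajectory_outliers:
                flag = "implausible"
        out[i] = (flag, resid, allow)
    return out


def qc_anthropometry(r: Registry, rules: QCConfig = None) -> tuple:
    """Flag suspect anthropometry; never silently delete.

    Returns ``(registry, report)``: the registry carries per-point
    ``qc_flags`` (``ok`` or one or more flags); the report counts points
    per rule. Exact duplicate rows (same subject, measure, age, value) are
    collapsed to a single ``ok`` row with the extras flagged ``duplicate``.
    Use :func:`retained_points` to obtain the curve-construction subset.
    """
    if rules is None:
        rules = QCConfig()
    r = r.canonicalize()
    a = r.anthropometry.copy()
    age = pd.to_numeric(a["age_months"]).to_numpy(float)
    val = pd.to_numeric(a["value"]).to_numpy(float)
    flags = [set() for _ in range(len(a))]

    dup_mask = a.duplicated(subset=["subject_id", "measure", "age_months", "value"], keep="first")
    for i in np.flatnonzero(dup_mask.to_numpy()):
        flags[i].add("duplicate")

    for i in range(len(a)):
        lo, hi = rules.hard_bounds[a.at[i, "measure"]]
        if not (lo <= val[i] <= hi):
            flags[i].add("implausible")

    # two passes: the second re-predicts after masking first-pass suspects,
    # so one corrupt point does not hide or create a neighbour's flag.
    # Where masking leaves the second pass with only distant neighbours
    # (curvature allowance dominating the threshold), the first-pass
    # verdict stands: it was made with the closest available support.
    order = a.groupby(["subject_id", "measure"], sort=False).indices
    for (sid, measure), idx in order.items():
        idx = idx[np.argsort(age[idx], kind="mergesort")]
        t, v = age[idx], val[idx]
        clean = np.array([not flags[j] for j in idx])
        pass1 = _trajectory_pass(t, v, measure, rules, clean)
        use2 = clean & np.array([f is None for f, _, _ in pass1])
        pass2 = _trajectory_pass(t, v, measure, rules, use2)
        cap = rules.outlier_mult * rules.residual_sd[measure]
        final = [None] * len(idx)
        for local in range(len(idx)):
            f2, resid2, allow2 = pass2[local]
            if f2 is not None:
                final[local] = f2
            elif resid2 is not None and resid2 <= cap + min(allow2, cap):
                final[local] = None          # cleared by an informative test
            else:
                final[local] = pass1[local][0]
        for local, f in enumerate(final):
            if f is not None:
                flags[idx[local]].add(f)
        if measure == "length_height":
            keep = [j for local, j in enumerate(idx)
                    if use2[local] and final[local] is None]
            keep = [j for j in keep if age[j] < rules.shrink_max_age_months]
            for p, q in zip(keep[:-1], keep[1:]):
                if val[q] < val[p] - rules.shrink_tolerance_cm:
                    flags[q].add("within_subject_jump")

    a["qc_flags"] = [";".join(sorted(f)) if f else "ok" for f in flags]
    out = r.copy()
    out.anthropometry = a

    flagged = a[a["qc_flags"] != "ok"]
    report = CleaningReport(input_by_measure=_count_by_measure(a))
    rule_counts = {f: 0 for f in ("duplicate", "unit_swap_suspect", "implausible", "within_subject_jump")}
    for f in flagged["qc_flags"]:
        for token in f.split(";"):
            rule_counts[token] += 1
    report.rule_counts = rule_counts
    dropped = a[a["qc_flags"] != "ok"] if rules.drop_flagged else a.iloc[0:0]
    report.dropped_by_measure = _count_by_measure(dropped)
    report.retained_by_measure = {
        m: report.input_by_measure[m] - report.dropped_by_measure.get(m, 0) for m in reg.MEASURES
    }
    s = r.subjects.set_index("subject_id", drop=False)
    report.retained_by_band = _retained_by_band(
        a[a["qc_flags"] == "ok"] if rules.drop_flagged else a, s)
    return out, report


def retained_points(r: Registry, drop_flagged: bool = True) -> pd.DataFrame:
    """Anthropometry subset used for curve construction."""
    a = r.anthropometry
    if not drop_flagged or "qc_flags" not in a.columns:
        return a
    return a[(a["qc_flags"] == "ok") | (a["qc_flags"] == "")].reset_index(drop=True)
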