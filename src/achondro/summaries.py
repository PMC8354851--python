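"""Registry summary tables: demographics, birth decades, anthropometry
counts, surgical burden, sleep studies and the imaging catalogue.

Every summary is a :class:`CohortSummary` holding a long-format frame with
one row per cell: a section (e.g. ``inheritance``), a label (``de_novo``),
a stratum (``total``/``living``/``deceased``, a birth decade, an age
band...), the count, its explicit denominator, and the percentage rounded
half-up to one decimal. Unknown is always an explicit category, so
category counts sum to their denominator. Continuous cells carry mean, SD,
median, quartiles and range in years.

Counting rules: surgical burden counts achondroplasia-related categories
only, pressure-equalizing-tube events without a recorded date are excluded
from counting, the full cohort is the denominator for category
percentages, and a subject's obstructive-sleep-apnea grade is the worst
across all of their sleep studies.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from achondro import registry as reg
from achondro.registry import Registry, birth_decades

TABLE_IDS = ("demographics", "birth_decade", "anthropometry_counts",
             "surgical_burden", "psg_by_decade", "imaging_catalogue")

SUMMARY_COLUMNS = ["section", "label", "stratum", "n", "denominator", "pct",
                   "mean", "sd", "median", "q1", "q3", "min", "max"]

AGE_BANDS = ("lt10y", "10to18y", "ge18y")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 79.55 -> 79.6, matching printed tables)."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to 1 decimal; NaN for 0 denominator."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * count / denominator, 1)


@dataclasses.dataclass
class CohortSummary:
    """One rendered summary table in long format."""

    table_id: str
    frame: pd.DataFrame
    denominators: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.table_id not in TABLE_IDS:
            raise ValueError(f"unknown table_id {self.table_id!r}")
        for c in SUMMARY_COLUMNS:
            if c not in self.frame.columns:
                self.frame[c] = np.nan
        self.frame = self.frame[SUMMARY_COLUMNS].reset_index(drop=True)

    def cell(self, section: str, label: str, stratum: str) -> pd.Series:
        f = self.frame
        hit = f[(f["section"] == section) & (f["label"] == label) & (f["stratum"] == stratum)]
        if len(hit) != 1:
            raise KeyError(f"cell ({section}, {label}, {stratum}): {len(hit)} matches")
        return hit.iloc[0]

    def pct(self, section: str, label: str, stratum: str = "total") -> float:
        return float(self.cell(section, label, stratum)["pct"])

    def count(self, section: str, label: str, stratum: str = "total") -> int:
        return int(self.cell(section, label, stratum)["n"])

    def equals(self, other: "CohortSummary") -> bool:
        if self.table_id != other.table_id:
            return False
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, check_dtype=False)
        except AssertionError:
            return False
        return True


def _cat(section, label, stratum, n, den):
    return {"section": section, "label": label, "stratum": stratum,
            "n": int(n), "denominator": int(den), "pct": percentage(n, den)}


def _cont(section, label, stratum, values):
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return {"section": section, "label": label, "stratum": stratum}
    return {"section": section, "label": label, "stratum": stratum,
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
            "median": float(np.median(values)),
            "q1": float(np.quantile(values, 0.25)), "q3": float(np.quantile(values, 0.75)),
            "min": float(values.min()), "max": float(values.max())}


def _category_rows(section, series, vocab, stratum, den):
    counts = series.value_counts()
    return [_cat(section, label, stratum, int(counts.get(label, 0)), den) for label in vocab]


def summarize_demographics(r: Registry) -> CohortSummary:
    """Population characteristics by vital status (total/living/deceased)."""
    s = r.subjects
    strata = {
        "total": s,
        "living": s[s["vital_status"] == "living"],
        "deceased": s[s["vital_status"] == "deceased"],
    }
    rows = []
    for name, sub in strata.items():
        den = len(sub)
        rows.append(_cat("participants", "n", name, den, len(s)))
        rows += _category_rows("sex", sub["sex"], reg.SEXES, name, den)
        rows.append(_cont("age_last_encounter", "years", name, pd.to_numeric(sub["age_last_encounter"])))
        rows += _category_rows("site", sub["site"], reg.SITES, name, den)
        rows += _category_rows("inheritance", sub["inheritance"], reg.INHERITANCES, name, den)
        rows += _category_rows("adopted", sub["adopted"], reg.TRISTATE, name, den)
        rows += _category_rows("gestation", sub["gestation"], reg.GESTATIONS, name, den)
        for flag in ("limb_lengthening", "gh_deficient", "gh_treated", "trial_participant"):
            rows.append(_cat(flag, "true", name, int((sub[flag] == "true").sum()), den))
    return CohortSummary("demographics", pd.DataFrame(rows),
                         {name: len(sub) for name, sub in strata.items()})


def summarize_birth_decades(r: Registry) -> CohortSummary:
    """Population, age and diagnosis timing/mode by 10-year birth cohort."""
    s = r.subjects.copy()
    s["decade"] = birth_decades(s)
    rows = []
    strata = list(reg.BIRTH_DECADES) + ["total"]
    for name in strata:
        sub = s if name == "total" else s[s["decade"] == name]
        den = len(sub)
        rows.append(_cat("population", "pac", name, den, len(s)))
        rows.append(_cat("population", "deceased", name, int((sub["vital_status"] == "deceased").sum()), den))
        rows.append(_cont("age_last_encounter", "years", name, pd.to_numeric(sub["age_last_encounter"])))
        rows += _category_rows("diagnosis_timing", sub["diagnosis_timing"], reg.DIAGNOSIS_TIMINGS, name, den)
        rows += _category_rows("diagnosis_mode", sub["diagnosis_mode"], reg.DIAGNOSIS_MODES, name, den)
    return CohortSummary("birth_decade", pd.DataFrame(rows),
                         {name: int((s["decade"] == name).sum()) for name in reg.BIRTH_DECADES})


def _age_band(age_last_years: pd.Series) -> pd.Series:
    age = pd.to_numeric(age_last_years)
    return pd.cut(age, [-0.001, 10.0 - 1e-9, 18.0 - 1e-9, np.inf], labels=AGE_BANDS).astype(str)


def summarize_anthropometry_counts(r: Registry) -> CohortSummary:
    """Measurement and contributor counts by measure and age at last contact."""
    s = r.subjects
    a = r.anthropometry
    band_of = dict(zip(s["subject_id"], _age_band(s["age_last_encounter"])))
    rows = []
    n_pac = len(s)
    for measure in list(reg.MEASURES) + ["all"]:
        sub = a if measure == "all" else a[a["measure"] == measure]
        bands = sub["subject_id"].map(band_of)
        for band in list(AGE_BANDS) + ["total"]:
            cell = sub if band == "total" else sub[bands == band]
            rows.append(_cat(f"points_{measure}", band, "total", len(cell), max(len(a), 1)))
            rows.append(_cat(f"subjects_{measure}", band, "total",
                             cell["subject_id"].nunique(), n_pac if n_pac else 1))
    contributors = a["subject_id"].nunique()
    rows.append(_cat("contributors", "any_measure", "total", contributors, n_pac if n_pac else 1))
    return CohortSummary("anthropometry_counts", pd.DataFrame(rows),
                         {"pac": n_pac, "points": len(a)})


def countable_surgeries(r: Registry) -> pd.DataFrame:
    """Achondroplasia-related surgical events eligible for counting.

    Pressure-equalizing-tube placements without a recorded procedure date
    are excluded; the non-achondroplasia category is kept separate.
    """
    g = r.surgeries
    ach = g[g["category"].isin(reg.ACH_SURGERY_CATEGORIES)]
    pe_undated = (ach["procedure"] == "pe_tubes") & (ach["date_known"] != "true")
    return ach[~pe_undated]


def summarize_surgical_burden(r: Registry) -> CohortSummary:
    """Surgical burden with the full cohort as denominator."""
    s = r.subjects
    n_pac = len(s)
    ach = countable_surgeries(r)
    per_subject_cats = ach.groupby("subject_id")["category"].nunique()
    ever_ids = set(per_subject_cats.index)
    known = set(s.loc[s["surgical_history_known"] == "true", "subject_id"])
    never = [sid for sid in s["subject_id"] if sid in known and sid not in ever_ids]
    unknown = [sid for sid in s["subject_id"] if sid not in known and sid not in ever_ids]

    rows = [
        _cat("any_ach_surgery", "ever", "total", len(ever_ids), n_pac),
        _cat("any_ach_surgery", "never", "total", len(never), n_pac),
        _cat("any_ach_surgery", "unknown", "total", len(unknown), n_pac),
    ]
    rows.append({"section": "procedures", "label": "total_ach", "stratum": "total",
                 "n": int(len(ach)), "denominator": n_pac, "pct": float("nan")})
    for cat in reg.ACH_SURGERY_CATEGORIES:
        sub = ach[ach["category"] == cat]
        rows.append(_cat(f"category_{cat}", "subjects", "total", sub["subject_id"].nunique(), n_pac))
        rows.append({"section": f"category_{cat}", "label": "procedures", "stratum": "total",
                     "n": int(len(sub)), "denominator": n_pac, "pct": float("nan")})
    dist = per_subject_cats.value_counts()
    n_ever = max(len(ever_ids), 1) if len(ever_ids) else 1
    for k in range(1, 6):
        rows.append(_cat("distinct_categories", str(k), "total", int(dist.get(k, 0)),
                         len(ever_ids) if ever_ids else 1))
    nonach = r.surgeries[r.surgeries["category"] == "non_achondroplasia_related"]
    rows.append({"section": "non_ach", "label": "subjects", "stratum": "total",
                 "n": int(nonach["subject_id"].nunique()), "denominator": n_pac, "pct": float("nan")})
    rows.append({"section": "non_ach", "label": "procedures", "stratum": "total",
                 "n": int(len(nonach)), "denominator": n_pac, "pct": float("nan")})
    return CohortSummary("surgical_burden", pd.DataFrame(rows),
                         {"pac": n_pac, "ever": len(ever_ids), "never": len(never), "unknown": len(unknown)})


def worst_osa_grade(psg: pd.DataFrame) -> pd.Series:
    """Subject-level worst obstructive-sleep-apnea grade across studies."""
    rank = psg["outcome"].map(reg.OSA_SEVERITY_ORDER)
    worst = rank.groupby(psg["subject_id"]).max()
    inv = {0: "no_osa", 1: "mild", 2: "moderate", 3: "severe"}
    return worst.map(inv)


def summarize_psg(r: Registry) -> CohortSummary:
    """Sleep-study uptake, age at first study, and worst OSA grade by decade."""
    s = r.subjects.copy()
    s["decade"] = birth_decades(s)
    psg = r.psg
    decade_of = dict(zip(s["subject_id"], s["decade"]))
    worst = worst_osa_grade(psg) if len(psg) else pd.Series(dtype=object)
    first_age = (pd.to_numeric(psg["age_at_study"]).groupby(psg["subject_id"]).min()
                 if len(psg) else pd.Series(dtype=float))
    rows = []
    for name in list(reg.BIRTH_DECADES) + ["total"]:
        sub = s if name == "total" else s[s["decade"] == name]
        den = len(sub)
        ids = set(sub["subject_id"])
        with_psg = [sid for sid in first_age.index if sid in ids]
        rows.append(_cat("population", "n", name, den, len(s)))
        rows.append(_cat("psg", "ge1_study", name, len(with_psg), den))
        rows.append(_cont("age_first_psg", "years", name, first_age.loc[with_psg]))
        modsev = [sid for sid in with_psg if worst.get(sid) in ("moderate", "severe")]
        rows.append(_cat("osa", "moderate_or_severe", name, len(modsev),
                         len(with_psg) if with_psg else 1))
    return CohortSummary("psg_by_decade", pd.DataFrame(rows),
                         {"pac": len(s), "with_psg": int(len(first_age))})


def summarize_imaging(r: Registry) -> CohortSummary:
    """Radiographic catalogue: per-modality counts and image availability."""
    s = r.subjects
    im = r.imaging
    n_pac = len(s)
    rows = []
    for modality in reg.IMAGING_MODALITIES:
        sub = im[im["modality"] == modality]
        rows.append({"section": "studies", "label": modality, "stratum": "total",
                     "n": int(len(sub)), "denominator": max(len(im), 1),
                     "pct": percentage(len(sub), len(im)) if len(im) else float("nan")})
    rows.append({"section": "studies", "label": "total", "stratum": "total",
                 "n": int(len(im)), "denominator": max(len(im), 1), "pct": float("nan")})
    rows.append(_cat("subjects", "ge1_study", "total", im["subject_id"].nunique(),
                     n_pac if n_pac else 1))
    avail = int((im["images_available"] == "true").sum())
    rows.append(_cat("images_available", "true", "total", avail, max(len(im), 1)))
    return CohortSummary("imaging_catalogue", pd.DataFrame(rows),
                         {"pac": n_pac, "studies": len(im)})


SUMMARIZERS = {
    "demographics": summarize_demographics,
    "birth_decade": summarize_birth_decades,
    "anthropometry_counts": summarize_anthropometry_counts,
    "surgical_burden": summarize_surgical_burden,
    "psg_by_decade": summarize_psg,
    "imaging_catalogue": summarize_imaging,
}


def _fmt(x, ndigits=1):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, float) and x == int(x) and ndigits == 0:
        return str(int(x))
    return f"{x:.{ndigits}f}"


def render_summary(summary: CohortSummary, fmt: str = "markdown") -> str:
    """Deterministic rendering: percentages and means to 1 decimal."""
    f = summary.frame
    if fmt == "csv":
        out = f.copy()
        return out.to_csv(index=False, na_rep="", lineterminator="\n")
    if fmt == "json":
        records = []
        for _, row in f.iterrows():
            rec = {}
            for c in SUMMARY_COLUMNS:
                v = row[c]
                if isinstance(v, float) and not np.isfinite(v):
                    v = None
                elif isinstance(v, (np.integer,)):
                    v = int(v)
                elif isinstance(v, (np.floating,)):
                    v = float(v)
                rec[c] = v
            records.append(rec)
        return json.dumps({"table_id": summary.table_id,
                           "denominators": {k: int(v) for k, v in summary.denominators.items()},
                           "rows": records}, indent=2, sort_keys=True)
    if fmt == "markdown":
        lines = [f"### {summary.table_id}", "",
                 "| section | label | stratum | n (%) | mean ± SD | median (IQR) | range |",
                 "|---|---|---|---|---|---|---|"]
        for _, row in f.iterrows():
            npct = ""
            if np.isfinite(row["n"]) if isinstance(row["n"], float) else row["n"] == row["n"]:
                if pd.notna(row["n"]):
                    npct = f"{int(row['n'])}"
                    if pd.notna(row["pct"]):
                        npct += f" ({_fmt(row['pct'])})"
            meansd = ""
            if pd.notna(row["mean"]):
                meansd = f"{_fmt(row['mean'])} ± {_fmt(row['sd'])}"
            med = ""
            if pd.notna(row["median"]):
                med = f"{_fmt(row['median'])} ({_fmt(row['q1'])}, {_fmt(row['q3'])})"
            rng = ""
            if pd.notna(row["min"]):
                rng = f"{_fmt(row['min'])}–{_fmt(row['max'])}"
            lines.append(f"| {row['section']} | {row['label']} | {row['stratum']} | {npct} | {meansd} | {med} | {rng} |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def summary_from_json(text: str) -> CohortSummary:
    d = json.loads(text)
    frame = pd.DataFrame(d["rows"], columns=SUMMARY_COLUMNS)
    for c in ("n", "denominator", "pct", "mean", "sd", "median", "q1", "q3", "min", "max"):
        frame[c] = pd.to_numeric(frame[c])
    return CohortSummary(d["table_id"], frame, d.get("denominators", {}))
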