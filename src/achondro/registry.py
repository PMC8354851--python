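"""Registry container, domain vocabularies, invariants and flat-file I/O.

A :class:`Registry` bundles five tables (subjects, anthropometry, surgeries,
polysomnography, imaging) as :class:`pandas.DataFrame` objects with fixed
column schemas. Categorical fields are plain strings drawn from the
module-level vocabularies below; "unknown" is a first-class category, not a
missing value. Booleans are serialized as ``true``/``false`` (empty string
where a field may be unknown), dates as ISO-8601, and all tables are kept in
a canonical sort order so that serialization is bit-reproducible.

Ages are measured in months internally (days / 30.4375); years = months/12.
``age_last_encounter`` on the subject table is in years, matching how
registry demographics are conventionally reported.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
MONTHS_PER_YEAR = 12.0
MAX_AGE_MONTHS = 1020.0  # 85-year ceiling on measurement ages

SEXES = ("male", "female")
SITES = ("hopkins", "dupont", "texas", "wisconsin")
VITAL_STATUSES = ("living", "deceased")
BIRTH_DECADES = ("pre1980", "d1980s", "d1990s", "d2000s", "post2010")
GESTATIONS = ("preterm", "term", "post_term", "unknown")
INHERITANCES = ("de_novo", "inherited", "unknown")
DIAGNOSIS_TIMINGS = ("prenatal", "at_birth", "within_first_month", "after_first_month", "unknown")
DIAGNOSIS_MODES = ("molecular_only", "clinical_with_or_without_molecular", "unknown")
MEASURES = ("length_height", "weight", "ofc")
POSITIONS = ("supine", "standing", "unknown")
QC_FLAGS = ("unit_swap_suspect", "implausible", "within_subject_jump", "duplicate", "ok")
SURGERY_CATEGORIES = ("ent", "brain", "foramen_magnum", "spine", "extremity", "non_achondroplasia_related")
ACH_SURGERY_CATEGORIES = ("ent", "brain", "foramen_magnum", "spine", "extremity")
PSG_OUTCOMES = ("no_osa", "mild", "moderate", "severe", "inconclusive")
OSA_SEVERITY_ORDER = {"no_osa": 0, "inconclusive": 0, "mild": 1, "moderate": 2, "severe": 3}
IMAGING_MODALITIES = ("xray", "ct", "mri", "echocardiogram", "ultrasound")

TRISTATE = ("true", "false", "unknown")
BOOLEAN = ("true", "false")

SUBJECT_COLUMNS = [
    "subject_id", "sex", "birth_date", "site", "vital_status",
    "age_last_encounter", "gestation", "gestational_weeks", "inheritance",
    "adopted", "diagnosis_timing", "diagnosis_mode", "limb_lengthening",
    "gh_deficient", "gh_treated", "trial_participant", "surgical_history_known",
]
ANTHROPOMETRY_COLUMNS = ["subject_id", "measure", "age_months", "value", "position", "qc_flags"]
SURGERY_COLUMNS = ["subject_id", "category", "procedure", "event_date", "date_known"]
PSG_COLUMNS = ["subject_id", "age_at_study", "outcome", "is_first_study"]
IMAGING_COLUMNS = ["subject_id", "modality", "study_date", "body_region", "images_available"]

_FLOAT_COLUMNS = {
    "subjects": ["age_last_encounter", "gestational_weeks"],
    "anthropometry": ["age_months", "value"],
    "psg": ["age_at_study"],
}

TABLE_FILES = {
    "subjects": "subjects.csv",
    "anthropometry": "anthropometry.csv",
    "surgeries": "surgeries.csv",
    "psg": "psg.csv",
    "imaging": "imaging.csv",
}

TABLE_COLUMNS = {
    "subjects": SUBJECT_COLUMNS,
    "anthropometry": ANTHROPOMETRY_COLUMNS,
    "surgeries": SURGERY_COLUMNS,
    "psg": PSG_COLUMNS,
    "imaging": IMAGING_COLUMNS,
}

_SORT_KEYS = {
    "subjects": ["subject_id"],
    "anthropometry": ["subject_id", "measure", "age_months", "value"],
    "surgeries": ["subject_id", "category", "event_date", "procedure"],
    "psg": ["subject_id", "age_at_study", "outcome"],
    "imaging": ["subject_id", "modality", "study_date", "body_region"],
}


class RegistryError(Exception):
    """Raised when a registry violates its schema or invariants."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    for c in _FLOAT_COLUMNS.get(name, []):
        df[c] = df[c].astype(float)
    return df


@dataclasses.dataclass
class Registry:
    """Five-table achondroplasia natural-history registry."""

    subjects: pd.DataFrame = dataclasses.field(default_factory=lambda: _empty_table("subjects"))
    anthropometry: pd.DataFrame = dataclasses.field(default_factory=lambda: _empty_table("anthropometry"))
    surgeries: pd.DataFrame = dataclasses.field(default_factory=lambda: _empty_table("surgeries"))
    psg: pd.DataFrame = dataclasses.field(default_factory=lambda: _empty_table("psg"))
    imaging: pd.DataFrame = dataclasses.field(default_factory=lambda: _empty_table("imaging"))
    provenance: dict = dataclasses.field(default_factory=dict)

    def tables(self):
        return {
            "subjects": self.subjects,
            "anthropometry": self.anthropometry,
            "surgeries": self.surgeries,
            "psg": self.psg,
            "imaging": self.imaging,
        }

    def copy(self) -> "Registry":
        return Registry(
            subjects=self.subjects.copy(),
            anthropometry=self.anthropometry.copy(),
            surgeries=self.surgeries.copy(),
            psg=self.psg.copy(),
            imaging=self.imaging.copy(),
            provenance=dict(self.provenance),
        )

    def canonicalize(self) -> "Registry":
        """Return a copy with canonical row order, column order and index."""
        out = {}
        for name, df in self.tables().items():
            df = df[TABLE_COLUMNS[name]].copy()
            df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
            out[name] = df
        return Registry(provenance=dict(self.provenance), **out)

    def validate(self) -> list:
        """Collect invariant violations (empty list means valid)."""
        return validate_registry(self)

    def equals(self, other: "Registry") -> bool:
        a, b = self.canonicalize(), other.canonicalize()
        for name in TABLE_FILES:
            da, db = a.tables()[name], b.tables()[name]
            if len(da) != len(db):
                return False
            try:
                pd.testing.assert_frame_equal(da, db, check_dtype=False)
            except AssertionError:
                return False
        return True


def derive_birth_decade(birth_date) -> str:
    """Map a birth date to its registry birth-decade category.

    Boundaries are closed on the decade-start date: before 1 Jan 1980 is
    ``pre1980``; 1 Jan 2010 and later is ``post2010``.
    """
    d = _as_date(birth_date)
    if d < _dt.date(1980, 1, 1):
        return "pre1980"
    if d < _dt.date(1990, 1, 1):
        return "d1980s"
    if d < _dt.date(2000, 1, 1):
        return "d1990s"
    if d < _dt.date(2010, 1, 1):
        return "d2000s"
    return "post2010"


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def months_between(birth_date, event_date) -> float:
    """Elapsed age in months between two dates (days / 30.4375)."""
    return (_as_date(event_date) - _as_date(birth_date)).days / DAYS_PER_MONTH


def months_to_years(months) -> float:
    return np.asarray(months, dtype=float) / MONTHS_PER_YEAR if np.ndim(months) else float(months) / MONTHS_PER_YEAR


def _check_vocab(violations, df, table, column, vocab):
    if column not in df.columns:
        violations.append(f"{table}: missing required column '{column}'")
        return
    bad = sorted(set(df[column].astype(str)) - set(vocab))
    if bad:
        violations.append(f"{table}.{column}: values outside vocabulary: {bad[:5]}")


def validate_registry(r: Registry) -> list:
    v = []
    for name, df in r.tables().items():
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        for c in missing:
            v.append(f"{name}: missing required column '{c}'")
    if v:
        return v

    s = r.subjects
    ids = s["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        v.append(f"subjects: duplicate subject_id {dupes[:5]}")
    known = set(ids)
    for name in ("anthropometry", "surgeries", "psg", "imaging"):
        df = r.tables()[name]
        if len(df):
            orphans = sorted(set(df["subject_id"].astype(str)) - known)
            if orphans:
                v.append(f"{name}: subject_id not in subjects table: {orphans[:10]}")

    _check_vocab(v, s, "subjects", "sex", SEXES)
    _check_vocab(v, s, "subjects", "site", SITES)
    _check_vocab(v, s, "subjects", "vital_status", VITAL_STATUSES)
    _check_vocab(v, s, "subjects", "gestation", GESTATIONS)
    _check_vocab(v, s, "subjects", "inheritance", INHERITANCES)
    _check_vocab(v, s, "subjects", "adopted", TRISTATE)
    _check_vocab(v, s, "subjects", "diagnosis_timing", DIAGNOSIS_TIMINGS)
    _check_vocab(v, s, "subjects", "diagnosis_mode", DIAGNOSIS_MODES)
    for col in ("limb_lengthening", "gh_deficient", "gh_treated", "trial_participant", "surgical_history_known"):
        _check_vocab(v, s, "subjects", col, BOOLEAN)

    if len(s):
        age = pd.to_numeric(s["age_last_encounter"], errors="coerce")
        if age.isna().any():
            v.append("subjects.age_last_encounter: non-numeric values")
        elif (age < 0).any():
            v.append("subjects.age_last_encounter: negative ages")
        for bd in s["birth_date"].astype(str):
            try:
                _as_date(bd)
            except ValueError:
                v.append(f"subjects.birth_date: unparseable date '{bd}'")
                break
        weeks = pd.to_numeric(s["gestational_weeks"], errors="coerce")
        preterm = s["gestation"].astype(str) == "preterm"
        bad = preterm & weeks.notna() & (weeks >= 37)
        if bad.any():
            v.append(
                "subjects: preterm subjects with gestational_weeks >= 37: "
                f"{sorted(s.loc[bad, 'subject_id'])[:5]}"
            )

    a = r.anthropometry
    _check_vocab(v, a, "anthropometry", "measure", MEASURES)
    _check_vocab(v, a, "anthropometry", "position", POSITIONS)
    if len(a):
        val = pd.to_numeric(a["value"], errors="coerce")
        agem = pd.to_numeric(a["age_months"], errors="coerce")
        if val.isna().any() or (val <= 0).any():
            v.append("anthropometry.value: values must be positive numbers")
        if agem.isna().any() or (agem < 0).any() or (agem > MAX_AGE_MONTHS).any():
            v.append(f"anthropometry.age_months: ages must lie in [0, {MAX_AGE_MONTHS:g}]")
        flags = a["qc_flags"].astype(str)
        tokens = set()
        for f in flags:
            if f:
                tokens.update(f.split(";"))
        bad = sorted(tokens - set(QC_FLAGS))
        if bad:
            v.append(f"anthropometry.qc_flags: unknown flags {bad}")

    _check_vocab(v, r.surgeries, "surgeries", "category", SURGERY_CATEGORIES)
    _check_vocab(v, r.surgeries, "surgeries", "date_known", BOOLEAN)
    _check_vocab(v, r.psg, "psg", "outcome", PSG_OUTCOMES)
    _check_vocab(v, r.psg, "psg", "is_first_study", BOOLEAN)
    _check_vocab(v, r.imaging, "imaging", "modality", IMAGING_MODALITIES)
    _check_vocab(v, r.imaging, "imaging", "images_available", BOOLEAN)
    return v


def birth_decades(subjects: pd.DataFrame) -> pd.Series:
    """Vectorized birth-decade derivation for a subjects table."""
    return subjects["birth_date"].map(derive_birth_decade)


def read_registry(paths) -> Registry:
    """Read a registry from CSV files.

    ``paths`` is either a directory containing the canonical file names
    (subjects.csv, anthropometry.csv, surgeries.csv, psg.csv, imaging.csv)
    or a mapping from table name to file path. Invariant violations are
    collected across all tables and raised together as a
    :class:`RegistryError`.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / fname for name, fname in TABLE_FILES.items()}
    frames = {}
    for name in TABLE_FILES:
        p = Path(paths[name])
        if not p.exists():
            raise RegistryError(f"{name}: file not found: {p}")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise RegistryError([f"{name}: missing required column '{c}'" for c in missing])
        for c in _FLOAT_COLUMNS.get(name, []):
            df[c] = pd.to_numeric(df[c].replace("", np.nan))
        frames[name] = df
    reg = Registry(**frames).canonicalize()
    violations = reg.validate()
    if violations:
        raise RegistryError(violations)
    return reg


def write_registry(r: Registry, directory) -> dict:
    """Write a registry to ``directory`` as five canonical CSV files.

    Row order (sorted by subject_id then age/date), column order and value
    formatting are fixed, so writing the same registry twice is
    byte-identical, and ``read_registry`` on the output reproduces an equal
    registry. Unknown dates and missing numerics serialize as empty strings.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    canon = r.canonicalize()
    out = {}
    for name, fname in TABLE_FILES.items():
        p = directory / fname
        canon.tables()[name].to_csv(p, index=False, na_rep="", lineterminator="\n")
        out[name] = p
    return out
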