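"""External average-stature reference curves (LMS or direct-percentile).

A reference table carries, per sex and measure, either LMS triples
(Box–Cox skewness L, median M, coefficient of variation S) or direct
percentile columns (p5/p50/p95) on an age grid in months. Centiles of an
LMS row follow the standard transformation::

    C_p(age) = M * (1 + L*S*z_p)**(1/L)      (L != 0)
    C_p(age) = M * exp(S*z_p)                (L == 0)

where z_p is the standard-normal quantile of the percentile. Between grid
ages, L, M and S (or the direct percentile values) are interpolated
linearly.

The bundled :func:`make_average_stature_reference` builds a synthetic
average-stature standard shaped like the WHO/CDC charts (anchored at their
published birth moments) for use when no external table is supplied; it is
a stand-in, not the WHO/CDC tables themselves.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from achondro.registry import MEASURES, SEXES

REFERENCE_COLUMNS = ["sex", "measure", "age_months", "kind", "L", "M", "S", "p5", "p50", "p95"]


class ReferenceError(Exception):
    pass


@dataclasses.dataclass
class ReferenceCurve:
    """A reference percentile table; one row per (sex, measure, age)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REFERENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ReferenceError(f"reference table missing columns {missing}")
        t = self.table[REFERENCE_COLUMNS].copy()
        for c in ("age_months", "L", "M", "S", "p5", "p50", "p95"):
            t[c] = pd.to_numeric(t[c], errors="coerce")
        kinds = set(t["kind"].astype(str))
        if not kinds <= {"lms", "pct"}:
            raise ReferenceError(f"unknown reference kind(s) {sorted(kinds - {'lms', 'pct'})}")
        lms_rows = t["kind"] == "lms"
        if lms_rows.any() and t.loc[lms_rows, ["M", "S"]].isna().any().any():
            raise ReferenceError("lms rows must populate L, M, S")
        if (~lms_rows).any() and t.loc[~lms_rows, ["p5", "p50", "p95"]].isna().any().any():
            raise ReferenceError("pct rows must populate p5, p50, p95")
        self.table = t.sort_values(["sex", "measure", "age_months"], kind="mergesort").reset_index(drop=True)

    def block(self, sex: str, measure: str) -> pd.DataFrame:
        b = self.table[(self.table["sex"] == sex) & (self.table["measure"] == measure)]
        if b.empty:
            raise ReferenceError(f"reference has no rows for sex={sex}, measure={measure}")
        return b

    def age_range(self, sex: str, measure: str) -> tuple:
        b = self.block(sex, measure)
        return float(b["age_months"].min()), float(b["age_months"].max())


def read_reference(path) -> ReferenceCurve:
    """Read a reference.csv table (UTF-8, RFC-4180)."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    return ReferenceCurve(df)


def write_reference(ref: ReferenceCurve, path) -> Path:
    p = Path(path)
    ref.table.to_csv(p, index=False, na_rep="", lineterminator="\n")
    return p


def _lms_centile(L, M, S, z):
    L, M, S = np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    safe_L = np.where(L == 0, 1.0, L)
    general = M * np.power(1.0 + safe_L * S * z, 1.0 / safe_L)
    return np.where(L == 0, M * np.exp(S * z), general)


def evaluate_reference(ref: ReferenceCurve, sex: str, measure: str, age_months, percentile) -> np.ndarray | float:
    """Evaluate a reference percentile at one or more ages (months).

    ``percentile`` is on the 0–100 scale (5, 50, 95, ...). LMS rows are
    evaluated through the LMS transform with L/M/S interpolated linearly in
    age; direct-percentile rows are interpolated linearly (only p5/p50/p95
    available). Ages outside the table's range raise ``ReferenceError``.
    """
    b = ref.block(sex, measure)
    ages = np.atleast_1d(np.asarray(age_months, dtype=float))
    lo, hi = float(b["age_months"].min()), float(b["age_months"].max())
    if (ages < lo - 1e-9).any() or (ages > hi + 1e-9).any():
        raise ReferenceError(f"requested age outside reference range [{lo:g}, {hi:g}] months")
    ages = np.clip(ages, lo, hi)
    x = b["age_months"].to_numpy(float)
    kind = b["kind"].iloc[0]
    if kind == "lms":
        z = norm.ppf(float(percentile) / 100.0)
        L = np.interp(ages, x, b["L"].fillna(1.0).to_numpy(float))
        M = np.interp(ages, x, b["M"].to_numpy(float))
        S = np.interp(ages, x, b["S"].to_numpy(float))
        vals = _lms_centile(L, M, S, z)
    else:
        col = {5: "p5", 50: "p50", 95: "p95"}.get(int(percentile))
        if col is None or abs(float(percentile) - int(percentile)) > 1e-9:
            raise ReferenceError("direct-percentile references carry only p5, p50 and p95")
        vals = np.interp(ages, x, b[col].to_numpy(float))
    return vals if np.ndim(age_months) else float(vals[0])


# ---------------------------------------------------------------------------
# Synthetic average-stature standard (WHO/CDC-like shape; stand-in table)
# ---------------------------------------------------------------------------

# Median anchors in months -> cm (length/height, OFC) or kg (weight), plus a
# constant coefficient of variation per measure. Birth rows match the WHO
# moments used for birth comparisons (length 49.9/49.1 cm, weight 3.3/3.2 kg,
# OFC 34.5/33.9 cm for males/females).
_MEDIAN_ANCHORS = {
    ("male", "length_height"): (
        {0: 49.9, 3: 61.4, 6: 67.6, 9: 72.0, 12: 75.7, 18: 82.3, 24: 87.1,
         36: 95.3, 48: 102.3, 60: 109.2, 84: 121.7, 120: 137.5, 144: 149.1,
         168: 163.2, 192: 173.5, 216: 176.8},
        0.037,
    ),
    ("female", "length_height"): (
        {0: 49.1, 3: 59.8, 6: 65.7, 9: 70.1, 12: 74.0, 18: 80.7, 24: 85.7,
         36: 94.1, 48: 101.6, 60: 108.4, 84: 120.8, 120: 138.2, 144: 151.5,
         168: 160.4, 192: 163.0, 216: 163.3},
        0.038,
    ),
    ("male", "weight"): (
        {0: 3.3, 3: 6.4, 6: 7.9, 12: 9.6, 24: 12.2, 36: 14.3, 60: 18.5,
         84: 23.0, 120: 32.0, 144: 40.5, 168: 51.0, 192: 61.0, 216: 68.0},
        0.17,
    ),
    ("female", "weight"): (
        {0: 3.2, 3: 5.8, 6: 7.3, 12: 8.9, 24: 11.5, 36: 13.9, 60: 18.0,
         84: 22.5, 120: 33.0, 144: 42.0, 168: 51.5, 192: 56.5, 216: 59.0},
        0.18,
    ),
    ("male", "ofc"): (
        {0: 34.5, 3: 40.5, 6: 43.3, 12: 46.1, 24: 48.3, 36: 49.5, 48: 50.2, 60: 50.8},
        0.033,
    ),
    ("female", "ofc"): (
        {0: 33.9, 3: 39.5, 6: 42.2, 12: 44.9, 24: 47.2, 36: 48.5, 48: 49.3, 60: 49.9},
        0.034,
    ),
}

# Weight is right-skewed: evaluated as log-normal (L = 0); length and OFC as
# normal (L = 1).
_REFERENCE_L = {"length_height": 1.0, "weight": 0.0, "ofc": 1.0}


def reference_median_function(sex: str, measure: str):
    """Monotone interpolant through the synthetic standard's median anchors."""
    anchors, _ = _MEDIAN_ANCHORS[(sex, measure)]
    x = np.array(sorted(anchors), float)
    y = np.array([anchors[k] for k in sorted(anchors)], float)
    return PchipInterpolator(x, y)


def make_average_stature_reference(step_months: float = 1.0) -> ReferenceCurve:
    """Build the bundled synthetic average-stature LMS reference table.

    Medians follow a monotone (PCHIP) interpolant through the anchor points
    above, sampled monthly up to 36 months and quarterly thereafter; S is
    constant per measure. The result stands in for an external CDC/WHO
    table in comparisons and demonstrations.
    """
    rows = []
    for (sex, measure), (anchors, s_coef) in _MEDIAN_ANCHORS.items():
        top = max(anchors)
        grid = list(np.arange(0.0, min(36.0, top) + 1e-9, step_months))
        if top > 36.0:
            grid += list(np.arange(39.0, top + 1e-9, 3.0))
        f = reference_median_function(sex, measure)
        for age in grid:
            rows.append({
                "sex": sex, "measure": measure, "age_months": float(age),
                "kind": "lms", "L": _REFERENCE_L[measure], "M": float(f(age)),
                "S": s_coef, "p5": np.nan, "p50": np.nan, "p95": np.nan,
            })
    return ReferenceCurve(pd.DataFrame(rows))


# Published sex-specific achondroplasia birth moments (mean, SD) used for the
# presumed-term rule: values in cm for length_height and OFC, kg for weight.
ACH_BIRTH_REFERENCE = {
    ("male", "length_height"): (47.90, 3.18),
    ("female", "length_height"): (47.28, 2.85),
    ("male", "weight"): (3.41, 0.50),
    ("female", "weight"): (3.32, 0.40),
    ("male", "ofc"): (37.1, 3.2),
    ("female", "ofc"): (36.4, 2.3),
}
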