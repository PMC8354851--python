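"""Printed counts from a published 1,374-subject multicenter achondroplasia
natural-history cohort, and a deterministic fixture registry rebuilt from
them.

The constants below transcribe the published summary tables (demographics
by vital status, birth-decade characteristics, anthropometry counts by
age band, surgical burden, sleep studies by decade, imaging catalogue).
:func:`fixture_registry` reconstructs a registry whose category counts
reproduce those tables, so the summary engine's arithmetic (counts,
denominators, half-up percentages) can be checked against the printed
values. Continuous fields (ages, dates) are filled with plausible
deterministic stand-ins; they are not part of the printed-count checks.

Two printed rows are mutually inconsistent and cannot both be matched by
any registry: the per-category surgical subject counts sum to 1,777 while
the distinct-category distribution implies 1,782, and the sleep-study
outcome rows sum to 662 subjects against 677 with at least one study. The
fixture matches the per-category counts and the per-decade sleep-study
counts exactly; the conflicting marginals come out within 5 subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from achondro import registry as reg
from achondro.registry import Registry

N_PAC = 1374

# --- demographics (total / deceased splits; living = total - deceased) ----
SEX = {"male": (704, 8), "female": (670, 12)}
SITE = {"hopkins": (299, 2), "dupont": (384, 3), "texas": (218, 8), "wisconsin": (473, 7)}
INHERITANCE = {"de_novo": (1044, 15), "inherited": (191, 1), "unknown": (139, 4)}
GESTATION = {"preterm": (174, 0), "term": (1008, 11), "post_term": (15, 0), "unknown": (177, 9)}
ADOPTED = {"true": (86, 0), "false": (N_PAC - 86, 20), "unknown": (0, 0)}
FLAGS = {"limb_lengthening": 17, "gh_deficient": 4, "gh_treated": 2, "trial_participant": 12}
N_DECEASED = 20

# --- birth decades --------------------------------------------------------
DECADE_N = {"pre1980": 234, "d1980s": 231, "d1990s": 314, "d2000s": 356, "post2010": 239}
DECADE_DECEASED = {"pre1980": 15, "d1980s": 3, "d1990s": 2, "d2000s": 0, "post2010": 0}
DIAGNOSIS_TIMING = {  # prenatal, at_birth, within_first_month, after_first_month, unknown
    "pre1980": (0, 40, 16, 51, 127),
    "d1980s": (13, 64, 42, 39, 73),
    "d1990s": (53, 72, 51, 86, 52),
    "d2000s": (73, 100, 74, 80, 29),
    "post2010": (76, 67, 39, 45, 12),
}
DIAGNOSIS_MODE = {  # molecular_only, clinical_with_or_without_molecular, unknown
    "pre1980": (1, 85, 148),
    "d1980s": (2, 138, 91),
    "d1990s": (10, 239, 65),
    "d2000s": (17, 315, 24),
    "post2010": (19, 213, 7),
}

# --- anthropometry counts by measure and age-at-last-contact band ---------
# (points, contributing subjects) for <10 y, 10-<18 y, >=18 y
ANTHRO_COUNTS = {
    "length_height": ((4725, 565), (4466, 369), (3553, 384)),
    "weight": ((5582, 555), (5160, 361), (4217, 376)),
    "ofc": ((3610, 558), (3269, 366), (2434, 315)),
}
BAND_CONTRIBUTORS = (579, 374, 412)   # any measure, per band; total 1,365
TOTAL_POINTS = 37016

# --- surgical burden ------------------------------------------------------
SURGERY_EVER, SURGERY_NEVER, SURGERY_UNKNOWN = 1094, 167, 113
SURGERY_SUBJECTS = {"ent": 893, "extremity": 291, "foramen_magnum": 281, "spine": 175, "brain": 137}
SURGERY_PROCEDURES = {"ent": 2803, "brain": 326, "foramen_magnum": 314, "spine": 425, "extremity": 684}
DISTINCT_CATEGORY_DIST = {1: 594, 2: 359, 3: 103, 4: 29, 5: 9}

# --- sleep studies --------------------------------------------------------
PSG_GE1 = {"pre1980": 35, "d1980s": 79, "d1990s": 127, "d2000s": 242, "post2010": 194}
PSG_MODSEV = {"pre1980": 16, "d1980s": 16, "d1990s": 38, "d2000s": 99, "post2010": 91}
PSG_AGE_MEAN = {"pre1980": 31.1, "d1980s": 5.6, "d1990s": 3.0, "d2000s": 2.2, "post2010": 0.8}

# --- imaging --------------------------------------------------------------
IMAGING_COUNTS = {"xray": 7201, "ct": 1069, "mri": 1826, "echocardiogram": 166, "ultrasound": 465}
IMAGING_SUBJECTS = 1251
IMAGING_AVAILABLE = 8099   # 75.5% of 10,727 studies

_DECADE_BIRTH = {"pre1980": "1970-06-15", "d1980s": "1985-06-15", "d1990s": "1995-06-15",
                 "d2000s": "2005-06-15", "post2010": "2013-06-15"}

# ages at last encounter (years) chosen so birth-decade membership and the
# <10 / 10-<18 / >=18 age-band sizes (588 / 374 / 412, the nine
# non-contributors all in the youngest band) are both satisfied
_DECADE_AGE_PLAN = {
    "pre1980": [(234, 34.9)],
    "d1980s": [(178, 20.0), (53, 15.0)],
    "d1990s": [(314, 14.8)],
    "d2000s": [(7, 12.0), (349, 8.0)],
    "post2010": [(239, 3.4)],
}


def _fill_column(n_rows, deceased_idx, counts):
    """Assign categories to rows: deceased rows first per the deceased
    counts, then living rows per (total - deceased), in index order."""
    values = [None] * n_rows
    living_idx = [i for i in range(n_rows) if i not in set(deceased_idx)]
    di = li = 0
    for label, (total, deceased) in counts.items():
        for _ in range(deceased):
            values[deceased_idx[di]] = label
            di += 1
        for _ in range(total - deceased):
            values[living_idx[li]] = label
            li += 1
    assert di == len(deceased_idx) and li == len(living_idx)
    return values


def _surgery_assignment():
    """0-1 fill: which ever-surgery subjects fall in which categories.

    Subject capacities follow the distinct-category distribution adjusted
    by the minimal 5-subject correction that makes the printed marginals
    jointly feasible (599x1 instead of 594x1, 354x2 instead of 359x2);
    categories then claim the subjects with the largest remaining capacity
    (max-fill construction).
    """
    capacities = [5] * 9 + [4] * 29 + [3] * 103 + [2] * 354 + [1] * 599
    caps = np.array(capacities, dtype=int)
    membership = {c: [] for c in SURGERY_SUBJECTS}
    for cat, n_c in sorted(SURGERY_SUBJECTS.items(), key=lambda kv: -kv[1]):
        order = np.lexsort((np.arange(len(caps)), -caps))
        chosen = [i for i in order if caps[i] > 0][:n_c]
        if len(chosen) < n_c:
            raise RuntimeError("surgery fill infeasible")
        membership[cat] = sorted(chosen)
        caps[chosen] -= 1
    if caps.sum() != 0:
        raise RuntimeError("surgery fill left unassigned capacity")
    return membership


def fixture_registry() -> Registry:
    """Deterministic registry reproducing the printed cohort tables."""
    decades = []
    for d in reg.BIRTH_DECADES:
        decades += [d] * DECADE_N[d]
    n = len(decades)
    assert n == N_PAC

    deceased_idx = []
    offset = 0
    for d in reg.BIRTH_DECADES:
        deceased_idx += list(range(offset, offset + DECADE_DECEASED[d]))
        offset += DECADE_N[d]
    vital = ["deceased" if i in set(deceased_idx) else "living" for i in range(n)]

    timing, mode, age_last = [], [], []
    for d in reg.BIRTH_DECADES:
        for label, count in zip(reg.DIAGNOSIS_TIMINGS, DIAGNOSIS_TIMING[d]):
            timing += [label] * count
        for label, count in zip(reg.DIAGNOSIS_MODES, DIAGNOSIS_MODE[d]):
            mode += [label] * count
        for count, age in _DECADE_AGE_PLAN[d]:
            age_last += [age] * count

    sex = _fill_column(n, deceased_idx, SEX)
    site = _fill_column(n, deceased_idx, SITE)
    inheritance = _fill_column(n, deceased_idx, INHERITANCE)
    gestation = _fill_column(n, deceased_idx, GESTATION)
    adopted = _fill_column(n, deceased_idx, ADOPTED)
    flags = {}
    for name, count in FLAGS.items():
        flags[name] = _fill_column(n, deceased_idx, {"true": (count, 0), "false": (n - count, N_DECEASED)})

    weeks = {"preterm": 34.0, "term": 39.0, "post_term": 42.5, "unknown": np.nan}
    subjects = pd.DataFrame({
        "subject_id": [f"P{i:05d}" for i in range(n)],
        "sex": sex,
        "birth_date": [_DECADE_BIRTH[d] for d in decades],
        "site": site,
        "vital_status": vital,
        "age_last_encounter": age_last,
        "gestation": gestation,
        "gestational_weeks": [weeks[g] for g in gestation],
        "inheritance": inheritance,
        "adopted": adopted,
        "diagnosis_timing": timing,
        "diagnosis_mode": mode,
        "limb_lengthening": flags["limb_lengthening"],
        "gh_deficient": flags["gh_deficient"],
        "gh_treated": flags["gh_treated"],
        "trial_participant": flags["trial_participant"],
        "surgical_history_known": "true",
    })

    # --- age bands and anthropometry -------------------------------------
    age = subjects["age_last_encounter"].to_numpy(float)
    band_idx = {
        0: np.flatnonzero(age < 10.0),
        1: np.flatnonzero((age >= 10.0) & (age < 18.0)),
        2: np.flatnonzero(age >= 18.0),
    }
    assert [len(band_idx[b]) for b in range(3)] == [588, 374, 412]
    # contributor layout per band: offsets chosen so the per-measure
    # contributor counts and the any-measure union both match
    contributor_plan = {
        0: {"length_height": (0, 565), "weight": (24, 555), "ofc": (0, 558)},
        1: {"length_height": (0, 369), "weight": (13, 361), "ofc": (0, 366)},
        2: {"length_height": (0, 384), "weight": (36, 376), "ofc": (0, 315)},
    }
    base_value = {"length_height": 100.0, "weight": 20.0, "ofc": 45.0}
    anthro_rows = []
    for b in range(3):
        for mi, measure in enumerate(reg.MEASURES):
            points, n_contrib = ANTHRO_COUNTS[measure][b]
            start, count = contributor_plan[b][measure]
            assert count == n_contrib
            contribs = band_idx[b][start:start + count]
            base, rem = divmod(points, count)
            for j, subj in enumerate(contribs):
                k = base + (1 if j < rem else 0)
                for p in range(k):
                    anthro_rows.append((subjects.at[subj, "subject_id"], measure,
                                        6.0 + p, base_value[measure], "unknown", ""))
    anthropometry = pd.DataFrame(anthro_rows, columns=reg.ANTHROPOMETRY_COLUMNS)
    assert len(anthropometry) == TOTAL_POINTS

    # --- surgeries --------------------------------------------------------
    membership = _surgery_assignment()
    ever_rows = [i for i in range(n)]  # ever subjects are the first 1,094 rows
    surgery_rows = []
    proc_name = {"ent": "adenotonsillectomy", "brain": "vp_shunt",
                 "foramen_magnum": "cervicomedullary_decompression",
                 "spine": "laminectomy", "extremity": "osteotomy"}
    for cat, members in membership.items():
        total_proc = SURGERY_PROCEDURES[cat]
        base, rem = divmod(total_proc, len(members))
        for j, local in enumerate(members):
            subj = ever_rows[local]
            k = base + (1 if j < rem else 0)
            for p in range(k):
                surgery_rows.append((subjects.at[subj, "subject_id"], cat, proc_name[cat],
                                     f"2010-01-{(p % 28) + 1:02d}", "true"))
    surgeries = pd.DataFrame(surgery_rows, columns=reg.SURGERY_COLUMNS)
    for cat in SURGERY_SUBJECTS:
        assert surgeries[surgeries["category"] == cat]["subject_id"].nunique() == SURGERY_SUBJECTS[cat]

    # history flag: never = confirmed negative, unknown = no validated history
    history = np.array(["true"] * n, dtype=object)
    history[SURGERY_EVER + SURGERY_NEVER:] = "false"
    subjects["surgical_history_known"] = history
    assert n - SURGERY_EVER - SURGERY_NEVER == SURGERY_UNKNOWN

    # --- sleep studies ----------------------------------------------------
    psg_rows = []
    offset = 0
    for d in reg.BIRTH_DECADES:
        block = list(range(offset, offset + DECADE_N[d]))
        offset += DECADE_N[d]
        with_psg = block[:PSG_GE1[d]]
        for j, subj in enumerate(with_psg):
            if j < PSG_MODSEV[d]:
                outcome = "moderate" if j % 2 == 0 else "severe"
            else:
                outcome = "mild" if j % 2 == 0 else "no_osa"
            psg_rows.append((subjects.at[subj, "subject_id"], PSG_AGE_MEAN[d], outcome, "true"))
    psg = pd.DataFrame(psg_rows, columns=reg.PSG_COLUMNS)

    # --- imaging ----------------------------------------------------------
    imaging_rows = []
    study_no = 0
    for modality in reg.IMAGING_MODALITIES:
        for _ in range(IMAGING_COUNTS[modality]):
            subj = study_no % IMAGING_SUBJECTS
            available = "true" if study_no < IMAGING_AVAILABLE else "false"
            imaging_rows.append((subjects.at[subj, "subject_id"], modality,
                                 "2015-06-01", "spine", available))
            study_no += 1
    imaging = pd.DataFrame(imaging_rows, columns=reg.IMAGING_COLUMNS)

    r = Registry(subjects=subjects, anthropometry=anthropometry, surgeries=surgeries,
                 psg=psg, imaging=imaging,
                 provenance={"source": "achondro.published_cohort.fixture_registry"})
    return r.canonicalize()
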