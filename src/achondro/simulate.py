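"""Synthetic achondroplasia registry generator with known ground truth.

The generator emulates the statistical structure of a multicenter
natural-history registry: ~50/50 sex split, five birth decades, ~12.7%
preterm, ~76% de novo inheritance, heteroscedastic sex-specific growth
that diverges from an average-stature standard in infancy, right-skewed
weight, rapid first-year head growth approaching a plateau, five
achondroplasia-related surgical categories, graded sleep-study outcomes,
and an imaging catalogue. Every default rate is an observed proportion
from published multicenter achondroplasia cohort tables; processes the
literature does not describe (visit spacing, surgery age distributions,
follow-up truncation) are documented stand-ins.

Growth model
------------
Stature (cm) for a subject of age ``t`` months::

    median(t) = birth + a*tau*(1 - exp(-t/tau)) + U(t/12)

where ``a`` (cm/month) and ``tau`` (months) shape the rapid infancy rise
and ``U`` integrates a piecewise-linear childhood velocity (cm/year) that
declines to exactly zero at the plateau age. OFC (cm) follows a
saturating exponential ``c + A*(1 - exp(-k t))``; weight (kg) is
multiplicative log-normal around a monotone median interpolant. Each
subject carries a persistent standard-normal growth effect ``b`` so that
trajectories are internally consistent (a large infant stays large), plus
small independent measurement noise per visit.

Determinism: the root seed is expanded into per-subject substreams
(``default_rng([seed, k])``), so subject ``k``'s data are invariant to the
cohort size.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from achondro import registry as reg
from achondro.registry import Registry, DAYS_PER_MONTH

# ---------------------------------------------------------------------------
# Growth models
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GrowthModelParams:
    """Parametric sex- and measure-specific growth process.

    Exactly one of the three parameter families is used, keyed by
    ``measure``:

    - ``length_height``: infancy exponential + piecewise-linear velocity
      (``velocity_knots`` in (years, cm/year), final knot at zero velocity
      = the stature plateau age).
    - ``ofc``: saturating exponential with birth value ``birth``, asymptote
      ``plateau_value`` and rate ``k_per_month``.
    - ``weight``: monotone (PCHIP) median through ``median_anchors``
      (months -> kg) with age-increasing log-scale SD (right skew).

    ``sd_birth``/``sd_adult`` give the between-subject SD at birth and at
    216 months (linear in age between); ``sigma_meas`` is the per-visit
    measurement SD (additive cm, or log-scale for weight).
    """

    measure: str
    birth: float = float("nan")
    sd_birth: float = 0.0
    sd_adult: float = 0.0
    sigma_meas: float = 0.0
    # stature
    infancy_amp: float = 0.0        # cm/month at birth
    infancy_tau: float = 8.0        # months
    velocity_knots: tuple = ()      # ((years, cm/yr), ..., (plateau_years, 0.0))
    # ofc
    plateau_value: float = float("nan")
    k_per_month: float = float("nan")
    # weight
    median_anchors: tuple = ()      # ((months, kg), ...)

    def __post_init__(self):
        if self.measure not in reg.MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.measure == "weight" and self.median_anchors:
            x = [a for a, _ in self.median_anchors]
            y = [v for _, v in self.median_anchors]
            self._weight_median = PchipInterpolator(np.array(x, float), np.array(y, float))

    # -- median curve -------------------------------------------------
    def median(self, age_months):
        t = np.asarray(age_months, dtype=float)
        if self.measure == "length_height":
            infancy = self.infancy_amp * self.infancy_tau * (1.0 - np.exp(-t / self.infancy_tau))
            out = self.birth + infancy + self._velocity_integral(t / 12.0)
        elif self.measure == "ofc":
            amp = self.plateau_value - self.birth
            out = self.birth + amp * (1.0 - np.exp(-self.k_per_month * t))
        else:
            top = self.median_anchors[-1][0]
            out = self._weight_median(np.clip(t, 0.0, top))
        return out if np.ndim(age_months) else float(out)

    def sd(self, age_months):
        t = np.asarray(age_months, dtype=float)
        frac = np.clip(t / 216.0, 0.0, 1.0)
        out = self.sd_birth + (self.sd_adult - self.sd_birth) * frac
        return out if np.ndim(age_months) else float(out)

    # -- stature velocity ---------------------------------------------
    def velocity(self, age_months):
        """Instantaneous growth velocity in cm/year (stature only)."""
        if self.measure != "length_height":
            raise ValueError("velocity is defined for length_height models")
        t = np.asarray(age_months, dtype=float)
        infancy = 12.0 * self.infancy_amp * np.exp(-t / self.infancy_tau)
        ty = t / 12.0
        kx = np.array([k[0] for k in self.velocity_knots])
        kv = np.array([k[1] for k in self.velocity_knots])
        u = np.interp(ty, kx, kv, left=kv[0], right=0.0)
        out = infancy + u
        return out if np.ndim(age_months) else float(out)

    def _velocity_integral(self, t_years):
        kx = np.array([k[0] for k in self.velocity_knots])
        kv = np.array([k[1] for k in self.velocity_knots])
        cum = np.concatenate([[0.0], np.cumsum(np.diff(kx) * (kv[:-1] + kv[1:]) / 2.0)])
        t = np.atleast_1d(np.asarray(t_years, dtype=float))
        tc = np.clip(t, kx[0], kx[-1])
        idx = np.clip(np.searchsorted(kx, tc, side="right") - 1, 0, len(kx) - 2)
        v_at = np.interp(tc, kx, kv)
        partial = (kv[idx] + v_at) / 2.0 * (tc - kx[idx])
        out = cum[idx] + partial
        return out if np.ndim(t_years) else float(out[0])

    @property
    def plateau_age_months(self):
        """Age at which stature velocity reaches zero (months)."""
        if self.measure != "length_height":
            return float("nan")
        return self.velocity_knots[-1][0] * 12.0

    def velocity_threshold_age_years(self, threshold_cm_per_year: float) -> float:
        """Analytic age (years) at which the declining velocity hits a threshold."""
        if self.measure != "length_height":
            raise ValueError("stature models only")
        x0, v0 = self.velocity_knots[-2]
        x1, _ = self.velocity_knots[-1]
        slope = v0 / (x1 - x0)
        return x1 - threshold_cm_per_year / slope

    def noiseless(self) -> "GrowthModelParams":
        """Copy with all between-subject and measurement noise set to zero."""
        return dataclasses.replace(self, sd_birth=0.0, sd_adult=0.0, sigma_meas=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["velocity_knots"] = [list(k) for k in self.velocity_knots]
        d["median_anchors"] = [list(k) for k in self.median_anchors]
        return d


def default_growth_models() -> dict:
    """Sex- and measure-specific defaults for the achondroplasia cohort.

    Birth means/SDs are the published cohort values; stature velocity knots
    are placed so velocity declines through 1 cm/yr and to 0 at the
    reported milestone ages (18.19 -> 19.37 y males, 15.43 -> 18.44 y
    females); OFC rates put 90% attainment near 11 months; weight medians
    rise to typical adult achondroplasia weights with age-increasing skew.
    """
    return {
        ("male", "length_height"): GrowthModelParams(
            measure="length_height", birth=47.90, sd_birth=3.18, sd_adult=5.6,
            sigma_meas=0.5, infancy_amp=1.50, infancy_tau=8.0,
            velocity_knots=((0.0, 4.21), (14.40, 4.21), (19.37, 0.0)),
        ),
        ("female", "length_height"): GrowthModelParams(
            measure="length_height", birth=47.28, sd_birth=2.85, sd_adult=5.2,
            sigma_meas=0.5, infancy_amp=1.30, infancy_tau=8.0,
            velocity_knots=((0.0, 6.60), (3.0, 6.60), (12.44, 1.9934), (18.44, 0.0)),
        ),
        ("male", "ofc"): GrowthModelParams(
            measure="ofc", birth=37.1, sd_birth=3.2, sd_adult=3.2,
            sigma_meas=0.3, plateau_value=56.5, k_per_month=0.1112,
        ),
        ("female", "ofc"): GrowthModelParams(
            measure="ofc", birth=36.4, sd_birth=2.3, sd_adult=2.3,
            sigma_meas=0.3, plateau_value=55.0, k_per_month=0.1088,
        ),
        ("male", "weight"): GrowthModelParams(
            measure="weight", birth=3.41, sd_birth=0.1466, sd_adult=0.22,
            sigma_meas=0.02,
            median_anchors=((0, 3.41), (3, 5.6), (6, 7.0), (12, 8.8), (24, 10.8),
                            (36, 12.3), (60, 15.0), (120, 24.0), (180, 42.0), (216, 50.0)),
        ),
        ("female", "weight"): GrowthModelParams(
            measure="weight", birth=3.32, sd_birth=0.1205, sd_adult=0.22,
            sigma_meas=0.02,
            median_anchors=((0, 3.32), (3, 5.3), (6, 6.6), (12, 8.3), (24, 10.3),
                            (36, 11.8), (60, 14.5), (120, 24.0), (180, 40.0), (216, 46.0)),
        ),
    }


# Deficit applied to measurements of preterm infants, fading out linearly by
# 24 months of age (additive cm for stature/OFC, multiplicative for weight).
PRETERM_DEFICIT = {"length_height": 3.5, "ofc": 2.5, "weight": 0.30}


def sample_trajectory(params: GrowthModelParams, sex: str, measure: str, visit_ages, rng,
                      subject_id: str = "S00000", preterm: bool = False) -> pd.DataFrame:
    """Draw one subject's measurements at the given visit ages (months).

    A persistent growth effect ``b ~ N(0, 1)`` scales the age-dependent SD
    (log-scale for weight), and independent measurement noise is added per
    visit, so the cross-sectional spread matches ``params.sd`` while the
    within-subject trajectory is non-decreasing in expectation.
    """
    ages = np.asarray(visit_ages, dtype=float)
    if len(ages) and (np.diff(ages) < 0).any():
        raise ValueError("visit_ages must be sorted ascending")
    b = rng.normal()
    eps = rng.normal(size=len(ages))
    med = np.atleast_1d(params.median(ages))
    sd = np.atleast_1d(params.sd(ages))
    if measure == "weight":
        values = med * np.exp(b * sd + eps * params.sigma_meas)
        if preterm:
            frac = np.clip(1.0 - ages / 24.0, 0.0, 1.0)
            values = values * (1.0 - PRETERM_DEFICIT["weight"] * frac)
    else:
        values = med + b * sd + eps * params.sigma_meas
        if preterm:
            frac = np.clip(1.0 - ages / 24.0, 0.0, 1.0)
            values = values - PRETERM_DEFICIT[measure] * frac
    position = np.where(ages < 24.0, "supine", "standing") if measure == "length_height" else "unknown"
    return pd.DataFrame({
        "subject_id": subject_id,
        "measure": measure,
        "age_months": ages,
        "value": values,
        "position": position,
        "qc_flags": "",
    })


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

_DECADE_SPANS = {
    "pre1980": (_dt.date(1957, 1, 1), _dt.date(1979, 12, 31)),
    "d1980s": (_dt.date(1980, 1, 1), _dt.date(1989, 12, 31)),
    "d1990s": (_dt.date(1990, 1, 1), _dt.date(1999, 12, 31)),
    "d2000s": (_dt.date(2000, 1, 1), _dt.date(2009, 12, 31)),
    "post2010": (_dt.date(2010, 1, 1), _dt.date(2017, 12, 31)),
}

# Diagnosis timing and mode by birth decade (observed per-decade counts).
_DIAGNOSIS_TIMING_COUNTS = {
    "pre1980": (0, 40, 16, 51, 127),
    "d1980s": (13, 64, 42, 39, 73),
    "d1990s": (53, 72, 51, 86, 52),
    "d2000s": (73, 100, 74, 80, 29),
    "post2010": (76, 67, 39, 45, 12),
}
_DIAGNOSIS_MODE_COUNTS = {
    "pre1980": (1, 85, 148),
    "d1980s": (2, 138, 91),
    "d1990s": (10, 239, 65),
    "d2000s": (17, 315, 24),
    "post2010": (19, 213, 7),
}

_PROCEDURES = {
    "ent": ["adenotonsillectomy", "pe_tubes", "tonsillectomy_revision"],
    "brain": ["vp_shunt", "vp_shunt_revision", "ventriculostomy"],
    "foramen_magnum": ["cervicomedullary_decompression"],
    "spine": ["laminectomy", "vertebral_fusion"],
    "extremity": ["osteotomy", "guided_growth", "limb_realignment"],
    "non_achondroplasia_related": ["appendectomy", "cesarean_section", "hernia_repair"],
}

_SURGERY_AGE_TRIANGLES = {  # years: (left, mode, right) -- stand-in distributions
    "ent": (0.3, 2.0, 10.0),
    "brain": (0.0, 1.0, 6.0),
    "foramen_magnum": (0.0, 1.5, 10.0),
    "spine": (5.0, 15.0, 40.0),
    "extremity": (2.0, 8.0, 20.0),
    "non_achondroplasia_related": (0.0, 20.0, 60.0),
}

_BODY_REGIONS = {
    "xray": ["long_bones", "spine", "cranium"],
    "ct": ["brain", "cervicomedullary_junction"],
    "mri": ["brain", "cervicomedullary_junction", "spine"],
    "echocardiogram": ["heart"],
    "ultrasound": ["brain", "abdomen"],
}


@dataclasses.dataclass
class VisitProcess:
    """Piecewise-constant visit intensity, denser in infancy (stand-in)."""

    rates_per_year: tuple = ((0.0, 2.0, 2.5), (2.0, 6.0, 1.2), (6.0, 21.0, 1.0), (21.0, 85.0, 0.15))
    birth_measurement_prob: float = 0.9
    p_length: float = 0.85
    p_weight: float = 0.95
    p_ofc_child: float = 0.80   # under 6 years
    p_ofc_later: float = 0.08
    max_age_years: float = 85.0


@dataclasses.dataclass
class ErrorRates:
    unit_swap: float = 0.0
    duplicate: float = 0.0
    implausible: float = 0.0


@dataclasses.dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic registry.

    All categorical rates default to the observed proportions of the
    published 1,374-subject multicenter cohort; growth-model parameters
    default to :func:`default_growth_models`.
    """

    n_subjects: int = 1374
    seed: int = 0
    sex_ratio: float = 0.512                       # probability of male
    decade_weights: tuple = (234, 231, 314, 356, 239)
    preterm_rate: float = 0.127
    post_term_rate: float = 0.011
    unknown_gestation_rate: float = 0.128
    de_novo_rate: float = 0.760
    unknown_inheritance_rate: float = 0.101
    adopted_rate: float = 0.063
    adopted_unknown_rate: float = 0.030
    deceased_rate: float = 20 / 1374
    site_weights: tuple = (299, 384, 218, 473)
    exclusion_rates: dict = dataclasses.field(default_factory=lambda: {
        "limb_lengthening": 0.012, "gh_treated": 0.001, "trial": 0.008, "gh_deficient": 0.003,
    })
    surgery_hazards: dict = dataclasses.field(default_factory=lambda: {
        "ent": 0.650, "brain": 0.100, "foramen_magnum": 0.205, "spine": 0.127, "extremity": 0.212,
    })
    surgery_extra_procedures: dict = dataclasses.field(default_factory=lambda: {
        "ent": 2.14, "brain": 1.38, "foramen_magnum": 0.12, "spine": 1.43, "extremity": 1.35,
    })
    surgical_history_unknown_rate: float = 113 / 1374
    nonach_surgery_rate: float = 302 / 1374
    psg_prob_by_decade: dict = dataclasses.field(default_factory=lambda: {
        "pre1980": 0.150, "d1980s": 0.342, "d1990s": 0.404, "d2000s": 0.680, "post2010": 0.812,
    })
    psg_modsev_by_decade: dict = dataclasses.field(default_factory=lambda: {
        "pre1980": 0.457, "d1980s": 0.203, "d1990s": 0.300, "d2000s": 0.409, "post2010": 0.469,
    })
    psg_age_by_decade: dict = dataclasses.field(default_factory=lambda: {
        "pre1980": (31.1, 16.9), "d1980s": (5.6, 7.9), "d1990s": (3.0, 4.2),
        "d2000s": (2.2, 3.1), "post2010": (0.8, 0.9),
    })
    psg_extra_studies_mean: float = 1.4
    imaging_any_rate: float = 0.910
    imaging_modality_weights: tuple = (7201, 1069, 1826, 166, 465)
    imaging_extra_studies_mean: float = 7.57
    imaging_available_rate: float = 0.755
    growth_models: dict = dataclasses.field(default_factory=default_growth_models)
    visit_process: VisitProcess = dataclasses.field(default_factory=VisitProcess)
    error_rates: ErrorRates = dataclasses.field(default_factory=ErrorRates)
    followup_beta: tuple = (2.6, 1.4)              # follow-up fraction of attained age
    age_last_years: float | None = None            # override: fixed follow-up for tests
    reference_date: _dt.date = _dt.date(2019, 1, 1)

    def __post_init__(self):
        for name in ("sex_ratio", "preterm_rate", "post_term_rate", "unknown_gestation_rate",
                     "de_novo_rate", "unknown_inheritance_rate", "adopted_rate", "deceased_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        w = np.asarray(self.decade_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("decade_weights must be non-negative with positive sum")
        self.decade_weights = tuple(w / w.sum())
        if abs(sum(self.decade_weights) - 1.0) > 1e-9:
            raise ValueError("decade_weights must sum to 1")

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "growth_models":
                v = {f"{sex}:{measure}": p.to_dict() for (sex, measure), p in v.items()}
            elif f.name in ("visit_process", "error_rates"):
                v = dataclasses.asdict(v)
            elif f.name == "reference_date":
                v = v.isoformat()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "growth_models" in d and isinstance(d["growth_models"], dict):
            gm = {}
            for key, pd_ in d["growth_models"].items():
                sex, measure = key.split(":")
                pd_ = dict(pd_)
                pd_["velocity_knots"] = tuple(tuple(k) for k in pd_.get("velocity_knots", ()))
                pd_["median_anchors"] = tuple(tuple(k) for k in pd_.get("median_anchors", ()))
                gm[(sex, measure)] = GrowthModelParams(**pd_)
            d["growth_models"] = gm
        if "visit_process" in d and isinstance(d["visit_process"], dict):
            d["visit_process"] = VisitProcess(**{k: tuple(tuple(r) for r in v) if k == "rates_per_year" else v
                                                 for k, v in d["visit_process"].items()})
        if "error_rates" in d and isinstance(d["error_rates"], dict):
            d["error_rates"] = ErrorRates(**d["error_rates"])
        if "reference_date" in d and isinstance(d["reference_date"], str):
            d["reference_date"] = _dt.date.fromisoformat(d["reference_date"])
        for key in ("decade_weights", "site_weights", "imaging_modality_weights", "followup_beta"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _choice(rng, items, probs):
    return items[rng.choice(len(items), p=np.asarray(probs, float) / np.sum(probs))]


def _visit_ages_months(cfg: CohortConfig, age_last_years: float, rng) -> np.ndarray:
    vp = cfg.visit_process
    ages = []
    if rng.random() < vp.birth_measurement_prob:
        ages.append(0.0)
    horizon = min(age_last_years, vp.max_age_years)
    for lo, hi, rate in vp.rates_per_year:
        a, b = lo, min(hi, horizon)
        if b <= a:
            continue
        n = rng.poisson(rate * (b - a))
        ages.extend(rng.uniform(a * 12.0, b * 12.0, size=n))
    return np.sort(np.asarray(ages, dtype=float))


def _sample_subject(cfg: CohortConfig, k: int) -> dict:
    """Draw one subject's full record set from its dedicated substream."""
    rng = np.random.default_rng([cfg.seed, k])
    sid = f"S{k:05d}"
    sex = "male" if rng.random() < cfg.sex_ratio else "female"
    decade = _choice(rng, reg.BIRTH_DECADES, cfg.decade_weights)
    d0, d1 = _DECADE_SPANS[decade]
    birth_date = d0 + _dt.timedelta(days=int(rng.integers(0, (d1 - d0).days + 1)))

    attained_years = (cfg.reference_date - birth_date).days / 365.25
    if cfg.age_last_years is not None:
        age_last = float(cfg.age_last_years)
    else:
        frac = rng.beta(*cfg.followup_beta)
        age_last = max(0.05, attained_years * frac)
    vital = "deceased" if rng.random() < cfg.deceased_rate else "living"

    u = rng.random()
    if u < cfg.preterm_rate:
        gestation, latent_preterm = "preterm", True
    elif u < cfg.preterm_rate + cfg.post_term_rate:
        gestation, latent_preterm = "post_term", False
    elif u < cfg.preterm_rate + cfg.post_term_rate + cfg.unknown_gestation_rate:
        gestation = "unknown"
        latent_preterm = rng.random() < cfg.preterm_rate
    else:
        gestation, latent_preterm = "term", False
    if gestation == "preterm":
        weeks = rng.uniform(28.0, 36.9)
    elif gestation == "term":
        weeks = rng.uniform(37.0, 41.9)
    elif gestation == "post_term":
        weeks = rng.uniform(42.0, 43.5)
    else:
        weeks = math.nan

    u = rng.random()
    if u < cfg.de_novo_rate:
        inheritance = "de_novo"
    elif u < cfg.de_novo_rate + cfg.unknown_inheritance_rate:
        inheritance = "unknown"
    else:
        inheritance = "inherited"

    u = rng.random()
    adopted = "true" if u < cfg.adopted_rate else ("unknown" if u < cfg.adopted_rate + cfg.adopted_unknown_rate else "false")
    site = _choice(rng, reg.SITES, cfg.site_weights)

    timing = _choice(rng, reg.DIAGNOSIS_TIMINGS, _DIAGNOSIS_TIMING_COUNTS[decade])
    mode = _choice(rng, reg.DIAGNOSIS_MODES, _DIAGNOSIS_MODE_COUNTS[decade])

    ex = cfg.exclusion_rates
    limb = rng.random() < ex["limb_lengthening"]
    gh_def = rng.random() < ex["gh_deficient"]
    gh_tx = rng.random() < ex["gh_treated"]
    trial = rng.random() < ex["trial"]
    history_known = rng.random() >= cfg.surgical_history_unknown_rate

    subject = {
        "subject_id": sid, "sex": sex, "birth_date": birth_date.isoformat(), "site": site,
        "vital_status": vital, "age_last_encounter": round(age_last, 4),
        "gestation": gestation,
        "gestational_weeks": round(weeks, 1) if not math.isnan(weeks) else math.nan,
        "inheritance": inheritance, "adopted": adopted,
        "diagnosis_timing": timing, "diagnosis_mode": mode,
        "limb_lengthening": "true" if limb else "false",
        "gh_deficient": "true" if gh_def else "false",
        "gh_treated": "true" if gh_tx else "false",
        "trial_participant": "true" if trial else "false",
        "surgical_history_known": "true" if history_known else "false",
    }

    # anthropometry
    visit_ages = _visit_ages_months(cfg, age_last, rng)
    vp = cfg.visit_process
    anthro_frames = []
    preterm_effect = latent_preterm or gestation == "preterm"
    for measure in reg.MEASURES:
        if measure == "length_height":
            keep = rng.random(len(visit_ages)) < vp.p_length
        elif measure == "weight":
            keep = rng.random(len(visit_ages)) < vp.p_weight
        else:
            p = np.where(visit_ages < 72.0, vp.p_ofc_child, vp.p_ofc_later)
            keep = rng.random(len(visit_ages)) < p
        ages = visit_ages[keep]
        if len(ages) == 0:
            continue
        params = cfg.growth_models[(sex, measure)]
        anthro_frames.append(
            sample_trajectory(params, sex, measure, ages, rng, subject_id=sid, preterm=preterm_effect)
        )

    # surgeries
    surgery_rows = []
    if history_known:
        for cat in reg.ACH_SURGERY_CATEGORIES:
            if rng.random() >= cfg.surgery_hazards[cat]:
                continue
            first_age = rng.triangular(*_SURGERY_AGE_TRIANGLES[cat])
            if first_age > age_last:
                continue
            n_proc = 1 + rng.poisson(cfg.surgery_extra_procedures[cat])
            age = first_age
            for j in range(n_proc):
                if age > age_last:
                    break
                proc = _PROCEDURES[cat][int(rng.integers(len(_PROCEDURES[cat])))]
                date_known = not (cat == "ent" and proc == "pe_tubes" and rng.random() < 0.05)
                event_date = birth_date + _dt.timedelta(days=int(age * 365.25))
                surgery_rows.append({
                    "subject_id": sid, "category": cat, "procedure": proc,
                    "event_date": event_date.isoformat() if date_known else "",
                    "date_known": "true" if date_known else "false",
                })
                age += rng.exponential(1.5)
        if rng.random() < cfg.nonach_surgery_rate:
            n_proc = 1 + rng.poisson(0.52)
            for j in range(n_proc):
                age = rng.uniform(0.0, age_last)
                proc = _PROCEDURES["non_achondroplasia_related"][int(rng.integers(3))]
                event_date = birth_date + _dt.timedelta(days=int(age * 365.25))
                surgery_rows.append({
                    "subject_id": sid, "category": "non_achondroplasia_related", "procedure": proc,
                    "event_date": event_date.isoformat(), "date_known": "true",
                })

    # polysomnography
    psg_rows = []
    if rng.random() < cfg.psg_prob_by_decade[decade]:
        if rng.random() < cfg.psg_modsev_by_decade[decade]:
            worst = "moderate" if rng.random() < 0.55 else "severe"
        else:
            worst = _choice(rng, ("no_osa", "mild", "inconclusive"), (0.47, 0.41, 0.12))
        mu, sd = cfg.psg_age_by_decade[decade]
        first_age = float(np.clip(rng.normal(mu, sd), 0.1, max(0.1, age_last)))
        n_studies = 1 + rng.poisson(cfg.psg_extra_studies_mean)
        ages = [first_age]
        for _ in range(n_studies - 1):
            nxt = ages[-1] + rng.exponential(2.0)
            if nxt > age_last:
                break
            ages.append(nxt)
        worst_rank = reg.OSA_SEVERITY_ORDER[worst]
        lesser = [o for o in ("no_osa", "mild", "moderate") if reg.OSA_SEVERITY_ORDER[o] <= worst_rank]
        worst_at = int(rng.integers(len(ages)))
        for j, a in enumerate(ages):
            outcome = worst if j == worst_at else lesser[int(rng.integers(len(lesser)))]
            psg_rows.append({
                "subject_id": sid, "age_at_study": round(a, 3), "outcome": outcome,
                "is_first_study": "true" if j == 0 else "false",
            })

    # imaging
    imaging_rows = []
    if rng.random() < cfg.imaging_any_rate:
        n_studies = 1 + rng.poisson(cfg.imaging_extra_studies_mean)
        w = np.asarray(cfg.imaging_modality_weights, float)
        w = w / w.sum()
        for _ in range(n_studies):
            modality = _choice(rng, reg.IMAGING_MODALITIES, w)
            age = rng.uniform(0.0, age_last)
            study_date = birth_date + _dt.timedelta(days=int(age * 365.25))
            region = _BODY_REGIONS[modality][int(rng.integers(len(_BODY_REGIONS[modality])))]
            imaging_rows.append({
                "subject_id": sid, "modality": modality, "study_date": study_date.isoformat(),
                "body_region": region,
                "images_available": "true" if rng.random() < cfg.imaging_available_rate else "false",
            })

    return {
        "subject": subject,
        "anthropometry": anthro_frames,
        "surgeries": surgery_rows,
        "psg": psg_rows,
        "imaging": imaging_rows,
    }


def generate_cohort(cfg: CohortConfig) -> Registry:
    """Generate a full synthetic registry for the configured cohort.

    Deterministic for a fixed ``(cfg, cfg.seed)``; subject ``k``'s records
    do not change when ``n_subjects`` changes.
    """
    if cfg.n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    subjects, anthro, surgeries, psg, imaging = [], [], [], [], []
    for k in range(cfg.n_subjects):
        rec = _sample_subject(cfg, k)
        subjects.append(rec["subject"])
        anthro.extend(rec["anthropometry"])
        surgeries.extend(rec["surgeries"])
        psg.extend(rec["psg"])
        imaging.extend(rec["imaging"])

    def _frame(rows, name):
        if not rows:
            return None
        df = pd.DataFrame(rows)
        return df[reg.TABLE_COLUMNS[name]]

    r = Registry(
        subjects=_frame(subjects, "subjects") if subjects else Registry().subjects,
        anthropometry=(pd.concat(anthro, ignore_index=True)[reg.ANTHROPOMETRY_COLUMNS]
                       if anthro else Registry().anthropometry),
        surgeries=_frame(surgeries, "surgeries") if surgeries else Registry().surgeries,
        psg=_frame(psg, "psg") if psg else Registry().psg,
        imaging=_frame(imaging, "imaging") if imaging else Registry().imaging,
        provenance={
            "source": "achondro.simulate.generate_cohort",
            "seed": cfg.seed,
            "n_subjects": cfg.n_subjects,
            "note": "visit spacing, surgery ages and follow-up truncation are synthetic stand-ins",
        },
    ).canonicalize()
    if subjects:
        r.anthropometry["value"] = r.anthropometry["value"].round(4)
        r.anthropometry["age_months"] = r.anthropometry["age_months"].round(4)
        r = r.canonicalize()
    return r


# ---------------------------------------------------------------------------
# Error injection (ground truth for the cleaning stage)
# ---------------------------------------------------------------------------

UNIT_SWAP_FACTOR = {"length_height": 1 / 2.54, "ofc": 1 / 2.54, "weight": 2.2046}
OUTLIER_SCALE = {"length_height": 3.5, "ofc": 2.5, "weight": 0.15}  # weight on log scale


def inject_errors(r: Registry, error_rates: ErrorRates, rng) -> tuple:
    """Corrupt a clean registry and return (registry, ground-truth ledger).

    Each anthropometry row is independently hit by at most one corruption:
    a unit swap (cm recorded as inches, i.e. value/2.54, or kg recorded as
    pounds, value*2.2046), an exact duplicate row, or a gross outlier
    displaced by +-8 SD (multiplicative on the log scale for weight). The
    ledger lists every injected corruption with original and corrupted
    values; its length equals the corruption count.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = r.canonicalize()
    a = out.anthropometry
    ledger_rows = []
    dup_rows = []
    p_swap, p_dup, p_imp = error_rates.unit_swap, error_rates.duplicate, error_rates.implausible
    u = rng.random(len(a))
    signs = rng.random(len(a)) < 0.5
    for i in range(len(a)):
        measure = a.at[i, "measure"]
        orig = float(a.at[i, "value"])
        if u[i] < p_swap:
            new = round(orig * UNIT_SWAP_FACTOR[measure], 4)
            a.at[i, "value"] = new
            kind = "unit_swap"
        elif u[i] < p_swap + p_dup:
            dup_rows.append(a.loc[i].copy())
            new = orig
            kind = "duplicate"
        elif u[i] < p_swap + p_dup + p_imp:
            if measure == "weight":
                factor = math.exp((8 if signs[i] else -8) * OUTLIER_SCALE["weight"])
                new = round(orig * factor, 4)
            else:
                delta = (8 if signs[i] else -8) * OUTLIER_SCALE[measure]
                new = round(max(orig + delta, 0.1), 4)
            a.at[i, "value"] = new
            kind = "implausible"
        else:
            continue
        ledger_rows.append({
            "subject_id": a.at[i, "subject_id"], "measure": measure,
            "age_months": float(a.at[i, "age_months"]),
            "kind": kind, "original_value": orig, "corrupted_value": new,
        })
    if dup_rows:
        a = pd.concat([a, pd.DataFrame(dup_rows)], ignore_index=True)
    out.anthropometry = a
    out = out.canonicalize()
    out.provenance = dict(r.provenance)
    out.provenance["errors_injected"] = len(ledger_rows)
    ledger = pd.DataFrame(ledger_rows, columns=[
        "subject_id", "measure", "age_months", "kind", "original_value", "corrupted_value",
    ])
    return out, ledger
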