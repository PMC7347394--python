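"""Synthetic SEN1500-like cohort generator.

Produces patient tables with the marginal covariate structure of the
development registry (prevalences, gestational-age median/IQR, birth-weight
trend) and an outcome drawn from a *known* logistic mechanism, so that the
development and validation stages can be exercised against ground truth.

Correlation structure is deliberately minimal: birth weight tracks
gestational age, a few diagnoses become more likely at lower gestational
age, Apgar scores fall with resuscitation intensity; everything else is
independent. Only marginals are published for the source registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .exceptions import ConfigError, SchemaError
from .models import ModelSpec, published_model, score_table

__all__ = [
    "CohortConfig",
    "DEFAULT_PREVALENCES",
    "PLAIN_DIAGNOSES",
    "SEVERE_DIAGNOSES",
    "SEVERE_PLAIN_PAIRS",
    "generate_covariates",
    "assign_diagnoses",
    "simulate_outcome",
    "generate_cohort",
]

#: Plain yes/no diagnosis columns.
PLAIN_DIAGNOSES = (
    "rds", "pneumothorax", "pda", "nec", "gi_perforation",
    "early_sepsis", "late_sepsis", "ivh", "pvl", "rop", "bpd",
)

#: Severity-adjusted diagnosis columns ("advanced_resuscitation" is derived
#: from the delivery-room resuscitation level, not drawn independently).
SEVERE_DIAGNOSES = (
    "advanced_resuscitation", "severe_rds", "severe_pda", "severe_nec",
    "severe_infection", "severe_rop", "severe_ivh", "severe_pvl",
    "severe_bpd", "severe_pneumothorax", "severe_anemia",
)

#: severe flag -> plain flag implications that must hold on every cohort.
SEVERE_PLAIN_PAIRS = {
    "severe_rds": "rds",
    "severe_pda": "pda",
    "severe_nec": "nec",
    "severe_pneumothorax": "pneumothorax",
    "severe_ivh": "ivh",
    "severe_pvl": "pvl",
    "severe_bpd": "bpd",
    "severe_rop": "rop",
}

#: Diagnoses whose probability increases as gestational age decreases,
#: with the per-week log-odds slope used by the generator.
_GA_LINKED = {"rds": 0.45, "ivh": 0.30, "nec": 0.20}

RESUSCITATION_LEVELS = ("nil", "positive_pressure", "intubation", "compressions", "adrenaline")
ADVANCED_RESUSCITATION = frozenset({"intubation", "compressions", "adrenaline"})

DEFAULT_PREVALENCES = {
    # perinatal
    "maternal_steroids_partial": 0.189,
    "maternal_steroids_full": 0.694,
    "chorioamnionitis": 0.185,
    "maternal_hypertension": 0.201,
    "multiple_pregnancy": 0.357,
    "male": 0.511,
    "low_weight_p10": 0.344,
    "inborn": 0.945,
    "level3": 0.991,
    "cesarean": 0.711,
    "resus_positive_pressure": 0.290,
    "resus_intubation": 0.295,
    "resus_compressions": 0.026,
    "resus_adrenaline": 0.038,
    "postnatal_steroids": 0.063,
    # plain diagnoses
    "rds": 0.640,
    "pneumothorax": 0.049,
    "pda": 0.359,
    "nec": 0.077,
    "gi_perforation": 0.027,
    "early_sepsis": 0.047,
    "late_sepsis": 0.336,
    "ivh": 0.267,
    "pvl": 0.063,
    "rop": 0.216,
    "bpd": 0.277,
    # severity-adjusted diagnoses
    "severe_rds": 0.348,
    "severe_pda": 0.056,
    "severe_nec": 0.049,
    "severe_infection": 0.160,
    "severe_rop": 0.042,
    "severe_ivh": 0.094,
    "severe_pvl": 0.026,
    "severe_bpd": 0.145,
    "severe_pneumothorax": 0.049,
    "severe_anemia": 0.488,
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    ``true_model`` (a ModelSpec or a published model id) is the logistic
    mechanism generating outcomes. When ``target_mortality`` is set, the
    mechanism's intercept is shifted so the cohort-mean death probability
    matches it; set to ``None`` to use the mechanism untouched.
    """

    n: int = 1000
    seed: int = 0
    prevalences: dict = field(default_factory=dict)
    ga_median: float = 29.1
    ga_iqr: tuple = (27.2, 30.8)
    ga_range: tuple = (22.0, 34.0)
    bw_slope: float = 95.0
    bw_sd: float = 170.0
    temp_median: float = 36.0
    temp_sd: float = 0.74
    true_model: Union[str, ModelSpec] = "M1"
    target_mortality: Optional[float] = 0.148
    death_timing: tuple = (0.185, 0.653, 0.162)
    sim_day_of_life: int = 1

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        merged = dict(DEFAULT_PREVALENCES)
        for key, value in self.prevalences.items():
            if key not in merged:
                raise ConfigError(f"unknown prevalence field {key!r}")
            merged[key] = value
        for key, value in merged.items():
            if not (0.0 <= float(value) <= 1.0):
                raise ConfigError(f"prevalence {key!r} must be in [0,1], got {value}")
        if merged["maternal_steroids_partial"] + merged["maternal_steroids_full"] > 1.0 + 1e-12:
            raise ConfigError("maternal_steroids_partial + maternal_steroids_full exceeds 1")
        resus_sum = sum(merged[f"resus_{lvl}"] for lvl in RESUSCITATION_LEVELS[1:])
        if resus_sum > 1.0 + 1e-12:
            raise ConfigError("resuscitation level probabilities exceed 1")
        self.prevalences = merged
        if self.target_mortality is not None and not (0.0 <= self.target_mortality <= 1.0):
            raise ConfigError(f"target_mortality must be in [0,1], got {self.target_mortality}")
        timing = tuple(float(x) for x in self.death_timing)
        if len(timing) != 3 or any(not (0.0 <= x <= 1.0) for x in timing):
            raise ConfigError(f"death_timing must be three probabilities, got {timing}")
        if abs(sum(timing) - 1.0) > 1e-9:
            raise ConfigError(f"death_timing must sum to 1, got sum {sum(timing)}")
        self.death_timing = timing

    def resolve_model(self) -> ModelSpec:
        if isinstance(self.true_model, ModelSpec):
            return self.true_model
        return published_model(self.true_model)


@lru_cache(maxsize=16)
def _fit_truncnorm(lo: float, hi: float, median: float, q1: float, q3: float):
    """Location/scale of a normal truncated to [lo, hi] matching median and IQR."""

    def residuals(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        q25, q50, q75 = stats.truncnorm.ppf([0.25, 0.5, 0.75], a, b, loc=loc, scale=scale)
        return [q50 - median, (q75 - q25) - (q3 - q1)]

    sigma0 = (q3 - q1) / 1.349
    sol = optimize.fsolve(residuals, [median, np.log(sigma0)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _rng_for(config: CohortConfig, stream: int, rng=None):
    return rng if rng is not None else np.random.default_rng([config.seed, stream])


def generate_covariates(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Draw perinatal/neonatal covariates for ``config.n`` patients.

    Diagnosis flags and outcome columns are added by :func:`assign_diagnoses`
    and :func:`simulate_outcome`; this function emits everything else,
    including the derived ``advanced_resuscitation`` indicator.
    """
    rng = _rng_for(config, 0, rng)
    n = config.n
    prev = config.prevalences

    loc, scale = _fit_truncnorm(
        config.ga_range[0], config.ga_range[1],
        config.ga_median, config.ga_iqr[0], config.ga_iqr[1],
    )
    a, b = (config.ga_range[0] - loc) / scale, (config.ga_range[1] - loc) / scale
    ga = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    ga = np.round(ga, 2)

    bw_intercept = 1117.0 - config.bw_slope * config.ga_median
    bw = bw_intercept + config.bw_slope * ga + rng.normal(0.0, config.bw_sd, size=n)
    bw = np.clip(np.round(bw), 310, 1990).astype(int)

    steroid_p = np.array([
        1.0 - prev["maternal_steroids_partial"] - prev["maternal_steroids_full"],
        prev["maternal_steroids_partial"],
        prev["maternal_steroids_full"],
    ])
    steroids = rng.choice(np.array(["none", "partial", "full"]), size=n, p=steroid_p)

    resus_p = np.array([
        1.0 - sum(prev[f"resus_{lvl}"] for lvl in RESUSCITATION_LEVELS[1:]),
        prev["resus_positive_pressure"], prev["resus_intubation"],
        prev["resus_compressions"], prev["resus_adrenaline"],
    ])
    resus_idx = rng.choice(len(RESUSCITATION_LEVELS), size=n, p=resus_p)
    resus = np.array(RESUSCITATION_LEVELS)[resus_idx]

    # Apgar scores fall with increasing resuscitation intensity.
    apgar1 = np.clip(np.round(7.6 - 1.3 * resus_idx + rng.normal(0, 1.5, n)), 0, 10).astype(int)
    apgar5 = np.clip(np.round(9.2 - 1.1 * resus_idx + rng.normal(0, 1.2, n)), 0, 10).astype(int)

    temp = np.clip(np.round(rng.normal(config.temp_median, config.temp_sd, n), 1), 32.0, 39.0)
    crib_rate = np.clip(np.exp(6.0 - 0.19 * ga), 0.05, 25.0)
    crib1 = rng.poisson(crib_rate)

    table = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "maternal_steroids": steroids,
        "chorioamnionitis": (rng.random(n) < prev["chorioamnionitis"]).astype(int),
        "maternal_hypertension": (rng.random(n) < prev["maternal_hypertension"]).astype(int),
        "multiple_pregnancy": (rng.random(n) < prev["multiple_pregnancy"]).astype(int),
        "sex": np.where(rng.random(n) < prev["male"], "male", "female"),
        "gestational_age": ga,
        "birth_weight": bw,
        "low_weight_p10": (rng.random(n) < prev["low_weight_p10"]).astype(int),
        "inborn": (rng.random(n) < prev["inborn"]).astype(int),
        "level_of_care": np.where(rng.random(n) < prev["level3"], 3, 2),
        "cesarean": (rng.random(n) < prev["cesarean"]).astype(int),
        "resuscitation": resus,
        "apgar1": apgar1,
        "apgar5": apgar5,
        "admission_temp": temp,
        "crib1": crib1,
        "postnatal_steroids": (rng.random(n) < prev["postnatal_steroids"]).astype(int),
    })
    table["advanced_resuscitation"] = table["resuscitation"].isin(ADVANCED_RESUSCITATION).astype(int)
    return table


def _calibrated_probs(ga: np.ndarray, target: float, slope: float, ga_center: float) -> np.ndarray:
    """Per-patient probabilities sigmoid(c + slope*(center-ga)) with c solved
    so the cohort mean equals ``target`` exactly in expectation."""
    if target <= 1e-12:
        return np.zeros_like(ga)
    if target >= 1.0 - 1e-12:
        return np.ones_like(ga)
    lin = slope * (ga_center - ga)

    def mean_gap(c):
        return float(np.mean(expit(c + lin))) - target

    # expit is monotone in c, so logit(target) +/- max|lin| brackets the root
    span = float(np.max(np.abs(lin))) + 1.0 if len(lin) else 1.0
    center = float(logit(target))
    c = optimize.brentq(mean_gap, center - span, center + span)
    return expit(c + lin)


def assign_diagnoses(patients: pd.DataFrame, config: CohortConfig, rng=None) -> pd.DataFrame:
    """Add plain and severity-adjusted diagnosis flags.

    Plain prevalences follow the configured marginals; RDS, IVH and NEC are
    more likely at lower gestational age. Each paired severe flag is drawn
    conditional on its plain flag, so severe implies plain by construction.
    """
    if "gestational_age" not in patients.columns:
        raise SchemaError("assign_diagnoses requires generated covariates")
    rng = _rng_for(config, 1, rng)
    out = patients.copy()
    n = len(out)
    prev = config.prevalences
    ga = out["gestational_age"].to_numpy(dtype=float)

    for diag in PLAIN_DIAGNOSES:
        target = prev[diag]
        if diag in _GA_LINKED and n > 0:
            p = _calibrated_probs(ga, target, _GA_LINKED[diag], config.ga_median)
        else:
            p = np.full(n, target)
        out[diag] = (rng.random(n) < p).astype(int)

    for severe, plain in SEVERE_PLAIN_PAIRS.items():
        plain_prev = prev[plain]
        cond = min(1.0, prev[severe] / plain_prev) if plain_prev > 0 else 0.0
        out[severe] = ((out[plain] == 1) & (rng.random(n) < cond)).astype(int)

    for severe in ("severe_infection", "severe_anemia"):
        out[severe] = (rng.random(n) < prev[severe]).astype(int)
    return out


def simulate_outcome(patients: pd.DataFrame, true_model=None, config: Optional[CohortConfig] = None,
                     rng=None, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw outcome, day of death and length of stay from a logistic mechanism.

    Each patient dies with probability ``p_i = expit(z_i + c)`` where ``z_i``
    comes from ``true_model`` and ``c`` is a calibration offset matching the
    configured target mortality (0 when no target is set). The realised
    ``p_true`` is stored so downstream checks can compare against the
    generator's own probabilities. Deaths get a day of death drawn over the
    three timing windows (first day / days 2-30 / beyond) and their stay ends
    there; survivor stays shorten with gestational age.
    """
    config = config or CohortConfig(n=len(patients))
    if rng is None:
        rng = np.random.default_rng(seed) if seed is not None else _rng_for(config, 2)
    model = config.resolve_model() if true_model is None else (
        published_model(true_model) if isinstance(true_model, str) else true_model
    )

    missing = sorted(set(model.required_fields()) - set(patients.columns))
    if missing:
        raise SchemaError(f"predictors missing from table: {missing}")

    out = patients.copy()
    n = len(out)
    day = config.sim_day_of_life if model.needs_day else None
    z = score_table(model, out, day_of_life=day) if n else np.array([])

    offset = 0.0
    if config.target_mortality is not None and n > 0:
        finite = np.isfinite(z)
        if finite.any():
            def mean_gap(c):
                return float(np.mean(expit(z + c))) - config.target_mortality
            lo, hi = -30.0, 30.0
            if mean_gap(lo) < 0 < mean_gap(hi):
                offset = optimize.brentq(mean_gap, lo, hi)
    p = expit(z + offset)

    died = rng.random(n) < p
    ga = out["gestational_age"].to_numpy(dtype=float) if "gestational_age" in out else np.full(n, 29.0)

    # survivor stay: shifted negative binomial, mean falling with GA, min 1 day
    mean_los = np.clip(30.0 + 8.0 * (30.0 - ga), 5.0, 130.0)
    r = 6.0
    p_nb = r / (r + mean_los - 1.0)
    los = 1 + rng.negative_binomial(r, p_nb)

    day_of_death = np.full(n, -1, dtype=int)
    n_dead = int(died.sum())
    if n_dead:
        window = rng.choice(3, size=n_dead, p=np.asarray(config.death_timing))
        dod = np.empty(n_dead, dtype=int)
        dod[window == 0] = 1
        dod[window == 1] = rng.integers(2, 31, size=int((window == 1).sum()))
        dod[window == 2] = rng.integers(31, 121, size=int((window == 2).sum()))
        day_of_death[died] = dod
        los[died] = dod

    out["length_of_stay"] = los.astype(int)
    out["outcome"] = np.where(died, "died", "survived")
    out["day_of_death"] = pd.array(
        [d if d > 0 else pd.NA for d in day_of_death], dtype="Int64"
    )
    out["p_true"] = p
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Full generator: covariates, diagnoses and outcome, deterministic in
    ``config.seed``."""
    table = generate_covariates(config)
    table = assign_diagnoses(table, config)
    return simulate_outcome(table, config=config)
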