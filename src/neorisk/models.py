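"""Scoring engine for the published VLBW mortality equations.

Four logistic equations are shipped as package data: a prenatal model
(``M1``), a 24-hours-of-life model (``M2``) and a during-admission model
stratified on day 30 (``M3_early`` for days 1-30, ``M3_late`` beyond).
Each equation is an intercept plus coefficient-weighted encoded covariates;
the death probability is the logistic transform of the linear predictor.

The published coefficient tables (with their printed odds ratios and
confidence intervals, kept for cross-checking) live in
``data/published_models.json`` so that fitted and published models share a
single scoring code path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ScoringError, StratumError

__all__ = [
    "Term",
    "ModelSpec",
    "CategoryBands",
    "RiskPrediction",
    "load_published_models",
    "published_model",
    "published_cutoffs",
    "published_bands",
    "linear_predictor",
    "design_matrix",
    "death_probability",
    "odds_ratio",
    "categorize",
    "select_submodel",
    "predict_record",
    "predict_table",
]

CATEGORIES = ("mild", "moderate", "severe", "very_severe")

#: Encodings understood by the scoring engine.
_TERM_KINDS = frozenset({"numeric", "flag", "equals", "in", "days"})


@dataclass(frozen=True)
class Term:
    """One model term: a named predictor with its encoding rule and coefficient.

    Parameters
    ----------
    name : str
        Unique term name within the model.
    field : str or None
        Source column in the patient table; ``None`` for the day-of-life term.
    kind : str
        Encoding rule: ``numeric`` (value times ``scale``), ``flag`` (0/1
        column), ``equals`` (indicator of ``field == value``), ``in``
        (indicator of membership in ``values``) or ``days`` (the day-of-life
        argument supplied at scoring time).
    beta, se : float
        Coefficient and its standard error.
    """

    name: str
    field: Optional[str]
    kind: str
    beta: float
    se: float
    scale: float = 1.0
    value: object = None
    values: tuple = ()
    published_or: Optional[float] = None
    published_ci: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in _TERM_KINDS:
            raise ConfigError(f"unknown term kind {self.kind!r} for term {self.name!r}")
        if not (self.se > 0):
            raise ConfigError(f"term {self.name!r}: standard error must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic equation: intercept plus ordered terms.

    ``day_window`` is the applicability window in days of life for the
    day-stratified sub-models (``(1, 30)`` / ``(31, None)``); ``None`` means
    the model applies irrespective of day.
    """

    model_id: str
    intercept: float
    terms: tuple = ()
    intercept_se: Optional[float] = None
    day_window: Optional[tuple] = None
    description: str = ""

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ConfigError(f"model {self.model_id}: duplicate term names")

    @property
    def needs_day(self) -> bool:
        return any(t.kind == "days" for t in self.terms) or self.day_window is not None

    def required_fields(self) -> list:
        return [t.field for t in self.terms if t.field is not None]

    def coefficients(self) -> dict:
        return {t.name: t.beta for t in self.terms}

    def check_day(self, day_of_life: Optional[int]) -> None:
        if self.day_window is None:
            return
        if day_of_life is None:
            raise ScoringError(
                f"model {self.model_id} requires day_of_life (window {self.day_window})"
            )
        lo, hi = self.day_window
        if day_of_life < lo or (hi is not None and day_of_life > hi):
            raise StratumError(
                f"model {self.model_id} applies to days {lo}-{hi if hi is not None else 'inf'};"
                f" got day {day_of_life}"
            )

    def with_coefficients(self, intercept: float, betas: Mapping, ses: Mapping) -> "ModelSpec":
        """Return a copy carrying estimated coefficients (same term structure)."""
        new_terms = tuple(
            replace(t, beta=float(betas[t.name]), se=float(ses[t.name]),
                    published_or=None, published_ci=None)
            for t in self.terms
        )
        return replace(self, intercept=float(intercept), terms=new_terms)

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "description": self.description,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "day_window": list(self.day_window) if self.day_window else None,
            "terms": [],
        }
        for t in self.terms:
            td = {"name": t.name, "field": t.field, "kind": t.kind,
                  "beta": t.beta, "se": t.se}
            if t.scale != 1.0:
                td["scale"] = t.scale
            if t.kind == "equals":
                td["value"] = t.value
            if t.kind == "in":
                td["values"] = list(t.values)
            d["terms"].append(td)
        return d

    @classmethod
    def from_dict(cls, model_id: str, d: Mapping) -> "ModelSpec":
        terms = []
        for td in d["terms"]:
            terms.append(
                Term(
                    name=td["name"],
                    field=td.get("field"),
                    kind=td["kind"],
                    beta=float(td["beta"]),
                    se=float(td["se"]),
                    scale=float(td.get("scale", 1.0)),
                    value=td.get("value"),
                    values=tuple(td.get("values", ())),
                    published_or=td.get("or"),
                    published_ci=tuple(td["ci"]) if td.get("ci") else None,
                )
            )
        window = d.get("day_window")
        return cls(
            model_id=model_id,
            intercept=float(d["intercept"]),
            intercept_se=d.get("intercept_se"),
            terms=tuple(terms),
            day_window=tuple(window) if window else None,
            description=d.get("description", ""),
        )


@dataclass(frozen=True)
class CategoryBands:
    """Three ascending probability thresholds splitting [0,1] into four
    severity intervals: [0,t1] mild, (t1,t2] moderate, (t2,t3] severe,
    (t3,1] very_severe."""

    thresholds: tuple
    provenance: str = "published_table4"

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 3:
            raise ConfigError("CategoryBands needs exactly three thresholds")
        if not (0.0 < t[0] < t[1] < t[2] < 1.0):
            raise ConfigError(f"thresholds must be strictly increasing in (0,1): {t}")
        object.__setattr__(self, "thresholds", t)


@dataclass(frozen=True)
class RiskPrediction:
    """Scored record: linear predictor, death/survival probability, category."""

    model_id: str
    z: float
    p_death: float
    p_survival: float
    category: Optional[str] = None

    @property
    def p_death_percent(self) -> float:
        """Mortality as a percentage rounded to one decimal (calculator style)."""
        return round(100.0 * self.p_death, 1)

    @property
    def p_survival_percent(self) -> float:
        return round(100.0 - 100.0 * self.p_death, 1)


# ---------------------------------------------------------------------------
# published constants

@lru_cache(maxsize=1)
def _published_data() -> dict:
    with resources.files("neorisk.data").joinpath("published_models.json").open() as fh:
        return json.load(fh)


def load_published_models() -> dict:
    """Return the four published ModelSpecs keyed by model id."""
    raw = _published_data()
    return {mid: ModelSpec.from_dict(mid, d) for mid, d in raw["models"].items()}


def published_model(model_id: str) -> ModelSpec:
    models = load_published_models()
    try:
        return models[model_id]
    except KeyError:
        raise ConfigError(f"unknown model id {model_id!r}; known: {sorted(models)}") from None


def published_cutoffs() -> dict:
    """Kappa-optimal classification cut points from the development cohort."""
    return dict(_published_data()["cutoffs"])


def published_bands(model_id: str) -> CategoryBands:
    """Published FNR-derived severity band thresholds for ``model_id``."""
    bands = _published_data()["bands"]
    if model_id not in bands:
        raise ConfigError(f"no published bands for model {model_id!r}")
    return CategoryBands(tuple(bands[model_id]), provenance="published_table4")


# ---------------------------------------------------------------------------
# scoring

def _encode_series(term: Term, table: pd.DataFrame, day_of_life) -> np.ndarray:
    if term.kind == "days":
        day = np.asarray(day_of_life, dtype=float)
        if day.ndim == 0:
            day = np.full(len(table), float(day))
        return day
    if term.field not in table.columns:
        raise ScoringError(f"missing predictor column {term.field!r} for term {term.name!r}")
    col = table[term.field]
    if term.kind == "numeric":
        x = col.to_numpy(dtype=float) * term.scale
    elif term.kind == "flag":
        x = col.to_numpy(dtype=float)
    elif term.kind == "equals":
        x = (col == term.value).to_numpy(dtype=float)
    else:  # "in"
        x = col.isin(term.values).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ScoringError(f"non-finite values in predictor {term.field!r}")
    return x


def design_matrix(model: ModelSpec, table: pd.DataFrame, day_of_life=None) -> pd.DataFrame:
    """Encode a patient table into the model's design matrix (no intercept).

    ``day_of_life`` may be a scalar applied to every row or an array-like of
    per-row days; it is required whenever the model has a day term.
    """
    if any(t.kind == "days" for t in model.terms) and day_of_life is None:
        raise ScoringError(f"model {model.model_id} requires day_of_life")
    missing = [f for f in model.required_fields() if f not in table.columns]
    if missing:
        raise ScoringError(
            f"model {model.model_id}: missing predictor column(s) {sorted(set(missing))}"
        )
    data = {t.name: _encode_series(t, table, day_of_life) for t in model.terms}
    return pd.DataFrame(data, index=table.index)


def score_table(model: ModelSpec, table: pd.DataFrame, day_of_life=None) -> np.ndarray:
    """Vectorised linear predictor z for every row of ``table``."""
    X = design_matrix(model, table, day_of_life)
    beta = np.array([t.beta for t in model.terms], dtype=float)
    return model.intercept + X.to_numpy(dtype=float) @ beta


def linear_predictor(model: ModelSpec, patient: Mapping, day_of_life: Optional[int] = None) -> float:
    """Linear predictor z = intercept + sum(beta_j * x_j) for one record.

    Raises ``ScoringError`` if a predictor is missing and ``StratumError`` if
    a day-stratified model is applied outside its window.
    """
    model.check_day(day_of_life)
    if isinstance(patient, pd.Series):
        row = patient.to_frame().T
    else:
        row = pd.DataFrame([dict(patient)])
    return float(score_table(model, row, day_of_life)[0])


def death_probability(z):
    """Logistic death probability 1 / (1 + e^-z); accepts scalars or arrays."""
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ScoringError("linear predictor must be finite")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z_arr))
    return float(p) if np.isscalar(z) or z_arr.ndim == 0 else p


def odds_ratio(beta: float, se: float):
    """Odds ratio exp(beta) with 95% Wald CI exp(beta +/- 1.96*se)."""
    if not se > 0:
        raise ConfigError("standard error must be > 0")
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


def categorize(p_death: float, bands: CategoryBands) -> str:
    """Map a death probability to a severity category.

    Intervals are [0,t1] -> mild, (t1,t2] -> moderate, (t2,t3] -> severe,
    (t3,1] -> very_severe; boundary values belong to the lower interval.
    """
    p = float(p_death)
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise ConfigError(f"probability out of [0,1]: {p}")
    t1, t2, t3 = bands.thresholds
    if p <= t1:
        return "mild"
    if p <= t2:
        return "moderate"
    if p <= t3:
        return "severe"
    return "very_severe"


def select_submodel(day_of_life: int) -> str:
    """Route a day of life to the during-admission sub-model (day 30 split)."""
    day = int(day_of_life)
    if day < 1:
        raise ConfigError(f"day_of_life must be >= 1, got {day}")
    return "M3_early" if day <= 30 else "M3_late"


def predict_record(model: ModelSpec, patient: Mapping, day_of_life=None,
                   bands: Optional[CategoryBands] = None) -> RiskPrediction:
    """Score one record: z, death/survival probability and severity category."""
    z = linear_predictor(model, patient, day_of_life)
    p = death_probability(z)
    cat = categorize(p, bands) if bands is not None else None
    return RiskPrediction(model_id=model.model_id, z=z, p_death=p,
                          p_survival=1.0 - p, category=cat)


def predict_table(model: ModelSpec, table: pd.DataFrame, day_of_life=None,
                  bands: Optional[CategoryBands] = None) -> pd.DataFrame:
    """Score every row; returns a frame with z, p_death, p_survival, category."""
    z = score_table(model, table, day_of_life)
    p = death_probability(z)
    out = pd.DataFrame(
        {"z": z, "p_death": p, "p_survival": 1.0 - p}, index=table.index
    )
    out["model_id"] = model.model_id
    if bands is not None:
        out["category"] = [categorize(pi, bands) for pi in p]
    return out
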