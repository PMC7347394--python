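"""Validation-stage statistics.

Discrimination (AUC with DeLong CI), accuracy at a fixed cutoff, Cohen Kappa
with the strength-of-concordance bands, Brier score, Hosmer-Lemeshow
calibration, Nagelkerke pseudo-R2, FNR at band thresholds, and the real-time
per-day scoring scenario for the during-admission model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .development import DEFAULT_EXPANSION_RULE, ExpansionRule, apply_time_windows, fnr_at
from .exceptions import ConfigError, SchemaError
from .models import (CategoryBands, ModelSpec, load_published_models,
                     score_table, select_submodel)

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "brier",
    "cohen_kappa",
    "kappa_strength",
    "accuracy_at_cutoff",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "real_time_scenario",
    "evaluate_model",
    "timing_percentages",
    "EvaluationReport",
    "RealTimeResult",
]

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


def _coerce_binary(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "OUS":
        return (np.char.lower(arr.astype(str)) == "died").astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# discrimination

def auc(scores, outcomes):
    """AUC in the Mann-Whitney form (ties get half credit) with a 95% DeLong CI.

    Returns ``(auc, ci_low, ci_high)``. Requires both outcome classes.
    """
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    if len(s) != len(y):
        raise ConfigError("scores and outcomes must have equal length")
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ConfigError("both outcome classes required for AUC")

    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    point = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong structural components
    v01 = (all_ranks[:m] - pos_ranks) / n
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.96 * np.sqrt(max(var, 0.0))
    return float(point), float(max(0.0, point - half)), float(min(1.0, point + half))


def brier(probs, outcomes) -> float:
    """Mean squared deviation between predicted probabilities and outcomes."""
    p = np.asarray(probs, dtype=float)
    y = _coerce_binary(outcomes)
    if len(p) != len(y):
        raise ConfigError("probs and outcomes must have equal length")
    if len(p) == 0:
        raise ConfigError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("probabilities must lie in [0,1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# agreement

def kappa_strength(kappa: float) -> str:
    """Strength-of-concordance label for a Kappa value."""
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "very good"


def cohen_kappa(predicted, observed):
    """Chance-corrected agreement between two binary vectors.

    Returns ``(kappa, strength_label)``. When expected agreement is 1 (both
    vectors constant and equal) kappa is defined as 1 with a warning.
    """
    a = _coerce_binary(predicted)
    b = _coerce_binary(observed)
    if len(a) != len(b):
        raise ConfigError("inputs must have equal length")
    if len(a) == 0:
        raise ConfigError("empty input")
    n = len(a)
    po = float(np.mean(a == b))
    pe = float((np.mean(a) * np.mean(b)) + ((1 - np.mean(a)) * (1 - np.mean(b))))
    if pe >= 1.0 - 1e-15:
        warnings.warn("expected agreement is 1; kappa defined as 1", stacklevel=2)
        k = 1.0
    else:
        k = (po - pe) / (1.0 - pe)
    return float(k), kappa_strength(k)


def accuracy_at_cutoff(scores, outcomes, cutoff: float) -> float:
    """Percent of records classified correctly with predicted-death iff
    score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    pred = (s >= cutoff).astype(int)
    return float(100.0 * np.mean(pred == y))


def confusion_counts(scores, outcomes, cutoff: float) -> dict:
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    pred = (s >= cutoff).astype(int)
    return {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
    }


# ---------------------------------------------------------------------------
# calibration

def hosmer_lemeshow(probs, outcomes, g: int = 10):
    """Hosmer-Lemeshow grouped calibration test.

    Equal-frequency groups of predicted risk (ties collapsed and merged, with
    a log note), Pearson statistic over observed vs expected deaths and
    survivals, p-value from chi-square with (groups - 2) df.
    Returns ``(statistic, p_value)``.
    """
    p = np.asarray(probs, dtype=float)
    y = _coerce_binary(outcomes)
    n = len(p)
    if n < 2 * g:
        raise ConfigError(f"need at least {2 * g} observations for g={g} groups")
    groups = pd.qcut(p, g, labels=False, duplicates="drop")
    n_groups = int(groups.max()) + 1
    if n_groups < g:
        logger.info("hosmer_lemeshow: tie collapse reduced %d groups to %d", g, n_groups)
    if n_groups < 2:
        raise ConfigError("fewer than 2 distinct risk groups; test undefined")
    stat = 0.0
    for k in range(n_groups):
        mask = groups == k
        nk = int(mask.sum())
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        denom = exp * (1.0 - exp / nk)
        if denom <= 0:
            denom = 1e-10
        stat += (obs - exp) ** 2 / denom
    df = max(n_groups - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Rescaled likelihood-ratio pseudo-R2.

    R2 = (1 - exp(2(L0 - L1)/n)) / (1 - exp(2*L0/n)).
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ConfigError("model log-likelihood below null log-likelihood")
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        raise ConfigError("degenerate null likelihood")
    return float((1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)) / denom)


def _bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    q = np.clip(p, 1e-15, 1 - 1e-15)
    return float(np.sum(y * np.log(q) + (1 - y) * np.log1p(-q)))


# ---------------------------------------------------------------------------
# reports

@dataclass
class EvaluationReport:
    """Validation-stage summary for one model on one cohort."""

    model_id: str
    n: int
    deaths: int
    auc: float
    auc_ci: tuple
    brier: float
    nagelkerke: Optional[float]
    hl_statistic: float
    hl_groups: int
    hl_p: float
    cutoff: float
    accuracy: float
    kappa: float
    kappa_strength: str
    confusion: dict
    band_thresholds: Optional[tuple] = None
    band_fnr: Optional[tuple] = None

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "n": self.n,
            "deaths": self.deaths,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "brier": self.brier,
            "nagelkerke_r2": self.nagelkerke,
            "hosmer_lemeshow": {"statistic": self.hl_statistic,
                                "groups": self.hl_groups, "p": self.hl_p},
            "cutoff": self.cutoff,
            "accuracy_percent": self.accuracy,
            "kappa": self.kappa,
            "kappa_strength": self.kappa_strength,
            "confusion": self.confusion,
        }
        if self.band_thresholds is not None:
            d["bands"] = {"thresholds": list(self.band_thresholds),
                          "fnr": list(self.band_fnr)}
        return d

    def to_text(self) -> str:
        lines = [
            f"Model {self.model_id}: n={self.n} ({self.deaths} died)",
            f"  AUC        {self.auc:.3f} (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})",
            f"  Brier      {self.brier:.3f}",
            f"  Kappa      {self.kappa:.3f} ({self.kappa_strength}) at cutoff {self.cutoff:g}",
            f"  Accuracy   {self.accuracy:.2f}%",
            f"  HL         chi2={self.hl_statistic:.2f} (g={self.hl_groups}), p={self.hl_p:.3g}",
        ]
        if self.nagelkerke is not None:
            lines.append(f"  Nagelkerke R2 {self.nagelkerke:.3f}")
        if self.band_thresholds is not None:
            ts = ", ".join(f"{t:g}" for t in self.band_thresholds)
            lines.append(f"  Severity band thresholds: {ts}")
        return "\n".join(lines)


def evaluate_model(probs, outcomes, cutoff: float, model_id: str = "model",
                   bands: Optional[CategoryBands] = None, hl_groups: int = 10) -> EvaluationReport:
    """Full validation-stage report for predicted probabilities vs outcomes.

    Nagelkerke R2 is computed from the Bernoulli log-likelihood of the
    supplied probabilities against the prevalence-only null; it is reported
    as None when the model likelihood falls below the null (possible for a
    transported model that was never fit to this cohort).
    """
    p = np.asarray(probs, dtype=float)
    y = _coerce_binary(outcomes)
    point, lo, hi = auc(p, y)
    pred = (p >= cutoff).astype(int)
    k, label = cohen_kappa(pred, y)
    hl_stat, hl_p = hosmer_lemeshow(p, y, g=hl_groups)
    groups_used = min(hl_groups, len(np.unique(pd.qcut(p, hl_groups, labels=False, duplicates="drop"))))
    l1 = _bernoulli_loglik(p, y)
    prevalence = float(np.mean(y))
    l0 = _bernoulli_loglik(np.full(len(y), prevalence), y)
    try:
        r2 = nagelkerke_r2(l1, l0, len(y))
    except ConfigError:
        logger.info("evaluate_model: model likelihood below null; R2 omitted")
        r2 = None
    band_thresholds = band_fnr = None
    if bands is not None:
        band_thresholds = tuple(bands.thresholds)
        band_fnr = tuple(fnr_at(p, y, t) for t in bands.thresholds)
    return EvaluationReport(
        model_id=model_id, n=len(y), deaths=int(y.sum()),
        auc=point, auc_ci=(lo, hi), brier=brier(p, y), nagelkerke=r2,
        hl_statistic=hl_stat, hl_groups=groups_used, hl_p=hl_p,
        cutoff=float(cutoff), accuracy=accuracy_at_cutoff(p, y, cutoff),
        kappa=k, kappa_strength=label,
        confusion=confusion_counts(p, y, cutoff),
        band_thresholds=band_thresholds, band_fnr=band_fnr,
    )


@dataclass
class RealTimeResult:
    """Per-day discrimination of the during-admission model."""

    per_day: dict
    mean_auc: Optional[float]

    def to_dict(self) -> dict:
        return {"per_day": {str(d): v for d, v in self.per_day.items()},
                "mean_auc": self.mean_auc}


def real_time_scenario(cohort: pd.DataFrame, models: Optional[Mapping] = None,
                       rule: ExpansionRule = DEFAULT_EXPANSION_RULE,
                       days: Sequence = (1, 8, 15, 31, 61)) -> RealTimeResult:
    """Score the during-admission model as if evaluated live on given days.

    For each day d: keep patients with length of stay >= d, gate diagnoses by
    the applicability windows at day d, score with the day-appropriate
    sub-model and compute the AUC against final outcome. Days whose subset
    has a single outcome class are reported as undefined and excluded from
    the unweighted mean.
    """
    if "length_of_stay" not in cohort.columns or "outcome" not in cohort.columns:
        raise SchemaError("real_time_scenario requires length_of_stay and outcome")
    models = dict(models) if models is not None else load_published_models()
    per_day = {}
    aucs = []
    for d in days:
        subset = cohort[cohort["length_of_stay"] >= d]
        model_id = select_submodel(d)
        if subset.empty or subset["outcome"].nunique() < 2:
            logger.info("real_time_scenario: day %d skipped (single outcome class)", d)
            per_day[int(d)] = {"model_id": model_id, "n": int(len(subset)), "auc": None}
            continue
        gated = apply_time_windows(subset, int(d), rule)
        z = score_table(models[model_id], gated, day_of_life=int(d))
        point, lo, hi = auc(expit(z), gated["outcome"])
        per_day[int(d)] = {"model_id": model_id, "n": int(len(subset)),
                           "auc": point, "auc_ci": [lo, hi]}
        aucs.append(point)
    mean_auc = float(np.mean(aucs)) if aucs else None
    return RealTimeResult(per_day=per_day, mean_auc=mean_auc)


def timing_percentages(counts: Sequence) -> tuple:
    """Death-timing percentages (one decimal) from window counts.

    E.g. counts (373, 1315, 327) -> (18.5, 65.3, 16.2).
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ConfigError("counts must sum to a positive total")
    return tuple(round(100.0 * x / total, 1) for x in c)
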