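"""Model-development stage.

Covers univariable preselection, the pseudo-evolution day expansion with
diagnosis time-window gating, maximum-likelihood logistic fitting (including
the day-30 stratified during-admission model), Kappa-optimal cutoff search
and FNR-based severity band derivation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigError, SchemaError, StratumError
from .models import CategoryBands, ModelSpec, Term, design_matrix, published_model

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionRule",
    "FitResult",
    "CutoffResult",
    "DEFAULT_EXPANSION_RULE",
    "preselect_variables",
    "apply_time_windows",
    "expand_pseudo_days",
    "fit_logistic",
    "refit_model",
    "fit_dynamic_model3",
    "select_cutoff_max_kappa",
    "derive_fnr_thresholds",
]


@dataclass(frozen=True)
class ExpansionRule:
    """Standardized pseudo-days and diagnosis applicability windows.

    ``windows`` maps a diagnosis family to ``(start, end)`` in days of life;
    ``end=None`` means open-ended, retained strictly after ``start``. Closed
    windows are inclusive on both sides. Gating applies to the plain flag and
    its severe counterpart alike.
    """

    standardized_days: tuple = (1, 3, 8, 15, 22, 31, 46, 61)
    windows: Mapping = field(default_factory=lambda: {
        "rds": (0, 7),
        "nec": (14, 45),
        "ivh": (0, 10),
        "pvl": (21, None),
        "bpd": (28, None),
    })
    #: columns gated by each window family
    family_columns: Mapping = field(default_factory=lambda: {
        "rds": ("rds", "severe_rds"),
        "nec": ("nec", "severe_nec"),
        "ivh": ("ivh", "severe_ivh"),
        "pvl": ("pvl", "severe_pvl"),
        "bpd": ("bpd", "severe_bpd"),
    })

    def __post_init__(self):
        days = tuple(int(d) for d in self.standardized_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("standardized_days must be strictly increasing")
        for fam, (start, end) in self.windows.items():
            if end is not None and end < start:
                raise ConfigError(f"window for {fam!r} has start > end")
        object.__setattr__(self, "standardized_days", days)

    def active(self, family: str, day: int) -> bool:
        start, end = self.windows[family]
        if end is None:
            return day > start
        return start <= day <= end


DEFAULT_EXPANSION_RULE = ExpansionRule()


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood logistic fit."""

    model: ModelSpec
    loglik: float
    loglik_null: float
    converged: bool
    n_used: int
    dropped: list = field(default_factory=list)
    diagnostics: str = ""

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "beta": self.model.intercept,
                 "se": self.model.intercept_se}]
        for t in self.model.terms:
            rows.append({"term": t.name, "beta": t.beta, "se": t.se})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    kappa: float


# ---------------------------------------------------------------------------
# univariable preselection

def preselect_variables(cohort: pd.DataFrame, candidates: Mapping, alpha: float = 0.15,
                        outcome: str = "outcome") -> pd.DataFrame:
    """Univariable screen against the outcome.

    ``candidates`` maps variable name to ``"categorical"`` or
    ``"continuous"``. Categorical variables are tested with the chi-square
    contingency test (Yates continuity correction on 2x2 tables),
    continuous ones with the two-sided Mann-Whitney U (asymptotic, tie
    corrected). A variable is kept iff p < alpha. Returns one row per
    candidate with the test used, p-value, selection flag and any exclusion
    reason (constant columns are excluded as "degenerate").
    """
    if outcome not in cohort.columns:
        raise SchemaError(f"outcome column {outcome!r} not in table")
    y = _binary_outcome(cohort[outcome])
    rows = []
    for name, var_type in candidates.items():
        if name not in cohort.columns:
            rows.append({"variable": name, "type": var_type, "test": None,
                         "p_value": np.nan, "selected": False, "reason": "missing column"})
            continue
        col = cohort[name]
        if col.nunique(dropna=True) < 2:
            rows.append({"variable": name, "type": var_type, "test": None,
                         "p_value": np.nan, "selected": False, "reason": "degenerate"})
            continue
        reason = ""
        if var_type == "categorical":
            table = pd.crosstab(col, y)
            chi2_res = stats.chi2_contingency(table.to_numpy())
            p = float(chi2_res.pvalue)
            test = "chi-square"
            if (chi2_res.expected_freq < 5).any():
                reason = "small expected cell"
                logger.info("preselect: %s has expected cells < 5", name)
        elif var_type == "continuous":
            x = col.to_numpy(dtype=float)
            g1, g0 = x[y == 1], x[y == 0]
            p = float(stats.mannwhitneyu(g1, g0, alternative="two-sided",
                                         method="asymptotic").pvalue)
            test = "mann-whitney"
        else:
            raise ConfigError(f"candidate {name!r}: type must be categorical or continuous")
        rows.append({"variable": name, "type": var_type, "test": test,
                     "p_value": p, "selected": bool(p < alpha), "reason": reason})
    return pd.DataFrame(rows)


def _binary_outcome(series: pd.Series) -> np.ndarray:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return (series.astype(str).str.lower() == "died").to_numpy(dtype=int)
    return series.to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# pseudo-evolution expansion

def apply_time_windows(table: pd.DataFrame, pseudo_day, rule: ExpansionRule = DEFAULT_EXPANSION_RULE) -> pd.DataFrame:
    """Zero out windowed diagnosis flags that do not apply at ``pseudo_day``.

    ``pseudo_day`` may be a scalar or a per-row array. Non-windowed columns
    pass through untouched; a gated flag never exceeds the original flag.
    """
    out = table.copy()
    day = np.asarray(pseudo_day)
    if day.ndim == 0:
        day = np.full(len(out), int(day))
    for family, cols in rule.family_columns.items():
        start, end = rule.windows[family]
        active = (day > start) if end is None else ((day >= start) & (day <= end))
        for col in cols:
            if col in out.columns:
                out[col] = np.where(active, out[col].to_numpy(), 0)
    return out


def expand_pseudo_days(cohort: pd.DataFrame, rule: ExpansionRule = DEFAULT_EXPANSION_RULE) -> pd.DataFrame:
    """Replicate each patient over the standardized days within their stay.

    One row per (patient, d) for every standardized day d <= length of stay;
    for deceased patients rows stop at the day of death. Each row carries the
    pseudo-day as ``pseudo_day``, window-gated diagnosis flags and the
    patient's final hospital outcome.
    """
    if "length_of_stay" not in cohort.columns:
        raise SchemaError("expand_pseudo_days requires length_of_stay")
    los = cohort["length_of_stay"].to_numpy(dtype=int)
    limit = los.astype(float)
    if "day_of_death" in cohort.columns:
        dod = pd.to_numeric(cohort["day_of_death"], errors="coerce").to_numpy(dtype=float)
        limit = np.fmin(limit, np.where(np.isnan(dod), np.inf, dod))
    days = np.asarray(rule.standardized_days)

    pieces = []
    for d in days:
        mask = limit >= d
        if not mask.any():
            continue
        block = cohort.loc[mask].copy()
        block["pseudo_day"] = int(d)
        pieces.append(apply_time_windows(block, int(d), rule))
    if not pieces:
        out = cohort.iloc[0:0].copy()
        out["pseudo_day"] = pd.Series(dtype=int)
        return out
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["id", "pseudo_day"], kind="stable").reset_index(drop=True) \
        if "id" in out.columns else out.reset_index(drop=True)


def expected_expansion_rows(length_of_stay: Iterable, rule: ExpansionRule = DEFAULT_EXPANSION_RULE,
                            day_of_death: Optional[Iterable] = None) -> int:
    """Closed-form row count: sum over patients of |{d in days : d <= limit}|."""
    los = np.asarray(list(length_of_stay), dtype=float)
    limit = los
    if day_of_death is not None:
        dod = np.array([np.nan if pd.isna(d) else float(d) for d in day_of_death])
        limit = np.fmin(los, np.where(np.isnan(dod), np.inf, dod))
    days = np.asarray(rule.standardized_days, dtype=float)
    return int(sum((days <= lim).sum() for lim in limit))


# ---------------------------------------------------------------------------
# logistic fitting

def _drop_collinear(X: pd.DataFrame) -> tuple:
    """Greedily drop later columns until the design (with intercept) has full
    column rank. Returns (reduced X, [(name, reason), ...])."""
    dropped = []
    cols = list(X.columns)
    mat = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in cols])
    rank = np.linalg.matrix_rank(mat)
    while rank < mat.shape[1] and cols:
        # drop the latest column whose removal does not reduce the rank
        for j, c in sorted(enumerate(cols), reverse=True):
            sub = np.delete(mat, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                dropped.append((c, "collinear"))
                logger.info("fit_logistic: dropping collinear column %s", c)
                cols.pop(j)
                mat = sub
                break
        else:  # pragma: no cover - defensive
            break
        rank = np.linalg.matrix_rank(mat)
    return X[cols], dropped


def fit_logistic(table: pd.DataFrame, outcome: str, variables: Sequence) -> FitResult:
    """Maximum-likelihood logistic regression of ``outcome`` on ``variables``.

    Complete-case analysis; collinear columns are dropped (and logged) before
    fitting; separation or non-convergence is flagged in the result rather
    than raised.
    """
    if outcome not in table.columns:
        raise SchemaError(f"outcome column {outcome!r} not in table")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise SchemaError(f"variables missing from table: {missing}")
    sub = table[list(variables) + [outcome]].dropna()
    y = _binary_outcome(sub[outcome])
    if len(np.unique(y)) < 2:
        raise ConfigError("outcome has a single class; cannot fit")
    X = sub[list(variables)].astype(float)
    n_dropped_rows = len(table) - len(sub)
    if n_dropped_rows:
        logger.info("fit_logistic: %d incomplete rows dropped", n_dropped_rows)
    X, dropped = _drop_collinear(X)
    if len(sub) <= X.shape[1] + 1:
        raise ConfigError("fewer observations than parameters")

    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    diagnostics = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in statsmodels
            converged = False
            diagnostics = f"fit failed: {exc}"
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="bfgs")
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
                converged = False
                diagnostics = diagnostics or str(w.message)
    if converged:
        converged = bool(res.mle_retvals.get("converged", True))

    params = res.params
    ses = res.bse.copy()
    ses[~np.isfinite(ses) | (ses <= 0)] = np.nan
    terms = tuple(
        Term(name=c, field=c, kind="numeric", beta=float(params[c]),
             se=float(ses[c]) if np.isfinite(ses[c]) else 1e-6)
        for c in X.columns
    )
    spec = ModelSpec(model_id="fitted", intercept=float(params["const"]),
                     intercept_se=float(ses["const"]) if np.isfinite(ses["const"]) else None,
                     terms=terms, description="fitted logistic model")
    return FitResult(model=spec, loglik=float(res.llf), loglik_null=float(res.llnull),
                     converged=converged, n_used=len(sub), dropped=dropped,
                     diagnostics=diagnostics)


def refit_model(spec: ModelSpec, table: pd.DataFrame, outcome: str = "outcome",
                day_of_life=None) -> FitResult:
    """Re-estimate the coefficients of ``spec`` on ``table`` keeping its term
    structure and encodings (the shared design-matrix code path)."""
    X = design_matrix(spec, table, day_of_life=day_of_life)
    X[outcome] = table[outcome].to_numpy()
    fit = fit_logistic(X, outcome, [t.name for t in spec.terms])
    betas = {t.name: t.beta for t in fit.model.terms}
    ses = {t.name: t.se for t in fit.model.terms}
    # terms dropped as collinear keep beta 0 so the spec structure is preserved
    for t in spec.terms:
        betas.setdefault(t.name, 0.0)
        ses.setdefault(t.name, 1e-6)
    refitted = spec.with_coefficients(fit.model.intercept, betas, ses)
    refitted = ModelSpec(model_id=spec.model_id, intercept=refitted.intercept,
                         intercept_se=fit.model.intercept_se, terms=refitted.terms,
                         day_window=spec.day_window,
                         description=f"refit of {spec.model_id}")
    return FitResult(model=refitted, loglik=fit.loglik, loglik_null=fit.loglik_null,
                     converged=fit.converged, n_used=fit.n_used, dropped=fit.dropped,
                     diagnostics=fit.diagnostics)


def fit_dynamic_model3(cohort: pd.DataFrame, rule: ExpansionRule = DEFAULT_EXPANSION_RULE,
                       spec_early: Optional[ModelSpec] = None,
                       spec_late: Optional[ModelSpec] = None) -> tuple:
    """Fit the day-30 stratified during-admission model on expanded rows.

    The cohort is pseudo-day expanded; rows with pseudo_day <= 30 feed the
    early sub-model and the rest the late sub-model, with the pseudo-day
    entering both as the numeric days-of-life covariate. Term structures
    default to the published during-admission sub-models.
    """
    spec_early = spec_early or published_model("M3_early")
    spec_late = spec_late or published_model("M3_late")
    expanded = expand_pseudo_days(cohort, rule)
    early = expanded[expanded["pseudo_day"] <= 30]
    late = expanded[expanded["pseudo_day"] > 30]
    if early.empty:
        raise StratumError("early stratum (days <= 30) is empty")
    if late.empty:
        raise StratumError("late stratum (days > 30) is empty")
    fit_early = refit_model(spec_early, early, day_of_life=early["pseudo_day"].to_numpy())
    fit_late = refit_model(spec_late, late, day_of_life=late["pseudo_day"].to_numpy())
    return fit_early, fit_late


# ---------------------------------------------------------------------------
# cutoff and band selection

def _kappa_curve(scores: np.ndarray, y: np.ndarray) -> tuple:
    """Cohen Kappa of (score >= t) vs y for every unique candidate t.

    Vectorised via suffix counts on the sorted scores: O(n log n).
    """
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    yy = y[order]
    n = len(s)
    pos_total = yy.sum()
    # suffix sums: predictions positive for indices >= k
    suffix_pos = np.concatenate([np.cumsum(yy[::-1])[::-1], [0]])
    first_idx = np.flatnonzero(np.concatenate([[True], s[1:] != s[:-1]]))
    cand = s[first_idx]
    k = first_idx  # cutoff = cand -> predicted positive are indices >= k
    tp = suffix_pos[k]
    pred_pos = n - k
    fp = pred_pos - tp
    fn = pos_total - tp
    tn = n - pred_pos - fn
    po = (tp + tn) / n
    pe = (pred_pos * pos_total + (n - pred_pos) * (n - pos_total)) / (n * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 1.0)
    return cand, kappa


def select_cutoff_max_kappa(scores, outcomes) -> CutoffResult:
    """Cutoff over all unique score values maximizing Cohen Kappa of
    (score >= cutoff) vs outcome; ties broken toward the smallest cutoff."""
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    if len(np.unique(y)) < 2:
        raise ConfigError("both outcome classes required to select a cutoff")
    cand, kappa = _kappa_curve(s, y)
    best = float(np.max(kappa))
    idx = int(np.flatnonzero(kappa >= best - 1e-12)[0])
    return CutoffResult(cutoff=float(cand[idx]), kappa=best)


def _coerce_binary(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "OUS":
        return (np.char.lower(arr.astype(str)) == "died").astype(int)
    return arr.astype(int)


def fnr_at(scores, outcomes, threshold: float) -> float:
    """False negative rate: deaths scoring strictly below the threshold over
    all deaths."""
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    n_dead = int(y.sum())
    if n_dead == 0:
        raise ConfigError("FNR undefined with no deaths")
    return float(np.sum((s < threshold) & (y == 1)) / n_dead)


def derive_fnr_thresholds(scores, outcomes, fnr_levels=(0.20, 0.50, 0.80)) -> CategoryBands:
    """Severity-band thresholds from the empirical FNR curve.

    For each target level q the threshold is the smallest observed score t
    with FNR(t) >= q. Duplicate thresholds are perturbed to the next distinct
    observed score (logged) so the bands stay strictly increasing.
    """
    s = np.asarray(scores, dtype=float)
    y = _coerce_binary(outcomes)
    n_dead = int(y.sum())
    if n_dead == 0:
        raise ConfigError("at least one death required to derive FNR thresholds")
    uniq = np.unique(s)
    dead_sorted = np.sort(s[y == 1])
    # FNR at candidate t = #(dead < t) / n_dead
    fnr = np.searchsorted(dead_sorted, uniq, side="left") / n_dead

    thresholds = []
    for q in fnr_levels:
        idx = np.flatnonzero(fnr >= q)
        t = float(uniq[idx[0]]) if len(idx) else float(uniq[-1])
        thresholds.append(t)
    # enforce strict increase by bumping duplicates to the next distinct score
    for i in range(1, len(thresholds)):
        if thresholds[i] <= thresholds[i - 1]:
            nxt = uniq[uniq > thresholds[i - 1]]
            bumped = float(nxt[0]) if len(nxt) else np.nextafter(thresholds[i - 1], np.inf)
            logger.info("derive_fnr_thresholds: bumping duplicate threshold %g -> %g",
                        thresholds[i], bumped)
            thresholds[i] = bumped
    # CategoryBands requires values in (0,1); clip pathological edges
    eps = 1e-9
    thresholds = list(np.clip(thresholds, eps, 1 - eps))
    for i in range(1, 3):
        if thresholds[i] <= thresholds[i - 1]:
            thresholds[i] = min(1 - eps, thresholds[i - 1] + eps)
    return CategoryBands(tuple(thresholds), provenance="derived_from_data")
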