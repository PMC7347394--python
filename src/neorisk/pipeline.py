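"""End-to-end orchestration: simulate -> develop -> validate -> predict.

Every machine-readable artifact is stamped with the seed and a hash of the
resolved configuration, so any number in any output can be regenerated from
config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import development as dev
from . import evaluation as ev
from .cohort import PLAIN_DIAGNOSES, SEVERE_DIAGNOSES, CohortConfig, generate_cohort
from .exceptions import ConfigError, SchemaError
from .io import write_cohort
from .models import (CategoryBands, ModelSpec, death_probability, predict_table,
                     published_bands, published_cutoffs, published_model,
                     score_table, select_submodel)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "develop_models", "validate_models", "predict_cohort",
            "config_hash", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_development": 4000,
        "n_validation": 3000,
        "true_model": "M1",
        "target_mortality": 0.148,
    },
    "develop": {"fnr_levels": [0.20, 0.50, 0.80]},
    "validate": {"bands": "published"},
}

_CATEGORICAL_CANDIDATES = (
    "maternal_steroids", "chorioamnionitis", "maternal_hypertension",
    "multiple_pregnancy", "sex", "low_weight_p10", "inborn", "level_of_care",
    "cesarean", "resuscitation", "postnatal_steroids",
) + PLAIN_DIAGNOSES + SEVERE_DIAGNOSES
_CONTINUOUS_CANDIDATES = (
    "gestational_age", "birth_weight", "apgar1", "apgar5", "admission_temp", "crib1",
)


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _merge_config(config: Optional[Mapping]) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# development stage

def develop_models(cohort: pd.DataFrame, fnr_levels=(0.20, 0.50, 0.80),
                   rule: dev.ExpansionRule = dev.DEFAULT_EXPANSION_RULE) -> dict:
    """Run the full development stage on a cohort.

    Preselects candidates, re-estimates the four equations (the
    during-admission pair on pseudo-day expanded rows), picks Kappa-optimal
    cutoffs and derives FNR severity bands on the training scores.
    """
    candidates = {c: "categorical" for c in _CATEGORICAL_CANDIDATES}
    candidates.update({c: "continuous" for c in _CONTINUOUS_CANDIDATES})
    preselection = dev.preselect_variables(cohort, candidates)

    results = {"preselection": preselection, "fits": {}, "cutoffs": {}, "bands": {}}

    for model_id in ("M1", "M2"):
        fit = dev.refit_model(published_model(model_id), cohort)
        z = score_table(fit.model, cohort)
        probs = death_probability(z)
        cut = dev.select_cutoff_max_kappa(probs, cohort["outcome"])
        bands = dev.derive_fnr_thresholds(probs, cohort["outcome"], fnr_levels)
        results["fits"][model_id] = fit
        results["cutoffs"][model_id] = cut
        results["bands"][model_id] = bands

    fit_early, fit_late = dev.fit_dynamic_model3(cohort, rule)
    expanded = dev.expand_pseudo_days(cohort, rule)
    for model_id, fit in (("M3_early", fit_early), ("M3_late", fit_late)):
        mask = expanded["pseudo_day"] <= 30 if model_id == "M3_early" else expanded["pseudo_day"] > 30
        stratum = expanded[mask]
        z = score_table(fit.model, stratum, day_of_life=stratum["pseudo_day"].to_numpy())
        probs = death_probability(z)
        cut = dev.select_cutoff_max_kappa(probs, stratum["outcome"])
        bands = dev.derive_fnr_thresholds(probs, stratum["outcome"], fnr_levels)
        results["fits"][model_id] = fit
        results["cutoffs"][model_id] = cut
        results["bands"][model_id] = bands
    return results


def _development_artifact(results: dict) -> dict:
    return {
        "preselection": results["preselection"].to_dict(orient="records"),
        "models": {mid: fit.model.to_dict() for mid, fit in results["fits"].items()},
        "fit_stats": {
            mid: {"loglik": fit.loglik, "loglik_null": fit.loglik_null,
                  "converged": fit.converged, "n": fit.n_used,
                  "dropped": fit.dropped}
            for mid, fit in results["fits"].items()
        },
        "cutoffs": {mid: {"cutoff": c.cutoff, "kappa": c.kappa}
                    for mid, c in results["cutoffs"].items()},
        "bands": {mid: list(b.thresholds) for mid, b in results["bands"].items()},
    }


# ---------------------------------------------------------------------------
# validation stage

def validate_models(cohort: pd.DataFrame, models: Optional[Mapping] = None,
                    cutoffs: Optional[Mapping] = None,
                    bands: Optional[Mapping] = None,
                    rule: dev.ExpansionRule = dev.DEFAULT_EXPANSION_RULE) -> dict:
    """Validation stage: score a held-out cohort and compute the full report
    per model, plus the real-time per-day scenario for the during-admission
    pair. Defaults to the published equations, cut points and bands."""
    if models is None:
        models = {mid: published_model(mid) for mid in ("M1", "M2", "M3_early", "M3_late")}
    cutoffs = dict(cutoffs) if cutoffs is not None else published_cutoffs()
    reports = {}
    for model_id in ("M1", "M2"):
        model = models[model_id]
        probs = death_probability(score_table(model, cohort))
        band = bands[model_id] if bands else published_bands(model_id)
        reports[model_id] = ev.evaluate_model(
            probs, cohort["outcome"], cutoffs[model_id], model_id=model_id, bands=band
        )
    expanded = dev.expand_pseudo_days(cohort, rule)
    for model_id in ("M3_early", "M3_late"):
        mask = expanded["pseudo_day"] <= 30 if model_id == "M3_early" else expanded["pseudo_day"] > 30
        stratum = expanded[mask]
        if stratum.empty or stratum["outcome"].nunique() < 2:
            logger.info("validate: stratum %s empty or single-class; skipped", model_id)
            continue
        probs = death_probability(
            score_table(models[model_id], stratum, day_of_life=stratum["pseudo_day"].to_numpy())
        )
        band = bands[model_id] if bands else published_bands(model_id)
        reports[model_id] = ev.evaluate_model(
            probs, stratum["outcome"], cutoffs[model_id], model_id=model_id, bands=band
        )
    realtime = ev.real_time_scenario(cohort, models={k: models[k] for k in ("M3_early", "M3_late")},
                                     rule=rule)
    return {"reports": reports, "real_time": realtime}


# ---------------------------------------------------------------------------
# prediction

def predict_cohort(cohort: pd.DataFrame, model_choice: str, day: Optional[int] = None,
                   bands_source: str = "published",
                   derived_bands: Optional[Mapping] = None,
                   models: Optional[Mapping] = None) -> pd.DataFrame:
    """Score a cohort with one model (or with day-based sub-model routing).

    ``model_choice`` is M1, M2, M3_early, M3_late, or M3 (routes per record
    by ``day``, or by a ``day_of_life`` column when ``day`` is None).
    """
    models = dict(models) if models is not None else None

    def get_model(mid):
        return models[mid] if models else published_model(mid)

    def get_bands(mid):
        if bands_source == "derived":
            if not derived_bands or mid not in derived_bands:
                raise ConfigError(f"no derived bands available for {mid}")
            return derived_bands[mid]
        return published_bands(mid)

    if model_choice in ("M1", "M2"):
        return predict_table(get_model(model_choice), cohort, bands=get_bands(model_choice))
    if model_choice in ("M3_early", "M3_late"):
        model = get_model(model_choice)
        d = day if day is not None else cohort["day_of_life"].to_numpy()
        if np.ndim(d) == 0:
            model.check_day(int(d))
        return predict_table(model, cohort, day_of_life=d, bands=get_bands(model_choice))
    if model_choice == "M3":
        if day is not None:
            days = np.full(len(cohort), int(day))
        elif "day_of_life" in cohort.columns:
            days = cohort["day_of_life"].to_numpy(dtype=int)
        else:
            raise SchemaError("model M3 needs --day or a day_of_life column")
        out = []
        for mid in ("M3_early", "M3_late"):
            mask = (days <= 30) if mid == "M3_early" else (days > 30)
            if mask.any():
                part = predict_table(get_model(mid), cohort[mask],
                                     day_of_life=days[mask], bands=get_bands(mid))
                out.append(part)
        return pd.concat(out).sort_index()
    raise ConfigError(f"unknown model choice {model_choice!r}")


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: Optional[Mapping] = None, outdir="neorisk_run") -> dict:
    """simulate -> develop -> validate with artifacts on disk.

    Returns a manifest dict (also written to ``manifest.json``) naming every
    artifact; outputs are byte-identical across runs with the same config.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    h = config_hash(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": seed, "config_hash": h}

    sim = cfg["simulate"]
    dev_cfg = CohortConfig(n=int(sim["n_development"]), seed=seed,
                           true_model=sim.get("true_model", "M1"),
                           target_mortality=sim.get("target_mortality", 0.148))
    val_cfg = CohortConfig(n=int(sim["n_validation"]), seed=seed + 1,
                           true_model=sim.get("true_model", "M1"),
                           target_mortality=sim.get("target_mortality", 0.148))
    cohort_dev = generate_cohort(dev_cfg)
    cohort_val = generate_cohort(val_cfg)
    dev_csv = out / "cohort_development.csv"
    val_csv = out / "cohort_validation.csv"
    write_cohort(cohort_dev, dev_csv)
    write_cohort(cohort_val, val_csv)

    results = develop_models(cohort_dev, fnr_levels=tuple(cfg["develop"]["fnr_levels"]))
    dev_artifact = {**stamp, **_development_artifact(results)}
    _dump_json(dev_artifact, out / "development.json")

    fitted = {mid: fit.model for mid, fit in results["fits"].items()}
    cutoffs = {mid: c.cutoff for mid, c in results["cutoffs"].items()}
    band_choice = cfg["validate"].get("bands", "published")
    bands = results["bands"] if band_choice == "derived" else None
    validation = validate_models(cohort_val, models=fitted, cutoffs=cutoffs, bands=bands)
    val_artifact = {
        **stamp,
        "bands_provenance": band_choice,
        "reports": {mid: rep.to_dict() for mid, rep in validation["reports"].items()},
        "real_time": validation["real_time"].to_dict(),
    }
    _dump_json(val_artifact, out / "validation.json")
    with open(out / "validation.txt", "w") as fh:
        for rep in validation["reports"].values():
            fh.write(rep.to_text() + "\n\n")
        rt = validation["real_time"]
        fh.write("Real-time scenario AUC by day:\n")
        for d, info in rt.per_day.items():
            auc_txt = "undefined" if info["auc"] is None else f"{info['auc']:.3f}"
            fh.write(f"  day {d:>3} ({info['model_id']}): {auc_txt} (n={info['n']})\n")
        if rt.mean_auc is not None:
            fh.write(f"  unweighted mean: {rt.mean_auc:.3f}\n")

    manifest = {
        **stamp,
        "artifacts": {
            "cohort_development": dev_csv.name,
            "cohort_validation": val_csv.name,
            "development": "development.json",
            "validation": "validation.json",
            "validation_text": "validation.txt",
        },
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest
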