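import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neorisk.cohort import CohortConfig, generate_cohort
from neorisk.development import (DEFAULT_EXPANSION_RULE, ExpansionRule,
                                 apply_time_windows, derive_fnr_thresholds,
                                 expand_pseudo_days, expected_expansion_rows,
                                 fit_dynamic_model3, fit_logistic, fnr_at,
                                 preselect_variables, refit_model,
                                 select_cutoff_max_kappa)
from neorisk.exceptions import ConfigError, SchemaError, StratumError
from neorisk.models import published_model

from .conftest import minimal_patient


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_kappa_cutoff(scores, y):
    """Exhaustive search over all unique score values with a from-scratch
    kappa; independent of the production implementation."""
    def kappa(pred, obs):
        n = len(obs)
        po = np.mean(pred == obs)
        p1, o1 = np.mean(pred), np.mean(obs)
        pe = p1 * o1 + (1 - p1) * (1 - o1)
        return 1.0 if pe == 1.0 else (po - pe) / (1 - pe)

    best_cut, best_k = None, -np.inf
    for t in np.unique(scores):
        k = kappa((scores >= t).astype(int), y)
        if k > best_k + 1e-12:
            best_k, best_cut = k, t
    return best_cut, best_k


# ---------------------------------------------------------------------------

class TestExpansionRule:
    def test_defaults(self):
        rule = DEFAULT_EXPANSION_RULE
        assert rule.standardized_days == (1, 3, 8, 15, 22, 31, 46, 61)
        assert rule.windows["rds"] == (0, 7)
        assert rule.windows["nec"] == (14, 45)
        assert rule.windows["ivh"] == (0, 10)
        assert rule.windows["pvl"] == (21, None)
        assert rule.windows["bpd"] == (28, None)

    def test_days_must_increase(self):
        with pytest.raises(ConfigError):
            ExpansionRule(standardized_days=(1, 3, 3))


def _one_patient_cohort(los, outcome="survived", day_of_death=None, **flags):
    pat = minimal_patient(**flags)
    pat.update(length_of_stay=los, outcome=outcome)
    df = pd.DataFrame([pat])
    df["day_of_death"] = pd.array([day_of_death], dtype="Int64")
    return df


class TestExpandPseudoDays:
    @pytest.mark.parametrize("los,days", [
        (1, [1]),
        (20, [1, 3, 8, 15]),
        (70, [1, 3, 8, 15, 22, 31, 46, 61]),
    ])
    def test_day_subsets(self, los, days):
        expanded = expand_pseudo_days(_one_patient_cohort(los))
        assert expanded["pseudo_day"].tolist() == days

    def test_death_truncates_expansion(self):
        cohort = _one_patient_cohort(10, outcome="died", day_of_death=10)
        assert expand_pseudo_days(cohort)["pseudo_day"].tolist() == [1, 3, 8]

    def test_outcome_label_repeated(self):
        cohort = _one_patient_cohort(40, outcome="died", day_of_death=40)
        expanded = expand_pseudo_days(cohort)
        assert (expanded["outcome"] == "died").all()

    def test_row_count_closed_form(self):
        cohort = generate_cohort(CohortConfig(n=500, seed=13))
        expanded = expand_pseudo_days(cohort)
        assert len(expanded) == expected_expansion_rows(
            cohort["length_of_stay"], day_of_death=cohort["day_of_death"].tolist()
        )

    @given(los=st.lists(st.integers(1, 100), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_row_count_property(self, los):
        cohort = pd.concat([_one_patient_cohort(l) for l in los], ignore_index=True)
        cohort["id"] = [f"P{i}" for i in range(len(los))]
        expanded = expand_pseudo_days(cohort)
        days = np.array(DEFAULT_EXPANSION_RULE.standardized_days)
        assert len(expanded) == sum(int((days <= l).sum()) for l in los)


class TestTimeWindows:
    def test_rds_window(self):
        df = pd.DataFrame([minimal_patient(rds=1, severe_rds=1)])
        assert apply_time_windows(df, 1)["rds"].iloc[0] == 1
        assert apply_time_windows(df, 7)["rds"].iloc[0] == 1
        gated = apply_time_windows(df, 8)
        assert gated["rds"].iloc[0] == 0
        assert gated["severe_rds"].iloc[0] == 0  # severe gated with its family

    def test_bpd_open_window(self):
        df = pd.DataFrame([minimal_patient(bpd=1)])
        assert apply_time_windows(df, 22)["bpd"].iloc[0] == 0
        assert apply_time_windows(df, 28)["bpd"].iloc[0] == 0
        assert apply_time_windows(df, 31)["bpd"].iloc[0] == 1

    def test_nec_window(self):
        df = pd.DataFrame([minimal_patient(nec=1)])
        assert apply_time_windows(df, 13)["nec"].iloc[0] == 0
        assert apply_time_windows(df, 14)["nec"].iloc[0] == 1
        assert apply_time_windows(df, 45)["nec"].iloc[0] == 1
        assert apply_time_windows(df, 46)["nec"].iloc[0] == 0

    def test_pvl_open_window(self):
        df = pd.DataFrame([minimal_patient(pvl=1)])
        assert apply_time_windows(df, 21)["pvl"].iloc[0] == 0
        assert apply_time_windows(df, 22)["pvl"].iloc[0] == 1

    def test_non_windowed_pass_through(self):
        df = pd.DataFrame([minimal_patient(severe_anemia=1, severe_infection=1)])
        gated = apply_time_windows(df, 1)
        assert gated["severe_anemia"].iloc[0] == 1
        assert gated["severe_infection"].iloc[0] == 1

    def test_gated_never_exceeds_original(self, cohort_small):
        for day in (1, 8, 22, 61):
            gated = apply_time_windows(cohort_small, day)
            for cols in DEFAULT_EXPANSION_RULE.family_columns.values():
                for col in cols:
                    assert (gated[col] <= cohort_small[col]).all()


class TestPreselection:
    def test_perfect_association_selected(self, cohort_small):
        cohort = cohort_small.copy()
        cohort["mirror"] = (cohort["outcome"] == "died").astype(int)
        report = preselect_variables(cohort, {"mirror": "categorical"})
        row = report.iloc[0]
        assert row["selected"] and row["p_value"] < 1e-10

    def test_constant_excluded_as_degenerate(self, cohort_small):
        cohort = cohort_small.copy()
        cohort["flat"] = 1
        report = preselect_variables(cohort, {"flat": "categorical"})
        assert not report.iloc[0]["selected"]
        assert report.iloc[0]["reason"] == "degenerate"

    def test_true_ga_effect_detected(self, cohort_10k):
        report = preselect_variables(cohort_10k, {"gestational_age": "continuous"})
        assert report.iloc[0]["selected"]
        assert report.iloc[0]["test"] == "mann-whitney"

    def test_type_one_error_rate_near_alpha(self):
        # independent continuous variable: selection rate ~ alpha = 0.15
        rng = np.random.default_rng(55)
        n, reps = 400, 200
        y = pd.Series(np.where(rng.random(n) < 0.3, "died", "survived"))
        hits = 0
        for _ in range(reps):
            df = pd.DataFrame({"outcome": y, "x": rng.normal(size=n)})
            hits += int(preselect_variables(df, {"x": "continuous"}).iloc[0]["selected"])
        assert hits / reps == pytest.approx(0.15, abs=0.08)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        df = pd.DataFrame({"outcome": ["died"] * 50 + ["survived"] * 50})
        df["noise"] = np.concatenate([np.zeros(50), np.zeros(50)])
        # constant column is dropped as collinear; intercept ~ log-odds(0.5) = 0
        fit = fit_logistic(df, "outcome", ["noise"])
        assert fit.model.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.dropped and fit.dropped[0][0] == "noise"

    def test_duplicated_predictor_dropped(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        df = pd.DataFrame({
            "x": x,
            "x_copy": x,
            "outcome": np.where(rng.random(500) < 1 / (1 + np.exp(-x)), "died", "survived"),
        })
        fit = fit_logistic(df, "outcome", ["x", "x_copy"])
        assert fit.dropped == [("x_copy", "collinear")]
        assert fit.converged

    def test_loglik_dominates_null(self, cohort_small):
        fit = refit_model(published_model("M1"), cohort_small)
        assert fit.loglik >= fit.loglik_null

    def test_separation_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        df = pd.DataFrame({"x": x, "outcome": np.where(x > 0, "died", "survived")})
        fit = fit_logistic(df, "outcome", ["x"])
        assert not fit.converged

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "outcome": ["survived"] * 3})
        with pytest.raises(ConfigError):
            fit_logistic(df, "outcome", ["x"])

    def test_parameter_recovery_smoke(self):
        # one replicate; each estimate within 5 fitted SEs of truth
        cfg = CohortConfig(n=20000, seed=31, true_model="M1", target_mortality=None)
        cohort = generate_cohort(cfg)
        fit = refit_model(published_model("M1"), cohort)
        truth = {t.name: t.beta for t in published_model("M1").terms}
        for t in fit.model.terms:
            assert abs(t.beta - truth[t.name]) < 5 * t.se, t.name


class TestDynamicModel3:
    def test_empty_late_stratum_raises(self):
        cohort = pd.concat([_one_patient_cohort(5) for _ in range(60)], ignore_index=True)
        cohort["id"] = [f"P{i}" for i in range(60)]
        cohort.loc[:20, "outcome"] = "died"
        cohort.loc[:20, "day_of_death"] = 3
        with pytest.raises(StratumError, match="late"):
            fit_dynamic_model3(cohort)

    def test_day_routing(self):
        cohort = generate_cohort(CohortConfig(n=800, seed=17))
        expanded = expand_pseudo_days(cohort)
        late_days = set(expanded.loc[expanded["pseudo_day"] > 30, "pseudo_day"])
        assert late_days <= {31, 46, 61}
        early_days = set(expanded.loc[expanded["pseudo_day"] <= 30, "pseudo_day"])
        assert early_days <= {1, 3, 8, 15, 22}

    def test_days_of_life_sign_recovered(self):
        cfg = CohortConfig(n=6000, seed=19, true_model="M3_early", sim_day_of_life=1)
        cohort = generate_cohort(cfg)
        fit_early, fit_late = fit_dynamic_model3(cohort)
        beta_days = {t.name: t.beta for t in fit_early.model.terms}["days_of_life"]
        assert beta_days < 0
        assert fit_early.converged


class TestCutoffSelection:
    def test_perfect_separation_kappa_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        res = select_cutoff_max_kappa(scores, y)
        assert res.kappa == pytest.approx(1.0)
        assert 0.2 < res.cutoff <= 0.8

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = rng.integers(10, 500)
            scores = rng.random(n).round(3)  # induce ties
            y = (rng.random(n) < rng.uniform(0.1, 0.5)).astype(int)
            if y.sum() in (0, n):
                continue
            res = select_cutoff_max_kappa(scores, y)
            cut_bf, k_bf = brute_force_kappa_cutoff(scores, y)
            assert res.kappa == pytest.approx(k_bf, abs=1e-12)
            assert res.cutoff == pytest.approx(cut_bf)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            select_cutoff_max_kappa([0.1, 0.2], [1, 1])

    def test_null_kappa_small(self):
        rng = np.random.default_rng(29)
        small = 0
        reps = 40
        for _ in range(reps):
            s = rng.random(1000)
            y = (rng.random(1000) < 0.3).astype(int)
            small += int(select_cutoff_max_kappa(s, y).kappa < 0.1)
        assert small >= int(0.9 * reps)


class TestFnrThresholds:
    def test_printed_definition_fixture(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.ones(5, dtype=int)
        bands = derive_fnr_thresholds(scores, y)
        # one of five deaths below 0.2 -> FNR(0.2) = 0.20
        assert bands.thresholds[0] == pytest.approx(0.2)
        assert bands.thresholds[1] == pytest.approx(0.4)  # FNR: 0.3->0.4, 0.4->0.6
        assert bands.thresholds[2] == pytest.approx(0.5)  # FNR(0.5) = 0.8
        assert fnr_at(scores, y, bands.thresholds[0]) >= 0.20

    def test_levels_match_direct_evaluation(self):
        rng = np.random.default_rng(3)
        scores = rng.random(300)
        y = (rng.random(300) < 0.25).astype(int)
        bands = derive_fnr_thresholds(scores, y)
        uniq = np.sort(np.unique(scores))
        for t, q in zip(bands.thresholds, (0.20, 0.50, 0.80)):
            assert fnr_at(scores, y, t) >= q
            below = uniq[uniq < t]
            if len(below):
                assert fnr_at(scores, y, below[-1]) < q

    def test_zero_level_threshold_below_min_dead(self):
        scores = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([0, 1, 1, 1, 1, 1])
        bands = derive_fnr_thresholds(scores, y, fnr_levels=(0.0, 0.5, 0.8))
        assert bands.thresholds[0] <= 0.1
        assert fnr_at(scores, y, bands.thresholds[0]) == 0.0

    def test_fnr_monotone(self):
        rng = np.random.default_rng(8)
        scores = rng.random(100)
        y = (rng.random(100) < 0.4).astype(int)
        grid = np.sort(np.unique(scores))
        vals = [fnr_at(scores, y, t) for t in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_no_deaths_rejected(self):
        with pytest.raises(ConfigError):
            derive_fnr_thresholds([0.1, 0.2], [0, 0])

    def test_duplicate_thresholds_bumped(self):
        # all deaths share one score: naive thresholds would coincide
        scores = np.array([0.1, 0.5, 0.5, 0.5, 0.9, 0.95])
        y = np.array([0, 1, 1, 1, 0, 0])
        bands = derive_fnr_thresholds(scores, y)
        assert bands.thresholds[0] < bands.thresholds[1] < bands.thresholds[2]
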