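import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import gnet
from gnet.analysis import (
    CATEGORY_ORDER,
    ExclusionCriteria,
    apply_exclusions,
    binomial_ci_lower,
    category_tests,
    compare_models,
    corrected_recognition,
    fit_recognition_model,
    fit_study_model,
)
from gnet.glmm import fit_logistic_glmm
from gnet.schedule import Phase, Role


# --------------------------------------------------------------------------
# helpers


def _manual_log(pid, p2_response, p3_response):
    """75 phase-2 rows (25 familiar + 50 novel) and 100 phase-3 rows
    (50 old + 50 distractor) with constant responses."""
    rows = []
    for i in range(75):
        role = Role.FAMILIAR.value if i < 25 else Role.NOVEL.value
        rows.append((pid, Phase.INCIDENTAL.value, i, f"s{i}", role, p2_response))
    for i in range(100):
        role = Role.OLD.value if i < 50 else Role.DISTRACTOR.value
        rows.append((pid, Phase.RECOGNITION.value, i, f"t{i}", role, p3_response))
    return pd.DataFrame(
        rows, columns=["participant_id", "phase", "trial_index", "stimulus_id", "role", "response"]
    )


# --------------------------------------------------------------------------
# exclusions


@pytest.mark.parametrize("method", ["exact", "wilson", "normal"])
def test_all_old_responder_excluded_under_every_ci_method(method):
    """Pressing "old" on every phase-2 trial gives 25/75 correct; the CI
    lower bound falls below 0.33 whichever interval is used."""
    log = _manual_log("P1", "OLD", "NOT_SEEN")
    report = apply_exclusions(log, ExclusionCriteria(ci_method=method))
    row = report.iloc[0]
    assert row["study_p_hat"] == pytest.approx(25 / 75)
    assert row["study_ci_low"] < 0.33
    assert "STUDY_CHANCE" in row["reasons"]
    assert row["excluded"]


def test_clean_participant_not_excluded():
    log = pd.concat(
        [
            _manual_log("P1", "OLD", "NOT_SEEN").query("role == 'FAMILIAR' or phase == 'RECOGNITION'"),
            _manual_log("P1", "NEW", "NOT_SEEN").query("role == 'NOVEL'"),
        ]
    )
    report = apply_exclusions(log)
    row = report.iloc[0]
    assert row["study_p_hat"] == 1.0
    assert not row["excluded"]
    assert row["reasons"] == ""


def test_missed_rule_counts_phases_two_and_three():
    log = _manual_log("P1", "NONE", "SEEN")  # 75 of 175 required trials missed
    row = apply_exclusions(log).iloc[0]
    assert row["miss_fraction"] == pytest.approx(75 / 175)
    assert "MISSED" in row["reasons"]


def test_maybe_overuse_strict_vs_lax():
    log = _manual_log("P1", "NEW", "NOT_SEEN")
    log.loc[(log["phase"] == Phase.RECOGNITION.value) & (log["trial_index"] < 30), "response"] = "MAYBE"
    # fix phase 2 correctness so only the maybe rule can fire
    log.loc[log["role"] == Role.FAMILIAR.value, "response"] = "OLD"
    strict = apply_exclusions(log, ExclusionCriteria(maybe_criterion="strict")).iloc[0]
    lax = apply_exclusions(log, ExclusionCriteria(maybe_criterion="lax")).iloc[0]
    assert strict["maybe_count"] == 30
    assert "MAYBE_OVERUSE" in strict["reasons"]   # 30 > 25% of 100
    assert "MAYBE_OVERUSE" not in lax["reasons"]  # 30 < 50


def test_missing_phase_rejected():
    log = _manual_log("P1", "NEW", "NOT_SEEN")
    with pytest.raises(ValueError):
        apply_exclusions(log[log["phase"] == Phase.INCIDENTAL.value])


def test_exact_ci_matches_tail_probability_search():
    """Clopper-Pearson lower bound for 45/75 equals the p solving
    P(X >= 45 | p) = alpha/2 found by direct root search."""
    k, n = 45, 75
    lower = binomial_ci_lower(k, n, 0.95, "exact")
    oracle = optimize.brentq(lambda p: stats.binom.sf(k - 1, n, p) - 0.025, 1e-9, 1 - 1e-9)
    assert lower == pytest.approx(oracle, abs=1e-9)
    assert binomial_ci_lower(0, 0) == 0.0
    with pytest.raises(ValueError):
        binomial_ci_lower(1, 2, method="bogus")


# --------------------------------------------------------------------------
# corrected recognition


def _one_category_log(pid="P1", hits=7, fas=2, cat="FULLY_NOVEL"):
    rows = []
    for i in range(10):
        resp = "SEEN" if i < hits else "NOT_SEEN"
        rows.append((pid, Phase.RECOGNITION.value, i, f"o{i}", Role.OLD.value, resp))
    for i in range(10):
        resp = "SEEN" if i < fas else "NOT_SEEN"
        rows.append((pid, Phase.RECOGNITION.value, 10 + i, f"d{i}", Role.DISTRACTOR.value, resp))
    log = pd.DataFrame(
        rows, columns=["participant_id", "phase", "trial_index", "stimulus_id", "role", "response"]
    )
    cats = {f"o{i}": cat for i in range(10)} | {f"d{i}": cat for i in range(10)}
    return log, cats


def test_corrected_recognition_formula():
    log, cats = _one_category_log(hits=7, fas=2)
    out = corrected_recognition(log, cats)
    row = out.iloc[0]
    assert (row["hits"], row["false_alarms"], row["corrected_recognition"]) == (7, 2, 5)
    assert row["n_old_responded"] == 10 and row["n_distractor_responded"] == 10


def test_all_maybe_yields_empty_counts():
    log, cats = _one_category_log()
    log["response"] = "MAYBE"
    row = corrected_recognition(log, cats).iloc[0]
    assert row["corrected_recognition"] == 0
    assert row["n_old_responded"] == 0 and row["n_distractor_responded"] == 0


def test_corrected_recognition_invariances():
    log, cats = _one_category_log(hits=6, fas=3)
    base = corrected_recognition(log, cats)
    shuffled = corrected_recognition(log.sample(frac=1, random_state=0), cats)
    assert shuffled.equals(base)
    relabel = {sid: f"X_{sid}" for sid in cats}
    log2 = log.assign(stimulus_id=log["stimulus_id"].map(relabel))
    cats2 = {relabel[k]: v for k, v in cats.items()}
    again = corrected_recognition(log2, cats2)
    assert again["corrected_recognition"].equals(base["corrected_recognition"])


def test_missing_category_rejected():
    log, cats = _one_category_log()
    del cats["o0"]
    with pytest.raises(ValueError):
        corrected_recognition(log, cats)


def test_simulated_cohort_scores_positive_for_fully_novel(pool, scores):
    cohort = gnet.CohortParams(
        mean=dataclasses.replace(gnet.ParticipantParams(), recog_oldtype_effect=2.5),
        n_participants=12, seed=8,
    )
    log, _ = gnet.simulate_cohort(pool, cohort, scores)
    out = corrected_recognition(log, scores)
    fn = out[out["category"] == "FULLY_NOVEL"]
    assert fn["corrected_recognition"].mean() > 0
    assert out["corrected_recognition"].abs().le(10).all()


# --------------------------------------------------------------------------
# category tests


def _scores_frame(matrix):
    rows = []
    for p, vals in enumerate(matrix):
        for cat, v in zip(CATEGORY_ORDER, vals):
            rows.append({"participant_id": f"P{p}", "category": cat, "corrected_recognition": v})
    return pd.DataFrame(rows)


def test_flat_profiles_give_zero_contrast():
    rng = np.random.default_rng(0)
    per_participant = rng.integers(-2, 5, size=12)
    mat = np.repeat(per_participant[:, None], 5, axis=1)
    out = category_tests(_scores_frame(mat))
    assert out["linear_contrast"]["estimate"] == 0.0


def test_monotone_scores_give_positive_contrast():
    rng = np.random.default_rng(1)
    base = np.arange(5, dtype=float)  # increases with novelty order
    mat = base[None, :] + rng.normal(0, 0.5, size=(20, 5))
    out = category_tests(_scores_frame(mat))
    c = out["linear_contrast"]
    assert c["estimate"] > 0
    assert c["p"] < 0.001
    assert c["F"] == pytest.approx(c["t"] ** 2)
    a = out["anova"]
    assert a["p_gg"] < 0.01
    assert 0 <= a["ng2"] <= 1


def test_category_tests_require_variance():
    mat = np.ones((10, 5))
    with pytest.raises(ValueError):
        category_tests(_scores_frame(mat))
    with pytest.raises(ValueError):
        category_tests(_scores_frame(np.random.default_rng(0).normal(size=(1, 5))))


def test_old_vs_distractor_wilcoxon_on_log(cohort_log, scores):
    log, _, _ = cohort_log
    summaries = corrected_recognition(log, scores)
    out = category_tests(summaries, log)
    assert 0 <= out["shapiro"]["p"] <= 1
    # generator has a positive old-type effect: old items attract more SEEN
    assert out["old_vs_distractor"]["p"] < 0.05


# --------------------------------------------------------------------------
# mixed models


def test_study_model_recovery(cohort_log, zscores):
    log, _, cohort = cohort_log
    fit = fit_study_model(log, zscores, "dtf")
    truth = {"intercept": cohort.mean.study_intercept, "dtf": cohort.mean.study_dtf_slope}
    for name, t in truth.items():
        est, se = fit.coef[name], fit.fixed_effects.loc[name, "se"]
        assert abs(est - t) < 3 * se
    assert fit.coef["dtf"] > 0
    assert fit.fixed_effects.loc["dtf", "p"] < 0.001
    with pytest.raises(ValueError):
        fit_study_model(log, zscores, "dtan")


def test_recognition_model_recovery(cohort_log, zscores):
    log, _, cohort = cohort_log
    fit = fit_recognition_model(log, zscores, "dtf")
    truth = {
        "intercept": cohort.mean.recog_intercept,
        "trial_type_old": cohort.mean.recog_oldtype_effect,
        "dtf": cohort.mean.recog_diff_slope,
        "trial_type_old:dtf": cohort.mean.recog_interaction,
    }
    for name, t in truth.items():
        est, se = fit.coef[name], fit.fixed_effects.loc[name, "se"]
        assert abs(est - t) < 3 * se, name
    assert fit.conditional_r2 >= fit.marginal_r2


def test_permuted_index_effect_vanishes(cohort_log, zscores):
    log, _, _ = cohort_log
    rng = np.random.default_rng(0)
    permuted = zscores.copy()
    permuted["dtf"] = rng.permutation(permuted["dtf"].to_numpy())
    fit = fit_study_model(log, permuted, "dtf")
    assert abs(fit.fixed_effects.loc["dtf", "z"]) < 3


def test_shuffled_trial_type_effect_vanishes(cohort_log, zscores):
    log, _, _ = cohort_log
    rng = np.random.default_rng(1)
    p3 = log["phase"] == Phase.RECOGNITION.value
    shuffled = log.copy()
    shuffled.loc[p3, "role"] = rng.permutation(shuffled.loc[p3, "role"].to_numpy())
    fit = fit_recognition_model(shuffled, zscores, "dtf")
    est, se = fit.coef["trial_type_old"], fit.fixed_effects.loc["trial_type_old", "se"]
    assert abs(est) < 3 * se


def test_compare_models_bookkeeping(cohort_log, zscores):
    log, _, _ = cohort_log
    fits = [fit_recognition_model(log, zscores, ix) for ix in ("dtf", "dtaf", "dtan")]
    table = compare_models(fits)
    assert len(table) == 3
    assert table["dAIC"].iloc[0] == 0.0
    assert (table["dAIC"] >= 0).all()
    assert set(table["support"]) <= {"supported", "no support"}
    dup = compare_models([fits[0], fits[0]])
    assert (dup["dAIC"] == 0).all()
    small = fit_recognition_model(log[log["participant_id"] != "P001"], zscores, "dtf")
    with pytest.raises(ValueError):
        compare_models([fits[0], small])
    with pytest.raises(ValueError):
        compare_models([fits[0]])


def test_useless_predictor_costs_about_two_aic():
    """Adding an unrelated covariate raises AIC by ~2 (the parameter
    penalty) minus a chi-square(1)/1 improvement: small and positive-ish."""
    rng = np.random.default_rng(3)
    deltas = []
    for _ in range(15):
        n = 600
        x = rng.normal(size=n)
        junk = rng.normal(size=n)
        groups = rng.integers(0, 20, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.6 * x)))).astype(float)
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([X1, junk])
        Z = np.ones((n, 1))
        f1 = fit_logistic_glmm(y, X1, Z, groups)
        f2 = fit_logistic_glmm(y, X2, Z, groups)
        deltas.append(f2.aic - f1.aic)
    assert -0.5 < np.mean(deltas) < 3.0
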