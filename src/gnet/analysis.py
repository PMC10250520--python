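"""Trial-level analysis pipeline: exclusions, recognition scoring,
category-level tests, and mixed logistic models.

The pipeline mirrors how GNET response logs are analyzed:

1. **Exclusions.** Participants are dropped if (a) they missed more than a
   third of the response-required trials (phases 2-3 combined); (b) the lower
   bound of the two-sided 95% binomial confidence interval for their phase-2
   correctness is below 0.33 — the success probability a responder pressing
   "old" on every trial would attain (25 familiars correct, 50 novels wrong
   out of 75), so survivors distinguish familiars from novels above that
   baseline; or (c) they overused "maybe seen" in the recognition test
   (strict: more than 25% of phase-3 trials; lax: 50 or more).
2. **Corrected recognition.** "Maybe seen" and missing responses are treated
   as missed. Per participant and novel category (10 old + 10 distractor
   items), the corrected recognition score is hits ("seen" to old) minus
   false alarms ("seen" to distractors).
3. **Category tests.** One-way repeated-measures ANOVA over the five ordered
   categories (Greenhouse-Geisser corrected, generalized eta-squared), a
   linear polynomial contrast over the category order, per-category one-sample
   Wilcoxon tests of above-chance performance, and a Shapiro-Wilk screen plus
   paired Wilcoxon comparing "seen" counts to old vs distractor items.
4. **Mixed logistic models.** Study phase: P("new" | novel trial) as a
   function of a difference index with a random intercept and random index
   slope per participant. Recognition phase: P("already seen") as a function
   of trial type (old = 1, distractor = 0), a difference index, and their
   interaction, with a random intercept and random trial-type slope per
   participant. Models fitted with DTF, DTAF or DTAN are compared by AIC
   (models >= 10 AIC units above the best have no support) and by marginal /
   conditional pseudo-R2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMResult, fit_logistic_glmm
from .schedule import Phase, Role, TrialSchedule
from .simulate import Response
from .stimgen import NOVEL_CATEGORIES

__all__ = [
    "ExclusionCriteria",
    "apply_exclusions",
    "binomial_ci_lower",
    "corrected_recognition",
    "category_tests",
    "fit_study_model",
    "fit_recognition_model",
    "compare_models",
]

CATEGORY_ORDER = [c.value for c in NOVEL_CATEGORIES]

#: Linear polynomial contrast over the five ordered novel categories
#: (novel color combinations ... fully novel). With these signs, performance
#: increasing with novelty yields a POSITIVE contrast estimate.
LINEAR_CONTRAST = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])


# --------------------------------------------------------------------------
# Exclusions


@dataclass(frozen=True)
class ExclusionCriteria:
    """Configuration of the participant-exclusion rules."""

    miss_threshold: float = 1.0 / 3.0
    chance_p: float = 0.33
    ci_level: float = 0.95
    ci_method: str = "exact"          # exact | wilson | normal
    maybe_criterion: str = "strict"   # strict: > 25% of phase-3 trials; lax: >= 50
    maybe_fraction: float = 0.25
    maybe_lax_count: int = 50


def binomial_ci_lower(k: int, n: int, level: float = 0.95, method: str = "exact") -> float:
    """Lower bound of a two-sided binomial CI for a success probability.

    ``exact`` is Clopper-Pearson; ``wilson`` the score interval; ``normal``
    the Wald interval (clipped to 0).
    """
    if n == 0:
        return 0.0
    if method == "exact":
        return float(stats.binomtest(k, n).proportion_ci(level, method="exact").low)
    if method == "wilson":
        return float(stats.binomtest(k, n).proportion_ci(level, method="wilson").low)
    if method == "normal":
        p = k / n
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        return max(0.0, p - zcrit * np.sqrt(p * (1.0 - p) / n))
    raise ValueError(f"unknown CI method {method!r}")


def apply_exclusions(log: pd.DataFrame, criteria: ExclusionCriteria | None = None) -> pd.DataFrame:
    """Evaluate all exclusion rules per participant.

    Returns one row per participant: ``miss_fraction``, ``study_p_hat``,
    ``study_ci_low``, ``maybe_count``, ``excluded`` and ``reasons`` (a
    comma-joined subset of MISSED, STUDY_CHANCE, MAYBE_OVERUSE).
    """
    crit = criteria or ExclusionCriteria()
    rows = []
    for pid, d in log.groupby("participant_id", sort=True):
        p2 = d[d["phase"] == Phase.INCIDENTAL.value]
        p3 = d[d["phase"] == Phase.RECOGNITION.value]
        if len(p2) == 0 or len(p3) == 0:
            raise ValueError(f"participant {pid} is missing a response phase")
        reasons = []

        required = pd.concat([p2, p3])
        miss_fraction = float((required["response"] == Response.NONE.value).mean())
        if miss_fraction > crit.miss_threshold:
            reasons.append("MISSED")

        answered = p2[p2["response"] != Response.NONE.value]
        correct = (
            ((answered["role"] == Role.FAMILIAR.value) & (answered["response"] == Response.OLD.value))
            | ((answered["role"] == Role.NOVEL.value) & (answered["response"] == Response.NEW.value))
        )
        k, n = int(correct.sum()), len(answered)
        p_hat = k / n if n else np.nan
        ci_low = binomial_ci_lower(k, n, crit.ci_level, crit.ci_method)
        if ci_low < crit.chance_p:
            reasons.append("STUDY_CHANCE")

        maybe_count = int((p3["response"] == Response.MAYBE.value).sum())
        if crit.maybe_criterion == "strict":
            overuse = maybe_count > crit.maybe_fraction * len(p3)
        elif crit.maybe_criterion == "lax":
            overuse = maybe_count >= crit.maybe_lax_count
        else:
            raise ValueError(f"unknown maybe criterion {crit.maybe_criterion!r}")
        if overuse:
            reasons.append("MAYBE_OVERUSE")

        rows.append(
            {
                "participant_id": pid,
                "miss_fraction": miss_fraction,
                "study_p_hat": p_hat,
                "study_ci_low": ci_low,
                "maybe_count": maybe_count,
                "excluded": bool(reasons),
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Corrected recognition


def corrected_recognition(
    log: pd.DataFrame,
    categories: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Per participant x category hit/false-alarm counts and corrected scores.

    ``categories`` maps stimulus_id -> novel category (a dict, or a scores
    DataFrame with ``stimulus_id``/``category`` columns). Phase-3 roles come
    from the log itself. MAYBE and NONE responses are treated as missed and
    enter neither hits nor false alarms.
    """
    if isinstance(categories, pd.DataFrame):
        cat_by_id = dict(zip(categories["stimulus_id"], categories["category"].astype(str)))
    else:
        cat_by_id = {k: str(v) for k, v in categories.items()}

    p3 = log[log["phase"] == Phase.RECOGNITION.value].copy()
    missing = set(p3["stimulus_id"]) - set(cat_by_id)
    if missing:
        raise ValueError(f"no category for phase-3 stimuli: {sorted(missing)[:5]}")
    if not p3["role"].isin([Role.OLD.value, Role.DISTRACTOR.value]).all():
        raise ValueError("phase-3 rows must carry OLD/DISTRACTOR roles")
    p3["category"] = p3["stimulus_id"].map(cat_by_id)
    p3["answered"] = ~p3["response"].isin([Response.MAYBE.value, Response.NONE.value])
    p3["seen"] = p3["response"] == Response.SEEN.value

    rows = []
    for (pid, cat), d in p3.groupby(["participant_id", "category"], sort=True):
        old = d[d["role"] == Role.OLD.value]
        dis = d[d["role"] == Role.DISTRACTOR.value]
        hits = int((old["seen"] & old["answered"]).sum())
        fas = int((dis["seen"] & dis["answered"]).sum())
        rows.append(
            {
                "participant_id": pid,
                "category": cat,
                "hits": hits,
                "false_alarms": fas,
                "n_old_responded": int(old["answered"].sum()),
                "n_distractor_responded": int(dis["answered"].sum()),
                "corrected_recognition": hits - fas,
            }
        )
    out = pd.DataFrame(rows)
    out["category"] = pd.Categorical(out["category"], categories=CATEGORY_ORDER, ordered=True)
    return out.sort_values(["participant_id", "category"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Category-level tests


def category_tests(summaries: pd.DataFrame, log: pd.DataFrame | None = None) -> dict:
    """Category-level statistics on corrected recognition scores.

    ``summaries`` is the output of :func:`corrected_recognition`. Returns a
    dict with keys ``anova`` (repeated-measures, Greenhouse-Geisser),
    ``linear_contrast``, ``wilcoxon_by_category`` and, when the raw ``log``
    is supplied, ``shapiro`` and ``old_vs_distractor`` (paired Wilcoxon on
    per-participant "seen" counts).
    """
    wide = summaries.pivot(index="participant_id", columns="category", values="corrected_recognition")
    wide = wide.reindex(columns=CATEGORY_ORDER).dropna()
    if len(wide) < 2:
        raise ValueError("need at least 2 participants with complete category scores")
    varying = (wide.to_numpy().std(axis=0) > 0).sum()
    if varying < 2:
        raise ValueError("fewer than 2 categories with variance; tests undefined")

    import pingouin as pg

    long = wide.reset_index().melt(
        id_vars="participant_id", var_name="category", value_name="score"
    )
    aov = pg.rm_anova(
        data=long, dv="score", within="category", subject="participant_id",
        correction=True, effsize="ng2", detailed=True,
    )
    effect, error = aov.iloc[0], aov.iloc[1]
    df1, df2 = float(effect["DF"]), float(error["DF"])
    eps_raw = float(effect.get("eps", np.nan))
    eps = eps_raw if np.isfinite(eps_raw) and eps_raw > 0 else 1.0
    p_gg = float(effect.get("p_GG_corr", np.nan))
    p_unc = float(effect.get("p_unc", np.nan))
    anova = {
        "F": float(effect.get("F", np.nan)),  # NaN when within-variance is 0
        "df1": df1,
        "df2": df2,
        "p_uncorrected": p_unc,
        "gg_epsilon": eps,
        "df1_gg": df1 * eps,
        "df2_gg": df2 * eps,
        "p_gg": p_gg if np.isfinite(p_gg) else p_unc,
        "ng2": float(effect.get("ng2", np.nan)),
    }

    # Linear polynomial contrast over the ordered categories: per-participant
    # contrast scores tested against zero (F = t^2 on 1, N-1 df).
    L = wide.to_numpy() @ LINEAR_CONTRAST
    tstat, pval = stats.ttest_1samp(L, 0.0)
    contrast = {
        "coefficients": LINEAR_CONTRAST.tolist(),
        "estimate": float(np.mean(L)),
        "t": float(tstat),
        "F": float(tstat**2),
        "df": len(L) - 1,
        "p": float(pval),
        "sign_convention": "positive = performance increases from novel color "
        "combinations to fully novel",
    }

    wilcoxon = {}
    for cat in CATEGORY_ORDER:
        x = wide[cat].to_numpy(dtype=float)
        if np.allclose(x, 0.0):
            wilcoxon[cat] = {"W": np.nan, "p": np.nan, "note": "all scores zero"}
            continue
        W, p = stats.wilcoxon(x, alternative="greater")
        wilcoxon[cat] = {"W": float(W), "p": float(p)}

    out = {"anova": anova, "linear_contrast": contrast, "wilcoxon_by_category": wilcoxon}

    if log is not None:
        p3 = log[log["phase"] == Phase.RECOGNITION.value]
        seen = p3[p3["response"] == Response.SEEN.value]
        counts = (
            seen.groupby(["participant_id", "role"]).size().unstack(fill_value=0)
            .reindex(columns=[Role.OLD.value, Role.DISTRACTOR.value], fill_value=0)
        )
        diff = (counts[Role.OLD.value] - counts[Role.DISTRACTOR.value]).to_numpy(dtype=float)
        sw_stat, sw_p = stats.shapiro(diff)
        if np.allclose(diff, 0.0):
            ovd = {"W": np.nan, "p": np.nan, "note": "no old/distractor difference"}
        else:
            W, p = stats.wilcoxon(diff)
            ovd = {"W": float(W), "p": float(p)}
        out["shapiro"] = {"W": float(sw_stat), "p": float(sw_p)}
        out["old_vs_distractor"] = ovd
    return out


# --------------------------------------------------------------------------
# Mixed logistic models


def _merge_scores(df: pd.DataFrame, scores: pd.DataFrame, index_choice: str) -> pd.DataFrame:
    idx = index_choice.lower()
    if idx not in scores.columns:
        raise ValueError(f"scores table lacks column {idx!r}")
    merged = df.merge(scores[["stimulus_id", idx]], on="stimulus_id", how="left")
    if merged[idx].isna().any():
        missing = merged.loc[merged[idx].isna(), "stimulus_id"].unique()
        raise ValueError(f"missing difference scores for: {missing[:5]}")
    return merged


def fit_study_model(log: pd.DataFrame, scores: pd.DataFrame, index_choice: str = "dtf") -> GLMMResult:
    """Mixed logistic model of phase-2 responses to novels.

    Outcome: "new" = 1, "old" = 0. Fixed effects: intercept + difference
    index. Random intercept and random index slope per participant.
    """
    if index_choice.lower() not in ("dtf", "dtaf"):
        raise ValueError("study-phase index must be DTF or DTAF")
    d = log[
        (log["phase"] == Phase.INCIDENTAL.value)
        & (log["role"] == Role.NOVEL.value)
        & (log["response"].isin([Response.OLD.value, Response.NEW.value]))
    ]
    d = _merge_scores(d, scores, index_choice)
    y = (d["response"] == Response.NEW.value).to_numpy(dtype=float)
    x = d[index_choice.lower()].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    Z = X.copy()
    return fit_logistic_glmm(
        y, X, Z, d["participant_id"].to_numpy(),
        fe_names=["intercept", index_choice.lower()],
        re_names=["intercept", index_choice.lower()],
        label=index_choice.upper(),
    )


def fit_recognition_model(
    log: pd.DataFrame,
    scores: pd.DataFrame,
    index_choice: str = "dtf",
) -> GLMMResult:
    """Mixed logistic model of phase-3 recognition responses.

    Outcome: "already seen" = 1, "not seen" = 0 (maybe/missed rows dropped).
    Fixed effects: intercept, trial type (old = 1, distractor = 0), the
    difference index, and their interaction. Random intercept and random
    trial-type slope per participant.
    """
    if index_choice.lower() not in ("dtf", "dtaf", "dtan"):
        raise ValueError("recognition index must be DTF, DTAF or DTAN")
    d = log[
        (log["phase"] == Phase.RECOGNITION.value)
        & (log["response"].isin([Response.SEEN.value, Response.NOT_SEEN.value]))
    ]
    d = _merge_scores(d, scores, index_choice)
    y = (d["response"] == Response.SEEN.value).to_numpy(dtype=float)
    x = d[index_choice.lower()].to_numpy(dtype=float)
    is_old = (d["role"] == Role.OLD.value).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), is_old, x, is_old * x])
    Z = np.column_stack([np.ones_like(x), is_old])
    return fit_logistic_glmm(
        y, X, Z, d["participant_id"].to_numpy(),
        fe_names=["intercept", "trial_type_old", index_choice.lower(), f"trial_type_old:{index_choice.lower()}"],
        re_names=["intercept", "trial_type_old"],
        label=index_choice.upper(),
    )


def compare_models(fits: list[GLMMResult], *, no_support_delta: float = 10.0) -> pd.DataFrame:
    """AIC comparison table across fits of the same observations.

    Models at least ``no_support_delta`` AIC units above the best-fitting
    model are labelled as having no support.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n_obs = {f.n_observations for f in fits}
    if len(n_obs) != 1 or len({f.observation_hash for f in fits}) != 1:
        raise ValueError("fits were computed on differing observation sets")
    best = min(f.aic for f in fits)
    rows = []
    for f in fits:
        delta = f.aic - best
        rows.append(
            {
                "model": f.label,
                "AIC": f.aic,
                "dAIC": delta,
                "marginal_R2": f.marginal_r2,
                "conditional_R2": f.conditional_r2,
                "converged": f.converged,
                "support": "no support" if delta >= no_support_delta else "supported",
            }
        )
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
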