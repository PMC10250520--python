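"""Serialization and the end-to-end demo pipeline.

Formats:

* **Pool JSON** — ``{"seed", "config", "stimuli": [{"id", "category",
  "base_familiar_id", "layout", "shapes", "colors"}, ...]}``. Pools are
  re-validated against their own embedded configuration on load, so pools
  from non-default grids round-trip too.
* **Scores CSV** — ``stimulus_id, category, base_familiar_id, dtf, dtaf, dtan``.
* **Schedule CSV** — ``phase, index, stimulus_id, role``.
* **Response-log CSV** — ``participant_id, phase, trial_index, stimulus_id,
  role, response``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, metrics, simulate as sim
from .schedule import Phase, Role, Trial, TrialSchedule, build_schedule
from .simulate import CohortParams, ParticipantParams
from .stimgen import Category, GenerationConfig, Stimulus, StimulusPool, generate_pool, render_stimulus

logger = logging.getLogger("gnet")

__all__ = [
    "pool_to_dict",
    "pool_from_dict",
    "save_pool",
    "load_pool",
    "save_schedule",
    "load_schedule",
    "save_responses",
    "load_responses",
    "RunConfig",
    "run_demo",
]


# --------------------------------------------------------------------------
# Pool JSON


def _stim_dict(s: Stimulus) -> dict:
    return {
        "id": s.id,
        "category": s.category.value,
        "base_familiar_id": s.base_familiar_id,
        "layout": s.layout.tolist(),
        "shapes": s.shapes.tolist(),
        "colors": s.colors.tolist(),
    }


def pool_to_dict(pool: StimulusPool) -> dict:
    return {
        "seed": pool.seed,
        "config": dataclasses.asdict(pool.config),
        "stimuli": [_stim_dict(s) for s in pool.all_stimuli()],
    }


def pool_from_dict(data: dict) -> StimulusPool:
    cfg = GenerationConfig(**data["config"])
    familiars, unused, novels = [], [], []
    for d in data["stimuli"]:
        try:
            s = Stimulus(
                layout=d["layout"],
                shapes=d["shapes"],
                colors=d["colors"],
                id=d["id"],
                category=Category(d["category"]),
                base_familiar_id=d.get("base_familiar_id"),
            )
            s.validate(cfg)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid stimulus {d.get('id', '<no id>')!r}: {exc}") from exc
        if s.category is Category.FAMILIAR:
            familiars.append(s)
        elif s.category is Category.UNUSED_ORIGINAL:
            unused.append(s)
        else:
            novels.append(s)
    pool = StimulusPool(familiars, unused, novels, seed=int(data["seed"]), config=cfg)
    pool.validate()
    return pool


def save_pool(pool: StimulusPool, path) -> None:
    Path(path).write_text(json.dumps(pool_to_dict(pool), indent=1))


def load_pool(path) -> StimulusPool:
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed pool JSON at {path}, line {exc.lineno}: {exc.msg}") from exc
    return pool_from_dict(data)


# --------------------------------------------------------------------------
# CSV round trips


def save_schedule(sched: TrialSchedule, path) -> None:
    sched.to_frame().to_csv(path, index=False)


def load_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"phase", "index", "stimulus_id", "role"}
    if not expected.issubset(df.columns):
        raise ValueError(f"schedule CSV must have columns {sorted(expected)}")
    return df


def save_responses(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


def load_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"participant_id", "phase", "trial_index", "stimulus_id", "role", "response"}
    if not expected.issubset(df.columns):
        raise ValueError(f"response CSV must have columns {sorted(expected)}")
    return df


# --------------------------------------------------------------------------
# End-to-end demo


@dataclass
class RunConfig:
    """Configuration of the demo pipeline: one top-level seed derives
    per-stage substreams, so any stage can be rerun in isolation."""

    seed: int = 0
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    n_participants: int = 95
    cohort_mean: ParticipantParams = field(default_factory=ParticipantParams)
    simulation_index: str = "dtf"
    ci_method: str = "exact"
    maybe_criterion: str = "strict"
    render_px: int = 0  # 0 disables PNG rendering
    out_dir: str = "gnet_demo"


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_demo(config: RunConfig | None = None) -> Path:
    """Run generate -> score -> schedule -> simulate -> analyze, writing all
    artifacts into ``config.out_dir``. Deterministic given the seed."""
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, sched_seed, sim_seed, _ = _stage_seeds(cfg.seed)

    try:
        pool = generate_pool(dataclasses.replace(cfg.generation, seed=gen_seed))
        save_pool(pool, out / "pool.json")
        logger.info("generate: %d stimuli", len(pool.all_stimuli()))
        if cfg.render_px:
            img_dir = out / "stimuli"
            img_dir.mkdir(exist_ok=True)
            for s in pool.all_stimuli():
                render_stimulus(s, cfg.render_px, config=pool.config).save(img_dir / f"{s.id}.png")
    except Exception as exc:
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc

    try:
        scores = metrics.compute_indices(pool)
        scores.to_csv(out / "scores.csv", index=False)
        corr = metrics.index_correlations(scores)
        corr.to_csv(out / "index_correlations.csv")
        logger.info("score: %d novels", len(scores))
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc

    try:
        sched = build_schedule(pool, seed=sched_seed)
        save_schedule(sched, out / "schedule.csv")
        logger.info("schedule: %d trials", len(sched.trials))
    except Exception as exc:
        raise RuntimeError(f"stage 'schedule' failed: {exc}") from exc

    try:
        cohort = CohortParams(mean=cfg.cohort_mean, n_participants=cfg.n_participants, seed=sim_seed)
        log, _ = sim.simulate_cohort(
            pool, cohort, scores, index=cfg.simulation_index, shared_schedule=sched
        )
        save_responses(log, out / "responses.csv")
        logger.info("simulate: %d participants, %d rows", cfg.n_participants, len(log))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        report = analyze(
            log, pool, sched, out,
            ci_method=cfg.ci_method, maybe_criterion=cfg.maybe_criterion, scores=scores,
        )
        (out / "report.txt").write_text(report)
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc
    return out


def analyze(
    log: pd.DataFrame,
    pool: StimulusPool,
    sched: TrialSchedule | None,
    out: Path,
    *,
    ci_method: str = "exact",
    maybe_criterion: str = "strict",
    scores: pd.DataFrame | None = None,
    indices: tuple[str, ...] = ("dtf", "dtaf", "dtan"),
) -> str:
    """The analysis stage: exclusions, recognition scores, category tests,
    and the three-index recognition model comparison. Returns a text report
    and writes CSV artifacts into ``out``."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if scores is None:
        scores = metrics.compute_indices(pool)

    crit = analysis.ExclusionCriteria(ci_method=ci_method, maybe_criterion=maybe_criterion)
    excl = analysis.apply_exclusions(log, crit)
    excl.to_csv(out / "exclusions.csv", index=False)
    kept = set(excl.loc[~excl["excluded"], "participant_id"])
    logger.info("exclusions: %d of %d participants excluded", int(excl["excluded"].sum()), len(excl))
    kept_log = log[log["participant_id"].isin(kept)]

    summaries = analysis.corrected_recognition(kept_log, scores)
    summaries.to_csv(out / "recognition_summaries.csv", index=False)
    tests = analysis.category_tests(summaries, kept_log)

    fits = [analysis.fit_recognition_model(kept_log, scores, ix) for ix in indices]
    comparison = analysis.compare_models(fits)
    comparison.to_csv(out / "model_comparison.csv", index=False)

    lines = [
        "GNET analysis report",
        "====================",
        f"participants: {len(excl)} total, {len(kept)} retained "
        f"({int(excl['excluded'].sum())} excluded)",
        "",
        "Corrected recognition (mean per category):",
    ]
    means = summaries.groupby("category", observed=True)["corrected_recognition"].mean()
    for cat, m in means.items():
        lines.append(f"  {cat}: {m:.3f}")
    a = tests["anova"]
    lines += [
        "",
        f"rm-ANOVA (Greenhouse-Geisser): F({a['df1_gg']:.2f},{a['df2_gg']:.2f}) = "
        f"{a['F']:.2f}, p = {a['p_gg']:.4g}, generalized eta^2 = {a['ng2']:.3f}",
        f"linear contrast: estimate = {tests['linear_contrast']['estimate']:.3f}, "
        f"F(1,{tests['linear_contrast']['df']}) = {tests['linear_contrast']['F']:.2f}, "
        f"p = {tests['linear_contrast']['p']:.4g} "
        f"({tests['linear_contrast']['sign_convention']})",
        "",
        "Recognition model comparison (AIC):",
        comparison.to_string(index=False),
        "",
        f"best-supported difference index: {comparison.iloc[0]['model']}",
    ]
    for f in fits:
        lines += ["", f"model {f.label}:", f.fixed_effects.to_string()]
    return "\n".join(lines) + "\n"
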