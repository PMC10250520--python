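"""Synthetic participants for end-to-end testing of the analysis pipeline.

The simulator produces trial-level response logs with exactly the statistical
structure the trial-level models assume:

* phase 2 (incidental learning), novel trials: the probability of a correct
  "new" response follows a logistic function of the trial's difference index;
* phase 2, familiar trials: a fixed per-participant probability of a correct
  "old" response;
* phase 3 (recognition): the probability of an "already seen" response
  follows a logistic function of trial type (old vs distractor), the
  difference index, and their interaction; "maybe seen" responses occur with
  a fixed trial-independent probability;
* any phase-2/3 response is independently replaced by a non-response with a
  fixed miss probability.

Cohorts draw per-participant intercepts and slopes from normal distributions
around population means (independent by default; an optional correlation
couples each intercept with its slope).

The difference index entering the linear predictors is standardized
(z-scored across the 100 novels of the pool), so slopes are in units of
log-odds per SD of the index, independent of which index is chosen. The
analysis module, by contrast, fits whatever index scale it is given.

No claim is made that these parameters describe human behavior; they are
conventions that give the pipeline data with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit

from .schedule import Phase, Role, TrialSchedule, build_schedule
from .stimgen import StimulusPool

__all__ = [
    "Response",
    "ParticipantParams",
    "CohortParams",
    "simulate_participant",
    "simulate_cohort",
]


class Response(str, Enum):
    OLD = "OLD"            # phase 2: "one of the familiars"
    NEW = "NEW"            # phase 2: "a novel picture"
    SEEN = "SEEN"          # phase 3: "already seen"
    NOT_SEEN = "NOT_SEEN"  # phase 3: "not seen"
    MAYBE = "MAYBE"        # phase 3: "maybe seen"
    NONE = "NONE"          # missed (no response)


PHASE2_RESPONSES = {Response.OLD, Response.NEW, Response.NONE}
PHASE3_RESPONSES = {Response.SEEN, Response.NOT_SEEN, Response.MAYBE, Response.NONE}


@dataclass(frozen=True)
class ParticipantParams:
    """One participant's generative parameters (log-odds scale slopes)."""

    study_intercept: float = 1.0
    study_dtf_slope: float = 0.5
    recog_intercept: float = -0.2
    recog_diff_slope: float = -0.8
    recog_oldtype_effect: float = 0.4
    recog_interaction: float = 0.35
    familiar_accuracy: float = 0.9
    maybe_rate: float = 0.1
    miss_rate: float = 0.02

    def validate(self) -> None:
        for name in ("familiar_accuracy", "maybe_rate", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "study_intercept", "study_dtf_slope", "recog_intercept",
            "recog_diff_slope", "recog_oldtype_effect", "recog_interaction",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CohortParams:
    """Population-level parameters: means plus between-participant SDs.

    Random effects are drawn for the study intercept/slope and for the
    recognition intercept/trial-type effect — mirroring the random-intercept
    + random-slope structure the analysis models estimate. ``re_correlation``
    optionally correlates each intercept with its slope (default independent).
    """

    mean: ParticipantParams = field(default_factory=ParticipantParams)
    sd_study_intercept: float = 0.5
    sd_study_slope: float = 0.25
    sd_recog_intercept: float = 0.5
    sd_recog_oldtype: float = 0.25
    re_correlation: float = 0.0
    n_participants: int = 95
    seed: int = 0

    def validate(self) -> None:
        self.mean.validate()
        for name in ("sd_study_intercept", "sd_study_slope", "sd_recog_intercept", "sd_recog_oldtype"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.re_correlation <= 1.0:
            raise ValueError("re_correlation must be in [-1, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")


def standardized_index(scores: pd.DataFrame, index: str = "dtf") -> pd.Series:
    """Z-score a difference index across the pool's novels (population SD)."""
    x = scores[index].astype(float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"index {index!r} has zero variance")
    return (x - x.mean()) / sd


def _bernoulli(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def simulate_participant(
    sched: TrialSchedule,
    params: ParticipantParams,
    rng: np.random.Generator,
    scores: pd.DataFrame,
    *,
    participant_id: str = "P1",
    index: str = "dtf",
) -> pd.DataFrame:
    """Simulate one participant's responses over phases 2 and 3.

    ``scores`` must contain one row per novel with the chosen difference
    index; it is z-scored across the pool before entering the linear
    predictors.
    """
    params.validate()
    z = standardized_index(scores, index)
    z_by_id = dict(zip(scores["stimulus_id"], z))

    rows = []
    for t in sched.trials:
        if t.phase is Phase.FAMILIARIZATION:
            continue
        if t.phase is Phase.INCIDENTAL:
            if t.role is Role.FAMILIAR:
                resp = Response.OLD if _bernoulli(rng, params.familiar_accuracy) else Response.NEW
            else:
                if t.stimulus_id not in z_by_id:
                    raise ValueError(f"no difference score for stimulus {t.stimulus_id}")
                eta = params.study_intercept + params.study_dtf_slope * z_by_id[t.stimulus_id]
                resp = Response.NEW if _bernoulli(rng, expit(eta)) else Response.OLD
        else:  # RECOGNITION
            if t.stimulus_id not in z_by_id:
                raise ValueError(f"no difference score for stimulus {t.stimulus_id}")
            if _bernoulli(rng, params.maybe_rate):
                resp = Response.MAYBE
            else:
                is_old = 1.0 if t.role is Role.OLD else 0.0
                x = z_by_id[t.stimulus_id]
                eta = (
                    params.recog_intercept
                    + params.recog_diff_slope * x
                    + params.recog_oldtype_effect * is_old
                    + params.recog_interaction * x * is_old
                )
                resp = Response.SEEN if _bernoulli(rng, expit(eta)) else Response.NOT_SEEN
        if _bernoulli(rng, params.miss_rate):
            resp = Response.NONE
        rows.append(
            {
                "participant_id": participant_id,
                "phase": t.phase.value,
                "trial_index": t.index,
                "stimulus_id": t.stimulus_id,
                "role": t.role.value,
                "response": resp.value,
            }
        )
    return pd.DataFrame(rows)


def draw_participant(
    cohort: CohortParams, rng: np.random.Generator
) -> ParticipantParams:
    """Draw one participant's parameters from the population distribution."""
    m = cohort.mean
    rho = cohort.re_correlation
    cov_study = np.array(
        [
            [cohort.sd_study_intercept**2, rho * cohort.sd_study_intercept * cohort.sd_study_slope],
            [rho * cohort.sd_study_intercept * cohort.sd_study_slope, cohort.sd_study_slope**2],
        ]
    )
    cov_recog = np.array(
        [
            [cohort.sd_recog_intercept**2, rho * cohort.sd_recog_intercept * cohort.sd_recog_oldtype],
            [rho * cohort.sd_recog_intercept * cohort.sd_recog_oldtype, cohort.sd_recog_oldtype**2],
        ]
    )
    si, ss = rng.multivariate_normal([m.study_intercept, m.study_dtf_slope], cov_study)
    ri, ro = rng.multivariate_normal([m.recog_intercept, m.recog_oldtype_effect], cov_recog)
    return replace(
        m,
        study_intercept=float(si),
        study_dtf_slope=float(ss),
        recog_intercept=float(ri),
        recog_oldtype_effect=float(ro),
    )


def simulate_cohort(
    pool: StimulusPool,
    cohort: CohortParams,
    scores: pd.DataFrame,
    *,
    index: str = "dtf",
    shared_schedule: TrialSchedule | None = None,
) -> tuple[pd.DataFrame, list[TrialSchedule]]:
    """Simulate a whole cohort on one pool.

    Each participant gets a fresh schedule (fresh randomization and
    old/distractor split) unless ``shared_schedule`` is given. Returns the
    concatenated response log and the per-participant schedules.
    """
    cohort.validate()
    ss = np.random.SeedSequence(cohort.seed)
    logs = []
    schedules = []
    for i, child in enumerate(ss.spawn(cohort.n_participants)):
        rng = np.random.default_rng(child)
        sched = shared_schedule or build_schedule(pool, seed=int(rng.integers(2**31)))
        params = draw_participant(cohort, rng)
        pid = f"P{i + 1:03d}"
        logs.append(
            simulate_participant(sched, params, rng, scores, participant_id=pid, index=index)
        )
        schedules.append(sched)
    return pd.concat(logs, ignore_index=True), schedules
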