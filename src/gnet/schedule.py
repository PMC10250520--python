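"""Three-phase trial schedule for the GNET.

Phase 1 (familiarization): each of the 5 familiars shown 5 times = 25 trials,
no response required. Phase 2 (incidental learning): 25 familiar presentations
(5 x 5) plus the 50 "old-half" novels, once each = 75 trials; participants
judge old vs new. Phase 3 (recognition test): the 50 phase-2 novels (OLD) plus
the 50 held-out novels (DISTRACTOR) = 100 trials; participants judge already
seen / not seen / maybe seen.

From each novel category, a uniform random half is assigned to phase 2 and the
other half held out as distractors, so novelty is counterbalanced between old
and distractor items. Within-phase orders are unconstrained uniform random
permutations. Timing fields (3.0 s stimulus, 3.0 s response window in phases
2-3, 1.5 s inter-trial interval) are metadata only; the toolkit does not
present stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .stimgen import NOVEL_CATEGORIES, Category, StimulusPool

__all__ = ["Phase", "Role", "Trial", "TrialSchedule", "build_schedule"]

FAMILIAR_REPETITIONS = 5  # presentations per familiar in phases 1 and 2

STIMULUS_DURATION_S = 3.0
RESPONSE_WINDOW_S = 3.0
ITI_S = 1.5


class Phase(str, Enum):
    FAMILIARIZATION = "FAMILIARIZATION"
    INCIDENTAL = "INCIDENTAL"
    RECOGNITION = "RECOGNITION"


class Role(str, Enum):
    FAMILIAR = "FAMILIAR"
    NOVEL = "NOVEL"
    OLD = "OLD"
    DISTRACTOR = "DISTRACTOR"


@dataclass(frozen=True)
class Trial:
    phase: Phase
    index: int
    stimulus_id: str
    role: Role
    stimulus_duration_s: float = STIMULUS_DURATION_S
    response_window_s: float | None = RESPONSE_WINDOW_S
    iti_s: float = ITI_S


@dataclass
class TrialSchedule:
    pool_seed: int
    seed: int
    trials: list[Trial]
    #: per category: (ids shown in phase 2, ids held out as distractors)
    assignment: dict[Category, tuple[list[str], list[str]]] = field(default_factory=dict)

    def phase_trials(self, phase: Phase) -> list[Trial]:
        return [t for t in self.trials if t.phase is phase]

    def roles(self) -> dict[str, Role]:
        """Phase-3 role (OLD/DISTRACTOR) per stimulus id."""
        return {
            t.stimulus_id: t.role
            for t in self.trials
            if t.phase is Phase.RECOGNITION
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": [t.phase.value for t in self.trials],
                "index": [t.index for t in self.trials],
                "stimulus_id": [t.stimulus_id for t in self.trials],
                "role": [t.role.value for t in self.trials],
            }
        )

    def validate(self) -> None:
        counts = {p: len(self.phase_trials(p)) for p in Phase}
        n_fam_trials = counts[Phase.FAMILIARIZATION]
        for t in self.trials:
            if t.role is Role.FAMILIAR and t.phase is Phase.RECOGNITION:
                raise ValueError("FAMILIAR role is confined to phases 1-2")
            if t.role is Role.NOVEL and t.phase is not Phase.INCIDENTAL:
                raise ValueError("NOVEL role is confined to phase 2")
            if t.role in (Role.OLD, Role.DISTRACTOR) and t.phase is not Phase.RECOGNITION:
                raise ValueError("OLD/DISTRACTOR roles are confined to phase 3")
        old_ids = {t.stimulus_id for t in self.trials if t.role is Role.OLD}
        dis_ids = {t.stimulus_id for t in self.trials if t.role is Role.DISTRACTOR}
        if old_ids & dis_ids:
            raise ValueError("a stimulus appears in phase 3 with both roles")
        del n_fam_trials, counts


def build_schedule(pool: StimulusPool, seed: int) -> TrialSchedule:
    """Build a randomized three-phase schedule for a pool.

    The old/distractor split is a uniform random half/half partition within
    each novel category; phase orders are uniform permutations. The schedule
    is a pure function of (pool, seed).
    """
    cfg = pool.config
    pool.validate()
    rng = np.random.default_rng(seed)
    per_cat = cfg.n_familiars * cfg.variants_per_familiar
    if per_cat % 2:
        raise ValueError("per-category novel count must be even for a half/half split")
    half = per_cat // 2

    assignment: dict[Category, tuple[list[str], list[str]]] = {}
    studied: list[str] = []
    distractors: list[str] = []
    for cat in NOVEL_CATEGORIES:
        ids = [s.id for s in pool.novels_by_category(cat)]
        perm = rng.permutation(len(ids))
        shown = [ids[i] for i in perm[:half]]
        held = [ids[i] for i in perm[half:]]
        assignment[cat] = (shown, held)
        studied.extend(shown)
        distractors.extend(held)

    trials: list[Trial] = []

    # Phase 1: each familiar x5, randomized order, no response window.
    p1 = [f.id for f in pool.familiars for _ in range(FAMILIAR_REPETITIONS)]
    for i, k in enumerate(rng.permutation(len(p1))):
        trials.append(
            Trial(Phase.FAMILIARIZATION, i, p1[k], Role.FAMILIAR, response_window_s=None)
        )

    # Phase 2: 25 familiar presentations + studied novels, once each.
    p2_ids = [f.id for f in pool.familiars for _ in range(FAMILIAR_REPETITIONS)] + studied
    p2_roles = [Role.FAMILIAR] * (cfg.n_familiars * FAMILIAR_REPETITIONS) + [Role.NOVEL] * len(studied)
    for i, k in enumerate(rng.permutation(len(p2_ids))):
        trials.append(Trial(Phase.INCIDENTAL, i, p2_ids[k], p2_roles[k]))

    # Phase 3: studied novels (OLD) + held-out novels (DISTRACTOR).
    p3_ids = studied + distractors
    p3_roles = [Role.OLD] * len(studied) + [Role.DISTRACTOR] * len(distractors)
    for i, k in enumerate(rng.permutation(len(p3_ids))):
        trials.append(Trial(Phase.RECOGNITION, i, p3_ids[k], p3_roles[k]))

    sched = TrialSchedule(pool_seed=pool.seed, seed=int(seed), trials=trials, assignment=assignment)
    sched.validate()
    return sched
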