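"""Adaptive 4-trial-round staircase targeting the 75%-correct morph level.

After each round of four trials in a condition, the next round's morph level
moves one 20% grid step toward more diagnostic emotional information when 2
or fewer trials were correct (< 75%), stays when exactly 3 were correct
(75%), and moves one step toward less diagnostic information when all 4 were
correct (> 75%), clamped at the grid bounds.  This transformed up-down rule
makes the per-trial accuracy hover near 75% once the staircase has settled;
the first rounds of each condition are treated as burn-in and excluded from
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    Condition,
    Emotion,
    MorphGrid,
    DEFAULT_GRID,
    StimulusSpec,
    TrialSchedule,
    build_exp2_schedule,
    EXP2_PSEUDOWORDS,
)
from .observers import ObserverProfile, simulate_response

__all__ = [
    "RoundRecord",
    "StaircaseState",
    "next_ml",
    "run_staircases",
    "simulate_experiment2",
    "mean_ml",
    "pool_audio_only",
    "DEFAULT_START_ML",
    "DEFAULT_BURN_IN",
]

DEFAULT_START_ML = 100  # unmanipulated original voice, centre of the grid
DEFAULT_BURN_IN = 4  # rounds per condition excluded from all summaries


@dataclass(frozen=True)
class RoundRecord:
    round_index: int  # 1-based
    morph_level: int
    n_correct: int


@dataclass
class StaircaseState:
    """Running state of one condition's staircase."""

    condition: Condition
    current_ml: int
    rounds_completed: int = 0
    history: list[RoundRecord] = field(default_factory=list)


def next_ml(current_ml: int, n_correct: int, grid: MorphGrid = DEFAULT_GRID) -> int:
    """Morph level of the next round from the last round's performance.

    n_correct <= 2 -> one step up (harder to misjudge: more diagnostic
    information), n_correct == 3 -> unchanged, n_correct == 4 -> one step
    down; clamped at the grid bounds.
    """
    if current_ml not in grid:
        raise ValueError(f"morph level {current_ml} is not on the grid")
    if not 0 <= n_correct <= 4:
        raise ValueError("n_correct must be between 0 and 4")
    if n_correct <= 2:
        return min(current_ml + grid.step, grid.ceiling)
    if n_correct == 3:
        return current_ml
    return max(current_ml - grid.step, grid.floor)


def _plan_round(rng: np.random.Generator) -> list[tuple[Emotion, int, str]]:
    """Stimulus identities for one 4-trial round.

    2 anger + 2 surprise in random order (keeps the 2-AFC unbiased within
    rounds); speakers sampled without replacement; each pseudoword used
    twice.
    """
    emotions = [Emotion.ANGER, Emotion.ANGER, Emotion.SURPRISE, Emotion.SURPRISE]
    rng.shuffle(emotions)  # type: ignore[arg-type]
    speakers = rng.choice(np.arange(1, 9), size=4, replace=False)
    words = list(EXP2_PSEUDOWORDS) * 2
    rng.shuffle(words)  # type: ignore[arg-type]
    return list(zip(emotions, (int(s) for s in speakers), words))


def run_staircases(
    observer: ObserverProfile,
    schedule: TrialSchedule,
    start_ml: int = DEFAULT_START_ML,
    rng_seed: int | np.random.SeedSequence = 0,
    grid: MorphGrid = DEFAULT_GRID,
) -> tuple[pd.DataFrame, dict[Condition, StaircaseState]]:
    """Run all four per-condition staircases of one observer.

    Follows the schedule's slot order; each condition's consecutive slot
    quadruples form its rounds, all four trials of a round at the round's
    morph level.  Returns the trial table and the final per-condition states
    (whose histories are the round log).
    """
    if schedule.experiment != "exp2":
        raise ValueError("run_staircases requires an Experiment-2 schedule")
    if start_ml not in grid:
        raise ValueError(f"start_ml {start_ml} is not on the grid")
    rng = np.random.default_rng(rng_seed)
    states = {c: StaircaseState(c, start_ml) for c in Condition}
    pending: dict[Condition, list[tuple[Emotion, int, str]]] = {c: [] for c in Condition}
    round_correct: dict[Condition, list[bool]] = {c: [] for c in Condition}
    rows = []
    for slot in schedule.slots:
        cond = slot.condition
        state = states[cond]
        if not pending[cond]:
            pending[cond] = _plan_round(rng)
            round_correct[cond] = []
        emotion, speaker, word = pending[cond].pop(0)
        stimulus = StimulusSpec(emotion, speaker, word, state.current_ml, cond)
        rec = simulate_response(stimulus, observer, rng)
        rec["trial_index"] = slot.trial_index
        rec["block"] = slot.block
        rec["round_index"] = state.rounds_completed + 1
        rec["trial_in_round"] = len(round_correct[cond]) + 1
        round_correct[cond].append(rec["correct"])
        rows.append(rec)
        if len(round_correct[cond]) == 4:
            n_corr = sum(round_correct[cond])
            state.history.append(
                RoundRecord(state.rounds_completed + 1, state.current_ml, n_corr)
            )
            state.rounds_completed += 1
            state.current_ml = next_ml(state.current_ml, n_corr, grid)
    return pd.DataFrame(rows), states


def simulate_experiment2(
    cohort: Sequence[ObserverProfile],
    rng_seed: int,
    start_ml: int = DEFAULT_START_ML,
    grid: MorphGrid = DEFAULT_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adaptive Experiment 2 for a whole cohort.

    Each observer gets an independent schedule and staircase stream derived
    from ``rng_seed``.  Returns (trial table, round table).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    seeds = np.random.SeedSequence(rng_seed).spawn(len(cohort))
    trial_frames, round_rows = [], []
    for observer, seed in zip(cohort, seeds):
        sched_seed, stair_seed = seed.spawn(2)
        schedule = build_exp2_schedule(int(sched_seed.generate_state(1)[0] % 2**31))
        trials, states = run_staircases(observer, schedule, start_ml, stair_seed, grid)
        trial_frames.append(trials)
        for cond, state in states.items():
            for r in state.history:
                round_rows.append(
                    {
                        "participant_id": observer.participant_id,
                        "group": observer.group,
                        "condition": cond.value,
                        "round_index": r.round_index,
                        "morph_level": r.morph_level,
                        "n_correct": r.n_correct,
                    }
                )
    return pd.concat(trial_frames, ignore_index=True), pd.DataFrame(round_rows)


def mean_ml(history: Iterable[RoundRecord], burn_in_rounds: int = DEFAULT_BURN_IN) -> float:
    """Mean round morph level after discarding the first burn-in rounds."""
    kept = [r.morph_level for r in history if r.round_index > burn_in_rounds]
    if not kept:
        raise ValueError("no rounds remain after burn-in")
    return float(np.mean(kept))


def pool_audio_only(ml_orig: float, ml_incong: float) -> float:
    """Pool the two auditory-only variants into one summary (their mean)."""
    return (ml_orig + ml_incong) / 2.0
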