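"""Stimulus grids and trial schedules for the two vocal-emotion experiments.

Experiment 1 presents every stimulus of a full factorial design exactly once
at the unmanipulated morph level (100%).  Experiment 2 crosses the same
conditions with a five-point morph-level grid (emotion anti-caricature 60% up
to caricature 140% in 20% steps) and presents 384 adaptive trials per
participant: 96 per condition, interleaved in 8 blocks of 48.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Emotion",
    "Condition",
    "AUDIO_ONLY_CONDITIONS",
    "MorphGrid",
    "StimulusSpec",
    "TrialSchedule",
    "SPEAKER_SEX",
    "EXP1_PSEUDOWORDS",
    "EXP2_PSEUDOWORDS",
    "build_exp1_stimuli",
    "build_exp2_stimuli",
    "build_exp2_schedule",
    "stimuli_to_frame",
]


class Emotion(str, Enum):
    """The two response alternatives of the 2-AFC task."""

    ANGER = "anger"
    SURPRISE = "surprise"


class Condition(str, Enum):
    """Presentation condition of a trial.

    The two auditory-only variants differ only in the nominal timing of the
    (blurred) visual stream and are pooled into a single auditory-only
    condition in all downstream summaries.
    """

    AV_CONGRUENT = "av_congruent"
    AV_INCONGRUENT = "av_incongruent"
    AUDIO_ONLY_ORIG = "audio_only_orig"
    AUDIO_ONLY_INCONG = "audio_only_incong"


AUDIO_ONLY_CONDITIONS = (Condition.AUDIO_ONLY_ORIG, Condition.AUDIO_ONLY_INCONG)

#: speakers 1-4 are female, 5-8 male (balanced 4/4)
SPEAKER_SEX = {i: ("female" if i <= 4 else "male") for i in range(1, 9)}

EXP1_PSEUDOWORDS = ("belam", "namil", "molen", "loman")
EXP2_PSEUDOWORDS = ("belam", "molen")


@dataclass(frozen=True)
class MorphGrid:
    """Closed grid of morph levels in percent; higher = more diagnostic
    emotional information = easier discrimination."""

    levels: tuple[int, ...] = (60, 80, 100, 120, 140)
    step: int = 20

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) < 2 or any(b - a != self.step for a, b in zip(lv, lv[1:])):
            raise ValueError("morph levels must increase in uniform steps")

    @property
    def floor(self) -> int:
        return self.levels[0]

    @property
    def ceiling(self) -> int:
        return self.levels[-1]

    def __contains__(self, level: int) -> bool:
        return level in self.levels


DEFAULT_GRID = MorphGrid()


@dataclass(frozen=True)
class StimulusSpec:
    """One presentable item: emotion x speaker x pseudoword x morph level x
    condition."""

    emotion: Emotion
    speaker_id: int
    pseudoword: str
    morph_level: int
    condition: Condition

    @property
    def speaker_sex(self) -> str:
        return SPEAKER_SEX[self.speaker_id]


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled presentation opportunity (Exp2: condition only; the
    stimulus identity is chosen at run time by the staircase sampler)."""

    trial_index: int
    block: int
    condition: Condition
    stimulus: StimulusSpec | None = None


@dataclass
class TrialSchedule:
    experiment: str
    slots: list[TrialSlot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slots)

    def condition_stream(self, condition: Condition) -> list[TrialSlot]:
        """Slots of one condition in presentation order; consecutive
        quadruples of this stream are that condition's staircase rounds."""
        return [s for s in self.slots if s.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.slots:
            row = {
                "trial_index": s.trial_index,
                "block": s.block,
                "condition": s.condition.value,
            }
            if s.stimulus is not None:
                st = s.stimulus
                row.update(
                    emotion=st.emotion.value,
                    speaker_id=st.speaker_id,
                    speaker_sex=st.speaker_sex,
                    pseudoword=st.pseudoword,
                    morph_level=st.morph_level,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def build_exp1_stimuli() -> list[StimulusSpec]:
    """Full factorial Experiment-1 stimulus set.

    2 emotions x 8 speakers x 4 pseudowords x 4 conditions = 256 items, all
    at the unmanipulated morph level of 100%.
    """
    return [
        StimulusSpec(emotion, spk, pw, 100, cond)
        for emotion in Emotion
        for spk in range(1, 9)
        for pw in EXP1_PSEUDOWORDS
        for cond in Condition
    ]


def build_exp2_stimuli(grid: MorphGrid = DEFAULT_GRID) -> list[StimulusSpec]:
    """Full factorial Experiment-2 stimulus set.

    2 emotions x 8 speakers x 2 pseudowords x 5 morph levels x 4 conditions
    = 640 items.
    """
    return [
        StimulusSpec(emotion, spk, pw, ml, cond)
        for emotion in Emotion
        for spk in range(1, 9)
        for pw in EXP2_PSEUDOWORDS
        for ml in grid.levels
        for cond in Condition
    ]


def build_exp1_schedule(rng_seed: int) -> TrialSchedule:
    """Experiment-1 schedule: every stimulus once, in random order, split
    into 4 blocks of 64 trials."""
    rng = np.random.default_rng(rng_seed)
    stimuli = build_exp1_stimuli()
    order = rng.permutation(len(stimuli))
    slots = [
        TrialSlot(
            trial_index=i,
            block=i // 64,
            condition=stimuli[j].condition,
            stimulus=stimuli[j],
        )
        for i, j in enumerate(order)
    ]
    return TrialSchedule(experiment="exp1", slots=slots)


def build_exp2_schedule(rng_seed: int) -> TrialSchedule:
    """Experiment-2 adaptive-testing schedule.

    384 trial slots (96 per condition) in 8 blocks of 48, with conditions in
    random order within each block.  Each block carries exactly 12 slots per
    condition, so each condition contributes exactly 3 complete 4-trial
    rounds per block and rounds never straddle a block boundary.
    """
    rng = np.random.default_rng(rng_seed)
    slots: list[TrialSlot] = []
    idx = 0
    for block in range(8):
        block_conditions = list(Condition) * 12
        rng.shuffle(block_conditions)  # type: ignore[arg-type]
        for cond in block_conditions:
            slots.append(TrialSlot(trial_index=idx, block=block, condition=cond))
            idx += 1
    return TrialSchedule(experiment="exp2", slots=slots)


def stimuli_to_frame(stimuli: Sequence[StimulusSpec]) -> pd.DataFrame:
    """Tabulate a stimulus set for CSV export."""
    return pd.DataFrame(
        {
            "emotion": [s.emotion.value for s in stimuli],
            "speaker_id": [s.speaker_id for s in stimuli],
            "speaker_sex": [s.speaker_sex for s in stimuli],
            "pseudoword": [s.pseudoword for s in stimuli],
            "morph_level": [s.morph_level for s in stimuli],
            "condition": [s.condition.value for s in stimuli],
        }
    )
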