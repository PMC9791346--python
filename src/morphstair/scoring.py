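"""Trial filtering, per-participant aggregation, and derived scores.

Implements the quantification rules shared by both experiments: exclusion of
trials with reaction times beyond 6000 ms from voice offset, pooling of the
two auditory-only streams into a single auditory-only condition, the
audiovisual benefit/cost difference scores, and the caricature-slope score
(accuracy gain per 20% morph-level step between the lowest and highest level
a participant performed on).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import AUDIO_ONLY_CONDITIONS, Condition
from .staircase import DEFAULT_BURN_IN

__all__ = [
    "POOLED_AUDIO",
    "POOLED_CONDITIONS",
    "SlopeScore",
    "filter_rt",
    "pool_condition_label",
    "summarize_exp1",
    "summarize_exp1_by_speaker_sex",
    "summarize_exp2",
    "benefit_cost",
    "accuracy_by_ml",
    "caricature_slope",
    "slope_table",
]

POOLED_AUDIO = "audio_only"
POOLED_CONDITIONS = (POOLED_AUDIO, Condition.AV_CONGRUENT.value, Condition.AV_INCONGRUENT.value)

_AUDIO_LABELS = {c.value for c in AUDIO_ONLY_CONDITIONS}


def filter_rt(trials: pd.DataFrame, cutoff_ms: float = 6000.0) -> tuple[pd.DataFrame, dict]:
    """Drop trials with rt_ms strictly greater than the cutoff.

    Returns the retained trials and an exclusion report
    ``{"n_total", "n_excluded", "proportion_excluded"}``.
    """
    slow = trials["rt_ms"] > cutoff_ms
    report = {
        "n_total": int(len(trials)),
        "n_excluded": int(slow.sum()),
        "proportion_excluded": float(slow.mean()) if len(trials) else 0.0,
    }
    return trials.loc[~slow].copy(), report


def pool_condition_label(condition: pd.Series) -> pd.Series:
    """Map the two auditory-only variants onto one pooled label."""
    return condition.where(~condition.isin(_AUDIO_LABELS), POOLED_AUDIO)


def _pool_audio_columns(wide: pd.DataFrame) -> pd.DataFrame:
    """Average the two auditory-only columns into ``audio_only``.

    Pooling is the unweighted mean of the two per-condition summaries, which
    equals round-level pooling here because the streams are equal-sized.
    """
    out = wide.copy()
    a, b = (c.value for c in AUDIO_ONLY_CONDITIONS)
    out[POOLED_AUDIO] = (out[a] + out[b]) / 2.0
    return out.drop(columns=[a, b])[list(POOLED_CONDITIONS)]


def summarize_exp1(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy in the three pooled conditions.

    Expects RT-filtered Experiment-1 trials.  A participant with no retained
    trials in some condition gets NaN there (flagged, not dropped).
    """
    acc = (
        trials.groupby(["participant_id", "group", "condition"], observed=True)["correct"]
        .mean()
        .unstack("condition")
    )
    wide = _pool_audio_columns(acc.reindex(columns=[c.value for c in Condition]))
    return wide.reset_index("group")


def summarize_exp1_by_speaker_sex(trials: pd.DataFrame) -> pd.DataFrame:
    """Long accuracy table per participant x pooled condition x speaker sex,
    shaped for the mixed ANOVA (one observation per cell)."""
    acc = (
        trials.assign(condition=lambda d: pool_condition_label(d["condition"]))
        .groupby(["participant_id", "group", "condition", "speaker_sex"], observed=True)[
            "correct"
        ]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    return acc


def summarize_exp2(rounds: pd.DataFrame, burn_in_rounds: int = DEFAULT_BURN_IN) -> pd.DataFrame:
    """Per-participant mean post-burn-in morph level per pooled condition.

    ``rounds`` is the round log (participant_id, group, condition,
    round_index, morph_level, n_correct); the first ``burn_in_rounds`` rounds
    of every condition are excluded before averaging.
    """
    kept = rounds[rounds["round_index"] > burn_in_rounds]
    ml = (
        kept.groupby(["participant_id", "group", "condition"], observed=True)["morph_level"]
        .mean()
        .unstack("condition")
    )
    wide = _pool_audio_columns(ml.reindex(columns=[c.value for c in Condition]))
    return wide.reset_index("group")


def benefit_cost(summary: pd.DataFrame) -> pd.DataFrame:
    """Audiovisual benefit and cost difference scores.

    benefit = AV congruent minus pooled auditory-only, cost = AV incongruent
    minus pooled auditory-only, on the experiment's native scale: accuracy
    differences in Experiment 1 (positive benefit = facilitation), morph-level
    differences in Experiment 2 (negative benefit = facilitation, since lower
    morph levels mean better performance).  Scores inherit NaN from missing
    condition summaries.
    """
    out = summary[["group"]].copy()
    out["benefit"] = summary[Condition.AV_CONGRUENT.value] - summary[POOLED_AUDIO]
    out["cost"] = summary[Condition.AV_INCONGRUENT.value] - summary[POOLED_AUDIO]
    return out


def accuracy_by_ml(
    trials: pd.DataFrame, burn_in_rounds: int = DEFAULT_BURN_IN
) -> pd.DataFrame:
    """Post-burn-in accuracy at each visited morph level, per participant and
    pooled condition.

    The two auditory-only streams are combined by averaging their accuracies
    at each morph level (their trial counts are summed); a level visited by
    only one stream keeps that stream's accuracy.
    """
    kept = trials[trials["round_index"] > burn_in_rounds]
    per_cond = (
        kept.groupby(
            ["participant_id", "group", "condition", "morph_level"], observed=True
        )["correct"]
        .agg(n_trials="size", accuracy="mean")
        .reset_index()
    )
    per_cond["condition"] = pool_condition_label(per_cond["condition"])
    pooled = (
        per_cond.groupby(
            ["participant_id", "group", "condition", "morph_level"], observed=True
        )
        .agg(n_trials=("n_trials", "sum"), accuracy=("accuracy", "mean"))
        .reset_index()
    )
    return pooled


@dataclass(frozen=True)
class SlopeScore:
    """Accuracy change per 20% morph-level step between the lowest and
    highest qualifying levels."""

    ml_low: int
    ml_high: int
    acc_low: float
    acc_high: float
    n_steps: int
    score: float


def caricature_slope(
    acc_by_ml: Mapping[int, tuple[int, float]],
    min_trials_per_ml: int = 4,
    step: int = 20,
) -> SlopeScore | None:
    """Caricature-slope score from a participant-condition accuracy profile.

    ``acc_by_ml`` maps morph level -> (n_trials, accuracy).  Uses the lowest
    and highest levels with at least ``min_trials_per_ml`` trials; returns
    None (missing, not an error) when fewer than two levels qualify — which
    happens for participants whose staircase never left one extreme level.
    """
    qualifying = sorted(ml for ml, (n, _) in acc_by_ml.items() if n >= min_trials_per_ml)
    if len(qualifying) < 2:
        return None
    lo, hi = qualifying[0], qualifying[-1]
    acc_lo, acc_hi = acc_by_ml[lo][1], acc_by_ml[hi][1]
    n_steps = (hi - lo) // step
    return SlopeScore(lo, hi, acc_lo, acc_hi, n_steps, (acc_hi - acc_lo) / n_steps)


def slope_table(
    acc_ml: pd.DataFrame, min_trials_per_ml: int = 4, step: int = 20
) -> pd.DataFrame:
    """Caricature slopes for every participant x pooled condition, with an
    availability flag where the score is undefined."""
    rows = []
    for (pid, group, cond), sub in acc_ml.groupby(
        ["participant_id", "group", "condition"], observed=True
    ):
        profile = {
            int(ml): (int(n), float(a))
            for ml, n, a in zip(sub["morph_level"], sub["n_trials"], sub["accuracy"])
        }
        s = caricature_slope(profile, min_trials_per_ml, step)
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "condition": cond,
                "available": s is not None,
                "ml_low": s.ml_low if s else np.nan,
                "ml_high": s.ml_high if s else np.nan,
                "n_steps": s.n_steps if s else np.nan,
                "slope": s.score if s else np.nan,
            }
        )
    return pd.DataFrame(rows)
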