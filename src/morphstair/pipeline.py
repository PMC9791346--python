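"""End-to-end orchestration of the simulated studies.

``run_exp1`` / ``run_exp2`` generate a cohort, simulate the experiment,
apply the quantification rules (RT exclusion, auditory pooling, burn-in),
and write the result bundle: trial/round logs, participant summaries,
benefit/cost scores, the mixed ANOVA table, matched-subgroup and slope
statistics (Experiment 2), quality-of-life correlations, and a JSON
manifest.  ``calibrate_type1`` estimates the empirical type-I error of the
group-difference test under a null cohort.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from . import scoring, staircase
from .config import RunConfig
from .design import Condition
from .matching import match_groups
from .observers import (
    CohortConfig,
    GroupParams,
    cohort_to_frame,
    sample_cohort,
    simulate_experiment1,
)
from .scoring import POOLED_AUDIO
from .staircase import simulate_experiment2
from .stats import mixed_rm_anova, spearman, t_test

__all__ = [
    "simulate_to_dir",
    "analyze_dir",
    "run_exp1",
    "run_exp2",
    "calibrate_type1",
    "welch_t_rows",
]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def _test_dict(res) -> dict:
    return dataclasses.asdict(res)


def simulate_to_dir(config: RunConfig, outdir: str | Path) -> dict:
    """Generate cohort and trial logs into ``outdir``; returns file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    cohort = sample_cohort(config.cohort, config.rng_seed)
    cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)
    files = {"config": "config.yaml", "cohort": "cohort.csv"}
    if config.experiment == "exp1":
        trials = simulate_experiment1(cohort, config.rng_seed)
        trials.to_csv(out / "trials.csv", index=False)
        files["trials"] = "trials.csv"
    else:
        trials, rounds = simulate_experiment2(cohort, config.rng_seed, config.start_ml)
        trials.to_csv(out / "trials.csv", index=False)
        rounds.to_csv(out / "rounds.csv", index=False)
        files.update(trials="trials.csv", rounds="rounds.csv")
    return files


def analyze_dir(outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Run the full analysis on a simulated bundle in ``outdir``."""
    out = Path(outdir)
    if config is None:
        config = RunConfig.from_yaml(out / "config.yaml")
    if config.experiment == "exp1":
        return _analyze_exp1(config, out)
    return _analyze_exp2(config, out)


def _qol_correlations(cohort_df: pd.DataFrame, summary: pd.DataFrame, dv_col: str) -> dict:
    """Spearman correlation of CI users' auditory performance with the
    WHOQOL-BREF environmental-health score."""
    ci = summary[summary["group"] == "CI"]
    key = f"qol_vs_{dv_col}_ci"
    if len(ci) < 3:
        return {key: {"note": "fewer than 3 participants", "n": int(len(ci))}}
    qol = cohort_df.set_index("participant_id").loc[ci.index, "qol_env"]
    res = spearman(ci[dv_col], qol)
    return {key: dataclasses.asdict(res)}


def _analyze_exp1(config: RunConfig, out: Path) -> dict:
    trials = pd.read_csv(out / "trials.csv")
    cohort_df = pd.read_csv(out / "cohort.csv")
    kept, rt_report = scoring.filter_rt(trials, config.rt_cutoff_ms)

    summary = scoring.summarize_exp1(kept)
    summary.to_csv(out / "summaries.csv")
    bc = scoring.benefit_cost(summary)
    bc.to_csv(out / "benefit_cost.csv")

    by_spsex = scoring.summarize_exp1_by_speaker_sex(kept)
    anova = mixed_rm_anova(
        by_spsex, dv="accuracy", subject="participant_id",
        within=["condition", "speaker_sex"], between="group",
    )
    anova.to_csv(out / "anova.csv")

    ci_b = bc.loc[bc["group"] == "CI", "benefit"]
    nh_b = bc.loc[bc["group"] == "NH", "benefit"]
    ci_c = bc.loc[bc["group"] == "CI", "cost"]
    nh_c = bc.loc[bc["group"] == "NH", "cost"]
    tests = {
        # preregistered direction: larger accuracy benefit for CI users
        "benefit_ci_vs_nh": _test_dict(t_test(ci_b, nh_b, welch=True, alternative="greater")),
        "cost_ci_vs_nh": _test_dict(t_test(ci_c, nh_c, welch=True)),
        "benefit_vs_zero_ci": _test_dict(t_test(ci_b)),
        "benefit_vs_zero_nh": _test_dict(t_test(nh_b)),
    }
    tests.update(_qol_correlations(cohort_df, summary, POOLED_AUDIO))
    _write_json(out / "tests.json", tests)

    manifest = {
        "experiment": "exp1",
        "rng_seed": config.rng_seed,
        "n_per_group": config.cohort.n_per_group,
        "rt_exclusion": rt_report,
        "group_means": bc.groupby("group")[["benefit", "cost"]].mean().to_dict(),
        "files": ["config.yaml", "cohort.csv", "trials.csv", "summaries.csv",
                  "benefit_cost.csv", "anova.csv", "tests.json"],
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def _analyze_exp2(config: RunConfig, out: Path) -> dict:
    trials = pd.read_csv(out / "trials.csv")
    rounds = pd.read_csv(out / "rounds.csv")
    cohort_df = pd.read_csv(out / "cohort.csv")
    kept, rt_report = scoring.filter_rt(trials, config.rt_cutoff_ms)

    summary = scoring.summarize_exp2(rounds, config.burn_in_rounds)
    summary.to_csv(out / "summaries.csv")
    bc = scoring.benefit_cost(summary)
    bc.to_csv(out / "benefit_cost.csv")

    long = summary.reset_index().melt(
        id_vars=["participant_id", "group"],
        value_vars=list(scoring.POOLED_CONDITIONS),
        var_name="condition", value_name="ml",
    )
    anova = mixed_rm_anova(
        long, dv="ml", subject="participant_id", within=["condition"], between="group"
    )
    anova.to_csv(out / "anova.csv")

    ci = summary[summary["group"] == "CI"]
    nh = summary[summary["group"] == "NH"]
    match = match_groups(
        ci[POOLED_AUDIO].to_numpy(), nh[POOLED_AUDIO].to_numpy(),
        min_group_size=config.min_group_size,
        ci_ids=ci.index.to_numpy(), nh_ids=nh.index.to_numpy(),
        strategy=config.matching_strategy,
    )
    (out / "matching.json").write_text(match.to_json())
    mci, mnh = summary.loc[match.kept_ci], summary.loc[match.kept_nh]

    acc_ml = scoring.accuracy_by_ml(kept, config.burn_in_rounds)
    slopes = scoring.slope_table(acc_ml, config.min_trials_per_ml)
    slopes.to_csv(out / "slopes.csv", index=False)

    tests = {
        # preregistered: larger ML benefit (more negative) for CI users
        "benefit_ci_vs_nh": _test_dict(t_test(
            bc.loc[bc["group"] == "CI", "benefit"],
            bc.loc[bc["group"] == "NH", "benefit"],
            welch=True, alternative="less",
        )),
        "cost_ci_vs_nh": _test_dict(t_test(
            bc.loc[bc["group"] == "CI", "cost"],
            bc.loc[bc["group"] == "NH", "cost"], welch=True,
        )),
        "matched_audio_ci_vs_nh": _test_dict(t_test(
            mci[POOLED_AUDIO], mnh[POOLED_AUDIO]
        )),
        # preregistered: matched CI users reach lower congruent MLs
        "matched_congruent_ci_vs_nh": _test_dict(t_test(
            mci[Condition.AV_CONGRUENT.value], mnh[Condition.AV_CONGRUENT.value],
            alternative="less",
        )),
        "matched_incongruent_ci_vs_nh": _test_dict(t_test(
            mci[Condition.AV_INCONGRUENT.value], mnh[Condition.AV_INCONGRUENT.value]
        )),
    }
    slope_tests = {}
    for (group, cond), sub in slopes.groupby(["group", "condition"], observed=True):
        vals = sub.loc[sub["available"], "slope"]
        if len(vals) >= 2:
            slope_tests[f"slope_vs_zero_{group}_{cond}"] = {
                "n_available": int(len(vals)),
                **_test_dict(t_test(vals, alternative="greater")),
            }
    tests.update(slope_tests)
    tests.update(_qol_correlations(cohort_df, summary, POOLED_AUDIO))
    _write_json(out / "tests.json", tests)

    manifest = {
        "experiment": "exp2",
        "rng_seed": config.rng_seed,
        "n_per_group": config.cohort.n_per_group,
        "rt_exclusion": rt_report,
        "group_mean_ml": summary.groupby("group")[list(scoring.POOLED_CONDITIONS)]
        .mean().to_dict(),
        "matched_n_per_group": len(match.kept_ci),
        "matched_removals": match.removals,
        "files": ["config.yaml", "cohort.csv", "trials.csv", "rounds.csv",
                  "summaries.csv", "benefit_cost.csv", "anova.csv", "matching.json",
                  "slopes.csv", "tests.json"],
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def run_exp1(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate and analyze Experiment 1 (fixed-intensity accuracy study)."""
    if config.experiment != "exp1":
        config = dataclasses.replace(config, experiment="exp1")
    simulate_to_dir(config, outdir)
    return analyze_dir(outdir, config)


def run_exp2(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate and analyze Experiment 2 (adaptive staircase study)."""
    if config.experiment != "exp2":
        config = dataclasses.replace(config, experiment="exp2")
    simulate_to_dir(config, outdir)
    return analyze_dir(outdir, config)


def welch_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t test of two (reps x n) matrices.

    Returns (t, Welch-Satterthwaite df, two-tailed p) per row; used by the
    vectorised type-I-error calibration.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def _p_correct_vec(ml: float, theta: np.ndarray, slope: float, lapse: float) -> np.ndarray:
    q = 0.25 / (0.5 - lapse)
    alpha = theta - slope * np.log(q / (1.0 - q))
    return 0.5 + (0.5 - lapse) * expit((ml - alpha) / slope)


def calibrate_type1(
    n_reps: int = 10_000,
    rng_seed: int = 0,
    n_per_group: int = 25,
    trials_per_condition: int = 64,
    group: GroupParams | None = None,
    slope: float = 10.0,
    lapse: float = 0.02,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the Experiment-1 group-benefit Welch test.

    Simulates ``n_reps`` null cohorts in which both listener groups share the
    same generating law (default: the NH parameters), computes each
    participant's audiovisual accuracy benefit (congruent minus pooled
    auditory-only) from binomially aggregated trial counts, and applies the
    two-tailed Welch test between the groups.  Under the null the rejection
    rate should sit at ``alpha``.
    """
    from .observers import NH_DEFAULTS

    gp = group or NH_DEFAULTS
    rng = np.random.default_rng(rng_seed)
    n_total = 2 * n_per_group
    shape = (n_reps, n_total)
    theta = rng.normal(gp.theta_aud_mean, gp.theta_aud_sd, size=shape)
    a = (0.0 - gp.benefit_mean) / gp.benefit_sd
    benefit = sps.truncnorm.rvs(
        a, np.inf, loc=gp.benefit_mean, scale=gp.benefit_sd, size=shape, random_state=rng
    )
    p_aud = _p_correct_vec(100.0, theta, slope, lapse)
    p_cong = _p_correct_vec(100.0, theta - benefit, slope, lapse)
    n_t = trials_per_condition
    acc_cong = rng.binomial(n_t, p_cong) / n_t
    acc_aud = rng.binomial(2 * n_t, p_aud) / (2 * n_t)  # two pooled audio streams
    score = acc_cong - acc_aud
    t, df, p = welch_t_rows(score[:, :n_per_group], score[:, n_per_group:])
    return {
        "n_reps": int(n_reps),
        "alpha": float(alpha),
        "rejection_rate": float(np.mean(p < alpha)),
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }
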