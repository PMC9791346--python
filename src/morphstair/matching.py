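"""Performance matching of the two listener groups by iterative pair removal.

Because some cochlear-implant users underperform even at the easiest morph
level and some normal-hearing controls overperform at the hardest, group
comparisons of audiovisual effects can be confounded by baseline auditory
performance.  The matching procedure removes pairs consisting of the
lowest-performing CI user (highest auditory-only morph level) and the
highest-performing NH control (lowest morph level) until the absolute
difference of the group means is minimal, yielding subgroups with equated
auditory-only performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["MatchResult", "match_groups"]


@dataclass
class MatchResult:
    removals: int
    kept_ci: list[int]
    kept_nh: list[int]
    removed_ci: list[int]
    removed_nh: list[int]
    mean_diff_trace: list[float] = field(default_factory=list)

    @property
    def achieved_diff(self) -> float:
        return self.mean_diff_trace[self.removals]

    def to_json(self) -> str:
        return json.dumps(
            {
                "removals": self.removals,
                "achieved_diff": self.achieved_diff,
                "kept_ci": self.kept_ci,
                "kept_nh": self.kept_nh,
                "removed_ci": self.removed_ci,
                "removed_nh": self.removed_nh,
                "mean_diff_trace": self.mean_diff_trace,
            },
            indent=2,
        )


def _removal_order(values: np.ndarray, ids: np.ndarray, worst_is_max: bool) -> np.ndarray:
    """Indices in removal order; ties on value drop the larger id first."""
    sign = -1.0 if worst_is_max else 1.0
    return np.lexsort((-ids, sign * values))


def match_groups(
    ci_ml: Sequence[float],
    nh_ml: Sequence[float],
    min_group_size: int = 2,
    ci_ids: Sequence[int] | None = None,
    nh_ids: Sequence[int] | None = None,
    strategy: str = "global",
) -> MatchResult:
    """Equate group means by removing worst-CI / best-NH pairs.

    Lower morph level = better performance, so the "lowest-performing" CI
    user is the one with the largest auditory-only morph level and the
    "highest-performing" NH control the one with the smallest.  For each
    admissible removal count k the absolute difference of the trimmed group
    means is evaluated; ``strategy="global"`` returns the smallest k
    attaining the overall minimum (ties broken toward retaining more
    participants), ``strategy="greedy"`` stops at the first local minimum.
    """
    ci = np.asarray(ci_ml, dtype=float)
    nh = np.asarray(nh_ml, dtype=float)
    if ci.size != nh.size:
        raise ValueError("groups must have equal size")
    if min_group_size < 2:
        raise ValueError("min_group_size must be >= 2 (means need two values)")
    if ci.size < min_group_size:
        raise ValueError("groups smaller than min_group_size")
    if strategy not in ("global", "greedy"):
        raise ValueError(f"unknown strategy: {strategy!r}")
    n = ci.size
    ci_ids = np.arange(n) if ci_ids is None else np.asarray(ci_ids)
    nh_ids = np.arange(n) if nh_ids is None else np.asarray(nh_ids)

    ci_order = _removal_order(ci, ci_ids, worst_is_max=True)
    nh_order = _removal_order(nh, nh_ids, worst_is_max=False)

    k_max = n - min_group_size
    trace: list[float] = []
    stopped_early = False
    for k in range(k_max + 1):
        ci_mean = ci[ci_order[k:]].mean()
        nh_mean = nh[nh_order[k:]].mean()
        trace.append(abs(float(ci_mean - nh_mean)))
        if strategy == "greedy" and k > 0 and trace[k] >= trace[k - 1]:
            stopped_early = True
            break

    if strategy == "global":
        best_k = int(np.argmin(trace))  # argmin takes the first == smallest k
    else:
        best_k = len(trace) - 2 if stopped_early else len(trace) - 1

    return MatchResult(
        removals=best_k,
        kept_ci=[int(i) for i in np.sort(ci_ids[ci_order[best_k:]])],
        kept_nh=[int(i) for i in np.sort(nh_ids[nh_order[best_k:]])],
        removed_ci=[int(i) for i in ci_ids[ci_order[:best_k]]],
        removed_nh=[int(i) for i in nh_ids[nh_order[:best_k]]],
        mean_diff_trace=trace,
    )
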