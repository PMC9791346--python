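"""Inferential statistics for the vocal-emotion analyses.

Thin, explicit wrappers over scipy for the t family and Spearman rank
correlation, plus a split-plot (mixed repeated-measures) ANOVA with
Greenhouse-Geisser and Huynh-Feldt sphericity corrections for designs with
one or two within-subject factors and an optional between-subject group
factor — the design used for both experiments (condition x speaker sex
within, listener group between).

The ANOVA is computed from orthonormal within-subject contrasts: for each
within effect the subjects' contrast scores form an N x d matrix whose
hypothesis and error SSCP traces reproduce the classical univariate
sums of squares, and whose pooled covariance yields the epsilon estimates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "t_test", "spearman", "mixed_rm_anova"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    tail: str  # "one" or "two"
    alternative: str  # "two-sided", "greater", "less"
    note: str | None = None


def t_test(
    x,
    y=None,
    paired: bool = False,
    welch: bool = False,
    alternative: str = "two-sided",
    popmean: float = 0.0,
) -> TestResult:
    """Student / Welch / paired / one-sample t test.

    With ``y=None`` a one-sample test of ``mean(x) == popmean`` is run.
    ``welch=True`` uses the Welch statistic with Welch-Satterthwaite
    (fractional) degrees of freedom.  One-tailed tests pass
    ``alternative="greater"`` or ``"less"``; their p is half the two-tailed p
    when the effect lies on the predicted side.
    """
    x = np.asarray(x, dtype=float)
    tail = "two" if alternative == "two-sided" else "one"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if y is None:
            res = sps.ttest_1samp(x, popmean, alternative=alternative)
        elif paired:
            res = sps.ttest_rel(x, np.asarray(y, float), alternative=alternative)
        else:
            res = sps.ttest_ind(
                x, np.asarray(y, float), equal_var=not welch, alternative=alternative
            )
    stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    note = "undefined statistic: zero variance" if math.isnan(stat) else None
    return TestResult(stat, df, p, tail, alternative, note)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    note: str | None = None


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), "constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(x))


def _effect_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows orthogonal to the constant."""
    a = np.column_stack([np.ones(k) / math.sqrt(k), np.eye(k)[:, : k - 1]])
    q, _ = np.linalg.qr(a)
    return q[:, 1:].T


def _epsilons(cov: np.ndarray, n_subjects: int, n_groups: int) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilon from the pooled covariance
    of a within effect's orthonormal contrast scores."""
    d = cov.shape[0]
    if d == 1:
        return 1.0, 1.0  # sphericity is vacuous for a single contrast
    tr = float(np.trace(cov))
    tr2 = float(np.trace(cov @ cov))
    if tr2 <= 0:
        return 1.0, 1.0
    eps_gg = tr * tr / (d * tr2)
    num = n_subjects * d * eps_gg - 2.0
    den = d * (n_subjects - n_groups - d * eps_gg)
    eps_hf = min(1.0, num / den) if den > 0 else 1.0
    return eps_gg, eps_hf


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Split-plot ANOVA: one or two within factors, optional between factor.

    Requires a complete balanced design (exactly one observation per subject
    per within-cell; equal group sizes when ``between`` is given).  Returns a
    table with one row per effect: F, df1, df2, epsilon estimates,
    uncorrected and Huynh-Feldt-corrected p for within effects, and partial
    eta squared.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")
    levels = {w: sorted(data[w].unique()) for w in within}
    cells = list(itertools.product(*(levels[w] for w in within)))
    m = len(cells)

    pivot = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", observed=True
    )
    counts = data.groupby([subject, *within], observed=True)[dv].size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(f"design is not one observation per cell; offending cells:\n{bad}")
    col_order = cells if len(within) > 1 else [c[0] for c in cells]
    missing = [c for c in col_order if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        raise ValueError(f"incomplete design; missing cells: {missing or 'NaN values'}")
    pivot = pivot[col_order]
    y = pivot.to_numpy(dtype=float)
    n_subjects = y.shape[0]

    if between is not None:
        grp = data.groupby(subject, observed=True)[between].agg(lambda s: s.iloc[0])
        grp = grp.loc[pivot.index]
        group_labels = sorted(grp.unique())
        sizes = grp.value_counts()
        if sizes.nunique() != 1:
            raise ValueError("between-subject groups must have equal sizes")
        groups = [np.flatnonzero((grp == g).to_numpy()) for g in group_labels]
    else:
        groups = [np.arange(n_subjects)]
    g = len(groups)
    df_e = n_subjects - g

    contrasts = {w: _effect_contrasts(len(levels[w])) for w in within}
    const = {w: np.ones((1, len(levels[w]))) / math.sqrt(len(levels[w])) for w in within}

    rows = []

    # between-subject stratum
    v = y.mean(axis=1)
    vbar = v.mean()
    ss_err_b = sum(((v[idx] - v[idx].mean()) ** 2).sum() for idx in groups)
    if between is not None:
        ss_g = sum(len(idx) * (v[idx].mean() - vbar) ** 2 for idx in groups)
        f_b = (ss_g / (g - 1)) / (ss_err_b / df_e) if ss_err_b > 0 else float("nan")
        rows.append(
            {
                "effect": between,
                "F": f_b,
                "df1": g - 1,
                "df2": df_e,
                "eps_gg": np.nan,
                "eps_hf": np.nan,
                "p_unc": float(sps.f.sf(f_b, g - 1, df_e)) if np.isfinite(f_b) else np.nan,
                "p_hf": np.nan,
                "pes": ss_g / (ss_g + ss_err_b) if (ss_g + ss_err_b) > 0 else np.nan,
            }
        )

    # within-subject strata: each nonempty subset of within factors
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            mats = [contrasts[w] if w in subset else const[w] for w in within]
            c = mats[0]
            for mat in mats[1:]:
                c = np.kron(c, mat)
            d = c.shape[0]
            u = y @ c.T  # N x d contrast scores
            ubar = u.mean(axis=0)
            h = n_subjects * np.outer(ubar, ubar)
            e = np.zeros((d, d))
            for idx in groups:
                uc = u[idx] - u[idx].mean(axis=0)
                e += uc.T @ uc
            tr_e = float(np.trace(e))
            eps_gg, eps_hf = _epsilons(e / df_e, n_subjects, g)

            def _row(name: str, hmat: np.ndarray, extra_df: int) -> dict:
                df1 = d * extra_df
                df2 = d * df_e
                tr_h = float(np.trace(hmat))
                f = (tr_h / df1) / (tr_e / df2) if tr_e > 0 else float("nan")
                p_unc = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else np.nan
                p_hf = (
                    float(sps.f.sf(f, df1 * eps_hf, df2 * eps_hf))
                    if np.isfinite(f)
                    else np.nan
                )
                pes = tr_h / (tr_h + tr_e) if (tr_h + tr_e) > 0 else np.nan
                return {
                    "effect": name,
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "eps_gg": eps_gg,
                    "eps_hf": eps_hf,
                    "p_unc": p_unc,
                    "p_hf": p_hf,
                    "pes": pes,
                }

            rows.append(_row(" * ".join(subset), h, 1))
            if between is not None:
                hg = np.zeros((d, d))
                for idx in groups:
                    dev = u[idx].mean(axis=0) - ubar
                    hg += len(idx) * np.outer(dev, dev)
                rows.append(_row(" * ".join(subset) + f" * {between}", hg, g - 1))

    return pd.DataFrame(rows).set_index("effect")
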