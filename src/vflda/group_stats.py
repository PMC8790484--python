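"""Group-level statistics: ANOVA with partial eta squared, Holm post hocs,
chi-square with adjusted-residual analysis and Cohen's w, Pearson
correlations, and the median-split high/low-error subgrouping rule.

The mixed (split-plot) ANOVA decomposes a between-subjects group factor and
a within-subjects phase factor: the group effect is tested against subjects
within groups, phase and the interaction against the subject-by-phase
residual, with no sphericity correction.  For 66 subjects in 3 groups over
4 phases this yields the df pattern (2, 63), (3, 189), (6, 189).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ChiSquareResult",
    "SubgroupAssignment",
    "oneway_anova",
    "mixed_anova",
    "chisq_independence",
    "median_split",
    "pearson_correlation",
]

#: two-tailed 5% criterion for adjusted standardized residuals
RESIDUAL_Z = float(stats.norm.ppf(0.975))


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    w: float  # Cohen's effect size, sqrt(chi2 / N)
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    significant_cells: list[tuple[int, int]]


@dataclass
class SubgroupAssignment:
    group: str
    median_cutoff: float
    assignments: dict[str, str]  # subject -> "low_error" | "high_error"


def oneway_anova(
    samples: Mapping[str, Sequence[float]]
) -> tuple[AnovaResult, pd.DataFrame]:
    """One-way between-subjects ANOVA with Holm-adjusted pairwise t-tests.

    Pairwise comparisons use the pooled within-group error (t on N - k df),
    the convention behind printed post hocs like t(63).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    N, k = len(all_values), len(groups)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, N - k
    if ss_within == 0 and ss_between == 0:
        F = 0.0
    else:
        mse = ss_within / df_w
        F = (ss_between / df_b) / mse if mse > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    result = AnovaResult("group", float(F), df_b, df_w, p, float(eta))

    mse = ss_within / df_w if df_w > 0 else 0.0
    rows = []
    for (ga, va), (gb, vb) in itertools.combinations(groups.items(), 2):
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        t = (va.mean() - vb.mean()) / se if se > 0 else 0.0
        rows.append({"group_a": ga, "group_b": gb, "t": float(t), "df": df_w,
                     "p_raw": float(2 * stats.t.sf(abs(t), df_w))})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    return result, table


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "phase",
) -> list[AnovaResult]:
    """Split-plot ANOVA: between-subjects group x within-subjects phase.

    Requires every subject to have exactly one observation per phase level.
    Returns results for the group main effect, the phase main effect, and
    the interaction, each with partial eta squared.
    """
    phases = sorted(data[within].unique())
    P = len(phases)
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, aggfunc="first")
    if wide.isna().any().any() or len(wide) * P != len(data):
        raise ValueError("every subject needs exactly one value per phase")
    y = wide.to_numpy(dtype=float)
    group_of = wide.index.get_level_values(between).to_numpy()
    groups = sorted(set(group_of))
    N = len(wide)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = {g: y[group_of == g].mean() for g in groups}
    n_per_group = {g: int((group_of == g).sum()) for g in groups}
    phase_means = y.mean(axis=0)
    cell_means = {g: y[group_of == g].mean(axis=0) for g in groups}

    ss_group = P * sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_subj = P * sum((subj_means[i] - group_means[group_of[i]]) ** 2 for i in range(N))
    ss_phase = N * ((phase_means - grand) ** 2).sum()
    ss_inter = sum(
        n_per_group[g] * ((cell_means[g] - group_means[g] - phase_means + grand) ** 2).sum()
        for g in groups
    )
    resid = np.array([
        y[i] - subj_means[i] - cell_means[group_of[i]] + group_means[group_of[i]]
        for i in range(N)
    ])
    ss_err_within = (resid ** 2).sum()

    k = len(groups)
    df_group, df_subj = k - 1, N - k
    df_phase = P - 1
    df_inter = (k - 1) * (P - 1)
    df_err_w = (N - k) * (P - 1)

    def _res(name, ss_eff, df_eff, ss_err, df_err):
        if ss_eff == 0:
            F, p = 0.0, 1.0
        else:
            F = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(F, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaResult(name, float(F), df_eff, df_err, p, float(eta))

    return [
        _res(between, ss_group, df_group, ss_subj, df_subj),
        _res(within, ss_phase, df_phase, ss_err_within, df_err_w),
        _res(f"{between} x {within}", ss_inter, df_inter, ss_err_within, df_err_w),
    ]


def chisq_independence(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) with Haberman adjusted
    standardized residuals and Cohen's w = sqrt(chi2 / N).

    Cells whose |adjusted residual| exceeds the two-tailed 5% z-criterion
    (1.96) are flagged as significant.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("expected a 2-D table of non-negative counts")
    N = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if N == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: zero grand total or marginal")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    adj = (obs - expected) / np.sqrt(
        expected * np.outer(1 - row / N, 1 - col / N)
    )
    sig = [(int(i), int(j)) for i, j in zip(*np.where(np.abs(adj) > RESIDUAL_Z))]
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p=float(p), w=float(np.sqrt(chi2 / N)),
        expected=expected, adjusted_residuals=adj, significant_cells=sig,
    )


def median_split(
    total_errors: Mapping[str, float], group: str
) -> SubgroupAssignment:
    """High/low-error subgroups by the group median of total errors.

    A subject with total errors greater than OR EQUAL to the median joins
    the high-error subgroup.  The median of an even-sized sample is the
    midpoint of the two central order statistics.
    """
    if not total_errors:
        raise ValueError("group has no subjects")
    m = float(np.median(list(total_errors.values())))
    assignments = {
        s: "high_error" if v >= m else "low_error"
        for s, v in total_errors.items()
    }
    return SubgroupAssignment(group=group, median_cutoff=m, assignments=assignments)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> Optional[float]:
    """Pearson r; ``None`` signals an undefined correlation (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])
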