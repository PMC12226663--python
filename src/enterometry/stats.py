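"""Longitudinal responsiveness statistics for the measurement table.

Covers the analysis layer of a three-visit treatment-response study:
change over time by a linear mixed-effects model (fixed categorical
timepoint, random subject intercept, REML; joint Wald test of the
timepoint terms), group-mean percent change from baseline, agreement
between manual and semi-automated volumes by a two-way random-effects
absolute-agreement single-measures intraclass correlation ICC(2,1) with
its F-distribution confidence interval, and Pearson correlations with
Fisher-z intervals.  Missing follow-ups are handled by using available
data; nothing is imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .phantom import MEASUREMENTS, TIMEPOINTS

__all__ = [
    "ChangeTestResult", "AgreementResult", "CorrelationResult", "StudyResults",
    "percent_change", "fit_change_over_time", "icc_agreement", "pearson_ci",
    "run_study_analysis",
]

#: Agreement bands for ICC point estimates (Koo & Li convention).
ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"), (np.inf, "excellent"))


def percent_change(baseline_mean: float, followup_mean: float, rounded: bool = True) -> float:
    """Percent change of the group mean from baseline; positive = decrease.

    ``100 * (baseline - followup) / baseline``, rounded to the nearest
    integer percent (half away from zero), the resolution at which such
    changes are conventionally reported.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    pct = 100.0 * (baseline_mean - followup_mean) / baseline_mean
    if not rounded:
        return pct
    return math.floor(pct + 0.5) if pct >= 0 else -math.floor(-pct + 0.5)


@dataclass
class ChangeTestResult:
    measurement: str
    timepoint_means: dict[str, float]     # model-implied mean per timepoint
    p_value: float
    fixed_effects: dict[str, float]
    n_subjects: int
    n_observations: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")
        if not all(np.isfinite(list(self.timepoint_means.values()))):
            raise ValueError("non-finite timepoint mean")


def fit_change_over_time(table: pd.DataFrame, measurement: str) -> ChangeTestResult:
    """Mixed-effects change-over-time test for one measurement.

    Linear model ``y ~ timepoint`` with a random subject intercept, fitted
    by REML on available rows; the reported p-value is the joint Wald
    chi-square test of the timepoint fixed effects.
    """
    if measurement not in table.columns:
        raise ValueError(f"measurement {measurement!r} absent from table")
    df = table[["subject_id", "timepoint", measurement]].dropna().copy()
    df = df.rename(columns={measurement: "value"})
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS, ordered=True)
    per_subject = df.groupby("subject_id", observed=True)["timepoint"].nunique()
    if (per_subject >= 2).sum() < 2:
        raise ValueError(
            "need at least 2 subjects with at least 2 timepoints to model change over time"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(timepoint)", df, groups=df["subject_id"])
        fit = model.fit(reml=True)
    names = list(fit.fe_params.index)
    tp_idx = [i for i, nm in enumerate(names) if "timepoint" in nm]
    L = np.zeros((len(tp_idx), len(fit.params)))
    for row, i in enumerate(tp_idx):
        L[row, i] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wald = fit.wald_test(L, scalar=True)
    p = float(wald.pvalue)

    fe = dict(fit.fe_params)
    intercept = fe.get("Intercept", 0.0)
    means = {}
    for tp in TIMEPOINTS:
        if tp == TIMEPOINTS[0]:
            means[tp] = float(intercept)
        else:
            key = next((nm for nm in names if f"[T.{tp}]" in nm), None)
            if key is not None:
                means[tp] = float(intercept + fe[key])
    return ChangeTestResult(
        measurement=measurement,
        timepoint_means=means,
        p_value=p,
        fixed_effects={k: float(v) for k, v in fe.items()},
        n_subjects=df["subject_id"].nunique(),
        n_observations=len(df),
    )


@dataclass
class AgreementResult:
    icc_estimate: float
    ci_low: float
    ci_high: float
    band: str = field(init=False)
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc_estimate <= self.ci_high):
            raise ValueError("ICC estimate must lie inside its confidence interval")
        for bound, name in ICC_BANDS:
            if self.icc_estimate < bound:
                self.band = name
                break


def icc_agreement(manual, semiauto, ci: float = 0.95) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed directly from the two-way ANOVA mean squares (rows = subjects
    or exams, columns = the two raters); the confidence interval follows
    the standard F-distribution construction for ICC(A,1).
    """
    x = np.asarray(manual, dtype=float)
    y = np.asarray(semiauto, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    Y = np.column_stack([x[ok], y[ok]])
    n, k = Y.shape
    if n < 5:
        raise ValueError(f"need at least 5 complete pairs, got {n}")
    grand = Y.mean()
    if np.allclose(Y, grand):
        raise ValueError("ICC undefined: zero variance in both raters")
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_total = ((Y - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (two-way random, absolute agreement, single measures)
    alpha = 1.0 - ci
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lower = min(lower, icc)
    upper = max(upper, icc)
    return AgreementResult(icc_estimate=float(icc), ci_low=float(lower),
                           ci_high=float(upper), n_pairs=n)


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.ci_low <= self.r <= self.ci_high <= 1 + 1e-12):
            raise ValueError("correlation CI must bracket r inside [-1, 1]")


def pearson_ci(x, y, ci: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and two-sided p.

    Pairs with a missing value in either vector are dropped (pairwise
    deletion); at least 4 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0:  # degenerate perfect correlation: CI collapses
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zcrit = sps.norm.ppf(0.5 + ci / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi),
                             p_value=p, n_pairs=n)


#: Measurements entering the cross-correlation matrix (all visits pooled).
CORRELATION_MEASURES = ("max_thickness_mm", "length_cm", "manual_volume_mL", "semiauto_volume_mL")


@dataclass
class StudyResults:
    change_tests: pd.DataFrame
    percent_changes: pd.DataFrame
    agreement: AgreementResult
    correlations: pd.DataFrame        # square r matrix
    correlations_long: pd.DataFrame   # pairwise rows with CI and p


def run_study_analysis(table: pd.DataFrame) -> StudyResults:
    """The full statistics bundle for a longitudinal measurement table.

    Change-over-time mixed-effects tests for all five measurements,
    group-mean percent changes for baseline->week6 and baseline->month6,
    ICC(2,1) agreement of manual vs semi-automated volume over all pooled
    exams, and the pairwise Pearson correlation matrix of the four
    headline measures with all timepoints combined.
    """
    if table is None or len(table) == 0:
        raise ValueError("measurement table is empty")
    present = [m for m in MEASUREMENTS if m in table.columns]
    if not present:
        raise ValueError("table contains none of the study measurements")

    change_rows, pct_rows = [], []
    for m in present:
        res = fit_change_over_time(table, m)
        change_rows.append({
            "measurement": m,
            **{f"mean_{tp}": res.timepoint_means.get(tp, np.nan) for tp in TIMEPOINTS},
            "p_value": res.p_value,
            "n_subjects": res.n_subjects,
            "n_observations": res.n_observations,
        })
        group_means = table.groupby("timepoint", observed=True)[m].mean()
        for tp in TIMEPOINTS[1:]:
            if tp in group_means.index and TIMEPOINTS[0] in group_means.index:
                pct_rows.append({
                    "measurement": m,
                    "interval": f"baseline_to_{tp}",
                    "baseline_mean": group_means[TIMEPOINTS[0]],
                    "followup_mean": group_means[tp],
                    "percent_change": percent_change(
                        group_means[TIMEPOINTS[0]], group_means[tp]
                    ),
                })

    agreement = icc_agreement(
        table["manual_volume_mL"], table["semiauto_volume_mL"]
    ) if {"manual_volume_mL", "semiauto_volume_mL"} <= set(table.columns) else None
    if agreement is None:
        raise ValueError("table lacks the volume columns needed for agreement analysis")

    measures = [m for m in CORRELATION_MEASURES if m in table.columns]
    mat = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    long_rows = []
    for i, mi in enumerate(measures):
        for j in range(i + 1, len(measures)):
            mj = measures[j]
            c = pearson_ci(table[mi], table[mj])
            mat.loc[mi, mj] = mat.loc[mj, mi] = c.r
            long_rows.append({
                "measure_a": mi, "measure_b": mj, "r": c.r,
                "ci_low": c.ci_low, "ci_high": c.ci_high,
                "p_value": c.p_value, "n_pairs": c.n_pairs,
            })
    return StudyResults(
        change_tests=pd.DataFrame(change_rows),
        percent_changes=pd.DataFrame(pct_rows),
        agreement=agreement,
        correlations=mat,
        correlations_long=pd.DataFrame(long_rows),
    )


def plot_measurement_boxplots(table: pd.DataFrame, out_path=None):
    """Tukey box plots (whiskers at 1.5 x IQR) of each measurement by visit.

    Optional figure analogue of the usual treatment-response panel; needs
    matplotlib (``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    present = [m for m in MEASUREMENTS if m in table.columns]
    fig, axes = plt.subplots(1, len(present), figsize=(3 * len(present), 3.2))
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, present):
        data = [table.loc[table["timepoint"] == tp, m].dropna() for tp in TIMEPOINTS]
        ax.boxplot(data, tick_labels=TIMEPOINTS, whis=1.5)
        ax.set_title(m, fontsize=9)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
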