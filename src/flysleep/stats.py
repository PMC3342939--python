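"""Group-level statistics for sleep-architecture experiments.

Implements the statistical surface of the analysis: partitioning-score
normalization against cohort controls, two-sample distribution comparison
(Kolmogorov-Smirnov), Welch's t-test for pairwise contrasts, one- and
two-way ANOVA (Fisher LSD pairwise comparisons after the one-way model,
Type II sums of squares for unbalanced two-way designs), Fisher's exact
test for responder tables, and the log-rank test for activity-derived
lifespans.  Engines are scipy / statsmodels / lifelines; this module owns
the conventions (SEM with n-1 SD, degenerate-input behavior, tidy output
tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float | tuple
    p: float


def group_summary(
    df: pd.DataFrame, metrics: Sequence[str], by: Sequence[str] | str
) -> pd.DataFrame:
    """Mean, SEM (sample SD / sqrt(n)) and n per factor combination."""
    by = [by] if isinstance(by, str) else list(by)
    out = []
    for keys, grp in df.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        for m in metrics:
            vals = grp[m].dropna().to_numpy(float)
            row[f"{m}_n"] = vals.size
            row[f"{m}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{m}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


def partitioning_score(
    records: pd.DataFrame,
    design: pd.DataFrame,
    metric: str = "whole_sleep_bout_count",
) -> pd.DataFrame:
    """Sleep partitioning score: bout count normalized to cohort controls.

    Each fly's sleep-bout count is divided by the mean count of the
    control flies in its experimental cohort, so the control-group mean
    is exactly 1 in every cohort.
    """
    if metric not in records.columns:
        raise KeyError(f"records has no column {metric!r}")
    merged = records.merge(
        design[["fly_id", "cohort", "is_control", "diet", "genotype"]],
        on="fly_id",
        how="inner",
        validate="one_to_one",
    )
    if len(merged) < len(records):
        missing = set(records["fly_id"]) - set(merged["fly_id"])
        raise DesignError(f"flies absent from design table: {sorted(missing)}")
    scores = []
    for cohort, grp in merged.groupby("cohort"):
        ctrl = grp.loc[grp["is_control"], metric].dropna()
        if ctrl.empty:
            raise DesignError(f"cohort {cohort!r} has no control flies with {metric}")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise DesignError(f"cohort {cohort!r}: control mean of {metric} is zero")
        g = grp.copy()
        g["raw"] = g[metric]
        g["score"] = g[metric] / ctrl_mean
        scores.append(g)
    cols = ["fly_id", "cohort", "diet", "genotype", "is_control", "raw", "score"]
    return pd.concat(scores, ignore_index=True)[cols]


def ks_compare(lengths_a: Sequence[float], lengths_b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison of bout-length samples.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    distribution (bout lengths are integer minutes, so ties are expected
    and an exact p is not defined).
    """
    a = np.asarray(lengths_a, float)
    b = np.asarray(lengths_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult("ks_2samp", float(res.statistic), (a.size, b.size), float(res.pvalue))


def welch_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    If both groups have zero variance and equal means the comparison is
    vacuous and reported as t=0, p=1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, float(a.size + b.size - 2), 1.0)
        return TestResult("welch_t", np.inf, float(a.size + b.size - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df), float(res.pvalue))


def anova2(
    df: pd.DataFrame, metric: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way ANOVA with interaction (Type II sums of squares).

    Returns a table with rows for each main effect, the interaction, and
    the residual.  Every factor-level cell must be occupied.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[metric, factor_a, factor_b]].dropna().copy()
    for fac in (factor_a, factor_b):
        if data[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    full = data[factor_a].nunique() * data[factor_b].nunique()
    if len(cells) < full:
        present = set(cells.index)
        empty = [
            (a, b)
            for a in data[factor_a].unique()
            for b in data[factor_b].unique()
            if (a, b) not in present
        ]
        raise ValueError(f"empty design cell(s): {empty}")
    data = data.rename(columns={metric: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    if np.isclose(model.centered_tss, 0.0):
        # constant response: no variance to apportion
        table = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=["C(_a)", "C(_b)", "C(_a):C(_b)", "Residual"],
        )
    else:
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(_a)": factor_a,
            "C(_b)": factor_b,
            "C(_a):C(_b)": f"{factor_a}:{factor_b}",
        }
    )
    table.index.name = "effect"
    return table


def anova1_fisher_lsd(
    df: pd.DataFrame, metric: str, factor: str
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    LSD pairwise tests use the pooled ANOVA mean-square error and its
    residual df, with no multiplicity correction (the definition of LSD).
    """
    data = df[[metric, factor]].dropna()
    groups = {k: g[metric].to_numpy(float) for k, g in data.groupby(factor, sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [k for k, v in groups.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")
    values = list(groups.values())
    grand = np.concatenate(values)
    n_total, k = grand.size, len(values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    ss_between = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in values)
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0:
        omnibus = TestResult("anova1_F", 0.0, (df_b, df_w), 1.0)
    else:
        f_stat = (ss_between / df_b) / mse
        omnibus = TestResult(
            "anova1_F", float(f_stat), (df_b, df_w), float(sps.f.sf(f_stat, df_b, df_w))
        )
    rows = []
    for ga, gb in combinations(groups, 2):
        va, vb = groups[ga], groups[gb]
        se = np.sqrt(mse * (1 / va.size + 1 / vb.size))
        t = (va.mean() - vb.mean()) / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t), df_w)) if se > 0 else 1.0
        rows.append(
            {"group_a": ga, "group_b": gb, "diff": va.mean() - vb.mean(),
             "t": float(t), "df": df_w, "p": p}
        )
    return omnibus, pd.DataFrame(rows)


def responder_test(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 responder/non-responder table."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if tab.sum() == 0:
        raise ValueError("table is all zero")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), tab.sum(), float(p))


def logrank_lifespan(
    times_a: Sequence[float],
    times_b: Sequence[float],
    observed_a: Sequence[bool] | None = None,
    observed_b: Sequence[bool] | None = None,
) -> TestResult:
    """Two-group log-rank comparison of activity-derived lifespans.

    Flies alive at the end of recording are right-censored (pass
    ``observed_* = False`` for them).  Requires at least one death event
    overall.
    """
    from lifelines.statistics import logrank_test

    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    oa = np.ones_like(ta, bool) if observed_a is None else np.asarray(observed_a, bool)
    ob = np.ones_like(tb, bool) if observed_b is None else np.asarray(observed_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (oa.any() or ob.any()):
        raise ValueError("no death events in either group")
    res = logrank_test(ta, tb, event_observed_A=oa, event_observed_B=ob)
    return TestResult("logrank", float(res.test_statistic), 1, float(res.p_value))
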