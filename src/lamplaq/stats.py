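"""Group-level statistics: percent reductions, ANOVA, t-tests, time courses.

The percent reduction between arms is defined on arm means — ``100 * (1 -
mean(cko) / mean(control))`` — because the arms are independent animals with
no pairing; its uncertainty is propagated through the ratio by the
first-order delta method (cross-checked against a bootstrap in the test
suite).  ANOVA runs on untransformed area fractions, matching how the
measurements are reported; a log-transform switch is available.  No
multiple-testing correction is applied across regions: per-region p-values
are reported as-is, which mirrors the per-region starring convention of the
source analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

REGION_ORDER = ("CA1_SO", "CA1_SP", "CA1_SR", "CA1_SLM",
                "CA23_SO", "CA23_SP", "CA23_SR", "CA23_SLM",
                "DG_MO", "DG_SG", "DG_H", "CA1", "CA23", "DG", "HIPPO")


@dataclass
class ReductionEstimate:
    """Percent reduction of the cKO arm relative to control, with SEM."""
    region: str | None
    percent_reduction: float
    sem: float
    n_control: int
    n_cko: int
    defined: bool = True


def percent_reduction(control, cko, region: str | None = None) -> ReductionEstimate:
    """Reduction of arm means with delta-method SEM.

    With ``R = mean(cko) / mean(control)`` the reduction is ``100 (1 - R)``
    and ``Var(R) ~= SE_k^2 / m_c^2 + m_k^2 SE_c^2 / m_c^4`` to first order,
    where ``SE`` are the two arm standard errors.  A non-positive control
    mean leaves the reduction undefined (flagged, NaN).
    """
    c = np.asarray(control, dtype=float)
    k = np.asarray(cko, dtype=float)
    if c.size < 2 or k.size < 2:
        raise ValueError("need at least 2 animals per arm")
    mc, mk = c.mean(), k.mean()
    if mc <= 0:
        warnings.warn(f"control mean {mc} <= 0; reduction undefined", stacklevel=2)
        return ReductionEstimate(region, np.nan, np.nan, c.size, k.size, False)
    se_c = c.std(ddof=1) / np.sqrt(c.size)
    se_k = k.std(ddof=1) / np.sqrt(k.size)
    var_ratio = se_k ** 2 / mc ** 2 + (mk ** 2) * se_c ** 2 / mc ** 4
    return ReductionEstimate(region, 100.0 * (1.0 - mk / mc),
                             100.0 * float(np.sqrt(var_ratio)), c.size, k.size)


def reduction_table(measurements: pd.DataFrame,
                    value_col: str = "area_fraction_pct") -> pd.DataFrame:
    """Per-region reduction estimates from an animal measurement table.

    Expects one row per animal x region with an ``arm`` column holding
    ``control`` / ``cko``.
    """
    rows = []
    for region, grp in measurements.groupby("region", sort=False):
        c = grp.loc[grp.arm == "control", value_col].to_numpy()
        k = grp.loc[grp.arm == "cko", value_col].to_numpy()
        est = percent_reduction(c, k, region)
        rows.append({"region": region, "percent_reduction": est.percent_reduction,
                     "sem": est.sem, "n_control": est.n_control,
                     "n_cko": est.n_cko, "defined": est.defined})
    df = pd.DataFrame(rows)
    order = {r: i for i, r in enumerate(REGION_ORDER)}
    return df.sort_values("region", key=lambda s: s.map(lambda r: order.get(r, 99))
                          ).reset_index(drop=True)


def two_way_anova(table: pd.DataFrame, value_col: str = "area_fraction_pct",
                  log_transform: bool = False) -> pd.DataFrame:
    """Classical two-way ANOVA over arm x region with interaction.

    Returns a frame indexed by effect (``arm``, ``region``,
    ``arm:region``, ``residual``) with sum-of-squares, df, F and p (Type II
    sums of squares, valid for unbalanced layouts).  When one factor has a
    single level the model degenerates to a one-way ANOVA on the other
    factor, with a warning; if both are single-level it raises.
    """
    df = table.copy()
    for col in ("arm", "region", value_col):
        if col not in df.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if log_transform:
        df[value_col] = np.log(df[value_col] + np.finfo(float).tiny)
    df = df.rename(columns={value_col: "_y"})
    n_arm, n_reg = df.arm.nunique(), df.region.nunique()
    if n_arm < 2 and n_reg < 2:
        raise ValueError("both factors have a single level; nothing to test")
    if n_arm < 2 or n_reg < 2:
        kept = "region" if n_arm < 2 else "arm"
        warnings.warn(f"factor {'arm' if n_arm < 2 else 'region'} has one level; "
                      f"falling back to one-way ANOVA on {kept}", stacklevel=2)
        formula = f"_y ~ C({kept})"
        rename = {f"C({kept})": kept}
    else:
        formula = "_y ~ C(arm) + C(region) + C(arm):C(region)"
        rename = {"C(arm)": "arm", "C(region)": "region",
                  "C(arm):C(region)": "arm:region"}
    fit = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    aov = aov.rename(index={**rename, "Residual": "residual"})
    aov.index.name = "effect"
    return aov.rename(columns={"sum_sq": "sum_sq", "df": "df", "F": "F",
                               "PR(>F)": "p"})


@dataclass
class TTestResult:
    t: float
    p: float
    n_control: int
    n_cko: int


def t_test(control, cko) -> TTestResult:
    """Two-sided unpaired Student t-test with pooled variance.

    Two constant, equal arms give t = 0, p = 1 rather than NaN.
    """
    c = np.asarray(control, dtype=float)
    k = np.asarray(cko, dtype=float)
    if c.size < 2 or k.size < 2:
        raise ValueError("need at least 2 values per arm")
    if c.std(ddof=1) == 0 and k.std(ddof=1) == 0:
        if c.mean() == k.mean():
            return TTestResult(0.0, 1.0, c.size, k.size)
        return TTestResult(np.inf * np.sign(c.mean() - k.mean()), 0.0, c.size, k.size)
    t, p = sps.ttest_ind(c, k, equal_var=True)
    return TTestResult(float(t), float(p), c.size, k.size)


def time_course_summary(tables_by_age: dict[float, pd.DataFrame],
                        value_col: str = "area_fraction_pct",
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-age, per-region mean +/- SEM plus a one-way ANOVA across ages.

    ``tables_by_age`` maps age (months) to an animal measurement table.
    Regions observed in a single animal at some age get a NaN SEM there
    (flagged via ``sem_defined``).  The ANOVA frame has one row per region
    with F and p across ages.
    """
    if len(tables_by_age) < 2:
        raise ValueError("need measurements at >= 2 ages")
    summary_rows, anova_rows = [], []
    ages = sorted(tables_by_age)
    regions = list(dict.fromkeys(
        r for a in ages for r in tables_by_age[a].region.unique()))
    for region in regions:
        per_age = []
        for age in ages:
            vals = tables_by_age[age].loc[
                tables_by_age[age].region == region, value_col].to_numpy()
            n = vals.size
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            if n == 1:
                warnings.warn(f"single animal for {region} at {age} months; "
                              "SEM undefined", stacklevel=2)
            summary_rows.append({"age_months": age, "region": region,
                                 "mean": vals.mean() if n else np.nan,
                                 "sem": sem, "n": n, "sem_defined": n > 1})
            per_age.append(vals)
        groups = [g for g in per_age if g.size > 0]
        if len(groups) >= 2 and all(g.size > 0 for g in groups):
            f, p = sps.f_oneway(*groups)
            anova_rows.append({"region": region, "F": float(f), "p": float(p)})
    return pd.DataFrame(summary_rows), pd.DataFrame(anova_rows)
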