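"""End-point phenotype statistics.

Two-group comparisons with normality-driven test selection: Shapiro-Wilk
per group; if both groups look normal, an F-test of equal variances decides
between Student's and Welch's two-tailed t-test; any non-normal group sends
the comparison to the Mann-Whitney U-test.  Descriptives are median and
interquartile range with linear-interpolation quartiles.  Significance is
accepted at p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

log = logging.getLogger("duomics")


@dataclass
class EndpointResult:
    variable: str
    group_stats: dict       # group -> dict(median, iqr, q1, q3, n)
    test: str               # student_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    significant: bool
    trace: dict             # normality p per group, variance-test p

    def to_row(self) -> dict:
        row = dict(variable=self.variable, test=self.test,
                   statistic=self.statistic, p_value=self.p_value,
                   significant=self.significant)
        for g, s in self.group_stats.items():
            row[f"{g}_median"] = s["median"]
            row[f"{g}_iqr"] = s["iqr"]
            row[f"{g}_n"] = s["n"]
        row.update({f"trace_{k}": v for k, v in self.trace.items()})
        return row


def choose_test(x, y, alpha_norm: float = 0.05, alpha_var: float = 0.05):
    """Test-selection cascade; returns (test id, decision trace)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("normality testing needs n >= 3 per group")
    trace = {}
    normal = True
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            trace[f"shapiro_p_{name}"] = np.nan   # degenerate: treat as normal
            continue
        p = float(stats.shapiro(v).pvalue)
        trace[f"shapiro_p_{name}"] = p
        normal &= p > alpha_norm
    if not normal:
        trace["variance_p"] = np.nan
        return "mann_whitney", trace
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        trace["variance_p"] = np.nan
        return "student_t", trace
    big, small = max(vx, vy), min(vx, vy)
    dfn = (len(x) - 1) if vx >= vy else (len(y) - 1)
    dfd = (len(y) - 1) if vx >= vy else (len(x) - 1)
    F = big / small if small > 0 else np.inf
    p_var = float(2 * min(stats.f.sf(F, dfn, dfd), 1 - stats.f.sf(F, dfn, dfd)))
    p_var = min(p_var, 1.0)
    trace["variance_p"] = p_var
    return ("student_t" if p_var > alpha_var else "welch_t"), trace


def _descriptives(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return dict(median=float(med), q1=float(q1), q3=float(q3),
                iqr=float(q3 - q1), n=int(len(v)))


def compare(x, y, variable: str = "", alpha: float = 0.05,
            group_names: tuple = ("control", "alcohol")) -> EndpointResult:
    """Run the selected two-tailed test and report median (IQR) per group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    test, trace = choose_test(x, y)
    if np.array_equal(np.sort(x), np.sort(y)) and np.ptp(np.r_[x, y]) == 0:
        log.warning("identical constant samples for %s: p = 1", variable)
        stat, p = 0.0, 1.0
    elif test == "student_t":
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif test == "welch_t":
        stat, p = stats.ttest_ind(x, y, equal_var=False)
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return EndpointResult(
        variable=variable,
        group_stats={group_names[0]: _descriptives(x), group_names[1]: _descriptives(y)},
        test=test, statistic=float(stat), p_value=float(p),
        significant=bool(p <= alpha), trace=trace,
    )


def compare_table(df: pd.DataFrame, group_col: str, variables: list,
                  groups: tuple = ("control", "alcohol")) -> pd.DataFrame:
    rows = []
    for var in variables:
        x = df.loc[df[group_col] == groups[0], var].dropna()
        y = df.loc[df[group_col] == groups[1], var].dropna()
        rows.append(compare(x, y, variable=var, group_names=groups).to_row())
    return pd.DataFrame(rows)
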