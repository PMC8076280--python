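"""Paired baseline-vs-aAC statistical battery.

For every variable the paired differences are first gated through a
normality check: a one-sample Kolmogorov–Smirnov test of the differences
against a normal law with estimated mean and SD.  Because the parameters are
estimated, the plain KS p-value would be anti-conservative, so the
Lilliefors-corrected variant is the default (a flag restores the plain KS).
Normally distributed differences get the paired two-sided t-test; otherwise
the Wilcoxon signed-rank test (two-sided, zero differences dropped, exact
null distribution for n ≤ 25, normal approximation with continuity
correction above).  Degrees of freedom are reported as n − 1 for both
branches, mirroring common reporting practice for paired designs.

Family-wise error over a battery of variables is controlled with the
Holm–Bonferroni step-down procedure; the association between the composite
deterioration scores is measured with Spearman rank correlation, with an
exclusion mechanism for outlier-sensitivity re-runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "TestResult",
    "CorrelationResult",
    "normality_gate",
    "paired_compare",
    "holm_adjust",
    "spearman_corr",
    "run_battery",
]

ALPHA_DEFAULT = 0.05


@dataclass
class TestResult:
    """Result of one paired comparison."""

    variable: str
    test_used: Literal["paired_t", "wilcoxon_signed_rank"]
    statistic: float          # t for the t branch, Z for the Wilcoxon branch
    df: int                   # n - 1
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    degenerate: bool = False  # all-zero differences


@dataclass
class CorrelationResult:
    """Spearman rank correlation between two per-subject score vectors."""

    rho: float
    p_value: float
    n: int
    excluded_points: list = field(default_factory=list)


def normality_gate(differences: Sequence[float], alpha: float = ALPHA_DEFAULT,
                   lilliefors: bool = True) -> str:
    """Classify paired differences as ``'normal'`` or ``'non_normal'``.

    Kolmogorov–Smirnov against a normal with estimated mean/SD; Lilliefors
    correction by default, ``lilliefors=False`` restores the plain KS test.
    Constant differences are non-normal by convention (SD undefined).
    """
    d = np.asarray(differences, float)
    if d.size < 4:
        raise ValueError(f"normality gate needs n >= 4, got n = {d.size}")
    if np.ptp(d) == 0:
        warnings.warn("constant differences: normality undefined, gating to "
                      "non_normal", stacklevel=2)
        return "non_normal"
    if lilliefors:
        _, p = _lilliefors(d, dist="norm", pvalmethod="table")
    else:
        _, p = sps.kstest(d, "norm", args=(d.mean(), d.std(ddof=1)))
    return "normal" if p >= alpha else "non_normal"


def _wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank p and the normal-approximation Z.

    Zeros dropped; exact p for n ≤ 25 when there are no tied magnitudes,
    otherwise normal approximation with continuity correction.
    """
    nz = d[d != 0]
    n = nz.size
    # Z statistic from the approximation (reported even when p is exact).
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        approx = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                              alternative="two-sided", method="approx")
    z = float(approx.zstatistic)
    ties = np.unique(np.abs(nz)).size < n
    if n <= 25 and not ties:
        exact = sps.wilcoxon(nz, zero_method="wilcox",
                             alternative="two-sided", method="exact")
        return float(exact.pvalue), z
    return float(approx.pvalue), z


def paired_compare(baseline: Sequence[float], aac: Sequence[float],
                   gate: str | None = None, variable: str = "",
                   alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Compare paired baseline / after-alcohol vectors for one variable.

    ``gate`` is the output of :func:`normality_gate` on the differences; if
    ``None`` the gate is computed here.  All-zero differences yield a
    degenerate result with p = 1.
    """
    b = np.asarray(baseline, float)
    a = np.asarray(aac, float)
    if b.shape != a.shape:
        raise ValueError("baseline and aAC vectors must be the same length")
    n = b.size
    d = a - b
    df = n - 1
    if np.all(d == 0):
        return TestResult(variable, "wilcoxon_signed_rank", 0.0, df, 1.0,
                          degenerate=True)
    if gate is None:
        gate = normality_gate(d, alpha=alpha)
    if gate == "normal":
        t = sps.ttest_rel(a, b, alternative="two-sided")
        return TestResult(variable, "paired_t", float(t.statistic), df,
                          float(t.pvalue))
    p, z = _wilcoxon(d)
    return TestResult(variable, "wilcoxon_signed_rank", z, df, p)


def holm_adjust(p_values: Sequence[float], alpha: float = ALPHA_DEFAULT
                ) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Bonferroni step-down adjustment.

    Returns ``(p_adjusted, reject)`` in the input order.  Adjusted values
    follow the step-down running maximum
    ``p_adj_(i) = max_{j<=i} min(1, (m−j+1)·p_(j))`` over the ascending
    order; rejections are the tests with ``p_adjusted < alpha`` (strict),
    which form a prefix of the sorted order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepdown = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(stepdown))
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj < alpha


def spearman_corr(x: Sequence[float], y: Sequence[float],
                  exclude: Sequence[int] | None = None) -> CorrelationResult:
    """Spearman rank correlation with optional point exclusion.

    ``exclude`` lists integer positions to drop before computing ρ (used for
    outlier-sensitivity re-runs); at least 4 points must remain.  Average
    ranks are used for ties; the p-value is two-sided.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    excluded = sorted(set(int(i) for i in exclude)) if exclude else []
    keep = np.ones(x.size, bool)
    keep[excluded] = False
    xs, ys = x[keep], y[keep]
    if xs.size < 4:
        raise ValueError("Spearman correlation needs >= 4 points after exclusions")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return CorrelationResult(math.nan, math.nan, int(xs.size), excluded)
    res = sps.spearmanr(xs, ys)
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             int(xs.size), excluded)


def run_battery(baseline: pd.DataFrame, aac: pd.DataFrame,
                alpha: float = ALPHA_DEFAULT,
                families: dict[str, list[str]] | None = None,
                lilliefors: bool = True) -> pd.DataFrame:
    """Paired battery over aligned wide tables (subjects × variables).

    ``families`` maps a family label to its list of variable names for the
    Holm adjustment (default: all variables in one family).  Returns one row
    per variable: group means/SDs, mean impairment, test branch, statistic,
    df, raw and Holm-adjusted p, and significance at ``alpha``.
    """
    if list(baseline.columns) != list(aac.columns):
        raise ValueError("baseline and aAC tables must share the same variables")
    if not baseline.index.equals(aac.index):
        raise ValueError("baseline and aAC tables must be paired by subject")
    results: dict[str, TestResult] = {}
    rows = []
    for var in baseline.columns:
        b = baseline[var].to_numpy(float)
        a = aac[var].to_numpy(float)
        d = a - b
        if np.all(d == 0):
            res = paired_compare(b, a, variable=var)
        else:
            gate = normality_gate(d, alpha=alpha, lilliefors=lilliefors)
            res = paired_compare(b, a, gate=gate, variable=var, alpha=alpha)
        results[var] = res
        rows.append({
            "variable": var,
            "baseline_mean": b.mean(), "baseline_sd": b.std(ddof=1),
            "aac_mean": a.mean(), "aac_sd": a.std(ddof=1),
            "impairment_mean": d.mean(), "impairment_sd": d.std(ddof=1),
            "test_used": res.test_used, "statistic": res.statistic,
            "df": res.df, "p_raw": res.p_raw,
        })
    table = pd.DataFrame(rows).set_index("variable")
    if families is None:
        families = {"all": list(table.index)}
    table["family"] = ""
    table["p_holm"] = np.nan
    table["significant"] = False
    for fam, members in families.items():
        members = [m for m in members if m in table.index]
        if not members:
            continue
        p_adj, reject = holm_adjust(table.loc[members, "p_raw"].to_numpy(), alpha)
        table.loc[members, "family"] = fam
        table.loc[members, "p_holm"] = p_adj
        table.loc[members, "significant"] = reject
        for m, pa, rj in zip(members, p_adj, reject):
            results[m].p_adjusted = float(pa)
            results[m].significant = bool(rj)
    return table
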