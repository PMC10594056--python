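"""Group-comparison statistics: normality, robust outlier removal, and the
three one-way ANOVA variants with their post-hoc tests.

The analysis chain mirrors the study design for per-slice summaries: check
outliers (ROUT, Q = 1%), check normality (Kolmogorov–Smirnov with the
Lilliefors correction, since the null parameters are estimated from the
sample), then either ordinary one-way ANOVA + Tukey HSD (equal variances) or
the Welch and Brown–Forsythe equality-of-means tests + Dunnett T3 (unequal
variances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import DegenerateInputError, TooFewPointsError


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Normality


def ks_normality(sample: np.ndarray, lilliefors_correction: bool = True) -> TestResult:
    """KS test against a normal with estimated mean/SD.

    Lilliefors-corrected by default (the behavior of interactive stats
    packages when parameters are estimated); the plain fixed-parameter KS is
    available with ``lilliefors_correction=False``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise TooFewPointsError("normality test requires n >= 5")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample: normality test undefined")
    if lilliefors_correction:
        stat, p = lilliefors(x, dist="norm")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return TestResult("ks_normality", float(stat), float(p), meta={"n": x.size})


# ---------------------------------------------------------------------------
# ROUT outliers (constant model)


def rout_outliers(sample: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier flags for a univariate sample (constant/mean-only model).

    Robust center = median; scale = RSDR, the 68.27th percentile of the
    absolute residuals with the small-n correction n/(n−1); each point gets a
    t-like statistic |residual|/RSDR with df = n−1, and points are scanned
    from most to least extreme against the FDR thresholds
    α_i = q·(n−i+1)/n, stopping at the first non-significant point.

    Returns ``(flags, cleaned_sample)``.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 5:
        raise TooFewPointsError("ROUT requires n >= 5")
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    flags = np.zeros(n, dtype=bool)
    if rsdr <= 0:
        return flags, x
    t = np.abs(resid) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(p)  # most extreme first
    for rank, idx in enumerate(order, start=1):
        alpha_i = q * (n - rank + 1) / n
        if p[idx] < alpha_i:
            flags[idx] = True
        else:
            break
    return flags, x[~flags]


# ---------------------------------------------------------------------------
# ANOVA suite


@dataclass(frozen=True)
class AnovaSuiteResult:
    ordinary: TestResult
    welch: TestResult
    brown_forsythe: TestResult
    tukey: pd.DataFrame
    dunnett_t3: pd.DataFrame
    groups: tuple[str, ...]

    def summary(self) -> str:
        o, w, b = self.ordinary, self.welch, self.brown_forsythe
        lines = [
            f"Ordinary ANOVA: F({o.df[0]:.0f}, {o.df[1]:.0f}) = {o.statistic:.4f}, p = {o.p_value:.4g}",
            f"Welch ANOVA:    W({w.df[0]:.0f}, {w.df[1]:.2f}) = {w.statistic:.4f}, p = {w.p_value:.4g}",
            f"Brown-Forsythe: F*({b.df[0]:.0f}, {b.df[1]:.2f}) = {b.statistic:.4f}, p = {b.p_value:.4g}",
        ]
        return "\n".join(lines)


def _group_arrays(table: pd.DataFrame, value: str, group: str):
    names = list(pd.unique(table[group]))
    arrays = [table.loc[table[group] == g, value].to_numpy(dtype=float) for g in names]
    if len(arrays) < 2:
        raise TooFewPointsError("ANOVA requires >= 2 groups")
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise TooFewPointsError(f"group {g!r} has n < 2")
    return names, arrays


def welch_anova(arrays: list[np.ndarray]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (fractional error df)."""
    k = len(arrays)
    ni = np.array([a.size for a in arrays], dtype=float)
    mi = np.array([a.mean() for a in arrays])
    vi = np.array([a.var(ddof=1) for a in arrays])
    wi = ni / vi
    mw = (wi * mi).sum() / wi.sum()
    num = ((wi * (mi - mw) ** 2).sum()) / (k - 1)
    lam = ((1 - wi / wi.sum()) ** 2 / (ni - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    w = num / den
    df2 = (k**2 - 1) / (3.0 * lam)
    p = stats.f.sf(w, k - 1, df2)
    return TestResult("welch_anova", float(w), float(p), df=(float(k - 1), float(df2)))


def brown_forsythe_means(arrays: list[np.ndarray]) -> TestResult:
    """Brown–Forsythe F* test for equality of means under unequal variances."""
    k = len(arrays)
    ni = np.array([a.size for a in arrays], dtype=float)
    big_n = ni.sum()
    mi = np.array([a.mean() for a in arrays])
    vi = np.array([a.var(ddof=1) for a in arrays])
    grand = np.concatenate(arrays).mean()
    num = (ni * (mi - grand) ** 2).sum()
    ci = (1.0 - ni / big_n) * vi
    den = ci.sum()
    fstar = num / den
    gi = ci / den
    df2 = 1.0 / ((gi**2 / (ni - 1)).sum())
    p = stats.f.sf(fstar, k - 1, df2)
    return TestResult(
        "brown_forsythe_means", float(fstar), float(p), df=(float(k - 1), float(df2))
    )


def _smm_sf(x: float, m: int, df: float) -> float:
    """Survival function of the studentized maximum modulus with m means
    and df denominator degrees of freedom."""
    if x <= 0:
        return 1.0

    def integrand(u):
        return (2.0 * stats.norm.cdf(x * u) - 1.0) ** m * stats.chi.pdf(
            u * np.sqrt(df), df
        ) * np.sqrt(df)

    cdf, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def dunnett_t3(names: list[str], arrays: list[np.ndarray]) -> pd.DataFrame:
    """Dunnett T3 pairwise comparisons (unequal variances, small samples).

    Each pair uses the Welch t statistic and Welch df; the adjusted p comes
    from the studentized maximum modulus distribution with m = number of
    comparisons.
    """
    k = len(arrays)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
            t = abs(a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / (
                (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
                + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
            )
            p = _smm_sf(t, m, df)
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": a.mean() - b.mean(),
                    "t": t,
                    "df": df,
                    "p_adj": p,
                }
            )
    return pd.DataFrame(rows)


def tukey_hsd(names: list[str], arrays: list[np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": arrays[i].mean() - arrays[j].mean(),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def anova_suite(
    table: pd.DataFrame, value: str = "value", group: str = "group"
) -> AnovaSuiteResult:
    """Ordinary one-way ANOVA + Tukey HSD, Welch ANOVA, Brown–Forsythe F*,
    and Dunnett T3 pairwise comparisons, from a long-format group table."""
    names, arrays = _group_arrays(table, value, group)
    f, p = stats.f_oneway(*arrays)
    big_n = sum(a.size for a in arrays)
    ordinary = TestResult(
        "one_way_anova", float(f), float(p), df=(float(len(arrays) - 1), float(big_n - len(arrays)))
    )
    return AnovaSuiteResult(
        ordinary=ordinary,
        welch=welch_anova(arrays),
        brown_forsythe=brown_forsythe_means(arrays),
        tukey=tukey_hsd(names, arrays),
        dunnett_t3=dunnett_t3(names, arrays),
        groups=tuple(str(n) for n in names),
    )
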