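"""A-priori power / sample-size computation for a two-group comparison.

Two calculators are provided, matching the dialogs of the common power
software:

* ``power_t_apriori`` — unpaired two-sample t-test: noncentrality
  δ = d·√(n²/(2n)) and df = 2n − 2 for equal per-group n.
* ``power_wmw_apriori`` — Wilcoxon–Mann–Whitney under normal parent
  distributions via the asymptotic-relative-efficiency (ARE) approximation:
  the t-test noncentrality is scaled by √(3/π) and the df become
  N·(3/π) − 2 (fractional).

Both search the smallest equal per-group n whose achieved power (from the
noncentral t distribution at the two-sided critical t) reaches the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ARE_NORMAL = 3.0 / np.pi  # Wilcoxon vs t efficiency under normal parents

_MAX_N = 10**6


@dataclass(frozen=True)
class PowerResult:
    n_per_group: int
    total_n: int
    noncentrality: float
    df: float
    critical_t: float
    achieved_power: float
    method: str

    def summary(self) -> str:
        return (
            f"{self.method} a-priori power analysis\n"
            f"  Noncentrality parameter δ: {self.noncentrality:.7f}\n"
            f"  Critical t:                {self.critical_t:.7f}\n"
            f"  Df:                        {self.df:.7f}\n"
            f"  Sample size group 1:       {self.n_per_group}\n"
            f"  Sample size group 2:       {self.n_per_group}\n"
            f"  Total sample size:         {self.total_n}\n"
            f"  Actual power:              {self.achieved_power:.7f}"
        )


def _achieved(delta: float, df: float, alpha: float, tails: int) -> tuple[float, float]:
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, delta)
    return float(tcrit), float(power)


def _moments(n: int, d: float, wmw: bool) -> tuple[float, float]:
    delta = d * np.sqrt(n * n / (2.0 * n))  # = d·√(n/2) for equal groups
    df = 2.0 * n - 2.0
    if wmw:
        delta *= np.sqrt(ARE_NORMAL)
        df = 2.0 * n * ARE_NORMAL - 2.0
    return float(delta), float(df)


def _apriori(
    d: float, alpha: float, tails: int, target_power: float, wmw: bool
) -> PowerResult:
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < target_power < 1:
        raise ValueError("target power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    method = "Wilcoxon-Mann-Whitney (normal parents, ARE)" if wmw else "unpaired t-test"
    for n in range(2, _MAX_N + 1):
        delta, df = _moments(n, d, wmw)
        tcrit, power = _achieved(delta, df, alpha, tails)
        if power >= target_power:
            return PowerResult(
                n_per_group=n,
                total_n=2 * n,
                noncentrality=delta,
                df=df,
                critical_t=tcrit,
                achieved_power=power,
                method=method,
            )
    raise ValueError(f"target power unreachable within n <= {_MAX_N}")


def power_wmw_apriori(
    d: float, alpha: float = 0.05, tails: int = 2, target_power: float = 0.95
) -> PowerResult:
    """Smallest equal-group WMW design (normal parents) reaching the target power."""
    return _apriori(d, alpha, tails, target_power, wmw=True)


def power_t_apriori(
    d: float, alpha: float = 0.05, tails: int = 2, target_power: float = 0.95
) -> PowerResult:
    """Smallest equal-group unpaired-t design reaching the target power."""
    return _apriori(d, alpha, tails, target_power, wmw=False)


def achieved_power(
    n_per_group: int, d: float, alpha: float = 0.05, tails: int = 2, wmw: bool = True
) -> PowerResult:
    """Power of a fixed equal-group design (post-style evaluation of the same model)."""
    delta, df = _moments(n_per_group, d, wmw)
    tcrit, power = _achieved(delta, df, alpha, tails)
    return PowerResult(
        n_per_group=n_per_group,
        total_n=2 * n_per_group,
        noncentrality=delta,
        df=df,
        critical_t=tcrit,
        achieved_power=power,
        method="Wilcoxon-Mann-Whitney (normal parents, ARE)" if wmw else "unpaired t-test",
    )
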