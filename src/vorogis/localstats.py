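"""Local cluster statistics: Anselin Local Moran's I (LISA) and Getis–Ord Gi*.

Local Moran classifies each significant feature by the quadrant rule —
own value above/below the mean × spatial lag above/below the mean of lags —
into HH/LL clusters and HL/LH outliers at 95% confidence; Gi* bins features
into hot/cold spots at 90/95/99% confidence by the z thresholds
1.645/1.960/2.576.  The "optimized" variants are the same statistics with
Benjamini–Hochberg FDR correction of the per-feature p before
classification; automatic aggregation/scale selection is out of scope
because the hexagon size is a controlled, cross-group-constant pipeline
parameter.

Local Moran uses the classic Anselin scaling m2 = Σz²/n, which makes the
LISA decomposition exact: Σ_i I_i = S0 · I_global under identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError, TooFewPointsError, UndefinedStatisticError
from .weights import SpatialWeights

LISA_CLASSES = ("HH", "LL", "HL", "LH", "NS")
GI_CLASSES = ("hot99", "hot95", "hot90", "cold90", "cold95", "cold99", "NS")
LAG_TIE_TOL = 1e-12


@dataclass(frozen=True)
class LocalStatResult:
    name: str
    statistic: np.ndarray
    z_score: np.ndarray
    p_value: np.ndarray
    fdr_adjusted_p: np.ndarray | None
    classes: np.ndarray  # per-feature label
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.statistic.size


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def local_morans(
    values: np.ndarray,
    weights: SpatialWeights,
    alpha: float = 0.05,
    fdr: bool = False,
    n_perm: int | None = 999,
    seed: int | None = None,
    total_cells: int | None = None,
) -> LocalStatResult:
    """Anselin Local Moran's I with HH/LL/HL/LH classification.

    Inference is by conditional permutation (default 999, seeded): feature
    i's value is held fixed while the remaining values are permuted among
    its neighbors.  ``n_perm=None`` switches to the analytic (moment-based)
    normal approximation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise TooFewPointsError("Local Moran requires >= 5 features")
    z = x - x.mean()
    m2 = (z**2).sum() / n
    if m2 <= 0:
        raise UndefinedStatisticError("Local Moran undefined for a zero-variance field")
    w = weights.w.copy()
    np.fill_diagonal(w, 0.0)
    lag = w @ z
    stat = z / m2 * lag
    wi = w.sum(axis=1)
    wi2 = (w**2).sum(axis=1)
    if n_perm:
        rng = np.random.default_rng(seed)
        zsc = np.empty(n)
        pvals = np.empty(n)
        others = np.array([np.delete(np.arange(n), i) for i in range(n)])
        for i in range(n):
            nbr = np.nonzero(w[i])[0]
            if nbr.size == 0:
                zsc[i], pvals[i] = 0.0, 1.0
                continue
            # draw n_perm samples of the permuted lag: neighbors' weights applied
            # to values sampled without replacement from all-but-i
            pool = z[others[i]]
            picks = rng.random((n_perm, pool.size)).argsort(axis=1)[:, : nbr.size]
            sims = (pool[picks] * w[i, nbr]).sum(axis=1) * z[i] / m2
            mu, sd = sims.mean(), sims.std(ddof=1)
            zsc[i] = (stat[i] - mu) / sd if sd > 0 else 0.0
            pvals[i] = (np.count_nonzero(np.abs(sims - mu) >= abs(stat[i] - mu)) + 1) / (
                n_perm + 1
            )
    else:
        # exact conditional-randomization moments: value i held fixed, the
        # remaining values assigned without replacement to the other features
        s1 = -z  # sum of the pool (all z sum to 0)
        s2 = (z**2).sum() - z**2
        sigma2 = s2 / (n - 1) - (s1 / (n - 1)) ** 2
        var_lag = sigma2 * (wi2 - (wi**2 - wi2) / (n - 2))
        e_i = (z / m2) * wi * s1 / (n - 1)
        var_i = np.maximum((z / m2) ** 2 * var_lag, 1e-300)
        zsc = (stat - e_i) / np.sqrt(var_i)
        pvals = 2.0 * stats.norm.sf(np.abs(zsc))
    adj = _bh_adjust(pvals) if fdr else None
    eff_p = adj if fdr else pvals
    lagbar = lag.mean()
    classes = np.full(n, "NS", dtype=object)
    sig = eff_p <= alpha
    hi_val = z > 0
    dlag = lag - lagbar
    hi_lag = dlag > LAG_TIE_TOL
    lo_lag = dlag < -LAG_TIE_TOL
    classes[sig & hi_val & hi_lag] = "HH"
    classes[sig & ~hi_val & lo_lag] = "LL"
    classes[sig & hi_val & lo_lag] = "HL"
    classes[sig & ~hi_val & hi_lag] = "LH"
    return LocalStatResult(
        "local_morans_i",
        statistic=stat,
        z_score=zsc,
        p_value=pvals,
        fdr_adjusted_p=adj,
        classes=np.asarray(classes, dtype=object),
        meta={
            "alpha": alpha,
            "fdr": fdr,
            "n_perm": n_perm,
            "total_cells": total_cells,
            "n_features": n,
        },
    )


def gi_star(
    values: np.ndarray,
    weights_with_self: SpatialWeights,
    fdr: bool = False,
    total_cells: int | None = None,
) -> LocalStatResult:
    """Getis–Ord Gi* hot/cold-spot z-scores with confidence-bin classes.

    The neighborhood includes the feature itself (the weights must carry
    ``include_self``).  |z| ≥ 1.645/1.960/2.576 map to 90/95/99% classes,
    the sign distinguishing hot from cold; with ``fdr`` the bin test uses
    BH-adjusted p-values instead.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise TooFewPointsError("Gi* requires >= 5 features")
    if not weights_with_self.include_self:
        raise ContractError("Gi* requires include_self weights")
    if np.allclose(x, x[0]):
        raise UndefinedStatisticError("Gi* undefined for a zero-variance field")
    w = weights_with_self.w
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    wi = w.sum(axis=1)
    wi2 = (w**2).sum(axis=1)
    num = w @ x - xbar * wi
    den = s * np.sqrt((n * wi2 - wi**2) / (n - 1))
    zsc = num / den
    pvals = 2.0 * stats.norm.sf(np.abs(zsc))
    adj = _bh_adjust(pvals) if fdr else None
    eff_p = adj if fdr else pvals
    classes = np.full(n, "NS", dtype=object)
    # two-sided p thresholds equivalent to |z| >= 1.645 / 1.960 / 2.576
    for alpha, tag in ((0.10, "90"), (0.05, "95"), (0.01, "99")):
        m = eff_p <= alpha
        classes[m & (zsc > 0)] = f"hot{tag}"
        classes[m & (zsc < 0)] = f"cold{tag}"
    return LocalStatResult(
        "gi_star",
        statistic=zsc,
        z_score=zsc,
        p_value=pvals,
        fdr_adjusted_p=adj,
        classes=np.asarray(classes, dtype=object),
        meta={"fdr": fdr, "total_cells": total_cells, "n_features": n},
    )


def class_area_percentages(result: LocalStatResult) -> dict[str, float]:
    """Percent of the full tessellation's hexagons carrying each class label.

    The denominator is the total hexagon count of the tessellation (not just
    the occupied cells), so the percentages are section-area fractions.
    """
    total = result.meta.get("total_cells")
    if not total:
        raise ContractError("result lacks total-tessellation cell count metadata")
    labels = LISA_CLASSES if result.name == "local_morans_i" else GI_CLASSES
    out = {}
    for lab in labels:
        if lab == "NS":
            continue
        out[lab] = 100.0 * np.count_nonzero(result.classes == lab) / total
    return out
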