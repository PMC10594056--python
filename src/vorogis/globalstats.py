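"""Global pattern statistics: nearest-neighbor index, General G, Moran's I,
Ripley's K with a permutation envelope.

Inference is analytic (moment-based z against a normal reference) by
default; Moran's I additionally offers conditional-permutation inference.
The nearest-neighbor index follows the Clark–Evans convention: R < 1
clustering, R ≈ 1 randomness, R > 1 dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import RangeError, TooFewPointsError, UndefinedStatisticError
from .points import PointPattern, Rect, minimum_enclosing_rectangle
from .weights import SpatialWeights


@dataclass(frozen=True)
class GlobalStatResult:
    """A global statistic with its randomization moments and normal inference."""

    name: str
    statistic: float
    expected: float
    variance: float
    z_score: float
    p_value: float
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.name}: stat={self.statistic:.6g} expected={self.expected:.6g} "
            f"z={self.z_score:.4f} p={self.p_value:.4g}"
        )


def _normal_inference(stat: float, expected: float, variance: float) -> tuple[float, float]:
    if variance <= 0:
        return (np.nan, np.nan)
    z = (stat - expected) / np.sqrt(variance)
    p = 2.0 * stats.norm.sf(abs(z))
    return (float(z), float(p))


# ---------------------------------------------------------------------------
# Average Nearest Neighbor


def ann(pattern: PointPattern, area: float | None = None) -> GlobalStatResult:
    """Clark–Evans average-nearest-neighbor index.

    R = OMD/EMD with EMD = 0.5/√(n/A); SE = 0.26136/√(n²/A);
    z = (OMD − EMD)/SE.  The study area defaults to the minimum enclosing
    rectangle of the points, so peripheral isolated cells inflate it.
    """
    if pattern.n < 2:
        raise TooFewPointsError("ANN requires >= 2 points")
    if area is None:
        rect = minimum_enclosing_rectangle(pattern)
        area = rect.area
    if area <= 0:
        raise RangeError("study area must be > 0 (degenerate enclosing rectangle?)")
    tree = cKDTree(pattern.xy)
    d, _ = tree.query(pattern.xy, k=2)
    omd = float(d[:, 1].mean())
    n = pattern.n
    emd = 0.5 / np.sqrt(n / area)
    se = 0.26136 / np.sqrt(n**2 / area)
    r = omd / emd
    z, p = _normal_inference(omd, emd, se**2)
    return GlobalStatResult(
        "average_nearest_neighbor",
        statistic=float(r),
        expected=1.0,
        variance=float((se / emd) ** 2),
        z_score=z,
        p_value=p,
        meta={"omd": omd, "emd": float(emd), "area": float(area), "n": n},
    )


# ---------------------------------------------------------------------------
# General G (Getis–Ord high/low clustering)


def general_g(values: np.ndarray, weights: SpatialWeights) -> GlobalStatResult:
    """Getis–Ord General G of non-negative values under spatial randomization."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise TooFewPointsError("General G requires >= 3 features")
    if np.any(x < 0):
        raise ValueError("General G requires non-negative values")
    if np.allclose(x, x[0]) or np.all(x == 0):
        raise UndefinedStatisticError("General G undefined for a constant or all-zero field")
    w = weights.w.copy()
    np.fill_diagonal(w, 0.0)
    s0 = w.sum()
    cross = np.outer(x, x)
    np.fill_diagonal(cross, 0.0)
    denom = cross.sum()
    g = float((w * cross).sum() / denom)
    eg = s0 / (n * (n - 1))
    # randomization variance (Getis & Ord 1992)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    m1, m2 = x.sum(), (x**2).sum()
    m3, m4 = (x**3).sum(), (x**4).sum()
    b0 = (n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2
    b1 = -((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    b2 = -(2 * n * s1 - (n + 3) * s2 + 6 * s0**2)
    b3 = 4 * (n - 1) * s1 - 2 * (n + 1) * s2 + 8 * s0**2
    b4 = s1 - s2 + s0**2
    if n > 3:
        eg2_num = b0 * m2**2 + b1 * m4 + b2 * m1**2 * m2 + b3 * m1 * m3 + b4 * m1**4
        eg2_den = (m1**2 - m2) ** 2 * n * (n - 1) * (n - 2) * (n - 3)
        var = eg2_num / eg2_den - eg**2
    else:
        var = np.nan  # randomization moments need n >= 4
    z, p = _normal_inference(g, eg, var)
    return GlobalStatResult(
        "general_g",
        statistic=g,
        expected=float(eg),
        variance=float(var),
        z_score=z,
        p_value=p,
        meta={
            "conceptualization": weights.conceptualization,
            "standardization": weights.standardization,
        },
    )


# ---------------------------------------------------------------------------
# Global Moran's I


def _moran_randomization_variance(z2: np.ndarray, w: np.ndarray, n: int) -> float:
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z2**2).sum() / (z2.sum()) ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    return num / den - (1.0 / (n - 1)) ** 2


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    inference: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
) -> GlobalStatResult:
    """Global Moran's I with randomization-assumption inference.

    ``inference="permutation"`` replaces the analytic p with a conditional
    permutation pseudo p (statistic and moments still reported).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise TooFewPointsError("Moran's I requires >= 3 features")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom <= 0:
        raise UndefinedStatisticError("Moran's I undefined for a zero-variance field")
    w = weights.w.copy()
    np.fill_diagonal(w, 0.0)
    s0 = w.sum()
    stat = float(n / s0 * (z @ w @ z) / denom)
    expected = -1.0 / (n - 1)
    var = _moran_randomization_variance(z**2, w, n)
    zsc, p = _normal_inference(stat, expected, var)
    meta = {
        "conceptualization": weights.conceptualization,
        "standardization": weights.standardization,
        "inference": inference,
    }
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for k in range(n_perm):
            zp = rng.permutation(z)
            sims[k] = n / s0 * (zp @ w @ zp) / denom
        p = float((np.count_nonzero(np.abs(sims - expected) >= abs(stat - expected)) + 1) / (n_perm + 1))
        meta["n_perm"] = n_perm
    return GlobalStatResult(
        "morans_i",
        statistic=stat,
        expected=float(expected),
        variance=float(var),
        z_score=zsc,
        p_value=p,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Ripley's K


@dataclass(frozen=True)
class RipleyResult:
    distances: np.ndarray
    k: np.ndarray
    l: np.ndarray
    envelope_lo: np.ndarray | None  # pointwise envelope of L under CSR
    envelope_hi: np.ndarray | None
    meta: dict = field(default_factory=dict)


def _k_function(xy: np.ndarray, distances: np.ndarray, area: float) -> np.ndarray:
    n = xy.shape[0]
    d = pdist(xy)
    counts = np.searchsorted(np.sort(d), distances, side="right") * 2  # ordered pairs
    return area * counts / (n * (n - 1))


def ripleys_k(
    pattern: PointPattern,
    distances: np.ndarray | None = None,
    area: float | None = None,
    n_perm: int = 99,
    seed: int | None = None,
) -> RipleyResult:
    """Multi-distance spatial cluster analysis (Ripley's K), no edge correction.

    K(d) = A·ΣΣ 1[d_ij ≤ d]/(n(n−1)); L(d) = √(K/π).  The envelope is the
    pointwise min/max of L over ``n_perm`` CSR simulations with the same n
    in the minimum enclosing rectangle.
    """
    if pattern.n < 10:
        raise TooFewPointsError("Ripley's K requires >= 10 points")
    rect = minimum_enclosing_rectangle(pattern)
    if area is None:
        area = rect.area
    max_d = min(pattern.frame.width, pattern.frame.height) / 2.0
    if distances is None:
        distances = np.linspace(max_d / 10.0, max_d, 10)
    distances = np.asarray(distances, dtype=float)
    if distances.max() > max_d * (1 + 1e-9):
        raise RangeError("max distance exceeds half the shorter frame side")
    k = _k_function(pattern.xy, distances, area)
    l = np.sqrt(k / np.pi)
    lo = hi = None
    if n_perm:
        rng = np.random.default_rng(seed)
        sims = np.empty((n_perm, distances.size))
        for b in range(n_perm):
            xy = np.column_stack(
                [
                    rng.uniform(rect.x0, rect.x0 + rect.width, pattern.n),
                    rng.uniform(rect.y0, rect.y0 + rect.height, pattern.n),
                ]
            )
            sims[b] = np.sqrt(_k_function(xy, distances, area) / np.pi)
        lo, hi = sims.min(axis=0), sims.max(axis=0)
    return RipleyResult(
        distances=distances,
        k=k,
        l=l,
        envelope_lo=lo,
        envelope_hi=hi,
        meta={"area": float(area), "n_perm": n_perm, "edge_correction": "none", "n": pattern.n},
    )
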