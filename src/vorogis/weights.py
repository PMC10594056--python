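"""Spatial weights matrices for the global and local statistics.

Two conceptualizations are implemented, matching the tools' options used in
the pipeline: inverse Euclidean distance with a cutoff threshold, and a
fixed distance band.  The default threshold is the smallest distance that
guarantees every feature at least one neighbor (the maximum nearest-neighbor
distance).  Weights may be row-standardized.  ``include_self`` adds w_ii = 1
and is used only by the Gi* statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

COINCIDENT_EPS = 1e-6  # μm floor for inverse-distance weights between coincident features


@dataclass(frozen=True)
class SpatialWeights:
    w: np.ndarray  # (n, n), zero diagonal unless include_self
    conceptualization: str
    standardization: str  # "none" | "row"
    threshold: float
    include_self: bool = False

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def ensure_neighbor_threshold(coords: np.ndarray) -> float:
    """Smallest distance at which every feature has >= 1 neighbor
    (the maximum nearest-neighbor distance)."""
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


def build_weights(
    coords: np.ndarray,
    conceptualization: str = "inverse_distance",
    threshold: float | None = None,
    standardization: str = "none",
    include_self: bool = False,
) -> SpatialWeights:
    """Pairwise weights from feature coordinates.

    inverse_distance: w_ij = 1/d_ij for d_ij <= threshold, else 0.
    fixed_band:       w_ij = 1 for d_ij <= threshold, else 0.
    Coincident features under inverse distance get the capped weight
    1/COINCIDENT_EPS (with a warning).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("weights require >= 2 features")
    if conceptualization not in ("inverse_distance", "fixed_band"):
        raise ValueError(f"unknown conceptualization {conceptualization!r}")
    if standardization not in ("none", "row"):
        raise ValueError(f"unknown standardization {standardization!r}")
    d = squareform(pdist(coords))
    if threshold is None:
        threshold = ensure_neighbor_threshold(coords)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    band = d <= threshold * (1.0 + 1e-12)
    np.fill_diagonal(band, False)
    if conceptualization == "inverse_distance":
        coincident = band & (d < COINCIDENT_EPS)
        if coincident.any():
            import warnings

            warnings.warn("coincident features: inverse-distance weight capped at 1/eps")
        with np.errstate(divide="ignore"):
            w = np.where(band, 1.0 / np.maximum(d, COINCIDENT_EPS), 0.0)
    else:
        w = band.astype(float)
    if include_self:
        np.fill_diagonal(w, 1.0)
    if standardization == "row":
        rowsum = w.sum(axis=1, keepdims=True)
        nz = rowsum[:, 0] > 0
        w = w.copy()
        w[nz] = w[nz] / rowsum[nz]
    return SpatialWeights(
        w=w,
        conceptualization=conceptualization,
        standardization=standardization,
        threshold=float(threshold),
        include_self=include_self,
    )
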