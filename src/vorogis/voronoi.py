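"""Voronoi cellular sociology.

The population topography of a cell layer is quantified from the Voronoi
tessellation of the cell centroids (Marcelpoil–Usson "cellular sociology"):
marginal polygons — those whose site lies on the convex hull (open cells) or
with a vertex strictly outside the hull — are excluded, and the retained
polygons yield the mean roundness factor RFav, the area disorder
AD = 1 − (1 + σ_A/A_av)⁻¹ and the roundness-factor homogeneity
RFH = (1 + σ_RF/RFav)⁻¹.  A perfectly ordered population has AD = 0 and
RFH = 1; both are pure numbers in (0, 1] (AD in [0, 1)).

Open (unbounded) cells carry no area or perimeter: the tessellation is not
clipped to the frame because the exclusion rules remove those cells anyway.
Polygon metrics are exact (shoelace), not pixel-raster approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Voronoi, cKDTree
from shapely.geometry import Point, Polygon

from .errors import DegenerateInputError, DuplicateSiteError, TooFewPointsError, ContractError
from .points import PointPattern

DUPLICATE_TOL = 1e-6  # μm; sites closer than this are rejected as duplicates


@dataclass(frozen=True)
class VoronoiCell:
    """One site's Voronoi polygon and its shape metrics."""

    site_index: int
    vertices: np.ndarray | None  # closed ring (first != last; closure implicit); None if open
    area: float | None
    perimeter: float | None
    circularity: float | None  # RF = 4πA/L²
    open: bool
    marginal: bool = False


@dataclass(frozen=True)
class SociologyIndices:
    """Population-topography summary of the retained Voronoi cells."""

    n_retained: int
    mean_area: float
    sd_area: float
    mean_perimeter: float
    rf_av: float
    sd_rf: float
    area_disorder: float
    rf_homogeneity: float


def _ring_metrics(vertices: np.ndarray) -> tuple[float, float, float]:
    x, y = vertices[:, 0], vertices[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * ys - xs * y))
    perim = float(np.sum(np.hypot(xs - x, ys - y)))
    rf = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
    return float(area), perim, float(rf)


def cell_metrics(cell: VoronoiCell) -> tuple[float, float, float]:
    """(area, perimeter, RF) of a bounded cell; exact polygon geometry."""
    if cell.open or cell.vertices is None:
        raise ContractError("metrics are undefined for open (unbounded) cells")
    if cell.vertices.shape[0] < 3:
        raise ContractError("bounded cell must have >= 3 vertices")
    return _ring_metrics(cell.vertices)


def voronoi_cells(pattern: PointPattern) -> list[VoronoiCell]:
    """Voronoi polygon of every site; a cell is open iff its region is unbounded."""
    xy = pattern.xy
    n = xy.shape[0]
    if n < 3:
        raise TooFewPointsError(f"Voronoi tessellation requires >= 3 sites, got {n}")
    tree = cKDTree(xy)
    close = tree.query_pairs(DUPLICATE_TOL)
    if close:
        raise DuplicateSiteError(sorted(close))
    span = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-9 * max(1.0, np.abs(span).max())) < 2:
        raise DegenerateInputError("all sites are collinear; tessellation degenerate")
    vor = Voronoi(xy)
    cells: list[VoronoiCell] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            cells.append(VoronoiCell(i, None, None, None, None, open=True, marginal=True))
            continue
        verts = vor.vertices[region]
        area, perim, rf = _ring_metrics(verts)
        cells.append(VoronoiCell(i, verts, area, perim, rf, open=False))
    return cells


def convex_hull(pattern: PointPattern) -> np.ndarray:
    """Convex hull vertex ring (counter-clockwise in the coordinate frame)."""
    if pattern.n < 3:
        raise TooFewPointsError("convex hull requires >= 3 points")
    try:
        hull = ConvexHull(pattern.xy)
    except Exception as exc:  # qhull raises on collinear input
        raise DegenerateInputError(f"degenerate input for convex hull: {exc}") from exc
    return pattern.xy[hull.vertices]


def exclude_marginal(
    cells: list[VoronoiCell], hull: np.ndarray, eps: float | None = None
) -> list[VoronoiCell]:
    """Retain only non-marginal cells.

    A cell is marginal iff it is open (its site is a hull vertex) or any of
    its vertices lies strictly outside the hull by more than ``eps``
    (default 1e-9 × hull diameter).  A vertex exactly on the hull counts as
    inside.  Zero retained cells is a legal outcome.
    """
    hull_poly = Polygon(hull)
    if eps is None:
        span = hull.max(axis=0) - hull.min(axis=0)
        eps = 1e-9 * float(np.hypot(*span))
    retained = []
    for cell in cells:
        if cell.open:
            continue
        outside = any(
            hull_poly.distance(Point(vx, vy)) > eps for vx, vy in cell.vertices
        )
        if not outside:
            retained.append(cell)
    return retained


def population_indices(retained: list[VoronoiCell], ddof: int = 1) -> SociologyIndices:
    """RFav, AD and RFH of the retained polygon population.

    ``ddof=1`` (sample SD, the spreadsheet STDEV convention) by default;
    ``ddof=0`` gives the population SD.
    """
    if len(retained) < 2:
        raise TooFewPointsError("population indices require >= 2 retained cells")
    areas = np.array([c.area for c in retained])
    perims = np.array([c.perimeter for c in retained])
    rfs = np.array([c.circularity for c in retained])
    a_av = float(areas.mean())
    sd_a = float(areas.std(ddof=ddof))
    rf_av = float(rfs.mean())
    sd_rf = float(rfs.std(ddof=ddof))
    ad = 1.0 - 1.0 / (1.0 + sd_a / a_av)
    rfh = 1.0 / (1.0 + sd_rf / rf_av)
    return SociologyIndices(
        n_retained=len(retained),
        mean_area=a_av,
        sd_area=sd_a,
        mean_perimeter=float(perims.mean()),
        rf_av=rf_av,
        sd_rf=sd_rf,
        area_disorder=float(ad),
        rf_homogeneity=float(rfh),
    )


def sociology(pattern: PointPattern, ddof: int = 1) -> tuple[SociologyIndices, list[VoronoiCell]]:
    """Full Voronoi arm: tessellate, exclude marginal polygons, summarize."""
    cells = voronoi_cells(pattern)
    hull = convex_hull(pattern)
    retained = exclude_marginal(cells, hull)
    return population_indices(retained, ddof=ddof), retained
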