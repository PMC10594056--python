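"""Tabular and GeoJSON exports for visualization and downstream analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodist import Ellipse
from .hexgrid import HexGrid
from .localstats import LocalStatResult
from .voronoi import VoronoiCell


def cells_to_dataframe(cells: list[VoronoiCell]) -> pd.DataFrame:
    """Per-polygon table mirroring the spreadsheet layout: one row per
    bounded cell with Area, Perimeter and Circularity."""
    rows = [
        {
            "site_index": c.site_index,
            "Area": c.area,
            "Perimeter": c.perimeter,
            "Circularity": c.circularity,
        }
        for c in cells
        if not c.open
    ]
    return pd.DataFrame(rows)


def _polygon_feature(ring: np.ndarray, properties: dict) -> dict:
    coords = [[float(x), float(y)] for x, y in ring]
    coords.append(coords[0])
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [coords]},
        "properties": properties,
    }


def cells_to_geojson(cells: list[VoronoiCell]) -> dict:
    """Bounded Voronoi polygons as a GeoJSON FeatureCollection."""
    features = [
        _polygon_feature(
            c.vertices,
            {
                "site_index": c.site_index,
                "area": c.area,
                "perimeter": c.perimeter,
                "circularity": c.circularity,
                "marginal": c.marginal,
            },
        )
        for c in cells
        if not c.open
    ]
    return {"type": "FeatureCollection", "features": features}


def grid_to_dataframe(grid: HexGrid) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_index": np.arange(grid.n_cells),
            "center_x": grid.centers[:, 0],
            "center_y": grid.centers[:, 1],
            "count": grid.counts,
            "in_frame": grid.in_frame,
        }
    )


def grid_to_geojson(grid: HexGrid, classes: LocalStatResult | None = None) -> dict:
    """Hexagons with their join counts (and, optionally, cluster classes)."""
    features = []
    for i in range(grid.n_cells):
        props = {"cell_index": i, "count": int(grid.counts[i]), "in_frame": bool(grid.in_frame[i])}
        if classes is not None:
            props["class"] = str(classes.classes[i])
        features.append(_polygon_feature(grid.vertices(i), props))
    return {"type": "FeatureCollection", "features": features}


def ellipse_to_geojson(ellipse: Ellipse, n_vertices: int = 64) -> dict:
    """Deviational ellipse polygonized for map overlay."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ring = np.column_stack(
        [ellipse.semi_major * np.cos(t), ellipse.semi_minor * np.sin(t)]
    )
    c, s = np.cos(ellipse.rotation), np.sin(ellipse.rotation)
    ring = ring @ np.array([[c, s], [-s, c]]) + np.asarray(ellipse.center)
    return _polygon_feature(ring, {"semi_major": ellipse.semi_major,
                                   "semi_minor": ellipse.semi_minor,
                                   "rotation": ellipse.rotation})
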