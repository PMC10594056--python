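"""Calibrated 2D cell-centroid point patterns and their I/O.

Coordinates follow the image convention of the source micrographs: the origin
is the top-left corner and y increases downward.  Every statistic implemented
downstream is invariant under that reflection; the deviational-ellipse
rotation is reported in this frame.  All coordinates are carried in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParseError

GROUPS = ("single_minus", "single_hetero", "cocultured_minus", "other")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (x0, y0, width, height) in μm."""

    x0: float
    y0: float
    width: float
    height: float
    degenerate: bool = False

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def contains(self, xy: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= self.x0 - atol)
            & (xy[..., 0] <= self.x0 + self.width + atol)
            & (xy[..., 1] >= self.y0 - atol)
            & (xy[..., 1] <= self.y0 + self.height + atol)
        )


@dataclass(frozen=True)
class Calibration:
    """Pixel→μm scale of the source image."""

    microns_per_pixel: float
    image_width_px: int = 900
    image_height_px: int = 900

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def frame(self) -> Rect:
        return Rect(
            0.0,
            0.0,
            self.image_width_px * self.microns_per_pixel,
            self.image_height_px * self.microns_per_pixel,
        )


@dataclass(frozen=True)
class PointPattern:
    """A set of calibrated cell centroids inside a rectangular frame.

    Parameters
    ----------
    xy : (n, 2) array of μm coordinates.
    frame : the analysis rectangle; defaults downstream to the calibrated
        image rectangle, not the data extent.
    slice_id, group : provenance labels carried through every report.
    """

    xy: np.ndarray
    frame: Rect
    slice_id: str = "unnamed"
    group: str = "other"

    def __post_init__(self):
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if xy.size == 0:
            raise EmptyInputError("point pattern must contain at least one point")
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates in point pattern")
        if self.frame.width <= 0 and not self.frame.degenerate:
            raise ValueError("frame width must be > 0")
        if self.frame.height <= 0 and not self.frame.degenerate:
            raise ValueError("frame height must be > 0")
        if not np.all(self.frame.contains(xy, atol=1e-6 * max(1.0, self.frame.diagonal))):
            raise ValueError("every point must lie inside or on the frame boundary")
        object.__setattr__(self, "xy", xy)

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    def with_frame(self, frame: Rect) -> "PointPattern":
        return replace(self, frame=frame)


def _find_column(columns: Iterable[str], name: str) -> str | None:
    for c in columns:
        if str(c).strip().lower() == name.lower():
            return c
    return None


def read_centroids(
    path: str | Path,
    calibration: Calibration,
    slice_id: str = "unnamed",
    group: str = "other",
    coordinates_in_pixels: bool = True,
) -> PointPattern:
    """Read an ImageJ/FIJI "Measure"-style centroid table.

    The table must carry ``X`` and ``Y`` columns (case-insensitive); a leading
    unnamed index column and a ``Label`` column are tolerated, matching the
    FIJI export dialect.  When ``coordinates_in_pixels`` the coordinates are
    multiplied by the calibration scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: table has no rows")
    xcol = _find_column(df.columns, "x")
    ycol = _find_column(df.columns, "y")
    if xcol is None:
        raise FormatError(f"{path}: missing required column 'X'")
    if ycol is None:
        raise FormatError(f"{path}: missing required column 'Y'")
    coords = np.empty((df.shape[0], 2), dtype=float)
    for j, col in enumerate((xcol, ycol)):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(parsed.to_numpy(dtype=float)))[0]
        if bad.size:
            # +2: header line plus 1-based row numbering, as a user reads the CSV
            raise ParseError(
                f"{path}: non-numeric coordinate in column {col!r} at row {bad[0] + 2}"
            )
        coords[:, j] = parsed.to_numpy(dtype=float)
    if coordinates_in_pixels:
        coords = coords * calibration.microns_per_pixel
    return PointPattern(coords, frame=calibration.frame, slice_id=slice_id, group=group)


def write_centroids(pattern: PointPattern, path: str | Path) -> None:
    """Write the canonical pattern CSV (slice_id, group, x_um, y_um)."""
    df = pd.DataFrame(
        {
            "slice_id": pattern.slice_id,
            "group": pattern.group,
            "x_um": pattern.xy[:, 0],
            "y_um": pattern.xy[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_canonical(path: str | Path, frame: Rect | None = None) -> PointPattern:
    """Read a canonical pattern CSV written by :func:`write_centroids`."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: table has no rows")
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if frame is None:
        mer = minimum_enclosing_rectangle_xy(xy)
        frame = mer
    return PointPattern(
        xy,
        frame=frame,
        slice_id=str(df["slice_id"].iloc[0]),
        group=str(df["group"].iloc[0]),
    )


def minimum_enclosing_rectangle_xy(xy: np.ndarray) -> Rect:
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if xy.size == 0:
        raise EmptyInputError("cannot enclose an empty point set")
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    w, h = x1 - x0, y1 - y0
    return Rect(float(x0), float(y0), float(w), float(h), degenerate=(w == 0 or h == 0))


def minimum_enclosing_rectangle(pattern: PointPattern) -> Rect:
    """Smallest axis-aligned rectangle containing all points.

    This is the default study area of the nearest-neighbor and Ripley
    analyses; degenerate (zero-width/height) rectangles are returned flagged.
    """
    return minimum_enclosing_rectangle_xy(pattern.xy)
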