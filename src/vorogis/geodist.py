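"""Measuring geographic distributions of a point pattern.

Central feature (the point minimizing the summed Euclidean distance to all
others), mean center, median center (geometric median by Weiszfeld
iteration), standard distance and the standard deviational ellipse.  All
dispersion measures use divisor n (no degrees-of-freedom correction), the
classic definitions.  The ellipse rotation is reported in the image
coordinate frame, in [0, π).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import ConvergenceError, TooFewPointsError
from .points import PointPattern


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    rotation: float  # angle of the major axis, radians in [0, π)
    degenerate: bool = False

    @property
    def axis_ratio(self) -> float:
        return self.semi_minor / self.semi_major if self.semi_major > 0 else np.nan


@dataclass(frozen=True)
class DistributionSummary:
    central_feature_index: int
    mean_center: tuple[float, float]
    median_center: tuple[float, float]
    standard_distance: float
    ellipse: Ellipse


def central_feature(pattern: PointPattern) -> int:
    """Index of the point with the smallest summed distance to all others;
    ties break to the lowest index."""
    if pattern.n == 1:
        return 0
    sums = squareform(pdist(pattern.xy)).sum(axis=1)
    return int(np.argmin(sums))  # argmin returns the first (lowest) minimizer


def mean_center(pattern: PointPattern) -> tuple[float, float]:
    c = pattern.xy.mean(axis=0)
    return (float(c[0]), float(c[1]))


def median_center(
    pattern: PointPattern, tol: float = 1e-8, max_iter: int = 10_000
) -> tuple[float, float]:
    """Geometric median by Weiszfeld iteration (tolerance on the step size).

    When an iterate lands on a data point the standard perturbation (nudge by
    tol along +x) is applied so the iteration can continue.
    """
    xy = pattern.xy
    if pattern.n == 1:
        return (float(xy[0, 0]), float(xy[0, 1]))
    current = xy.mean(axis=0)
    step = np.inf
    for _ in range(max_iter):
        d = np.hypot(*(xy - current).T)
        coincident = d < tol
        if np.any(coincident):
            # if the coincident point is the majority point it is the median
            if np.count_nonzero(coincident) > pattern.n / 2:
                i = int(np.argmax(coincident))
                return (float(xy[i, 0]), float(xy[i, 1]))
            current = current + np.array([tol, 0.0])
            d = np.hypot(*(xy - current).T)
        w = 1.0 / d
        new = (xy * w[:, None]).sum(axis=0) / w.sum()
        step = float(np.hypot(*(new - current)))
        current = new
        if step < tol:
            return (float(current[0]), float(current[1]))
    raise ConvergenceError(f"Weiszfeld did not converge; last step {step:.3e} μm")


def standard_distance(pattern: PointPattern) -> float:
    """√[Σ((xi−x̄)² + (yi−ȳ)²)/n] — the standard-distance circle radius."""
    if pattern.n < 2:
        raise TooFewPointsError("standard distance requires >= 2 points")
    dev = pattern.xy - pattern.xy.mean(axis=0)
    return float(np.sqrt((dev**2).sum() / pattern.n))


def deviational_ellipse(pattern: PointPattern) -> Ellipse:
    """Standard deviational ellipse at 1 SD about the mean center, divisor n.

    Semi-axes are the square roots of the eigenvalues of the (divisor-n)
    coordinate covariance; the rotation is the principal-axis angle.
    Collinear input yields a degenerate (zero-minor-axis) flagged ellipse.
    """
    if pattern.n < 2:
        raise TooFewPointsError("deviational ellipse requires >= 2 points")
    c = pattern.xy.mean(axis=0)
    dev = pattern.xy - c
    cov = dev.T @ dev / pattern.n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major, minor = float(np.sqrt(max(evals[1], 0.0))), float(np.sqrt(max(evals[0], 0.0)))
    vx, vy = evecs[:, 1]
    rotation = float(np.arctan2(vy, vx)) % np.pi
    degenerate = minor <= 1e-12 * max(major, 1.0)
    return Ellipse((float(c[0]), float(c[1])), major, minor, rotation, degenerate)


def distribution_summary(pattern: PointPattern) -> DistributionSummary:
    return DistributionSummary(
        central_feature_index=central_feature(pattern),
        mean_center=mean_center(pattern),
        median_center=median_center(pattern),
        standard_distance=standard_distance(pattern),
        ellipse=deviational_ellipse(pattern),
    )
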