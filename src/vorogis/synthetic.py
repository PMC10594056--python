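"""Synthetic point patterns emulating the three slice phenotypes.

Cerebellar slices from Reelin-deficient (reln−/−) mice show Purkinje neurons
clumped in a compact central mass; slices with Reelin signalling show them
stratified into discrete layers; co-culture produces an intermediate,
centrifugally dispersing state.  The generator emulates these as static
snapshots — a Gaussian-mixture central mass, concentric arc bands, a
λ-mixture of the two — plus complete spatial randomness (CSR) for null
calibration.  All draws are rejection-sampled into the frame so the stated
distribution shape is preserved rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InfeasibleSpecError
from .points import PointPattern, Rect

DEFAULT_FRAME = Rect(0.0, 0.0, 900.0, 900.0)
#: two clusters, σ = 40 μm, centers 150 μm apart, emulating the paired
#: high-count areas seen in reln−/− single cultures
DEFAULT_CM_SIGMA = 40.0
DEFAULT_CM_SEPARATION = 150.0
#: three concentric bands 80 μm apart (radii 160/240/320 μm) with 12 μm
#: radial spread, emulating stratification into discrete layers
DEFAULT_BAND_RADII = (160.0, 240.0, 320.0)
DEFAULT_BAND_SPREAD = 12.0
DEFAULT_ANGLE_RANGE = (0.0, 2.0 * np.pi)
DEFAULT_N = 300

KINDS = ("central_mass", "layered", "dispersing", "csr")

# child-seed offsets for triad(); documented constants, not tunable
_TRIAD_OFFSETS = {"central_mass": 1, "dispersing": 2, "layered": 3}
_MAX_REJECT_ROUNDS = 1000


def _default_centers(frame: Rect) -> np.ndarray:
    cx = frame.x0 + frame.width / 2.0
    cy = frame.y0 + frame.height / 2.0
    half = DEFAULT_CM_SEPARATION / 2.0
    return np.array([[cx - half, cy], [cx + half, cy]])


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one synthetic phenotype.

    kind-specific fields: ``centers``/``sigmas``/``weights`` for
    ``central_mass``; ``band_center``/``band_radii``/``band_spread``/
    ``band_weights``/``angle_range`` for ``layered``; ``mix_lambda`` for
    ``dispersing`` (λ=0 → pure central mass, λ=1 → pure layered).
    """

    kind: str
    n: int = DEFAULT_N
    frame: Rect = DEFAULT_FRAME
    seed: int = 0
    centers: Sequence[tuple[float, float]] | None = None
    sigmas: Sequence[float] | None = None
    weights: Sequence[float] | None = None
    band_center: tuple[float, float] | None = None
    band_radii: Sequence[float] = DEFAULT_BAND_RADII
    band_spread: float = DEFAULT_BAND_SPREAD
    band_weights: Sequence[float] | None = None
    angle_range: tuple[float, float] = DEFAULT_ANGLE_RANGE
    mix_lambda: float = 0.5

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigmas is not None and any(s <= 0 for s in self.sigmas):
            raise ValueError("sigma must be > 0")
        if any(r <= 0 for r in self.band_radii):
            raise ValueError("band radii must be > 0")
        if self.band_spread <= 0:
            raise ValueError("band spread must be > 0")
        if not 0.0 <= self.mix_lambda <= 1.0:
            raise ValueError("mix_lambda must lie in [0, 1]")


def _draw_central_mass(rng: np.random.Generator, spec: PatternSpec, m: int) -> np.ndarray:
    centers = np.asarray(
        spec.centers if spec.centers is not None else _default_centers(spec.frame), float
    )
    k = centers.shape[0]
    sigmas = np.asarray(
        spec.sigmas if spec.sigmas is not None else [DEFAULT_CM_SIGMA] * k, float
    )
    weights = np.asarray(spec.weights if spec.weights is not None else [1.0] * k, float)
    weights = weights / weights.sum()
    comp = rng.choice(k, size=m, p=weights)
    return centers[comp] + rng.standard_normal((m, 2)) * sigmas[comp, None]


def _draw_layered(rng: np.random.Generator, spec: PatternSpec, m: int) -> np.ndarray:
    center = np.asarray(
        spec.band_center
        if spec.band_center is not None
        else (spec.frame.x0 + spec.frame.width / 2.0, spec.frame.y0 + spec.frame.height / 2.0),
        float,
    )
    radii = np.asarray(spec.band_radii, float)
    weights = np.asarray(
        spec.band_weights if spec.band_weights is not None else [1.0] * len(radii), float
    )
    weights = weights / weights.sum()
    band = rng.choice(len(radii), size=m, p=weights)
    r = radii[band] + rng.standard_normal(m) * spec.band_spread
    theta = rng.uniform(spec.angle_range[0], spec.angle_range[1], size=m)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _draw_csr(rng: np.random.Generator, spec: PatternSpec, m: int) -> np.ndarray:
    f = spec.frame
    return np.column_stack(
        [rng.uniform(f.x0, f.x0 + f.width, m), rng.uniform(f.y0, f.y0 + f.height, m)]
    )


def _draw(rng: np.random.Generator, spec: PatternSpec, m: int) -> np.ndarray:
    if spec.kind == "csr":
        return _draw_csr(rng, spec, m)
    if spec.kind == "central_mass":
        return _draw_central_mass(rng, spec, m)
    if spec.kind == "layered":
        return _draw_layered(rng, spec, m)
    # dispersing: per-point Bernoulli(λ) mixture of the two components;
    # λ = 0/1 degenerate exactly to the pure components
    if spec.mix_lambda == 0.0:
        return _draw_central_mass(rng, spec, m)
    if spec.mix_lambda == 1.0:
        return _draw_layered(rng, spec, m)
    pick = rng.random(m) < spec.mix_lambda
    out = np.empty((m, 2))
    n_lay = int(pick.sum())
    if m - n_lay:
        out[~pick] = _draw_central_mass(rng, spec, m - n_lay)
    if n_lay:
        out[pick] = _draw_layered(rng, spec, n_lay)
    return out


def generate(spec: PatternSpec) -> PointPattern:
    """Draw exactly ``spec.n`` points inside the frame, rejecting out-of-frame draws.

    Deterministic given ``spec.seed``.  Raises :class:`InfeasibleSpecError`
    when the rejection rate exceeds 99% (the spec is incompatible with the
    frame).
    """
    rng = np.random.default_rng(spec.seed)
    kept: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    for _ in range(_MAX_REJECT_ROUNDS):
        need = spec.n - n_kept
        if need <= 0:
            break
        batch = _draw(rng, spec, max(need * 2, 64))
        n_drawn += batch.shape[0]
        inside = spec.frame.contains(batch)
        batch = batch[inside]
        kept.append(batch)
        n_kept += batch.shape[0]
        if n_drawn >= 200 and n_kept < 0.01 * n_drawn:
            raise InfeasibleSpecError(
                f"rejection rate {1 - n_kept / n_drawn:.3f} > 0.99 for kind={spec.kind!r}"
            )
    if n_kept < spec.n:
        raise InfeasibleSpecError("could not fill the frame within the rejection budget")
    xy = np.concatenate(kept)[: spec.n]
    return PointPattern(
        xy, frame=spec.frame, slice_id=f"{spec.kind}-seed{spec.seed}", group="other"
    )


def triad(
    n: int = DEFAULT_N, frame: Rect = DEFAULT_FRAME, seed: int = 0, mix_lambda: float = 0.5
) -> dict[str, PointPattern]:
    """Three matched patterns — central_mass, dispersing (λ=0.5), layered —
    sharing frame and n, with child seeds derived as seed + fixed offsets.

    Mirrors the three experimental culture groups so every group comparison
    is testable without imaging data.
    """
    if n < 50:
        raise ValueError("triad requires n >= 50")
    out = {}
    for kind, off in _TRIAD_OFFSETS.items():
        spec = PatternSpec(kind=kind, n=n, frame=frame, seed=seed + off, mix_lambda=mix_lambda)
        pat = generate(spec)
        group = {
            "central_mass": "single_minus",
            "dispersing": "cocultured_minus",
            "layered": "single_hetero",
        }[kind]
        out[kind] = PointPattern(pat.xy, frame=frame, slice_id=pat.slice_id, group=group)
    return out
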