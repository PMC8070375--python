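"""Field-of-view parameterization and exact polar/Cartesian coordinate transforms.

A convex- or sector-array B-mode field of view (FOV) is an annular sector in
display coordinates, parameterized by the virtual apex position
(``x_offset``, ``y_offset``), the transducer radius ``r_c`` (apex to the top of
the FOV), the total opening angle ``theta_c`` and the imaging depth ``d_c``
(radial extent of the FOV beyond ``r_c``).  All lengths are display pixels and
all angles radians.

Coordinate conventions
----------------------
* Display (Cartesian) coordinates are 0-based, continuous and pixel-centered:
  image pixel ``(row k, col l)`` sits at ``(x = l, y = k)``; ``y`` increases
  downward, so the beam axis points along +y.
* The polar acquisition grid follows the echo-memory layout: columns index the
  ``W`` scanlines (angular index ``a``), rows index the ``H`` radial samples
  (index ``r``).  The grid is endpoint-inclusive: ``a = 0`` and ``a = W - 1``
  lie exactly on the FOV boundary scanlines at beam angles ``-theta_c/2`` and
  ``+theta_c/2``; ``r = 0`` and ``r = H - 1`` at radii ``r_c`` and
  ``r_c + d_c``.  Grid spacings are thus ``dr = d_c / (H - 1)`` and
  ``dtheta = theta_c / (W - 1)``.

The transform pair is

    x = (r_c + r * dr) * sin(-theta_c/2 + a * dtheta) + x_offset
    y = (r_c + r * dr) * cos(-theta_c/2 + a * dtheta) + y_offset

with beam angle measured from the downward display axis, and its exact inverse
via ``arctan2`` / Euclidean radius.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .exceptions import ApexUndefinedError, DegenerateFOVError, GeometryError

CONVEX = "convex"
SECTOR = "sector"
LINEAR = "linear"
_KINDS = (CONVEX, SECTOR, LINEAR)

#: apex radii below this (pixels) classify the FOV as a sector rather than convex
SECTOR_RC_MAX = 5.0


@dataclass(frozen=True)
class FOVGeometry:
    """Polar parameterization of a convex/sector FOV in display pixels.

    For ``kind="linear"`` (parallel scanlines, rectangular FOV) the polar
    parameters degenerate: ``theta_c`` is NaN, ``(x_offset, y_offset)`` is the
    top-left corner of the rectangle, ``d_c`` its height and ``width`` its
    lateral extent.
    """

    x_offset: float
    y_offset: float
    r_c: float
    theta_c: float
    d_c: float
    kind: str = CONVEX
    width: float | None = None  # linear FOVs only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise GeometryError(f"unknown FOV kind {self.kind!r}")
        if not self.d_c > 0:
            raise GeometryError(f"d_c must be > 0, got {self.d_c}")
        if self.r_c < 0:
            raise GeometryError(f"r_c must be >= 0, got {self.r_c}")
        if self.kind == LINEAR:
            if self.width is None or not self.width > 0:
                raise GeometryError("linear FOV requires a positive width")
        else:
            if not (0.0 < self.theta_c < math.pi):
                raise GeometryError(
                    f"theta_c must lie in (0, pi), got {self.theta_c}"
                )

    @property
    def is_polar(self) -> bool:
        return self.kind in (CONVEX, SECTOR)

    def spacings(self, grid_shape: tuple[int, int]) -> tuple[float, float]:
        """Return ``(dr, dtheta)`` for an H x W polar grid over this FOV."""
        self._require_polar()
        H, W = grid_shape
        if H < 2 or W < 2:
            raise GeometryError(f"grid_shape must be >= (2, 2), got {grid_shape}")
        return self.d_c / (H - 1), self.theta_c / (W - 1)

    def _require_polar(self) -> None:
        if not self.is_polar:
            raise DegenerateFOVError(
                "operation requires a convex or sector FOV, got linear"
            )

    # -- serialization (flat JSON/YAML mapping; angles in degrees on disk) ----

    def to_dict(self) -> dict:
        d = {
            "x_offset": float(self.x_offset),
            "y_offset": float(self.y_offset),
            "r_c": float(self.r_c),
            "theta_c_deg": float(np.degrees(self.theta_c))
            if self.is_polar
            else None,
            "d_c": float(self.d_c),
            "kind": self.kind,
        }
        if self.width is not None:
            d["width"] = float(self.width)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FOVGeometry":
        theta_deg = d.get("theta_c_deg")
        theta = math.nan if theta_deg is None else math.radians(theta_deg)
        return cls(
            x_offset=float(d["x_offset"]),
            y_offset=float(d["y_offset"]),
            r_c=float(d["r_c"]),
            theta_c=theta,
            d_c=float(d["d_c"]),
            kind=d.get("kind", CONVEX),
            width=float(d["width"]) if d.get("width") is not None else None,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FOVGeometry":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)

    def with_apex(self, x: float, y: float) -> "FOVGeometry":
        return replace(self, x_offset=float(x), y_offset=float(y))


@dataclass(frozen=True)
class PolarCoord:
    """Continuous position on an H x W polar grid: angular index ``a`` in
    [0, W-1], radial index ``r`` in [0, H-1]."""

    a: float
    r: float
    grid_shape: tuple[int, int] = field(default=(2, 2))

    def __post_init__(self) -> None:
        H, W = self.grid_shape
        if H < 2 or W < 2:
            raise GeometryError(f"grid_shape must be >= (2, 2), got {self.grid_shape}")


@dataclass(frozen=True)
class CartesianCoord:
    """Continuous display position (x = column, y = row, pixels)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError("coordinates must be finite")


# ---------------------------------------------------------------------------
# array-valued transforms (the workhorses; the typed wrappers call these)
# ---------------------------------------------------------------------------

def polar_indices_to_xy(a, r, grid_shape, fov: FOVGeometry):
    """Vectorized polar-grid indices -> display (x, y).

    ``a``, ``r`` may be scalars or broadcastable arrays of continuous grid
    indices. Returns float arrays (or scalars) ``x``, ``y``.
    """
    dr, dtheta = fov.spacings(grid_shape)
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    phi = -fov.theta_c / 2.0 + a * dtheta
    rho = fov.r_c + r * dr
    x = rho * np.sin(phi) + fov.x_offset
    y = rho * np.cos(phi) + fov.y_offset
    return x, y


def xy_to_polar_indices(x, y, grid_shape, fov: FOVGeometry):
    """Vectorized display (x, y) -> continuous polar-grid indices (a, r).

    Points outside the FOV yield out-of-range indices (``a`` outside
    [0, W-1] and/or ``r`` outside [0, H-1]); the caller filters.
    """
    dr, dtheta = fov.spacings(grid_shape)
    dx = np.asarray(x, dtype=float) - fov.x_offset
    dy = np.asarray(y, dtype=float) - fov.y_offset
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dx, dy)  # angle from the downward beam axis
    a = (phi + fov.theta_c / 2.0) / dtheta
    r = (rho - fov.r_c) / dr
    return a, r


# ---------------------------------------------------------------------------
# typed single-point API
# ---------------------------------------------------------------------------

def polar_to_cartesian(p: PolarCoord, fov: FOVGeometry) -> CartesianCoord:
    """Map a polar-grid position to display coordinates (exact transform)."""
    fov._require_polar()
    x, y = polar_indices_to_xy(p.a, p.r, p.grid_shape, fov)
    return CartesianCoord(float(x), float(y))


def cartesian_to_polar(
    c: CartesianCoord, fov: FOVGeometry, grid_shape: tuple[int, int]
) -> PolarCoord:
    """Map a display position to continuous polar-grid indices.

    Raises :class:`ApexUndefinedError` for the apex itself when ``r_c = 0``
    (the beam angle is undefined there).
    """
    fov._require_polar()
    dx = c.x - fov.x_offset
    dy = c.y - fov.y_offset
    if fov.r_c == 0.0 and dx == 0.0 and dy == 0.0:
        raise ApexUndefinedError("point at the apex with r_c = 0: angle undefined")
    a, r = xy_to_polar_indices(c.x, c.y, grid_shape, fov)
    return PolarCoord(float(a), float(r), grid_shape)


def allocate_scanlines(
    fov: FOVGeometry, N: int
) -> list[tuple[float, tuple[float, float], tuple[float, float]]]:
    """Allocate ``N`` scanlines uniformly over the FOV angle.

    Returns a list of ``(beam_angle, origin, endpoint)``: angles are uniform
    on [-theta_c/2, +theta_c/2] with s1 on the left boundary and sN on the
    right; each line runs from radius ``r_c`` to ``r_c + d_c`` from the apex.
    """
    fov._require_polar()
    if N < 2:
        raise GeometryError(f"need at least 2 scanlines, got {N}")
    angles = -fov.theta_c / 2.0 + np.arange(N) * (fov.theta_c / (N - 1))
    out = []
    for phi in angles:
        s, c = math.sin(phi), math.cos(phi)
        origin = (fov.r_c * s + fov.x_offset, fov.r_c * c + fov.y_offset)
        end = (
            (fov.r_c + fov.d_c) * s + fov.x_offset,
            (fov.r_c + fov.d_c) * c + fov.y_offset,
        )
        out.append((float(phi), origin, end))
    return out


def fov_contains_xy(x, y, fov: FOVGeometry, tol: float = 0.0):
    """Geometric membership test: is (x, y) inside the annular sector?

    Computed directly from radii/angles (independent of the grid transform).
    """
    fov._require_polar()
    dx = np.asarray(x, dtype=float) - fov.x_offset
    dy = np.asarray(y, dtype=float) - fov.y_offset
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dx, dy)
    half = fov.theta_c / 2.0
    return (
        (rho >= fov.r_c - tol)
        & (rho <= fov.r_c + fov.d_c + tol)
        & (phi >= -half - tol)
        & (phi <= half + tol)
    )


def fit_apex_on_canvas(
    fov: FOVGeometry, canvas: tuple[int, int], margin: float = 10.0
) -> FOVGeometry:
    """Return the geometry re-apexed so the whole FOV fits a (rows, cols)
    canvas, horizontally centered with its top ``margin`` pixels below row 0.

    Raises :class:`GeometryError` when the FOV cannot fit.
    """
    fov._require_polar()
    rows, cols = canvas
    half = fov.theta_c / 2.0
    y_top = fov.r_c * math.cos(half)  # highest FOV point relative to apex
    half_width = (fov.r_c + fov.d_c) * math.sin(half)
    if 2 * half_width > cols - 2 * margin:
        raise GeometryError("FOV too wide for the canvas")
    y_apex = margin - y_top
    if y_apex + fov.r_c + fov.d_c > rows - margin:
        raise GeometryError("FOV too deep for the canvas")
    return fov.with_apex(cols / 2.0, y_apex)


def iter_grid_corners(grid_shape: tuple[int, int]) -> Iterable[tuple[float, float]]:
    """The four (a, r) corners of an H x W polar grid."""
    H, W = grid_shape
    return [(0.0, 0.0), (W - 1.0, 0.0), (0.0, H - 1.0), (W - 1.0, H - 1.0)]
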