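"""Automatic FOV geometry recovery from scan-converted display frames.

Pipeline: crop the ultrasound image region (UIR) rectangle, binarize it,
detect the two straight boundary scanlines (left s1, right sN) with a line
Hough transform on the morphological boundary of the mask, intersect them to
obtain the apex, and read the radial extent off the foreground pixels:

* apex ``(x_offset, y_offset)`` = intersection of s1 and sN,
* ``theta_c`` = angle subtended between the two boundary lines at the apex,
* ``r_c`` = min apex distance over foreground pixels,
* ``d_c`` = max apex distance - ``r_c``.

Each Hough peak is refined by a total-least-squares fit to its inlier boundary
pixels, and the fitted line is pushed half a pixel along its outward normal to
undo the pixel-center quantization of the binary mask (boundary pixel centers
sit on average half a pixel inside the true FOV edge).

Degenerate cases: a rectangular (linear-array) FOV has parallel/vertical
edges and no apex; detection then falls back to a linear geometry spanning the
foreground bounding box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.transform import hough_line, hough_line_peaks

from . import geometry as geom
from .exceptions import BoundaryDetectionError, EmptyMaskError, GeometryError
from .geometry import FOVGeometry
from .scan_conversion import DisplayImage


@dataclass(frozen=True)
class UIRCrop:
    """Rectangle (integer pixels) of the ultrasound image region in a frame."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise GeometryError("UIR crop must have positive extent")
        if self.top < 0 or self.left < 0:
            raise GeometryError("UIR crop must lie inside the frame")

    def slice(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )

    @classmethod
    def full_frame(cls, frame: np.ndarray) -> "UIRCrop":
        return cls(0, 0, frame.shape[0], frame.shape[1])


@dataclass(frozen=True)
class BoundaryLine:
    """A boundary scanline in normal form: x*cos(angle) + y*sin(angle) = dist.

    ``angle`` is normalized to [0, pi); ``support`` counts inlier boundary
    pixels.  ``direction_point`` is the inlier centroid, used to orient the
    beam direction away from the apex.
    """

    angle: float
    dist: float
    support: int
    direction_point: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.support <= 0:
            raise GeometryError("boundary line must have positive support")
        if not (0.0 <= self.angle < math.pi):
            raise GeometryError("line angle must lie in [0, pi)")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunables for FOV estimation.

    threshold: binarization level (mask = intensity > threshold); the default
        0 assumes a pure black background inside the UIR.
    min_angle_deg: reject Hough peaks closer than this to vertical (boundary
        scanlines of any practical sector are tilted).
    max_angle_deg: reject near-horizontal peaks (arc chords).
    parallel_deg: boundary angles differing by less than this trigger the
        linear-FOV fallback (no stable apex).
    r_sector_max: apex radii below this classify as a sector array.
    """

    threshold: float = 0.0
    min_angle_deg: float = 5.0
    max_angle_deg: float = 88.0
    parallel_deg: float = 2.0
    r_sector_max: float = geom.SECTOR_RC_MAX
    accumulator_angle_deg: float = 1.0
    refine: bool = True
    refine_inlier_px: float = 2.0


def _as_array(frame) -> np.ndarray:
    if isinstance(frame, DisplayImage):
        return np.asarray(frame.data)
    return np.asarray(frame)


def binarize_uir(frame, crop: UIRCrop | None = None, threshold: float = 0.0) -> np.ndarray:
    """Binarize the UIR: boolean mask where cropped intensity > threshold.

    Raises :class:`EmptyMaskError` when no pixel is above threshold (the frame
    contains no FOV).
    """
    arr = _as_array(frame)
    if arr.ndim != 2:
        raise GeometryError("frame must be single-channel")
    if crop is None:
        crop = UIRCrop.full_frame(arr)
    if crop.top + crop.height > arr.shape[0] or crop.left + crop.width > arr.shape[1]:
        raise GeometryError("UIR crop exceeds the frame")
    mask = arr[crop.slice()] > threshold
    if not mask.any():
        raise EmptyMaskError("no foreground above threshold: frame has no FOV")
    return mask


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~binary_erosion(mask, border_value=0)


def _tls_refine(
    points_xy: np.ndarray, angle: float, dist: float, inlier_px: float
) -> tuple[float, float, np.ndarray]:
    """Total-least-squares line fit to boundary pixels near (angle, dist).

    Returns refined (angle, dist) in the same normal form plus the inlier
    points.  Falls back to the input line if too few inliers.
    """
    n = np.array([math.cos(angle), math.sin(angle)])
    for _ in range(2):
        resid = points_xy @ n - dist
        sel = np.abs(resid) < inlier_px
        pts = points_xy[sel]
        if len(pts) < 5:
            return angle, dist, points_xy[np.abs(points_xy @ n - dist) < inlier_px]
        mean = pts.mean(axis=0)
        cov = np.cov((pts - mean).T)
        evals, evecs = np.linalg.eigh(cov)
        n_new = evecs[:, 0]  # minor axis = line normal
        if n_new @ n < 0:
            n_new = -n_new
        n = n_new
        dist = float(n @ mean)
        angle = math.atan2(n[1], n[0])
    return angle, dist, pts


def _normalize_line(angle: float, dist: float) -> tuple[float, float]:
    """Normalize a normal-form line so angle lies in [0, pi)."""
    angle = math.remainder(angle, 2 * math.pi)
    if angle < 0:
        angle += math.pi
        dist = -dist
    if angle >= math.pi:
        angle -= math.pi
        dist = -dist
    return angle, dist


def detect_boundary_lines(
    mask: np.ndarray, config: ExtractionConfig | None = None
) -> tuple[BoundaryLine, BoundaryLine]:
    """Find the left (s1) and right (sN) straight FOV boundaries of a mask.

    Runs a line Hough transform on the mask's morphological boundary, keeps
    the highest-support peaks tilted away from vertical on each side of the
    mask centroid, and refines each by a total-least-squares fit to its inlier
    pixels (including a half-pixel outward-normal shift compensating the
    binarization quantization).

    Raises :class:`BoundaryDetectionError` when no supported pair of
    non-parallel tilted edges exists (candidate linear FOV).
    """
    cfg = config or ExtractionConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("empty mask")
    boundary = _mask_boundary(mask)
    ys, xs = np.nonzero(boundary)
    points_xy = np.column_stack([xs, ys]).astype(float)
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()

    step = math.radians(cfg.accumulator_angle_deg)
    thetas = np.arange(-math.pi / 2, math.pi / 2, step)
    accum, angles, dists = hough_line(boundary, theta=thetas)
    peak_votes, peak_angles, peak_dists = hough_line_peaks(
        accum, angles, dists, num_peaks=12, min_distance=9, min_angle=3
    )

    min_a = math.radians(cfg.min_angle_deg)
    max_a = math.radians(cfg.max_angle_deg)
    best: dict[str, tuple[int, float, float]] = {}
    for votes, ang, dist in zip(peak_votes, peak_angles, peak_dists):
        # hough theta is the normal angle; theta=0 is a vertical line
        if not (min_a < abs(ang) < max_a):
            continue
        # side of the centroid: x-position of the line at y = cy
        x_at_cy = (dist - cy * math.sin(ang)) / math.cos(ang)
        side = "left" if x_at_cy < cx else "right"
        if side not in best or votes > best[side][0]:
            best[side] = (int(votes), float(ang), float(dist))
    if len(best) < 2:
        raise BoundaryDetectionError(
            "fewer than two supported tilted boundary lines: candidate linear FOV"
        )

    lines: dict[str, BoundaryLine] = {}
    for side, (votes, ang, dist) in best.items():
        inliers = points_xy
        if cfg.refine:
            ang, dist, inliers = _tls_refine(points_xy, ang, dist, cfg.refine_inlier_px)
            # push half a pixel along the outward normal (away from centroid):
            # mask boundary pixel centers lie ~0.5 px inside the true edge
            n = np.array([math.cos(ang), math.sin(ang)])
            outward = 1.0 if (np.array([cx, cy]) @ n - dist) < 0 else -1.0
            dist += 0.5 * outward
        ang, dist = _normalize_line(ang, dist)
        centroid = tuple(inliers.mean(axis=0)) if len(inliers) else (cx, cy)
        lines[side] = BoundaryLine(ang, dist, max(votes, 1), centroid)

    s1, sN = lines["left"], lines["right"]
    if _lines_angle_deg(s1, sN) < cfg.parallel_deg:
        raise BoundaryDetectionError(
            "boundary lines are near-parallel: candidate linear FOV"
        )
    return s1, sN


def _lines_angle_deg(l1: BoundaryLine, l2: BoundaryLine) -> float:
    d = abs(l1.angle - l2.angle) % math.pi
    return math.degrees(min(d, math.pi - d))


def _intersect(l1: BoundaryLine, l2: BoundaryLine) -> tuple[float, float]:
    A = np.array(
        [
            [math.cos(l1.angle), math.sin(l1.angle)],
            [math.cos(l2.angle), math.sin(l2.angle)],
        ]
    )
    b = np.array([l1.dist, l2.dist])
    try:
        x, y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise BoundaryDetectionError("boundary lines do not intersect") from err
    return float(x), float(y)


def _linear_fallback(mask: np.ndarray, crop: UIRCrop) -> FOVGeometry:
    rows, cols = np.nonzero(mask)
    top, bottom = rows.min(), rows.max()
    left, right = cols.min(), cols.max()
    return FOVGeometry(
        x_offset=float(left + crop.left),
        y_offset=float(top + crop.top),
        r_c=0.0,
        theta_c=math.nan,
        d_c=float(bottom - top + 1),
        kind=geom.LINEAR,
        width=float(right - left + 1),
    )


def estimate_fov_geometry(
    frame,
    crop: UIRCrop | None = None,
    config: ExtractionConfig | None = None,
) -> FOVGeometry:
    """Recover the full FOV geometry from a display frame.

    Returns the apex offsets in *frame* coordinates (crop offsets folded in).
    A frame whose boundary detection degenerates (parallel or vertical edges)
    yields a linear geometry spanning the foreground bounding box; an
    all-background frame raises :class:`EmptyMaskError`.
    """
    cfg = config or ExtractionConfig()
    arr = _as_array(frame)
    if crop is None:
        crop = UIRCrop.full_frame(arr)
    mask = binarize_uir(arr, crop, cfg.threshold)

    try:
        s1, sN = detect_boundary_lines(mask, cfg)
    except BoundaryDetectionError:
        return _linear_fallback(mask, crop)

    ax, ay = _intersect(s1, sN)

    # beam angles of the two boundaries, oriented from the apex into the mask
    def beam_angle(line: BoundaryLine) -> float:
        ux = line.direction_point[0] - ax
        uy = line.direction_point[1] - ay
        return math.atan2(ux, uy)  # from the downward display axis

    phi1, phiN = beam_angle(s1), beam_angle(sN)
    theta_c = phiN - phi1
    if theta_c <= 0 or theta_c >= math.pi:
        return _linear_fallback(mask, crop)

    rows, cols = np.nonzero(mask)
    dist = np.sort(np.hypot(cols - ax, rows - ay))
    # The raw min/max pixel-center distances are biased inward, by up to
    # ~1/sqrt(theta_c) near a narrow sector tip where pixel centers are
    # sparse.  Extrapolate both radii from the pixel count in a thin annulus
    # band (area ~= theta_c/2 * (rho^2 - r_c^2)), clamped near the raw
    # extremes so foreground holes (anechoic regions) cannot drag them far.
    beta = theta_c / 2.0
    k = min(80, len(dist) - 1)
    rc_area = math.sqrt(max(0.0, float(dist[k]) ** 2 - (k + 1) / beta))
    r_c = float(np.clip(rc_area, dist[0] - 2.5, dist[0]))
    r_c = max(r_c, 0.0)
    rout_area = math.sqrt(float(dist[-1 - k]) ** 2 + (k + 1) / beta)
    r_outer = float(np.clip(rout_area, dist[-1], dist[-1] + 2.5))
    d_c = r_outer - r_c
    if d_c <= 0:
        raise BoundaryDetectionError("degenerate FOV: zero radial extent")
    kind = geom.SECTOR if r_c < cfg.r_sector_max else geom.CONVEX
    return FOVGeometry(
        x_offset=ax + crop.left,
        y_offset=ay + crop.top,
        r_c=r_c,
        theta_c=theta_c,
        d_c=d_c,
        kind=kind,
    )
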