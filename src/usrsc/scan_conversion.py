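"""Forward digital scan conversion (DSC) and reverse scan conversion (RSC).

Forward DSC renders an echo-memory image (polar grid: rows = radial samples,
columns = scanlines) onto a Cartesian display canvas.  Reverse scan conversion
recovers the polar representation from an already scan-converted display
frame.  Both directions are implemented as inverse mappings: every *output*
pixel computes its continuous source position through the exact geometry
transforms and samples the source with bilinear interpolation, so every output
pixel receives a value and no hole filling is needed.

Sampling policy: source positions outside the source image bounds yield 0
(black background); the bilinear stencil clamps to edge pixels at the image
border; no anti-aliasing prefilter is applied (plain bilinear).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import geometry as geom
from .exceptions import CanvasError, DegenerateFOVError, GeometryError
from .geometry import FOVGeometry


@dataclass
class EchoImage:
    """Pre-DSC polar-grid image: H radial samples x W scanlines.

    ``data[r, a]`` is the echo intensity at radial sample ``r`` of scanline
    ``a``; ``fov`` is the geometry the grid spans.
    """

    data: np.ndarray
    fov: FOVGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or min(self.data.shape) < 2:
            raise GeometryError("echo grid must be 2-D with shape >= (2, 2)")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("echo intensities must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class DisplayImage:
    """Scan-converted Cartesian image; pixels outside the FOV are 0."""

    data: np.ndarray
    crop: "object | None" = None  # UIRCrop, untyped to avoid a cycle
    fov: FOVGeometry | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise GeometryError("display image must be single-channel 2-D")


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a float image in [0, 255] to 8-bit (round half to even)."""
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an array as 8-bit grayscale PNG/PGM (quantizing floats)."""
    arr = img if img.dtype == np.uint8 else to_uint8(np.asarray(img, float))
    Image.fromarray(arr, mode="L").save(path)


def bilinear_sample(img: np.ndarray, x, y, fill: float = 0.0) -> np.ndarray:
    """Sample ``img`` at continuous positions (x = col, y = row).

    Positions outside [0, W-1] x [0, H-1] return ``fill``; the 2x2 stencil is
    clamped at the borders.  Output values are convex combinations of the four
    neighbors, hence bounded by the local min/max.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    xc = np.clip(x, 0, w - 1)
    yc = np.clip(y, 0, h - 1)
    x0 = np.clip(np.floor(xc).astype(np.intp), 0, w - 2)
    y0 = np.clip(np.floor(yc).astype(np.intp), 0, h - 2)
    fx = xc - x0
    fy = yc - y0
    v = (
        img[y0, x0] * (1.0 - fx) * (1.0 - fy)
        + img[y0, x0 + 1] * fx * (1.0 - fy)
        + img[y0 + 1, x0] * (1.0 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )
    return np.where(inside, v, fill)


def resize_bilinear(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Plain bilinear resize with pixel-center alignment.

    Output pixel (i, j) samples the source at
    ``((j + 0.5) * W_in / W_out - 0.5, (i + 0.5) * H_in / H_out - 0.5)``.
    """
    img = np.asarray(img, dtype=float)
    h_in, w_in = img.shape
    h_out, w_out = out_shape
    if h_out < 1 or w_out < 1:
        raise GeometryError(f"invalid output shape {out_shape}")
    ys = (np.arange(h_out) + 0.5) * (h_in / h_out) - 0.5
    xs = (np.arange(w_out) + 0.5) * (w_in / w_out) - 0.5
    X, Y = np.meshgrid(xs, ys)
    # interior resampling: clamp rather than zero-fill at the half-pixel rim
    X = np.clip(X, 0, w_in - 1)
    Y = np.clip(Y, 0, h_in - 1)
    return bilinear_sample(img, X, Y)


def downsample_image(img: np.ndarray, out_shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Bilinearly downsample to ``out_shape`` (default 64 x 64).

    Upsampling requests are rejected: this function is the inference-path
    reducer, not a general resizer.
    """
    img = np.asarray(img, dtype=float)
    if out_shape[0] > img.shape[0] or out_shape[1] > img.shape[1]:
        raise GeometryError(
            f"downsample target {out_shape} exceeds input shape {img.shape}"
        )
    return resize_bilinear(img, out_shape)


def reverse_scan_convert(
    display: "DisplayImage | np.ndarray",
    fov: FOVGeometry | None = None,
    out_shape: tuple[int, int] | None = None,
) -> EchoImage:
    """Recover the pre-DSC polar image from a scan-converted display frame.

    Every output polar pixel (r, a) computes its display position through the
    FOV transform and bilinearly samples the frame; sources outside the frame
    yield 0.  For a linear FOV the polar transform degenerates and the FOV
    rectangle is cropped and resized instead.
    """
    if isinstance(display, DisplayImage):
        frame = display.data
        fov = fov if fov is not None else display.fov
    else:
        frame = np.asarray(display)
    if fov is None:
        raise GeometryError("reverse_scan_convert needs an FOVGeometry")

    if fov.kind == geom.LINEAR:
        top = int(round(fov.y_offset))
        left = int(round(fov.x_offset))
        h = int(round(fov.d_c))
        w = int(round(fov.width))
        rect = np.asarray(frame, float)[
            max(top, 0) : top + h, max(left, 0) : left + w
        ]
        if rect.size == 0:
            raise CanvasError("linear FOV rectangle lies outside the frame")
        if out_shape is None:
            out_shape = rect.shape
        return EchoImage(resize_bilinear(rect, out_shape), fov)

    if out_shape is None:
        side = max(2, int(round(fov.d_c)))
        out_shape = (side, side)
    H, W = out_shape
    if H < 2 or W < 2:
        raise GeometryError(f"out_shape must be >= (2, 2), got {out_shape}")
    A, R = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    x, y = geom.polar_indices_to_xy(A, R, (H, W), fov)
    data = bilinear_sample(frame, x, y)
    return EchoImage(data, fov)


def forward_scan_convert(
    echo: EchoImage,
    out_shape: tuple[int, int],
    placement: tuple[float, float] | None = None,
) -> DisplayImage:
    """Render an echo-memory image onto a black Cartesian canvas (DSC).

    ``placement`` optionally overrides the apex position ``(x, y)`` on the
    canvas; otherwise the geometry's own offsets are used.  Canvas pixels whose
    polar coordinates fall inside the grid are bilinearly sampled from the
    echo image; all others are 0.  The returned image carries the effective
    geometry.
    """
    fov = echo.fov
    if fov.kind == geom.LINEAR:
        raise DegenerateFOVError("forward scan conversion needs a polar FOV")
    if placement is not None:
        fov = fov.with_apex(*placement)
    rows, cols = out_shape
    H, W = echo.grid_shape
    X, Y = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    a, r = geom.xy_to_polar_indices(X, Y, (H, W), fov)
    inside = (a >= 0) & (a <= W - 1) & (r >= 0) & (r <= H - 1)
    if not inside.any():
        raise CanvasError("FOV has zero visible area on the canvas")
    data = np.zeros(out_shape, dtype=float)
    data[inside] = bilinear_sample(echo.data, a[inside], r[inside])
    return DisplayImage(data, crop=None, fov=fov)
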