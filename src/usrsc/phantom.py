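"""Synthetic ultrasound phantoms: speckle echo images with known geometry.

The generator stands in for clinical B-mode data: it draws an echo-memory
image (polar grid) with a Rayleigh-envelope speckle texture, embeds elliptical
inclusions (anechoic / hypoechoic / hyperechoic, caricaturing fluid-filled,
dim and bright structures), and renders it through the forward scan converter
onto a display canvas, returning the exact FOV geometry used — ground truth
for the extraction and round-trip tests.

Speckle model: the coherent envelope of fully developed speckle is Rayleigh
distributed.  Each pixel draws a unit-scale Rayleigh envelope, which is
log-compressed (``log1p(gamma * e)``) as a display processor would, then
scaled so the *expected* 8-bit output equals the region's target mean.  The
normalizing expectation ``E[log1p(gamma * e)]`` is computed once by quadrature
over the Rayleigh density, so region sample means land on their targets
without Monte-Carlo calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geom
from .exceptions import GeometryError, USRSCError
from .geometry import FOVGeometry, fit_apex_on_canvas
from .scan_conversion import (
    DisplayImage,
    EchoImage,
    forward_scan_convert,
    to_uint8,
    write_image,
)

ANECHOIC = "anechoic"
HYPOECHOIC = "hypoechoic"
HYPERECHOIC = "hyperechoic"
_MODES = (ANECHOIC, HYPOECHOIC, HYPERECHOIC)

#: default FOV used when a phantom spec does not provide one: a convex probe
#: with a 120 px transducer radius, 65 degree opening and 400 px depth
DEFAULT_FOV = FOVGeometry(
    x_offset=0.0, y_offset=0.0, r_c=120.0, theta_c=math.radians(65.0), d_c=400.0
)

#: log-compression gain applied to the unit-scale Rayleigh envelope
SPECKLE_GAMMA = 3.0


@dataclass(frozen=True)
class Inclusion:
    """Elliptical inclusion in polar-grid units (a = column, r = row)."""

    center_a: float
    center_r: float
    axis_a: float
    axis_r: float
    mode: str = ANECHOIC

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise USRSCError(f"unknown inclusion mode {self.mode!r}")
        if self.axis_a <= 0 or self.axis_r <= 0:
            raise USRSCError("inclusion axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic echo image.

    Overlapping inclusions resolve last-wins (later entries paint over
    earlier ones).
    """

    shape: tuple[int, int] = (256, 192)  # H radial samples x W scanlines
    background_mean: float = 128.0
    speckle: bool = True
    inclusions: tuple[Inclusion, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.shape
        if H < 2 or W < 2:
            raise USRSCError(f"phantom grid must be >= (2, 2), got {self.shape}")
        if not (0.0 <= self.background_mean <= 255.0):
            raise USRSCError("background mean must lie in [0, 255]")
        for inc in self.inclusions:
            if not (0 <= inc.center_a < W and 0 <= inc.center_r < H):
                raise USRSCError("inclusion center outside the grid")


def _mode_mean(mode: str, background: float) -> float:
    if mode == ANECHOIC:
        return 4.0
    if mode == HYPOECHOIC:
        return 0.5 * background
    return 235.0  # hyperechoic: near saturation


def _log_envelope_mean(gamma: float) -> float:
    """E[log1p(gamma * e)] for e ~ Rayleigh(1), by quadrature."""
    e = np.linspace(0.0, 12.0, 4096)
    pdf = e * np.exp(-(e**2) / 2.0)
    return float(np.trapezoid(np.log1p(gamma * e) * pdf, e))


_LOG_ENV_MEAN = _log_envelope_mean(SPECKLE_GAMMA)


def mean_intensity_map(spec: PhantomSpec) -> np.ndarray:
    """Target mean-intensity map of a phantom (the speckle-free image)."""
    H, W = spec.shape
    out = np.full((H, W), float(spec.background_mean))
    A, R = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    for inc in spec.inclusions:
        sel = ((A - inc.center_a) / inc.axis_a) ** 2 + (
            (R - inc.center_r) / inc.axis_r
        ) ** 2 <= 1.0
        out[sel] = _mode_mean(inc.mode, spec.background_mean)
    return out


def generate_echo_phantom(
    spec: PhantomSpec, fov: FOVGeometry | None = None
) -> EchoImage:
    """Draw a reproducible speckle phantom on the polar grid.

    With ``spec.speckle`` off the exact region means are emitted; with it on,
    each pixel is a log-compressed Rayleigh envelope scaled to the region
    mean, clipped to [0, 255].
    """
    means = mean_intensity_map(spec)
    if not spec.speckle:
        data = means
    else:
        rng = np.random.default_rng(spec.seed)
        envelope = rng.rayleigh(scale=1.0, size=spec.shape)
        compressed = np.log1p(SPECKLE_GAMMA * envelope) / _LOG_ENV_MEAN
        data = np.clip(means * compressed, 0.0, 255.0)
    return EchoImage(data, fov if fov is not None else DEFAULT_FOV)


def render_display_frame(
    echo: EchoImage,
    canvas: tuple[int, int] = (600, 800),
    placement: tuple[float, float] | None = None,
    margin: float = 10.0,
) -> tuple[DisplayImage, FOVGeometry]:
    """Scan-convert an echo phantom onto a black display canvas.

    Without an explicit apex ``placement`` the FOV is centered with its top
    ``margin`` pixels below the canvas top.  Returns the display frame and the
    exact geometry used (ground truth for extraction tests).
    """
    fov = echo.fov
    if placement is None:
        fov = fit_apex_on_canvas(fov, canvas, margin=margin)
        placement = (fov.x_offset, fov.y_offset)
    display = forward_scan_convert(echo, canvas, placement=placement)
    return display, display.fov


# ---------------------------------------------------------------------------
# labeled dataset generation
# ---------------------------------------------------------------------------

DEFAULT_CLASSES = ("liver", "kidney", "gallbladder")


def _class_inclusions(
    label: str, shape: tuple[int, int], rng: np.random.Generator
) -> tuple[Inclusion, ...]:
    """Caricature texture recipes: liver = uniform speckle, gallbladder = a
    large anechoic sac, kidney = hypoechoic ellipse with a bright rim."""
    H, W = shape
    ca = rng.uniform(0.3 * W, 0.7 * W)
    cr = rng.uniform(0.35 * H, 0.65 * H)
    if label == "liver":
        return ()
    if label == "gallbladder":
        return (
            Inclusion(ca, cr, rng.uniform(0.18, 0.28) * W, rng.uniform(0.2, 0.3) * H, ANECHOIC),
        )
    if label == "kidney":
        aa = rng.uniform(0.16, 0.24) * W
        ar = rng.uniform(0.18, 0.26) * H
        return (
            Inclusion(ca, cr, aa, ar, HYPERECHOIC),  # bright rim
            Inclusion(ca, cr, 0.72 * aa, 0.72 * ar, HYPOECHOIC),  # dim cortex
        )
    raise USRSCError(f"no texture recipe for class {label!r}")


def random_fov(
    rng: np.random.Generator,
    canvas: tuple[int, int] = (600, 800),
    margin: float = 10.0,
    r_c_range: tuple[float, float] = (0.0, 150.0),
    theta_deg_range: tuple[float, float] = (40.0, 80.0),
) -> FOVGeometry:
    """Sample a convex/sector geometry guaranteed to fit the canvas."""
    rows, cols = canvas
    for _ in range(100):
        r_c = rng.uniform(*r_c_range)
        theta = math.radians(rng.uniform(*theta_deg_range))
        half = theta / 2.0
        d_max_rows = rows - 2 * margin + r_c * math.cos(half) - r_c
        d_max_cols = (cols / 2.0 - margin) / math.sin(half) - r_c
        d_max = min(d_max_rows, d_max_cols)
        if d_max < 50:
            continue
        d_c = rng.uniform(0.7, 0.95) * d_max
        kind = geom.SECTOR if r_c < geom.SECTOR_RC_MAX else geom.CONVEX
        fov = FOVGeometry(0.0, 0.0, r_c, theta, d_c, kind)
        fov = fit_apex_on_canvas(fov, canvas, margin=margin)
        # lateral jitter within the remaining horizontal slack
        slack = cols / 2.0 - margin - (r_c + d_c) * math.sin(half)
        if slack > 1:
            fov = fov.with_apex(fov.x_offset + rng.uniform(-slack, slack), fov.y_offset)
        return fov
    raise GeometryError("could not sample a FOV that fits the canvas")


def generate_labeled_dataset(
    n_per_class: int,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    out_dir: str | Path = "phantom_data",
    seed: int = 0,
    canvas: tuple[int, int] = (600, 800),
    grid_shape: tuple[int, int] = (256, 192),
    write_files: bool = True,
) -> pd.DataFrame:
    """Write ``n_per_class`` display frames per class with varied geometry.

    Returns the manifest: one row per frame with the file path, label and the
    ground-truth geometry columns.  Fully deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise USRSCError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for label in classes:
        for i in range(n_per_class):
            frame_seed = int(rng.integers(0, 2**31 - 1))
            frame_rng = np.random.default_rng(frame_seed)
            fov = random_fov(frame_rng, canvas)
            spec = PhantomSpec(
                shape=grid_shape,
                background_mean=float(frame_rng.uniform(110, 150)),
                speckle=True,
                inclusions=_class_inclusions(label, grid_shape, frame_rng),
                seed=frame_seed,
            )
            echo = generate_echo_phantom(spec, fov)
            display, fov_used = render_display_frame(
                echo, canvas, placement=(fov.x_offset, fov.y_offset)
            )
            name = f"{label}_{i:04d}.png"
            path = out_dir / name
            if write_files:
                write_image(path, display.data)
            rows.append(
                {
                    "file": str(path),
                    "label": label,
                    "kind": fov_used.kind,
                    "x_offset": fov_used.x_offset,
                    "y_offset": fov_used.y_offset,
                    "r_c": fov_used.r_c,
                    "theta_c_deg": math.degrees(fov_used.theta_c),
                    "d_c": fov_used.d_c,
                }
            )
    manifest = pd.DataFrame(rows)
    if write_files:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
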