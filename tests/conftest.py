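import math

import numpy as np
import pytest

from usrsc.geometry import FOVGeometry, fit_apex_on_canvas
from usrsc.phantom import PhantomSpec, generate_echo_phantom, render_display_frame


@pytest.fixture
def convex_fov() -> FOVGeometry:
    return FOVGeometry(
        x_offset=300.0, y_offset=-20.0, r_c=120.0,
        theta_c=math.radians(65.0), d_c=400.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_polar_fov(rng: np.random.Generator) -> FOVGeometry:
    """A random convex/sector geometry (not necessarily canvas-fitting)."""
    r_c = float(rng.uniform(0.0, 200.0))
    return FOVGeometry(
        x_offset=float(rng.uniform(-100, 100)),
        y_offset=float(rng.uniform(-100, 100)),
        r_c=r_c,
        theta_c=float(rng.uniform(math.radians(10), math.radians(170))),
        d_c=float(rng.uniform(50, 600)),
        kind="sector" if r_c < 5.0 else "convex",
    )


def rendered_phantom(
    r_c: float,
    theta_deg: float,
    canvas=(500, 600),
    margin: float = 12.0,
    depth_frac: float = 0.85,
    speckle: bool = True,
    seed: int = 11,
    apex_dx: float = 0.0,
):
    """Render a speckle phantom with a depth sized to fit the canvas.

    Returns (display frame array, ground-truth FOVGeometry).
    """
    theta = math.radians(theta_deg)
    half = theta / 2.0
    rows, cols = canvas
    d_max = min(
        rows - 2 * margin + r_c * math.cos(half) - r_c,
        (cols / 2.0 - margin - abs(apex_dx)) / math.sin(half) - r_c,
    )
    fov = FOVGeometry(
        0.0, 0.0, r_c, theta, depth_frac * d_max,
        kind="sector" if r_c < 5.0 else "convex",
    )
    fov = fit_apex_on_canvas(fov, canvas, margin=margin)
    fov = fov.with_apex(fov.x_offset + apex_dx, fov.y_offset)
    echo = generate_echo_phantom(
        PhantomSpec(shape=(200, 160), speckle=speckle, seed=seed), fov
    )
    display, fov_used = render_display_frame(
        echo, canvas, placement=(fov.x_offset, fov.y_offset)
    )
    return display.data, fov_used
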