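"""Bilinear resampling, forward DSC and reverse scan conversion."""

import math

import numpy as np
import pytest

from usrsc import (
    CanvasError,
    EchoImage,
    FOVGeometry,
    GeometryError,
    bilinear_sample,
    downsample_image,
    forward_scan_convert,
    reverse_scan_convert,
)
from usrsc.geometry import polar_indices_to_xy
from usrsc.phantom import PhantomSpec, Inclusion, generate_echo_phantom
from usrsc.scan_conversion import resize_bilinear


def oracle_bilinear(img, x, y):
    """Independent per-pixel bilinear sampler (scalar loops)."""
    h, w = img.shape
    if x < 0 or x > w - 1 or y < 0 or y > h - 1:
        return 0.0
    xc = min(max(x, 0.0), w - 1.0)
    yc = min(max(y, 0.0), h - 1.0)
    x0 = min(int(math.floor(xc)), w - 2)
    y0 = min(int(math.floor(yc)), h - 2)
    fx = xc - x0
    fy = yc - y0
    return (
        img[y0, x0] * (1.0 - fx) * (1.0 - fy)
        + img[y0, x0 + 1] * fx * (1.0 - fy)
        + img[y0 + 1, x0] * (1.0 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


class TestBilinearSample:
    def test_matches_scalar_oracle_bitwise(self, rng):
        for _ in range(20):
            img = rng.uniform(0, 255, size=(int(rng.integers(2, 40)), int(rng.integers(2, 40))))
            xs = rng.uniform(-2, img.shape[1] + 1, size=200)
            ys = rng.uniform(-2, img.shape[0] + 1, size=200)
            got = bilinear_sample(img, xs, ys)
            want = np.array([oracle_bilinear(img, x, y) for x, y in zip(xs, ys)])
            assert np.array_equal(got, want)  # bit-for-float identical

    def test_convex_combination_bound(self, rng):
        img = rng.uniform(0, 255, size=(30, 30))
        xs = rng.uniform(0, 29, size=500)
        ys = rng.uniform(0, 29, size=500)
        v = bilinear_sample(img, xs, ys)
        x0 = np.floor(xs).astype(int).clip(0, 28)
        y0 = np.floor(ys).astype(int).clip(0, 28)
        stack = np.stack(
            [img[y0, x0], img[y0, x0 + 1], img[y0 + 1, x0], img[y0 + 1, x0 + 1]]
        )
        assert np.all(v >= stack.min(axis=0) - 1e-12)
        assert np.all(v <= stack.max(axis=0) + 1e-12)

    def test_grid_points_exact(self, rng):
        img = rng.uniform(0, 255, size=(10, 12))
        Y, X = np.mgrid[0:10, 0:12]
        assert np.array_equal(bilinear_sample(img, X.astype(float), Y.astype(float)), img)


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample_image(np.full((100, 80), 37.0), (25, 16))
        assert out.shape == (25, 16)
        assert np.allclose(out, 37.0)

    def test_ramp_matches_resampling_oracle(self):
        """Rows of a downsampled horizontal ramp equal the ramp at output
        pixel-center source positions."""
        img = np.tile(np.arange(128, dtype=float), (128, 1))
        out = downsample_image(img, (64, 64))
        src_x = (np.arange(64) + 0.5) * (128 / 64) - 0.5
        want = np.array([oracle_bilinear(img, x, 10.3) for x in src_x])
        np.testing.assert_allclose(out[5], want, atol=1e-12)
        np.testing.assert_allclose(out[5], src_x, atol=1e-12)  # ramp value = x

    def test_range_preserved(self, rng):
        for _ in range(100):
            img = rng.uniform(0, 255, size=(int(rng.integers(8, 64)), int(rng.integers(8, 64))))
            h = int(rng.integers(2, img.shape[0] + 1))
            w = int(rng.integers(2, img.shape[1] + 1))
            out = downsample_image(img, (h, w))
            assert out.min() >= img.min() - 1e-9
            assert out.max() <= img.max() + 1e-9

    def test_upsampling_rejected(self):
        with pytest.raises(GeometryError):
            downsample_image(np.zeros((32, 32)), (64, 64))


@pytest.fixture
def smooth_echo(convex_fov):
    spec = PhantomSpec(
        shape=(200, 160),
        speckle=False,
        background_mean=120.0,
        inclusions=(
            Inclusion(80, 100, 30, 40, "anechoic"),
            Inclusion(40, 50, 15, 20, "hyperechoic"),
        ),
    )
    return generate_echo_phantom(spec, convex_fov)


class TestForwardScanConvert:
    def test_zeros_propagate(self, convex_fov):
        echo = EchoImage(np.zeros((64, 64)), convex_fov)
        disp = forward_scan_convert(echo, (600, 800))
        assert not disp.data.any()

    def test_constant_inside_fov_and_area(self, convex_fov):
        echo = EchoImage(np.full((128, 128), 200.0), convex_fov)
        disp = forward_scan_convert(echo, (600, 800))
        inside = disp.data > 0
        assert np.allclose(disp.data[inside], 200.0)
        analytic = (
            convex_fov.theta_c
            / 2.0
            * ((convex_fov.r_c + convex_fov.d_c) ** 2 - convex_fov.r_c**2)
        )
        assert inside.sum() == pytest.approx(analytic, rel=0.01)

    def test_impulse_lands_at_transform_location(self, convex_fov):
        echo_data = np.zeros((128, 96))
        a0, r0 = 30, 70
        echo_data[r0, a0] = 255.0
        echo = EchoImage(echo_data, convex_fov)
        disp = forward_scan_convert(echo, (600, 800))
        py, px = np.unravel_index(np.argmax(disp.data), disp.data.shape)
        ex, ey = polar_indices_to_xy(a0, r0, (128, 96), convex_fov)
        assert math.hypot(px - ex, py - ey) < 1.5

    def test_invisible_fov_rejected(self, convex_fov):
        echo = EchoImage(np.ones((64, 64)), convex_fov.with_apex(-5000.0, -5000.0))
        with pytest.raises(CanvasError):
            forward_scan_convert(echo, (100, 100))

    def test_monotonicity(self, convex_fov, rng):
        base = rng.uniform(10, 200, size=(64, 64))
        brighter = base + rng.uniform(0, 30, size=(64, 64))
        d0 = forward_scan_convert(EchoImage(base, convex_fov), (400, 500))
        d1 = forward_scan_convert(EchoImage(brighter, convex_fov), (400, 500))
        assert np.all(d1.data >= d0.data - 1e-12)


class TestReverseScanConvert:
    def test_zero_display_gives_zero_echo(self, convex_fov):
        echo = reverse_scan_convert(np.zeros((600, 800)), convex_fov, (128, 128))
        assert not echo.data.any()

    def test_constant_fov_gives_constant_echo(self, convex_fov):
        const = forward_scan_convert(
            EchoImage(np.full((128, 128), 180.0), convex_fov), (600, 800)
        )
        echo = reverse_scan_convert(const, out_shape=(100, 100))
        # interior polar pixels (sources well inside the FOV) are exactly 180
        assert np.allclose(echo.data[5:-5, 5:-5], 180.0)

    def test_round_trip_fidelity(self, smooth_echo):
        disp = forward_scan_convert(smooth_echo, (600, 800))
        back = reverse_scan_convert(disp, out_shape=smooth_echo.grid_shape)
        inner = (slice(10, -10), slice(10, -10))
        err = np.abs(back.data[inner] - smooth_echo.data[inner])
        assert err.mean() < 3.0
        a = smooth_echo.data[inner].ravel()
        b = back.data[inner].ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.98

    def test_background_independence(self, smooth_echo, convex_fov):
        """Altering pixels outside the FOV does not change the echo image."""
        disp = forward_scan_convert(smooth_echo, (600, 800))
        outside = disp.data == 0
        # stay clear of boundary-straddling stencils: erode the background
        from scipy.ndimage import binary_erosion

        safe = binary_erosion(outside, iterations=3)
        tampered = disp.data.copy()
        tampered[safe] = 250.0
        e0 = reverse_scan_convert(disp.data, convex_fov, (150, 150))
        e1 = reverse_scan_convert(tampered, convex_fov, (150, 150))
        interior = (slice(2, -2), slice(2, -2))
        np.testing.assert_array_equal(e0.data[interior], e1.data[interior])

    def test_linear_fov_crop_resize_path(self):
        frame = np.zeros((200, 300))
        frame[40:140, 100:180] = 99.0
        lin = FOVGeometry(100, 40, 0, math.nan, 100, kind="linear", width=80)
        echo = reverse_scan_convert(frame, lin, (50, 40))
        assert echo.data.shape == (50, 40)
        assert np.allclose(echo.data, 99.0)
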