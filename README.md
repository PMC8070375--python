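# usrsc — reverse scan conversion for B-mode ultrasound

Convex- and sector-array B-mode frames are acquired on a polar grid (W
scanlines × H radial samples) and resampled to a Cartesian raster for
display. For on-device image classification this display format is a poor
training input: the sector-shaped field of view (FOV) is a probe-specific
outline a network can learn as a spurious feature, and the black corners
waste input pixels. **Reverse scan conversion (RSC)** undoes the display
resampling — it recovers the rectangular polar ("echo-memory")
representation from an ordinary display frame, so labeled display images can
be turned into FOV-free training data that matches the pre-display images an
embedded classifier sees at inference time.

The package provides, for researchers building ultrasound image-analysis
datasets and real-time mobile imaging pipelines:

- **Exact FOV transforms** between display coordinates and the polar grid.
  The FOV is an annular sector with apex `(x_offset, y_offset)`, transducer
  radius `r_c`, opening angle `θ_c` and depth `d_c` (display pixels); grid
  index `(a, r)` maps to `x = (r_c + r·Δr)·sin(−θ_c/2 + a·Δθ) + x_offset`,
  `y = (r_c + r·Δr)·cos(·) + y_offset` with `Δr = d_c/(H−1)`,
  `Δθ = θ_c/(W−1)`.
- **Automatic FOV extraction** from a display frame: binarize the ultrasound
  image region, Hough-detect the two boundary scanlines, intersect them for
  the apex, and read `r_c`/`d_c` off the foreground radii.
- **Forward and reverse scan conversion** by inverse mapping with bilinear
  interpolation (hole-free by construction), plus the 64×64 inference-path
  downsampler.
- **Synthetic phantoms**: Rayleigh-speckle echo images with elliptical
  inclusions, rendered to display frames with known ground-truth geometry.
- **A dataset builder** producing the RSC variant and the cropped-display
  ("USI") baseline variant per frame, with a CSV manifest.
- **A scheduling simulator** for frame-synchronous vs frame-asynchronous
  classification (FSC/FAC) on a shared GPU: FAC splits the classification
  pipeline into M sub-pipelines run in the per-frame transfer idle windows,
  trading classification rate for imaging rate (`f_image ≈ M·f_cp`).

## Worked example

```python
import math
from usrsc import (FOVGeometry, PhantomSpec, Inclusion, generate_echo_phantom,
                   render_display_frame, estimate_fov_geometry,
                   reverse_scan_convert, TimingModel, simulate_fsc, simulate_fac)

# a speckle phantom with an anechoic (fluid-like) inclusion, rendered through
# the forward scan converter onto a 600x800 display canvas
spec = PhantomSpec(shape=(256, 192), background_mean=128.0, seed=7,
                   inclusions=(Inclusion(96, 128, 40, 50, "anechoic"),))
fov = FOVGeometry(0, 0, r_c=120.0, theta_c=math.radians(65.0), d_c=420.0)
echo = generate_echo_phantom(spec, fov)
frame, truth = render_display_frame(echo, canvas=(600, 800))

est = estimate_fov_geometry(frame.data)          # recover geometry from pixels
back = reverse_scan_convert(frame, est, out_shape=(256, 192))

model = TimingModel(t_transfer=25.0, t_irp=4.0, layer_times=(20.0, 20.0, 20.0))
fsc, fac = simulate_fsc(model, 400), simulate_fac(model, 400)
```

This prints (via the obvious `print` statements):

```
true  theta_c=65.00 deg  r_c=120.0  d_c=420.0  apex=(400.0, -91.2)
est   theta_c=64.82 deg  r_c=120.1  d_c=420.1  apex=(400.0, -91.3)  kind=convex
RSC grid (256, 192), MAE vs source echo: 11.38 intensity levels
FSC: 15.62 fps, 15.62 classifications/s
FAC: 40.00 fps, 13.33 classifications/s, M=3
```

The geometry is recovered to 0.2° and 0.1 px from the pixels alone. The
11-level round-trip MAE on this *speckled* phantom is interpolation smoothing
of sub-pixel speckle texture; on smooth phantoms the round trip is accurate
to ~0.3 intensity levels with normalized cross-correlation ≈ 0.998. The
scheduler rows show the FSC/FAC trade: with a 25 ms transfer period, a 4 ms
rendering pipeline and a 60 ms classifier, synchronous classification drags
imaging to 15.6 fps, while splitting the classifier into M = 3 sub-pipelines
restores 40 fps imaging at 13.3 classifications/s.

## Command line

```sh
usrsc phantom --classes liver,kidney,gallbladder --n 50 --seed 7 --out data/
usrsc extract-fov frame.png --out fov.json
usrsc rsc frame.png --fov fov.json --shape 256x256 --out echo.png
usrsc dsc echo.png --fov fov.json --canvas 600x800 --out display.png
usrsc build-dataset --manifest data/manifest.csv --variant both --out built/
usrsc schedule --model model.yaml --mode fac --frames 1000 --out result.json
```

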