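# Methods

## Problem setting

A convex- or sector-array B-mode ultrasound frame is acquired on a polar
grid — `W` scanlines (beam directions) by `H` radial echo samples — and then
resampled by the digital scan converter (DSC) onto a Cartesian raster for
display. The displayed field of view (FOV) is an annular sector parameterized
by the virtual apex position `(x_offset, y_offset)`, the transducer radius
`r_c` (apex to FOV top), the opening angle `theta_c` and the imaging depth
`d_c`, all in display pixels.

Reverse scan conversion (RSC) undoes the DSC: it recovers the polar
("echo-memory") representation from an already scan-converted display frame.
Training an image classifier on RSC images rather than display crops removes
the FOV outline — a probe-specific shape a network can otherwise learn as a
spurious feature — and uses every pixel of the rectangular input for echo
content. The package implements the full chain: FOV geometry extraction from
a display frame, the exact coordinate transforms, the resampling in both
directions, a synthetic phantom generator to exercise everything with known
ground truth, a dataset-building pipeline, and a discrete-event simulator of
how classification inference can be interleaved with real-time imaging.

## Coordinate transforms

Display coordinates are 0-based, continuous, pixel-centered; `y` grows
downward, so the beam axis points along `+y`. The polar grid follows the
echo-memory layout (columns = scanlines, rows = radial samples) and is
endpoint-inclusive: index `a = 0` lies on the left boundary scanline at beam
angle `−theta_c/2`, `a = W−1` on the right at `+theta_c/2`, `r = 0` at radius
`r_c` and `r = H−1` at `r_c + d_c`. Grid spacings are therefore
`dr = d_c/(H−1)` and `dtheta = theta_c/(W−1)`; this places the grid corners
exactly on the FOV outline, which the property tests assert to 1e−9. The
forward map is

    x = (r_c + r·dr)·sin(−theta_c/2 + a·dtheta) + x_offset
    y = (r_c + r·dr)·cos(−theta_c/2 + a·dtheta) + y_offset

and the inverse uses `arctan2` of the apex-relative coordinates (angle from
the downward axis) and the Euclidean radius. The pair is exact to floating
precision; round-trip error on random geometries measures ~1e−12 in index
units. The single degenerate input is the apex itself when `r_c = 0`, where
the beam angle is undefined; the scalar API raises a dedicated error there.

## Resampling

Both scan-conversion directions are implemented as *inverse* mappings: every
output pixel computes its continuous source position through the transform
and samples the source image bilinearly. This is the natural formulation for
the reverse direction and, unlike forward splatting, assigns every output
pixel by construction — there are no holes to fill, which is a deliberate
divergence from pipelines that forward-map and then patch unassigned pixels.

Numerical policy: source positions outside the source bounds return 0 (black
background, no extrapolation); the 2×2 stencil clamps to edge pixels at the
border; bilinear weights make every output a convex combination of its four
neighbors, so resampling can never overshoot the local intensity range
(property-tested). Downsampling to the classifier input size (default 64×64)
is plain bilinear with pixel-center alignment — output pixel `j` samples the
source at `(j + 0.5)·W_in/W_out − 0.5` — and applies no anti-aliasing
prefilter; the vectorized sampler is verified bit-for-float against a scalar
per-pixel reference implementation.

A forward-then-reverse round trip at matched grid resolution loses only
interpolation smoothing: on smooth (speckle-free) phantoms the mean absolute
error measures ~0.3 intensity levels (8-bit) and normalized cross-correlation
~0.998, evaluated ≥10 samples away from grid edges where the two
interpolation passes see incomplete stencils.

## FOV geometry extraction

Extraction assumes the ultrasound image region (UIR) crop rectangle is given
as configuration (display layouts are fixed per device; automatic removal of
on-screen annotations is out of scope) and proceeds:

1. **Binarize** the cropped UIR at a configurable threshold (default
   `intensity > 0`, i.e. a pure black background).
2. **Boundary lines.** A line Hough transform (1° angular, 1 px radial
   accumulator) runs on the morphological boundary of the mask (mask minus
   its erosion). Peaks closer than 5° to vertical or farther than 88° are
   discarded; the highest-support peak on each side of the mask centroid
   gives the left (s1) and right (sN) boundary scanline candidates. Each is
   then refined by a total-least-squares fit to its inlier boundary pixels
   (two passes, 2 px inlier band) — the accumulator quantization alone is too
   coarse for sub-degree accuracy — and pushed half a pixel along its outward
   normal, since boundary pixel *centers* sit on average half a pixel inside
   the true edge.
3. **Apex and angle.** The apex is the line intersection; `theta_c` is the
   angle subtended at the apex between the two boundary directions, each
   oriented from the apex toward its inlier centroid (robust for any opening
   angle below 180°).
4. **Radii.** The raw minimum/maximum apex distances over foreground pixel
   centers are biased inward — near a narrow sector tip no pixel center lies
   closer than about `1/sqrt(theta_c)` px to the apex. Both radii are instead
   extrapolated from the pixel count in a thin annulus band
   (`count ≈ theta_c/2 · (rho² − r_c²)` for uniformly gridded pixel centers,
   using the 80 nearest/farthest pixels), clamped within 2.5 px of the raw
   extremes so foreground holes (e.g. anechoic structures touching an arc)
   cannot drag the estimate far.
5. **Classification.** `r_c < 5 px` classifies the FOV as a sector array;
   boundary detection failing, or boundary angles within 2° of parallel,
   falls back to a linear (rectangular) geometry spanning the foreground
   bounding box.

Measured accuracy on rendered speckle phantoms: `theta_c` within ~0.4°, all
pixel parameters within ~1.3 px across transducer radii 0–150 px and opening
angles 40–90°; estimation is fully deterministic. The estimate inherits two
symmetries of the problem, verified in tests: left-right mirroring reflects
the apex about the crop midline, and integer upscaling scales the pixel
parameters while preserving the angle.

## Synthetic phantoms

The generator emulates the *geometry and first-order statistics* of B-mode
frames, not acoustics. Fully developed speckle has a Rayleigh-distributed
envelope; each pixel draws a unit-scale Rayleigh variate, log-compresses it
(`log1p(3e)`, a display-style dynamic-range compression), and scales by the
region's target mean divided by `E[log1p(3e)]` (computed once by quadrature),
so region sample means land on their 8-bit targets without calibration runs.
Elliptical inclusions come in three contrast modes — anechoic (mean 4,
fluid-like), hypoechoic (half the background mean) and hyperechoic (mean 235,
near saturation) — painted last-wins. Class recipes for the labeled dataset
("liver" = uniform speckle, "gallbladder" = large anechoic ellipse,
"kidney" = hypoechoic ellipse with a bright rim) are caricatures sufficient
to exercise the pipeline and give a classifier a learnable signal; they are
not anatomically validated. Everything is seeded and bit-reproducible.

What passing tests on phantoms therefore shows: the geometry chain is correct
and the pipeline is lossless where it claims to be. What it does not show:
robustness to real-device artifacts (annotation overlays intruding into the
FOV, compression noise, grayscale maps other than black-background), which
the phantom does not model.

## Dataset pipeline

`build_training_set` maps a manifest of labeled display frames to 64×64
training images in two variants: `rsc` (geometry → reverse scan convert to an
intermediate 256×256 polar grid → downsample) and `usi` (crop → downsample,
the baseline that keeps the FOV shape). Geometry is estimated once per source
directory by default (fixed-probe assumption) with a per-frame flag for mixed
acquisitions, or supplied per row to skip estimation. Failures are recorded
as `skipped:<reason>` rows without aborting the batch, and the pipeline is a
pure function of its inputs — re-runs are bit-identical. The intermediate
256×256 resolution comfortably oversamples a 64×64 target while keeping the
two-stage interpolation cheap.

## Scheduling simulation

The simulator models a mobile imaging device where one GPU runs both the
image-rendering pipeline (IRP, `t_irp` ms per frame) and classifier inference,
while frames arrive over a fixed transfer period `t_transfer` ms. Tasks are
non-preemptive. Frame-synchronous classification (FSC) runs the whole
classification pipeline (CP) after every IRP: the frame period becomes
`max(t_transfer, t_irp + t_cp)`. Frame-asynchronous classification (FAC)
splits the CP's layer list, order-preserving and greedy, into M sub-pipelines
each fitting the per-frame idle window `t_transfer − t_irp`, and runs one per
frame: imaging proceeds at the transfer rate and one classification completes
every M frames, so the rates balance as `f_image ≈ M · f_cp` (simulated
residual < 1/n_frames, limited only by edge effects of measuring mean rates
over a finite run). Greedy packing is optimal for contiguous partitions, and
a single layer exceeding the budget forms its own flagged, overrunning sCP.
An optional truncated-normal per-task jitter (seeded) models execution-time
variance; without it the simulation is exactly deterministic. The worked
example — 25 ms transfer, 4 ms IRP, three 20 ms layers — gives FSC 15.625 fps
vs FAC 40 fps (×2.56) at a classification-rate cost of 15.6 → 13.3 per
second. The simulator assumes data transfer is independent of the GPU; rates
are measured from event timestamps, not formulas.

## Problem sizes

Default test and acceptance runs use 200×160 echo grids rendered to
500×600–600×800 canvases, 27 + 100 frames for geometry recovery, 30 frames
for the pipeline determinism check, and 3×200 frames for the classifier
comparison, with 400-frame scheduler runs — sizes at which every measured
quantity is stable at its stated tolerance on a single CPU.

## Known limitations

- Steered-linear (trapezoidal) FOVs and multi-FOV frames are unsupported;
  geometry is display-pixel based (no mm calibration).
- The binarization default assumes a black background; noisy screenshots
  need a raised threshold.
- The linear-FOV path is a crop-and-resize fallback, with geometry limited
  to the bounding rectangle.
- The classifier comparison is an indicative synthetic analog: phantom
  classes are far more separable than clinical organ images.
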