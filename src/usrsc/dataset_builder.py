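"""End-to-end training-set builder: display frames in, 64x64 images out.

Two variants per source frame:

* ``rsc`` — estimate (or accept) the FOV geometry, reverse scan convert the
  frame to an intermediate polar grid, then bilinearly downsample to the
  network input size.  The FOV outline disappears: every output pixel carries
  echo content.
* ``usi`` — the baseline: crop the UIR rectangle and downsample it directly,
  keeping the FOV shape (and its black corners) in the image.

Failures (no foreground, degenerate geometry, unreadable file) are recorded
as ``skipped:<reason>`` rows and never abort the batch.  The pipeline is a
pure function of (inputs, config): re-runs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import USRSCError
from .fov_extraction import (
    ExtractionConfig,
    UIRCrop,
    binarize_uir,
    estimate_fov_geometry,
)
from .geometry import FOVGeometry
from .scan_conversion import (
    downsample_image,
    read_image,
    reverse_scan_convert,
    to_uint8,
    write_image,
)

VARIANTS = ("rsc", "usi")


@dataclass(frozen=True)
class BuildConfig:
    """Pipeline configuration.

    crop: UIR rectangle within each frame (None = full frame).
    out_shape: final image size fed to a classifier (the 64 x 64 default).
    rsc_shape: intermediate polar-grid resolution before the final resize.
    per_frame_geometry: estimate geometry for every frame instead of once per
        source directory (the default assumes a fixed probe per acquisition).
    """

    crop: UIRCrop | None = None
    out_shape: tuple[int, int] = (64, 64)
    rsc_shape: tuple[int, int] = (256, 256)
    variants: tuple[str, ...] = VARIANTS
    per_frame_geometry: bool = False
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise USRSCError(f"unknown variant {v!r}")


def _geometry_columns(fov: FOVGeometry | None) -> dict:
    if fov is None:
        return {
            "kind": None,
            "x_offset": None,
            "y_offset": None,
            "r_c": None,
            "theta_c_deg": None,
            "d_c": None,
        }
    return {
        "kind": fov.kind,
        "x_offset": fov.x_offset,
        "y_offset": fov.y_offset,
        "r_c": fov.r_c,
        "theta_c_deg": math.degrees(fov.theta_c) if fov.is_polar else None,
        "d_c": fov.d_c,
    }


def build_frame(
    frame: np.ndarray,
    variant: str,
    config: BuildConfig,
    fov: FOVGeometry | None = None,
) -> tuple[np.ndarray, FOVGeometry | None]:
    """Process one frame through one variant; returns (uint8 image, geometry).

    The RSC variant estimates geometry when none is supplied; the USI variant
    needs none (pure crop + downsample).
    """
    crop = config.crop or UIRCrop.full_frame(frame)
    if variant == "usi":
        # validate there is any echo content; an all-background frame is skipped
        binarize_uir(frame, crop, config.extraction.threshold)
        region = np.asarray(frame, float)[crop.slice()]
        return to_uint8(downsample_image(region, config.out_shape)), fov
    if variant != "rsc":
        raise USRSCError(f"unknown variant {variant!r}")
    if fov is None:
        fov = estimate_fov_geometry(frame, crop, config.extraction)
    echo = reverse_scan_convert(frame, fov, config.rsc_shape)
    return to_uint8(downsample_image(echo.data, config.out_shape)), fov


def build_training_set(
    input_manifest: pd.DataFrame | str | Path,
    out_dir: str | Path,
    config: BuildConfig | None = None,
) -> pd.DataFrame:
    """Run the dataset-building pipeline over an input manifest.

    ``input_manifest`` is a DataFrame (or CSV path) with columns ``file`` and
    ``label``, optionally ``fov_json`` pointing at a saved geometry to skip
    estimation.  Writes one 8-bit PNG per (frame, variant) into ``out_dir``
    plus ``manifest.csv``, and returns the output manifest with per-row
    status (``ok`` or ``skipped:<reason>``).
    """
    config = config or BuildConfig()
    if not isinstance(input_manifest, pd.DataFrame):
        input_manifest = pd.read_csv(input_manifest)
    if len(input_manifest) == 0:
        raise USRSCError("empty input manifest")
    if not {"file", "label"}.issubset(input_manifest.columns):
        raise USRSCError("input manifest needs 'file' and 'label' columns")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dir_geometry: dict[str, FOVGeometry] = {}
    rows = []
    for _, rec in input_manifest.iterrows():
        src = Path(rec["file"])
        label = rec["label"]
        fov_provided: FOVGeometry | None = None
        if "fov_json" in rec.index and isinstance(rec.get("fov_json"), str):
            fov_provided = FOVGeometry.load(rec["fov_json"])
        try:
            frame = read_image(src)
        except (OSError, ValueError) as err:
            for variant in config.variants:
                rows.append(
                    {
                        "source": str(src),
                        "label": label,
                        "variant": variant,
                        "output": None,
                        "status": f"skipped:unreadable ({err.__class__.__name__})",
                        **_geometry_columns(None),
                    }
                )
            continue
        for variant in config.variants:
            fov = fov_provided
            if fov is None and variant == "rsc" and not config.per_frame_geometry:
                key = str(src.parent)
                if key in dir_geometry:
                    fov = dir_geometry[key]
            out_path = out_dir / f"{src.stem}_{variant}.png"
            try:
                img, fov_used = build_frame(frame, variant, config, fov)
            except USRSCError as err:
                rows.append(
                    {
                        "source": str(src),
                        "label": label,
                        "variant": variant,
                        "output": None,
                        "status": f"skipped:{_reason(err)}",
                        **_geometry_columns(None),
                    }
                )
                continue
            if (
                variant == "rsc"
                and fov is None
                and fov_used is not None
                and not config.per_frame_geometry
            ):
                dir_geometry[str(src.parent)] = fov_used
            write_image(out_path, img)
            rows.append(
                {
                    "source": str(src),
                    "label": label,
                    "variant": variant,
                    "output": str(out_path),
                    "status": "ok",
                    **_geometry_columns(fov_used),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _reason(err: Exception) -> str:
    from .exceptions import BoundaryDetectionError, EmptyMaskError

    if isinstance(err, EmptyMaskError):
        return "no-foreground"
    if isinstance(err, BoundaryDetectionError):
        return "no-boundary"
    return err.__class__.__name__
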