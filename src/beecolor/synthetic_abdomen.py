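"""Synthetic abdomen ROI images and profiles with known group structure.

The generator emulates the features of a stereo-microscope abdomen image
that the extraction pipeline actually reacts to: dark cuticle background,
periodic tergite bands along the long axis with darkened seams, brighter
"yellow" marks on the anterior tergites, saturated specular highlights, and
pixel noise.  Images are gray (R = G = B): the pipeline averages the
channels before any analysis, so hue carries no information through it and
"yellow" is modelled purely as brightness.

Group structure follows the 2 x 2 design (colony origin gray/yellow x
incubation temperature 30/34 C, default 50 specimens per cell, 200 total):

* ``origin_effect`` — extra brightness carried by the yellow colony's
  anterior tergite marks, parameterized as the mean-gray shift it produces
  over the whole profile (the per-pixel increment inside the marks is
  ``origin_effect / mark_coverage``);
* ``temperature_effect`` — global additive brightness for the 34 C groups;
* ``specimen_sd`` — per-specimen global brightness jitter, the dominant
  source of within-group index variance (pixel noise is largely cancelled
  by the column medians).

Defaults are calibrated so the default dataset lands on a realistic scale:
base gray 0.22 puts group index means near 435-455 at profile length 1998,
specimen_sd 0.01 gives within-group index SDs near 20, origin_effect 0.006
a colony gap near 12 index units, and temperature_effect 0.002 a small
(~0.2 within-group SD) temperature signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coloration_index import coloration_index, group_label
from .image_io import RGBImage, ROIRect, write_image, write_roi_table
from .profile_extraction import (
    DEFAULT_TARGET_LENGTH,
    ColorationProfile,
    equalize_length,
)

__all__ = [
    "SynthParams",
    "GroupDesign",
    "SimulatedDataset",
    "generate_abdomen_image",
    "generate_dataset",
    "generate_profiles",
]


@dataclass(frozen=True)
class SynthParams:
    """Geometry and texture of one synthetic abdomen image."""

    width: int = 1998
    height: int = 300
    base_gray: float = 0.22
    n_tergites: int = 5
    seam_darkening: float = 0.05
    seam_fraction: float = 0.06  # fraction of a segment darkened at each seam
    yellow_amplitude: float = 0.0  # per-pixel mark brightness (standalone use)
    yellow_band_fraction: float = 0.3  # anterior fraction of a marked segment
    n_yellow_tergites: int = 3
    highlight_fraction: float = 0.0
    noise_sd: float = 0.02
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 1:
            raise ValueError("width must be >= 2 and height >= 1")
        if not 0 < self.base_gray <= 0.95:
            raise ValueError("base_gray must be in (0, 0.95]")
        if self.base_gray + self.yellow_amplitude > 0.95:
            raise ValueError(
                "base_gray + yellow_amplitude must not exceed 0.95 "
                "(marks would be masked wholesale)"
            )
        for name in ("seam_fraction", "yellow_band_fraction", "highlight_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.seam_darkening < 0 or self.yellow_amplitude < 0:
            raise ValueError("noise_sd, seam_darkening and yellow_amplitude must be >= 0")
        if self.n_tergites < 1:
            raise ValueError("n_tergites must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class GroupDesign:
    """The 2 x 2 experimental design and its injected effects (gray scale)."""

    n_per_group: int = 50
    origin_effect: float = 0.006
    temperature_effect: float = 0.002
    specimen_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in ("origin_effect", "temperature_effect", "specimen_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class SimulatedDataset:
    meta: pd.DataFrame
    rois: list[ROIRect]
    truth: pd.DataFrame  # specimen_id, truth_index
    images: list[RGBImage] | None = None
    image_dir: Path | None = None


def _template(width: int, p: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free column brightness template and the yellow-mark column mask.

    The template tiles the width into ``n_tergites`` segments, darkens the
    seams between them, and flags the anterior ``yellow_band_fraction`` of
    the first ``n_yellow_tergites`` segments as mark columns (brightness is
    added by the caller).
    """
    v = np.full(width, p.base_gray, dtype=float)
    bounds = np.round(np.linspace(0, width, p.n_tergites + 1)).astype(int)
    seg_len = width / p.n_tergites
    half = int(round(p.seam_fraction * seg_len / 2))
    for b in bounds[1:-1]:
        lo, hi = max(0, b - half), min(width, b + half)
        v[lo:hi] -= p.seam_darkening
    mark = np.zeros(width, dtype=bool)
    n_marked = min(p.n_yellow_tergites, p.n_tergites)
    for i in range(n_marked):
        lo = bounds[i]
        hi = lo + int(round(p.yellow_band_fraction * (bounds[i + 1] - lo)))
        mark[lo:hi] = True
    np.clip(v, 0.0, 0.95, out=v)
    return v, mark


def _mark_increment(mark: np.ndarray, mean_shift: float) -> float:
    """Per-pixel increment inside the marks producing ``mean_shift`` overall."""
    n_mark = int(mark.sum())
    if mean_shift == 0.0:
        return 0.0
    if n_mark == 0:
        raise ValueError("origin effect requested but no mark columns exist")
    return mean_shift * mark.size / n_mark


def generate_abdomen_image(
    params: SynthParams,
    specimen_id: str = "synthetic",
    mark_amplitude: float | None = None,
    brightness_offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[RGBImage, np.ndarray]:
    """Render one synthetic abdomen image and its ground-truth profile.

    The ground truth is the noise- and highlight-free column brightness,
    quantized to the image bit depth — exactly what the extraction pipeline
    recovers from a clean image.

    Returns ``(image, truth)`` where ``truth`` has length ``params.width``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if mark_amplitude is None:
        mark_amplitude = params.yellow_amplitude
    maxval = 2**params.bit_depth - 1
    col, mark = _template(params.width, params)
    col = col + mark_amplitude * mark + brightness_offset
    np.clip(col, 0.0, 0.95, out=col)
    truth = np.round(col * maxval) / maxval

    field_ = np.broadcast_to(col, (params.height, params.width))
    if params.noise_sd > 0:
        field_ = field_ + rng.normal(0.0, params.noise_sd, field_.shape)
    else:
        field_ = field_.copy()
    np.clip(field_, 0.0, 1.0, out=field_)
    pix = np.round(field_ * maxval)
    if params.highlight_fraction > 0:
        hl = rng.random(field_.shape) < params.highlight_fraction
        pix[hl] = maxval
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    pixels = np.repeat(pix.astype(dtype)[:, :, None], 3, axis=2)
    img = RGBImage(pixels=pixels, bit_depth=params.bit_depth, image_id=specimen_id)
    return img, truth


def _design_iter(design: GroupDesign, rng: np.random.Generator):
    """Yield (specimen_id, colony, temperature, brightness_offset, mark_shift)."""
    for temp in (30, 34):
        for colony in ("gray", "yellow"):
            for i in range(design.n_per_group):
                sid = f"{group_label(colony, temp)}_{i:03d}"
                offset = float(rng.normal(0.0, design.specimen_sd))
                if temp == 34:
                    offset += design.temperature_effect
                shift = design.origin_effect if colony == "yellow" else 0.0
                yield sid, colony, temp, offset, shift


def generate_dataset(
    design: GroupDesign = GroupDesign(),
    params: SynthParams = SynthParams(),
    out_dir: str | Path | None = None,
    target_length: int | None = None,
) -> SimulatedDataset:
    """Simulate the full 2 x 2 image dataset.

    Abdomen widths are drawn uniformly from [0.75 * width, width] so the
    length-equalization path is exercised; the ROI table covers each full
    frame.  With ``out_dir`` set, images are written as PNG (8-bit) or TIFF
    (16-bit) together with rois.csv, meta.csv and truth.csv and are not kept
    in memory; otherwise the images are returned in the dataset object.

    ``truth.csv`` holds the coloration index of each specimen's ground-truth
    profile after equalization to ``target_length`` (default: the maximum
    width).
    """
    rng = np.random.default_rng(design.seed)
    L = target_length if target_length is not None else params.width
    out_path = Path(out_dir) if out_dir is not None else None
    suffix = ".png" if params.bit_depth == 8 else ".tif"
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    meta_rows, rois, truth_rows = [], [], []
    images: list[RGBImage] | None = None if out_path is not None else []
    min_width = int(math.ceil(0.75 * params.width))
    for sid, colony, temp, offset, shift in _design_iter(design, rng):
        width = int(rng.integers(min_width, params.width + 1))
        img_seed = int(rng.integers(0, 2**31))
        p = SynthParams(**{**params.__dict__, "width": width, "seed": img_seed})
        _, mark = _template(width, p)
        amplitude = _mark_increment(mark, shift) if shift else 0.0
        img, truth_profile = generate_abdomen_image(
            p, specimen_id=sid, mark_amplitude=amplitude, brightness_offset=offset
        )
        fixed = equalize_length(ColorationProfile(truth_profile, sid), L)
        truth_rows.append({"specimen_id": sid, "truth_index": coloration_index(fixed)})
        meta_rows.append({"specimen_id": sid, "colony": colony, "temperature": temp})
        rois.append(ROIRect(image_id=sid, x0=0, y0=0, x1=width, y1=params.height))
        if out_path is not None:
            write_image(img, out_path / "images" / f"{sid}{suffix}")
        else:
            images.append(img)

    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        write_roi_table(rois, out_path / "rois.csv")
        meta.to_csv(out_path / "meta.csv", index=False)
        truth.to_csv(out_path / "truth.csv", index=False)
    return SimulatedDataset(
        meta=meta, rois=rois, truth=truth, images=images, image_dir=out_path
    )


def generate_profiles(
    design: GroupDesign = GroupDesign(),
    target_length: int = DEFAULT_TARGET_LENGTH,
    noise_sd: float = 0.005,
    params: SynthParams = SynthParams(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fast path: draw fixed-length profiles directly, skipping rasterization.

    The group structure is identical to :func:`generate_dataset`; per-column
    noise with SD ``noise_sd`` stands in for what pixel noise leaves behind
    after the column medians.  With ``noise_sd = 0`` and
    ``design.specimen_sd = 0`` every profile equals its group template
    exactly.

    Returns ``(X, meta)`` with ``X`` of shape (4 * n_per_group, target_length).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(design.seed)
    p = SynthParams(**{**params.__dict__, "width": target_length})
    base, mark = _template(target_length, p)
    profiles, meta_rows = [], []
    for sid, colony, temp, offset, shift in _design_iter(design, rng):
        amplitude = _mark_increment(mark, shift) if shift else 0.0
        v = base + amplitude * mark + offset
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, target_length)
        np.clip(v, 0.0, 0.95, out=v)
        profiles.append(v)
        meta_rows.append({"specimen_id": sid, "colony": colony, "temperature": temp})
    return np.asarray(profiles), pd.DataFrame(meta_rows)
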