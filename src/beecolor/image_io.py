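"""Reading, writing and cropping abdomen images and ROI tables.

Coordinate convention used throughout the package: pixel indices are 0-based
and rectangles are half-open, ``[x0, x1) x [y0, y1)``.  The x-axis (columns)
is the abdomen's long axis, anterior at ``x0``; every downstream profile has
length ``x1 - x0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "RGBImage",
    "ROIRect",
    "read_image",
    "write_image",
    "crop_roi",
    "compose_rois",
    "read_roi_table",
    "write_roi_table",
]

_DTYPE_FOR_DEPTH = {8: np.uint8, 16: np.uint16}
_DEPTH_FOR_DTYPE = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class RGBImage:
    """An H x W x 3 integer image with an explicit bit depth.

    Attributes
    ----------
    pixels : ndarray of uint8 or uint16, shape (H, W, 3)
    bit_depth : int
        8 or 16; all intensities lie in ``[0, 2**bit_depth - 1]``.
    image_id : str
        Identifier used to match the image to its ROI row (file stem on read).
    """

    pixels: np.ndarray
    bit_depth: int
    image_id: str

    def __post_init__(self) -> None:
        if self.bit_depth not in _DTYPE_FOR_DEPTH:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected 3 channels (H, W, 3), got array of shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        expected = _DTYPE_FOR_DEPTH[self.bit_depth]
        if px.dtype != expected:
            raise ValueError(
                f"pixel dtype {px.dtype} does not match bit_depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class ROIRect:
    """Rectangular region of interest, 0-based, half-open."""

    image_id: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"ROI coordinate {name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI for {self.image_id!r} has negative coordinates")
        if self.x0 >= self.x1:
            raise ValueError(f"ROI for {self.image_id!r} requires x0 < x1")
        if self.y0 >= self.y1:
            raise ValueError(f"ROI for {self.image_id!r} requires y0 < y1")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


def read_image(path: str | Path) -> RGBImage:
    """Read a PNG/TIFF/JPEG image as an :class:`RGBImage`.

    The image id is the file stem.  Grayscale or RGBA inputs are rejected:
    the pipeline is defined on 3-channel images only.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface decoder errors with the path
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[-1] != 3:
        n = 1 if arr.ndim == 2 else arr.shape[-1]
        raise ValueError(f"expected 3 channels in {path.name}, got {n}")
    depth = _DEPTH_FOR_DTYPE.get(arr.dtype)
    if depth is None:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path.name}")
    return RGBImage(pixels=arr, bit_depth=depth, image_id=path.stem)


def write_image(img: RGBImage, path: str | Path) -> Path:
    """Write an image losslessly; PNG for 8-bit, TIFF for 8- or 16-bit."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        if img.bit_depth != 8:
            raise ValueError("16-bit RGB PNG is not supported; use .tif")
    elif suffix not in (".tif", ".tiff"):
        raise ValueError(f"unsupported output format {suffix!r}; use .png or .tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.pixels)
    return path


def crop_roi(img: RGBImage, roi: ROIRect) -> RGBImage:
    """Crop ``img`` to ``roi``; pixels are copied, never aliased."""
    if roi.image_id != img.image_id:
        raise ValueError(
            f"ROI image_id {roi.image_id!r} does not match image {img.image_id!r}"
        )
    if roi.x1 > img.width or roi.y1 > img.height:
        raise ValueError(
            f"ROI ({roi.x0},{roi.y0})->({roi.x1},{roi.y1}) exceeds image "
            f"{img.image_id!r} of size {img.width}x{img.height}"
        )
    out = img.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()
    return replace(img, pixels=out)


def compose_rois(outer: ROIRect, inner: ROIRect) -> ROIRect:
    """Absolute rectangle equivalent to cropping ``inner`` out of an
    ``outer`` crop; ``inner`` coordinates are relative to ``outer``."""
    if inner.x1 > outer.width or inner.y1 > outer.height:
        raise ValueError("inner rectangle exceeds outer rectangle")
    return ROIRect(
        image_id=outer.image_id,
        x0=outer.x0 + inner.x0,
        y0=outer.y0 + inner.y0,
        x1=outer.x0 + inner.x1,
        y1=outer.y0 + inner.y1,
    )


_ROI_COLUMNS = ["image_id", "x0", "y0", "x1", "y1"]


def read_roi_table(path: str | Path) -> list[ROIRect]:
    """Read a CSV ROI table (columns image_id,x0,y0,x1,y1), one ROI per image."""
    df = pd.read_csv(path)
    missing = [c for c in _ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table {path} is missing columns: {missing}")
    rois: list[ROIRect] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        coords = {}
        for c in ("x0", "y0", "x1", "y1"):
            v = row[c]
            if pd.isna(v) or float(v) != int(v):
                raise ValueError(f"non-integer coordinate {c}={v!r} at row {rownum}")
            coords[c] = int(v)
        image_id = str(row["image_id"])
        if image_id in seen:
            raise ValueError(
                f"duplicate ROI for image {image_id!r} at row {rownum}; "
                "exactly one ROI per image is expected"
            )
        seen.add(image_id)
        try:
            rois.append(ROIRect(image_id=image_id, **coords))
        except ValueError as exc:
            raise ValueError(f"invalid ROI at row {rownum}: {exc}") from exc
    return rois


def write_roi_table(rois: list[ROIRect], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{c: getattr(r, c) for c in _ROI_COLUMNS} for r in rois]
    ).to_csv(path, index=False)
    return path
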