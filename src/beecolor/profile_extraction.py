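"""From ROI image to fixed-length coloration profile.

The coloration profile of an abdomen is the vector of per-column median gray
values along the long axis: the three color channels are averaged into a
grayscale matrix on an absolute [0, 1] scale, saturated pixels (> 0.95) and
desaturated pixels (== 0) are masked out, each pixel column is collapsed to
the median of its unmasked values, and the resulting vector is resampled to a
common length so abdomens of different pixel lengths become comparable.

Masking excludes pixels from the median rather than zero-filling them;
zero-filling would bias the profile toward dark.  Normalization divides by
the bit-depth maximum (sensor scale), not the per-image maximum, so the 0.95
saturation cutoff has a fixed physical meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import RGBImage, ROIRect, crop_roi

__all__ = [
    "GrayMatrix",
    "ColorationProfile",
    "FixedProfile",
    "DEFAULT_TARGET_LENGTH",
    "DEFAULT_SAT_THRESHOLD",
    "to_gray",
    "mask_invalid",
    "column_medians",
    "equalize_length",
    "extract_profile",
]

#: Profile length all specimens are resampled to.  The value is
#: data-dependent (the longest abdomen in a study sets it); 1998 columns is a
#: typical half-abdomen width at 8x stereo-microscope magnification.
DEFAULT_TARGET_LENGTH = 1998

#: Normalized gray value above which a pixel counts as saturated.
DEFAULT_SAT_THRESHOLD = 0.95


@dataclass
class GrayMatrix:
    """Normalized grayscale matrix with an exclusion mask (True = excluded)."""

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GrayMatrix values must be 2-D (H x W)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("GrayMatrix values must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")


@dataclass
class ColorationProfile:
    """Per-column median profile at native ROI width; NaN marks columns whose
    pixels were all masked."""

    values: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("profile values must lie in [0, 1]")


@dataclass
class FixedProfile:
    """Complete profile resampled to a fixed length (no missing entries)."""

    values: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fixed-length profile must have no missing entries")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("profile values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


def to_gray(img: RGBImage) -> GrayMatrix:
    """Average the three channels and normalize by the bit-depth maximum.

    The unweighted channel mean is used deliberately (not a luminance
    weighting): the quantity of interest is raw sensor brightness, and the
    saturation cutoff downstream is defined on that scale.
    """
    values = img.pixels.astype(float).mean(axis=2) / img.max_value
    return GrayMatrix(values=values)


def mask_invalid(
    gm: GrayMatrix, sat_threshold: float = DEFAULT_SAT_THRESHOLD
) -> GrayMatrix:
    """Mask saturated (strictly above ``sat_threshold``) and desaturated
    (exactly zero) pixels.  Values are left untouched."""
    if not 0 < sat_threshold <= 1:
        raise ValueError(f"sat_threshold must be in (0, 1], got {sat_threshold}")
    mask = gm.mask | (gm.values > sat_threshold) | (gm.values == 0.0)
    return GrayMatrix(values=gm.values.copy(), mask=mask)


def column_medians(gm: GrayMatrix, specimen_id: str = "") -> ColorationProfile:
    """Collapse each pixel column to the median of its unmasked values.

    A fully masked column yields NaN (filled later by interpolation).  An
    even count of unmasked pixels takes the mean of the two middle values.
    """
    if gm.mask.all():
        raise ValueError("every pixel is masked; no profile can be extracted")
    ma = np.ma.masked_array(gm.values, mask=gm.mask)
    med = np.ma.median(ma, axis=0)
    values = np.ma.filled(med, np.nan)
    return ColorationProfile(values=values, specimen_id=specimen_id)


def equalize_length(
    p: ColorationProfile, target_length: int = DEFAULT_TARGET_LENGTH
) -> FixedProfile:
    """Fill missing entries and resample the profile to ``target_length``.

    Interior gaps are filled by linear interpolation between the nearest
    non-missing neighbours; leading/trailing gaps take the nearest value.
    The complete profile is then resampled by linear interpolation over
    normalized position in [0, 1].  A complete profile already at the target
    length passes through unchanged.
    """
    if target_length < 2:
        raise ValueError("target_length must be at least 2")
    v = p.values
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError(
            f"profile {p.specimen_id!r} has fewer than 2 usable columns"
        )
    idx = np.arange(v.size)
    filled = np.interp(idx, idx[finite], v[finite]) if not finite.all() else v
    src = np.linspace(0.0, 1.0, v.size)
    dst = np.linspace(0.0, 1.0, target_length)
    out = np.interp(dst, src, filled)
    return FixedProfile(values=out, specimen_id=p.specimen_id)


def extract_profile(
    img: RGBImage,
    roi: ROIRect | None = None,
    target_length: int = DEFAULT_TARGET_LENGTH,
    sat_threshold: float = DEFAULT_SAT_THRESHOLD,
    max_masked_fraction: float = 0.5,
) -> FixedProfile:
    """Full extraction: crop -> gray -> mask -> column medians -> equalize.

    Parameters
    ----------
    roi
        Rectangle to crop first; ``None`` uses the whole image.
    max_masked_fraction
        Reject the specimen if more than this fraction of columns is fully
        masked (e.g. a specular highlight saturating whole columns); below
        the cutoff such columns are interpolated over, with a warning.
    """
    if roi is not None:
        img = crop_roi(img, roi)
    gm = mask_invalid(to_gray(img), sat_threshold=sat_threshold)
    profile = column_medians(gm, specimen_id=img.image_id)
    n_missing = int(np.isnan(profile.values).sum())
    if n_missing:
        frac = n_missing / profile.values.size
        if frac > max_masked_fraction:
            raise ValueError(
                f"specimen {img.image_id!r}: {n_missing} of "
                f"{profile.values.size} columns fully masked "
                f"({frac:.0%} > {max_masked_fraction:.0%}); rejecting"
            )
        warnings.warn(
            f"specimen {img.image_id!r}: {n_missing} fully masked column(s) "
            "filled by interpolation",
            stacklevel=2,
        )
    return equalize_length(profile, target_length=target_length)
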