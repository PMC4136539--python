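"""Dust-pattern quantification on registered body-part images.

The experimental pipeline photographs dissected body parts of dusted flies,
registers them to a standard, and binarizes dust-positive pixels.  This
module implements the downstream quantification on such binary rasters:

* **groomogram** — per-pixel average of the binary images across subjects,
  giving the fraction of flies dusted at each coordinate;
* **region fractions** — dust pixels over total pixels inside a binary
  region mask;
* **time-course normalization** — either dividing every sample by the mean
  of the zero-time samples of its body part, or dividing per-condition
  means by the maximum mean of that body part.

Images are assumed pre-registered: dimensions must match exactly and no
resampling is performed.  The binary convention is 0/1 (the 8-bit 0/255
convention is applied only when writing image files).  Coordinates are
row-major with the origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DustImage",
    "RegionMask",
    "DustMap",
    "binarize",
    "average_projection",
    "region_dust_fraction",
    "normalize_timecourse",
]


def _check_binary(pixels: np.ndarray, what: str) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"{what} must be a 2-D grid, got shape {pixels.shape}")
    vals = np.unique(pixels)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{what} must be binary (0/1); found values {vals[:5]}")
    return pixels.astype(np.uint8)


@dataclass(frozen=True)
class DustImage:
    """Binary dust raster of one subject's body part (1 = dust, 0 = clean)."""

    pixels: np.ndarray
    body_part: str = ""
    subject_id: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_binary(self.pixels, "DustImage.pixels"))
        if self.time_min < 0:
            raise ValueError("time_min must be nonnegative")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class RegionMask:
    """Binary region definition used to count dust pixels (1 = inside)."""

    pixels: np.ndarray
    region_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_binary(self.pixels, "RegionMask.pixels"))
        if int(self.pixels.sum()) == 0:
            raise ValueError("a region mask must contain at least one pixel")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class DustMap:
    """Per-pixel fraction of subjects dusted at each coordinate."""

    fractions: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.ndim != 2:
            raise ValueError("DustMap.fractions must be 2-D")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("DustMap values must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "fractions", fr)

    @property
    def shape(self):
        return self.fractions.shape


def binarize(
    raw_image: np.ndarray,
    threshold: float,
    channel: Optional[int] = None,
    body_part: str = "",
    subject_id: str = "",
    time_min: float = 0.0,
) -> DustImage:
    """Threshold a raw intensity or color image into a binary dust image.

    ``channel`` selects a color channel of an (H, W, C) image before
    thresholding; grayscale input needs none.  A pixel is dust-positive when
    its intensity is strictly greater than ``threshold``, which makes the
    operation idempotent on already-binary 0/1 input for any threshold in
    (0, 1).  The exact color criterion for dust is caller-defined.
    """
    raw = np.asarray(raw_image)
    if raw.ndim == 3:
        if channel is None:
            raise ValueError("color images need an explicit channel")
        if not 0 <= channel < raw.shape[2]:
            raise ValueError(f"channel {channel} out of range for shape {raw.shape}")
        raw = raw[:, :, channel]
    elif raw.ndim != 2:
        raise ValueError(f"malformed image of shape {raw.shape}")
    pixels = (raw.astype(float) > threshold).astype(np.uint8)
    return DustImage(pixels, body_part=body_part, subject_id=subject_id, time_min=time_min)


def average_projection(stack: Sequence[DustImage]) -> DustMap:
    """Per-pixel mean over a stack of binary images from different subjects.

    The result at each pixel equals the fraction of subjects dusted there.
    All images must share dimensions and body part.
    """
    if len(stack) == 0:
        raise ValueError("empty image stack")
    shape = stack[0].shape
    part = stack[0].body_part
    for img in stack[1:]:
        if img.shape != shape:
            raise ValueError(f"image dimensions differ: {img.shape} vs {shape}")
        if img.body_part != part:
            raise ValueError(f"mixed body parts in stack: {img.body_part!r} vs {part!r}")
    mean = np.mean([img.pixels for img in stack], axis=0)
    return DustMap(fractions=mean, n_subjects=len(stack))


def region_dust_fraction(image: DustImage, mask: RegionMask) -> float:
    """Dust pixels inside the mask divided by total pixels inside the mask."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} dimensions differ")
    inside = int(mask.pixels.sum())
    dusted = int(np.sum(image.pixels[mask.pixels == 1]))
    return dusted / inside


def normalize_timecourse(
    fractions_by_time: pd.DataFrame,
    mode: str = "zero_time",
    merge_abdomen: bool = False,
    abdomen_parts: Sequence[str] = ("abdomen_ventral", "abdomen_dorsal"),
) -> pd.DataFrame:
    """Normalize per-sample region dust fractions per body part.

    Parameters
    ----------
    fractions_by_time
        Long table with columns ``subject_id, body_part, time_min, fraction``.
    mode
        ``"zero_time"`` divides every sample by the mean of its body part's
        t = 0 samples (so the t = 0 group has mean 1 by construction);
        ``"max_mean"`` divides by the maximum over time of the body part's
        mean fraction (so the dirtiest time point normalizes to 1).
    merge_abdomen
        If True, the two abdomen views listed in ``abdomen_parts`` are
        combined after normalization by averaging their normalized values
        per subject and time point, labeled ``"abdomen"``.

    Returns a copy of the table with a ``normalized`` column.
    """
    required = {"subject_id", "body_part", "time_min", "fraction"}
    missing = required - set(fractions_by_time.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if mode not in ("zero_time", "max_mean"):
        raise ValueError("mode must be 'zero_time' or 'max_mean'")
    out = fractions_by_time.copy()
    denominators = {}
    for part, grp in out.groupby("body_part"):
        if mode == "zero_time":
            zero = grp.loc[grp["time_min"] == 0, "fraction"]
            if zero.empty:
                raise ValueError(f"body part {part!r} has no zero-time samples")
            denom = float(zero.mean())
        else:
            denom = float(grp.groupby("time_min")["fraction"].mean().max())
        if denom == 0:
            raise ValueError(f"zero normalization denominator for body part {part!r}")
        denominators[part] = denom
    out["normalized"] = [
        f / denominators[p] for p, f in zip(out["body_part"], out["fraction"])
    ]
    if merge_abdomen:
        both = out[out["body_part"].isin(abdomen_parts)]
        if not both.empty:
            merged = (
                both.groupby(["subject_id", "time_min"], as_index=False)
                .agg(fraction=("fraction", "mean"), normalized=("normalized", "mean"))
                .assign(body_part="abdomen")
            )
            out = pd.concat(
                [out[~out["body_part"].isin(abdomen_parts)], merged], ignore_index=True
            )
    return out
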