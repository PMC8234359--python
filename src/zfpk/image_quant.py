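"""Mask-based integrated-fluorescence quantification.

The measurement contract is deliberately simple: for a delineated region
of interest, the signal is the sum over member pixels of the
background-corrected intensity, with per-pixel clamping at zero.  Masks
are supplied externally (ground-truth masks from the synthetic renderer,
or PNG masks drawn by hand); automated embryo segmentation is out of
scope because the quantification it replaces used manual delineation.

Coordinates are (row, col) with origin at the top-left.  Masks serialize
as 8-bit PNG where any nonzero pixel is inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .core_data import (
    Compartment,
    RFUPoint,
    RFUSeries,
    Route,
    YOLK_MAX_TIME,
    derive_rob,
)


@dataclass(frozen=True)
class EmbryoImage:
    """A single-channel fluorescence frame.

    ``pixels`` may be integer or float but must lie within the nominal
    range of ``bit_depth``; ``background_level`` is a constant intensity
    offset subtracted (with clamping at zero) during quantification.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    background_level: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        lo, hi = float(px.min(initial=0)), float(px.max(initial=0))
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside {self.bit_depth}-bit range"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CompartmentMasks:
    """Whole-body and yolk regions for one frame; yolk must lie inside WB."""

    wb: np.ndarray
    yolk: np.ndarray

    def __post_init__(self) -> None:
        wb = np.asarray(self.wb, dtype=bool)
        yolk = np.asarray(self.yolk, dtype=bool)
        if wb.shape != yolk.shape:
            raise ValueError(f"mask shapes differ: {wb.shape} vs {yolk.shape}")
        if not wb.any():
            raise ValueError("whole-body mask is empty")
        if (yolk & ~wb).any():
            n = int((yolk & ~wb).sum())
            raise ValueError(
                f"yolk mask extends outside the whole-body mask ({n} pixel(s))"
            )
        object.__setattr__(self, "wb", wb)
        object.__setattr__(self, "yolk", yolk)


def integrated_intensity(image: EmbryoImage, mask: np.ndarray) -> float:
    """Sum of background-corrected intensities over a region of interest.

    Returns sum over masked pixels of max(0, pixel - background_level).
    An empty mask is an error: "no region drawn" must stay distinguishable
    from "region present but dark" (which returns 0).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    if not mask.any():
        raise ValueError("empty mask: no region of interest")
    vals = np.asarray(image.pixels, dtype=float)[mask] - image.background_level
    return float(np.clip(vals, 0.0, None).sum())


def quantify_timecourse(
    compound: str,
    route: Route,
    times: Sequence[float],
    images: Sequence[EmbryoImage],
    masks: Sequence[CompartmentMasks],
) -> tuple[RFUSeries, RFUSeries, RFUSeries]:
    """Quantify a frame sequence into WB, Yolk, and RoB time courses.

    Yolk (and hence RoB) observations are only emitted for t <= 72 h,
    beyond which the yolk contour is no longer discernible; the WB series
    covers all frames.  RoB is derived by subtraction on the yolk grid.
    """
    if not (len(times) == len(images) == len(masks)):
        raise ValueError(
            f"got {len(times)} times, {len(images)} images, {len(masks)} masks"
        )
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError(f"times must be strictly increasing, got {list(times)}")
    wb_points, yolk_points = [], []
    for t, img, mk in zip(times, images, masks):
        wb_points.append(RFUPoint(time=float(t), rfu=integrated_intensity(img, mk.wb)))
        if t <= YOLK_MAX_TIME:
            yolk_points.append(
                RFUPoint(time=float(t), rfu=integrated_intensity(img, mk.yolk))
            )
    wb = RFUSeries(compound, route, Compartment.WB, tuple(wb_points))
    yolk = RFUSeries(compound, route, Compartment.YOLK, tuple(yolk_points))
    wb_on_yolk_grid = wb.with_points(wb_points[: len(yolk_points)])
    rob = derive_rob(wb_on_yolk_grid, yolk)
    return wb, yolk, rob


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_image(path: str | Path, background_level: float = 0.0) -> EmbryoImage:
    """Load a single-channel 8/16-bit TIFF or PNG frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 1:
        px = px[:, :, 0]
    if px.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got {px.shape}")
    depth = 8 if px.dtype == np.uint8 else 16
    return EmbryoImage(px, bit_depth=depth, background_level=background_level)


def write_image(image: EmbryoImage, path: str | Path) -> None:
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    px = np.round(np.asarray(image.pixels, dtype=float)).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask PNG: nonzero pixels are inside the region."""
    px = iio.imread(Path(path))
    if px.ndim == 3:
        px = px[:, :, 0]
    return np.asarray(px) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
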