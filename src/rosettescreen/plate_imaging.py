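"""Green-pixel segmentation and per-well area measurement for 48-well plates.

The core observable of the screen is the *projected shoot area*: the number
of green-classified pixels inside each well of a top-view RGB plate image.
This module turns a :class:`PlateImage` into a boolean :class:`GreenMask`
and a :class:`WellGrid` partition into 48 per-well pixel counts
(:class:`WellAreaRecord`), one per seedling.

Segmentation is deliberately simple and fully configurable: the default
criterion is the excess-green vegetation index (2G − R − B > tau, with G
strictly dominant over both R and B), with an HSV colour-window alternative.
Well boxes come from a layout config (rows, columns, margins, pitch) rather
than from automatic plate detection — the plates are a fixed format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

__all__ = [
    "PlateImage",
    "SegmentationParams",
    "GreenMask",
    "WellBox",
    "WellGrid",
    "WellAreaRecord",
    "segment_green",
    "build_grid",
    "measure_wells",
    "records_to_frame",
]


class PlateFormatError(ValueError):
    """Raised for rasters that are not 8-bit-style H×W×3 RGB."""


class LayoutConfigError(ValueError):
    """Raised when a well-grid layout is inconsistent or out of bounds."""


@dataclass
class PlateImage:
    """One timestamped top-view RGB raster of one 48-well plate.

    ``time_days`` is the time since transplant in days; twice-daily imaging
    is encoded as fractional days (a.m. = d + 0.0, p.m. = d + 0.25).
    """

    pixels: np.ndarray
    plate_id: str
    round_id: str = ""
    time_days: float = 0.0
    layout_id: str = "default"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise PlateFormatError(
                f"expected an H×W×3 RGB raster, got shape {px.shape}"
            )
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise PlateFormatError("image has zero height or width")
        if self.time_days < 0:
            raise ValueError("time_days must be non-negative")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SegmentationParams:
    """Colour criterion for classifying a pixel as plant (green) material.

    method="excess_green": pixel is green iff 2G − R − B > tau and G > R and
    G > B, on the 0–255 scale.  tau defaults to 20.
    method="hsv_window": pixel is green iff hue (degrees), saturation and
    value all fall inside the configured windows.
    """

    method: str = "excess_green"
    tau: float = 20.0
    hue_window: tuple[float, float] = (60.0, 180.0)
    sat_window: tuple[float, float] = (0.15, 1.0)
    val_window: tuple[float, float] = (0.10, 1.0)

    def __post_init__(self) -> None:
        if self.method not in ("excess_green", "hsv_window"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")
        lo, hi = self.hue_window
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("hue window must lie within [0, 360)")


@dataclass
class GreenMask:
    """Boolean plant/background mask, same shape as the source image."""

    mask: np.ndarray
    plate_id: str = ""
    time_days: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass(frozen=True)
class WellBox:
    """Axis-aligned well rectangle with half-open pixel bounds.

    Rows/cols are 0-based; the box covers pixels [r0, r1) × [c0, c1), so a
    boundary pixel belongs to exactly one box.
    """

    row: int
    col: int
    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def n_pixels(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)


@dataclass
class WellGrid:
    n_rows: int
    n_cols: int
    well_boxes: list[WellBox] = field(default_factory=list)

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class WellAreaRecord:
    """Projected shoot area (green-pixel count) of one well at one time."""

    plate_id: str
    row: int
    col: int
    plant_id: str
    time_days: float
    area_px: int


def segment_green(
    image: PlateImage, params: SegmentationParams | None = None
) -> GreenMask:
    """Classify each pixel of a plate image as green plant material or not.

    Returns a boolean mask of the same height and width as the image.
    """
    if params is None:
        params = SegmentationParams()
    px = image.pixels
    if params.method == "excess_green":
        r = px[..., 0].astype(np.int32)
        g = px[..., 1].astype(np.int32)
        b = px[..., 2].astype(np.int32)
        mask = (2 * g - r - b > params.tau) & (g > r) & (g > b)
    else:
        hsv = rgb2hsv(px)
        hue = hsv[..., 0] * 360.0
        lo, hi = params.hue_window
        if lo <= hi:
            hue_ok = (hue >= lo) & (hue <= hi)
        else:  # window wraps around 0°
            hue_ok = (hue >= lo) | (hue <= hi)
        mask = (
            hue_ok
            & (hsv[..., 1] >= params.sat_window[0])
            & (hsv[..., 1] <= params.sat_window[1])
            & (hsv[..., 2] >= params.val_window[0])
            & (hsv[..., 2] <= params.val_window[1])
        )
    return GreenMask(mask=mask, plate_id=image.plate_id, time_days=image.time_days)


def build_grid(layout: Mapping) -> WellGrid:
    """Build the 48-well partition of the image plane from a layout config.

    Expected keys (all integers, pixels): ``n_rows`` (default 6), ``n_cols``
    (default 8), ``image_height``, ``image_width``, ``margin_top``,
    ``margin_left`` (default 0), ``pitch_y``, ``pitch_x`` (centre-to-centre
    spacing), and optional ``box_height``/``box_width`` (default = pitch).
    Boxes are emitted in row-major order and must be pairwise disjoint and
    inside the image bounds.
    """
    n_rows = int(layout.get("n_rows", 6))
    n_cols = int(layout.get("n_cols", 8))
    try:
        img_h = int(layout["image_height"])
        img_w = int(layout["image_width"])
        pitch_y = int(layout["pitch_y"])
        pitch_x = int(layout["pitch_x"])
    except KeyError as exc:
        raise LayoutConfigError(f"missing layout key: {exc}") from exc
    margin_top = int(layout.get("margin_top", 0))
    margin_left = int(layout.get("margin_left", 0))
    box_h = int(layout.get("box_height", pitch_y))
    box_w = int(layout.get("box_width", pitch_x))

    if box_h > pitch_y or box_w > pitch_x:
        raise LayoutConfigError(
            f"box ({box_h}×{box_w}) larger than pitch ({pitch_y}×{pitch_x}): "
            "wells would overlap"
        )
    if box_h <= 0 or box_w <= 0 or n_rows <= 0 or n_cols <= 0:
        raise LayoutConfigError("rows, cols and box sizes must be positive")

    boxes: list[WellBox] = []
    for row in range(n_rows):
        for col in range(n_cols):
            r0 = margin_top + row * pitch_y
            c0 = margin_left + col * pitch_x
            r1, c1 = r0 + box_h, c0 + box_w
            if r0 < 0 or c0 < 0 or r1 > img_h or c1 > img_w:
                raise LayoutConfigError(
                    f"well ({row},{col}) box [{r0},{r1})×[{c0},{c1}) exceeds "
                    f"image bounds {img_h}×{img_w}"
                )
            boxes.append(WellBox(row, col, r0, r1, c0, c1))
    return WellGrid(n_rows=n_rows, n_cols=n_cols, well_boxes=boxes)


def measure_wells(
    mask: GreenMask,
    grid: WellGrid,
    plant_ids: Mapping[tuple[int, int], str] | None = None,
) -> list[WellAreaRecord]:
    """Count green pixels inside every well box.

    Pixels outside all boxes (plate walls, background) are ignored.
    ``plant_ids`` optionally maps (row, col) to a plant identifier; by
    default the id is "<plate_id>:r<row>c<col>".
    """
    m = mask.mask
    records = []
    for box in grid.well_boxes:
        if box.r1 > m.shape[0] or box.c1 > m.shape[1]:
            raise ValueError(
                "grid and mask disagree: well box outside the mask frame"
            )
        area = int(np.count_nonzero(m[box.r0 : box.r1, box.c0 : box.c1]))
        key = (box.row, box.col)
        pid = (
            plant_ids[key]
            if plant_ids is not None and key in plant_ids
            else f"{mask.plate_id}:r{box.row}c{box.col}"
        )
        records.append(
            WellAreaRecord(
                plate_id=mask.plate_id,
                row=box.row,
                col=box.col,
                plant_id=pid,
                time_days=mask.time_days,
                area_px=area,
            )
        )
    return records


def records_to_frame(records: Iterable[WellAreaRecord]) -> pd.DataFrame:
    """Long-format table of well areas (one row per well per timepoint)."""
    return pd.DataFrame(
        [
            {
                "plate_id": r.plate_id,
                "row": r.row,
                "col": r.col,
                "plant_id": r.plant_id,
                "time_days": r.time_days,
                "area_px": r.area_px,
            }
            for r in records
        ]
    )
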