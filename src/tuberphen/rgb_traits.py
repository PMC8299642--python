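"""Shoot traits from top/side RGB images.

Foreground segmentation by Excess Green (ExG) thresholding with
morphological cleaning, followed by the standard shoot-architecture traits:
projected area, convex hull area, bounding height/width (side view) and mean
ExG, assembled into time series indexed by days after shoot emergence (DASE).

The segmenter here is a documented reference implementation (the imaging
platform this emulates used an unpublished learned model); any callable with
the same signature can be plugged into :func:`build_trait_series`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "View",
    "RgbImage",
    "PlantMask",
    "TraitRecord",
    "TraitSeries",
    "SegmentationConfig",
    "exg_index",
    "segment_plant",
    "projected_area",
    "convex_hull_area",
    "bounding_extent",
    "build_trait_series",
    "series_to_frame",
]


class View(str, enum.Enum):
    TOP = "top"
    SIDE = "side"


@dataclass(frozen=True)
class RgbImage:
    """Calibrated 2-D colour frame with acquisition metadata.

    ``pixels`` is H x W x 3, channel order R, G, B, integer values in
    [0, 255]. ``scale_mm_per_px`` converts pixel measures to millimetres
    when known; traits are reported in px/px^2 otherwise.
    """

    pixels: np.ndarray
    view: View = View.TOP
    dase: int = 0
    plant_id: str = ""
    condition: str = "Control"
    scale_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if self.scale_mm_per_px is not None and self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "view", View(self.view))


@dataclass(frozen=True)
class PlantMask:
    """Boolean foreground mask tied to its image dimensions."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """Reference segmenter settings.

    ExG map -> threshold (Otsu, or ``fixed_threshold`` when the map is flat
    or ``use_otsu`` is off) -> 3x3 opening then closing -> keep connected
    components covering at least ``min_component_fraction`` of the frame.
    """

    use_otsu: bool = True
    fixed_threshold: float = 0.10
    min_threshold: float = 0.0
    min_component_fraction: float = 0.005
    morph_radius: int = 1  # 3x3 square structuring element

    def __post_init__(self) -> None:
        if not (-1.0 <= self.fixed_threshold <= 2.0):
            raise ValueError("fixed_threshold outside the ExG range [-1, 2]")
        if not (0.0 <= self.min_component_fraction < 1.0):
            raise ValueError("min_component_fraction must be in [0, 1)")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be >= 0")


def exg_index(image: RgbImage,
              mask: PlantMask | None = None) -> tuple[np.ndarray, float]:
    """Per-pixel Excess Green index and its mean over the mask.

    ExG = (2G - (R + B)) / (R + G + B), in [-1, 2]; pure green maps to 2,
    achromatic pixels to 0, pure red or blue to -1. Black pixels
    (R + G + B = 0) are defined as 0 (background convention). The mean is
    taken over mask foreground, or the whole frame when no mask is given;
    an empty mask yields a NaN mean.
    """
    px = image.pixels.astype(np.float64)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        exg = np.where(total > 0, (2.0 * g - (r + b)) / np.where(total > 0, total, 1.0), 0.0)
    if mask is None:
        return exg, float(exg.mean())
    if mask.shape != exg.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {exg.shape}"
        )
    if mask.n_foreground == 0:
        return exg, float("nan")
    return exg, float(exg[mask.mask].mean())


def segment_plant(image: RgbImage,
                  cfg: SegmentationConfig | None = None) -> PlantMask:
    """Segment plant foreground by ExG thresholding.

    Deterministic for a fixed config. On a flat ExG map (e.g. a uniform
    frame) Otsu is undefined and the fixed threshold is used instead, so a
    uniform grey frame (ExG = 0 everywhere) yields an empty mask and a
    uniform pure-green frame a full one.
    """
    cfg = cfg or SegmentationConfig()
    exg, _ = exg_index(image)
    if cfg.use_otsu and np.ptp(exg) > 1e-9:
        thr = max(float(threshold_otsu(exg)), cfg.min_threshold)
    else:
        thr = cfg.fixed_threshold
    raw = exg > thr
    if cfg.morph_radius > 0:
        selem = morphology.footprint_rectangle(
            (2 * cfg.morph_radius + 1,) * 2)
        raw = morphology.closing(morphology.opening(raw, selem), selem)
    if cfg.min_component_fraction > 0 and raw.any():
        min_px = cfg.min_component_fraction * raw.size
        lab = cc_label(raw, connectivity=2)
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_px)
        keep = keep[keep != 0]
        raw = np.isin(lab, keep)
    return PlantMask(raw)


def _scaled(value_px: float, scale: float | None, power: int) -> float:
    return value_px * (scale ** power) if scale is not None else value_px


def projected_area(mask: PlantMask, scale: float | None = None) -> float:
    """Foreground area: pixel count, times scale^2 (mm^2) when calibrated."""
    return _scaled(float(mask.n_foreground), scale, 2)


def convex_hull_area(mask: PlantMask, scale: float | None = None) -> float:
    """Area of the convex hull of the union of foreground pixel squares.

    Pixels are unit squares; the hull is taken over the four corner points of
    every foreground pixel, so a single pixel has hull area 1 (not 0) and the
    hull area is never smaller than the projected area.
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("convex hull of an empty mask is undefined")
    corners = np.concatenate([
        np.stack([rows, cols], axis=1),
        np.stack([rows + 1, cols], axis=1),
        np.stack([rows, cols + 1], axis=1),
        np.stack([rows + 1, cols + 1], axis=1),
    ]).astype(float)
    if rows.size == 1:
        area = 1.0
    else:
        # qhull degenerates on collinear input (e.g. a 1-pixel-wide row);
        # corner points of unit squares are never all collinear, so this is safe
        area = float(ConvexHull(corners).volume)  # "volume" is area in 2-D
    return _scaled(area, scale, 2)


def bounding_extent(mask: PlantMask,
                    scale: float | None = None) -> tuple[float, float]:
    """(height, width) of the foreground bounding box, side-view extents."""
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("bounding extent of an empty mask is undefined")
    height = float(rows.max() - rows.min() + 1)
    width = float(cols.max() - cols.min() + 1)
    return _scaled(height, scale, 1), _scaled(width, scale, 1)


@dataclass(frozen=True)
class TraitRecord:
    """All shoot traits of one image. Areas in px^2 or mm^2 per ``units``."""

    dase: int
    view: View
    projected_area: float
    hull_area: float
    exg_mean: float
    height: float | None = None
    width: float | None = None
    units: str = "px"

    def __post_init__(self) -> None:
        if self.hull_area + 1e-9 < self.projected_area:
            raise ValueError("hull area cannot be smaller than projected area")


@dataclass(frozen=True)
class TraitSeries:
    """DASE-ordered trait records of one plant and view."""

    plant_id: str
    view: View
    condition: str
    records: tuple[TraitRecord, ...]

    def __post_init__(self) -> None:
        dases = [r.dase for r in self.records]
        if any(b <= a for a, b in zip(dases, dases[1:])):
            raise ValueError("records must have strictly increasing dase")


Segmenter = Callable[[RgbImage], PlantMask]


def build_trait_series(
    images: Sequence[RgbImage],
    cfg: SegmentationConfig | None = None,
    segmenter: Segmenter | None = None,
    exg_over_mask: bool = True,
) -> dict[tuple[str, View], TraitSeries]:
    """Segment every image and assemble per-(plant, view) trait series.

    Records are sorted by DASE regardless of input order; a duplicate
    (plant, view, dase) triple is an error. ``segmenter`` replaces the
    reference ExG segmenter when given. ``exg_over_mask`` averages ExG over
    the plant mask (default); turn off for whole-frame means.
    """
    if not images:
        raise ValueError("need at least one image")
    grouped: dict[tuple[str, View], list[RgbImage]] = {}
    for img in images:
        grouped.setdefault((img.plant_id, img.view), []).append(img)

    out: dict[tuple[str, View], TraitSeries] = {}
    for (plant, view), imgs in grouped.items():
        seen = {i.dase for i in imgs}
        if len(seen) != len(imgs):
            raise ValueError(f"duplicate (plant={plant}, view={view}, dase) records")
        records = []
        for img in sorted(imgs, key=lambda i: i.dase):
            mask = segmenter(img) if segmenter else segment_plant(img, cfg)
            _, mean_exg = exg_index(img, mask if exg_over_mask else None)
            scale = img.scale_mm_per_px
            empty = mask.n_foreground == 0
            h = w = None
            if view is View.SIDE and not empty:
                h, w = bounding_extent(mask, scale)
            records.append(TraitRecord(
                dase=img.dase,
                view=view,
                projected_area=projected_area(mask, scale),
                hull_area=0.0 if empty else convex_hull_area(mask, scale),
                exg_mean=mean_exg,
                height=h,
                width=w,
                units="mm" if scale is not None else "px",
            ))
        out[(plant, view)] = TraitSeries(plant, view, imgs[0].condition,
                                         tuple(records))
    return out


def series_to_frame(series: Mapping[tuple[str, View], TraitSeries]) -> pd.DataFrame:
    """Flatten trait series into a tidy table (one row per image)."""
    rows = []
    for (plant, view), s in series.items():
        for r in s.records:
            rows.append({
                "plant_id": plant, "condition": s.condition,
                "view": view.value, "dase": r.dase,
                "projected_area": r.projected_area, "hull_area": r.hull_area,
                "height": r.height, "width": r.width,
                "exg_mean": r.exg_mean, "units": r.units,
            })
    return pd.DataFrame(rows).sort_values(
        ["plant_id", "view", "dase"]).reset_index(drop=True)
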