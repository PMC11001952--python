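"""Cropland masking, slope rule, and morphological hole filling.

A classified rapeseed map is cleaned in a fixed order: rapeseed outside the
union of the two cropland layers, or on terrain steeper than 25 degrees, is
removed; then small fully-enclosed background holes are filled to preserve
the integrity of rapeseed fields.  Hole thresholds follow field-size
conventions: 1 ha for the small, scattered winter fields and 5 ha for the
large, regular spring fields.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from . import seasons

NODATA = 255
SLOPE_LIMIT_DEG = 25.0


@dataclasses.dataclass
class CropMap:
    """Binary rapeseed map: 0 non-rapeseed, 1 rapeseed, 255 no-data."""

    values: np.ndarray  # (H, W) uint8
    season: str = seasons.WINTER
    year: int | None = None
    pixel_area: float = 900.0  # m^2 per pixel (900 at 30 m)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        legal = np.isin(self.values, (0, 1, NODATA))
        if not legal.all():
            raise ValueError("crop map values must be 0, 1 or 255 (no-data)")

    @property
    def rapeseed_mask(self) -> np.ndarray:
        return self.values == 1

    def rapeseed_area_ha(self) -> float:
        return float(self.rapeseed_mask.sum()) * self.pixel_area / 1e4

    def copy(self) -> "CropMap":
        return CropMap(values=self.values.copy(), season=self.season,
                       year=self.year, pixel_area=self.pixel_area)


def union_cropland_mask(layer_a: np.ndarray, layer_b: np.ndarray,
                        target_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Merge two binary cropland layers by logical OR.

    A finer layer is first downsampled to the target grid by nearest
    neighbor; a residual shape mismatch after resampling is an error, never a
    silent crop.
    """
    a = np.asarray(layer_a, dtype=bool)
    b = np.asarray(layer_b, dtype=bool)
    if target_shape is None:
        target_shape = a.shape
    out = []
    for layer in (a, b):
        if layer.shape != target_shape:
            if (layer.shape[0] < target_shape[0]) or (layer.shape[1] < target_shape[1]):
                raise ValueError(f"cropland layer {layer.shape} coarser than "
                                 f"target grid {target_shape}")
            layer = transform.resize(layer.astype(np.uint8), target_shape,
                                     order=0, preserve_range=True,
                                     anti_aliasing=False).astype(bool)
        out.append(layer)
    return out[0] | out[1]


def slope_from_dem(dem: np.ndarray, pixel_size: float = 30.0) -> np.ndarray:
    """Terrain slope in degrees via Horn's 3x3 finite differences."""
    dem = np.asarray(dem, dtype=float)
    if not np.all(np.isfinite(dem)):
        raise ValueError("DEM must be finite")
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * pixel_size)
    ky = kx.T
    dzdx = ndimage.convolve(dem, kx[:, ::-1], mode="nearest")
    dzdy = ndimage.convolve(dem, ky[::-1, :], mode="nearest")
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def apply_masks(crop_map: CropMap, cropland: np.ndarray, slope: np.ndarray,
                slope_limit: float = SLOPE_LIMIT_DEG) -> CropMap:
    """Remove rapeseed outside cropland or on slopes strictly above the
    limit (a slope of exactly 25.0 degrees is kept); non-rapeseed pixels are
    unchanged.  Never increases the rapeseed count."""
    cropland = np.asarray(cropland, dtype=bool)
    slope = np.asarray(slope, dtype=float)
    if cropland.shape != crop_map.values.shape or slope.shape != crop_map.values.shape:
        raise ValueError("mask grids must match the crop map")
    out = crop_map.copy()
    remove = out.rapeseed_mask & (~cropland | (slope > slope_limit))
    out.values[remove] = 0
    return out


def hole_threshold_px(max_hole_area_ha: float, pixel_area: float = 900.0) -> int:
    """Hole-area threshold in pixels: nearest integer of ha * 10^4 / area.
    1 ha at 30 m -> 11 px; 5 ha -> 56 px."""
    return int(round(max_hole_area_ha * 1e4 / pixel_area))


def fill_holes(crop_map: CropMap, max_hole_area_ha: float | None = None) -> CropMap:
    """Fill small background holes fully enclosed by rapeseed.

    Holes are 4-connected background components (rapeseed fields are
    8-connected, the standard duality) that touch neither the raster border
    nor any no-data pixel; those with pixel area strictly below the season
    threshold (winter 1 ha, spring 5 ha by default) become rapeseed.  The
    operation never decreases the rapeseed count and is idempotent.
    """
    if max_hole_area_ha is None:
        max_hole_area_ha = seasons.HOLE_THRESHOLD_HA[crop_map.season]
    thr_px = hole_threshold_px(max_hole_area_ha, crop_map.pixel_area)
    out = crop_map.copy()
    background = out.values == 0
    labels = measure.label(background, connectivity=1)
    nodata = out.values == NODATA
    border = np.zeros_like(background)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    excluded = set(np.unique(labels[border & background]))
    if nodata.any():
        touch_nodata = ndimage.binary_dilation(nodata, structure=np.ones((3, 3)))
        excluded |= set(np.unique(labels[touch_nodata & background]))
    excluded.discard(0)
    counts = np.bincount(labels.ravel())
    for lab in np.unique(labels):
        if lab == 0 or lab in excluded:
            continue
        if counts[lab] < thr_px:
            out.values[labels == lab] = 1
    return out


def remove_small_objects(crop_map: CropMap, min_area_ha: float | None = None) -> CropMap:
    """Optional pass deleting rapeseed patches smaller than the season
    threshold (the literal area-opening tool behaviour); off by default in
    the pipeline."""
    if min_area_ha is None:
        min_area_ha = seasons.HOLE_THRESHOLD_HA[crop_map.season]
    thr_px = hole_threshold_px(min_area_ha, crop_map.pixel_area)
    out = crop_map.copy()
    labels = measure.label(out.rapeseed_mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.isin(labels, np.nonzero(counts < thr_px)[0]) & (labels > 0)
    out.values[small] = 0
    return out
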