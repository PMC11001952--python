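"""Sensor harmonization, vegetation indices, and monthly median composites.

Four indices describe rapeseed growth and flowering:

* ``NDVI = (nir - red) / (nir + red)`` — greenness;
* ``NDYI = (green - blue) / (green + blue)`` — yellowness, peaking when the
  yellow flowers raise green and depress blue reflectance;
* ``CI = nir * (red + green)`` — the canola index, high only during
  flowering and the basis for candidate-sample thresholding at 0.07;
* ``WRI = ((nir - green) / (nir + green)) * (blue / (green + red))`` — the
  winter-rapeseed index separating rapeseed from co-occurring winter crops.

Zero-denominator pixels become no-data (NaN), never 0: a silent 0 would
mimic a real index value.
"""

from __future__ import annotations

import datetime
from typing import Mapping

import numpy as np

from .stack import BANDS, CompositeStack, SceneImage, SceneStack, VIStack

VI_NAMES = ("NDVI", "NDYI", "CI", "WRI")

#: Identity harmonization coefficients: (gain, offset) per band per sensor.
#: Published cross-sensor linear coefficients can be supplied instead; none
#: are shipped because the calibration literature, not this package, owns
#: those constants.
IDENTITY_COEFFICIENTS: dict[str, dict[str, tuple[float, float]]] = {
    sensor: {band: (1.0, 0.0) for band in BANDS}
    for sensor in ("TM", "ETM+", "OLI", "OLI2", "SYNTH")
}


def harmonize(stack: SceneStack,
              coefficients: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
              ) -> SceneStack:
    """Apply per-sensor linear band adjustments ``gain * rho + offset``.

    Output reflectance is clipped to [0, 1]; validity masks are unchanged.
    Raises ``KeyError`` naming the sensor if one present in the stack has no
    coefficient entry.
    """
    if coefficients is None:
        coefficients = IDENTITY_COEFFICIENTS
    for img in stack:
        if img.sensor not in coefficients:
            raise KeyError(f"no harmonization coefficients for sensor {img.sensor!r}")
    images = []
    for img in stack:
        table = coefficients[img.sensor]
        bands = np.empty_like(img.bands)
        for b, name in enumerate(BANDS):
            gain, offset = table[name]
            bands[b] = np.clip(gain * img.bands[b] + offset, 0.0, 1.0)
        images.append(SceneImage(date=img.date, sensor=img.sensor, bands=bands,
                                 valid=img.valid.copy()))
    return SceneStack(images=images, geotransform=stack.geotransform, crs=stack.crs)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def ndvi(blue: np.ndarray, green: np.ndarray, red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    return _safe_ratio(nir - red, nir + red)


def ndyi(blue: np.ndarray, green: np.ndarray, red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    return _safe_ratio(green - blue, green + blue)


def ci(blue: np.ndarray, green: np.ndarray, red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    return nir * (red + green)


def wri(blue: np.ndarray, green: np.ndarray, red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    return _safe_ratio(nir - green, nir + green) * _safe_ratio(blue, green + red)


_VI_FUNCS = {"NDVI": ndvi, "NDYI": ndyi, "CI": ci, "WRI": wri}


def compute_indices(stack: SceneStack) -> VIStack:
    """Compute NDVI, NDYI, CI, WRI per image; masks propagate, degenerate
    pixels (zero denominators) become no-data."""
    n = len(stack)
    h, w = stack.shape
    layers = {name: np.empty((n, h, w)) for name in VI_NAMES}
    valid = np.empty((n, h, w), dtype=bool)
    for i, img in enumerate(stack):
        args = tuple(img.band(b) for b in BANDS)
        for name in VI_NAMES:
            layer = _VI_FUNCS[name](*args)
            layer[~img.valid] = np.nan
            layers[name][i] = layer
        valid[i] = img.valid
    return VIStack(dates=stack.dates, layers=layers, valid=valid,
                   geotransform=stack.geotransform, crs=stack.crs)


def monthly_median_composite(stack: SceneStack | VIStack) -> CompositeStack:
    """Per-pixel, per-month median over valid observations only.

    Months with no valid observation at a pixel are no-data there.  The
    result is independent of image order, and even observation counts use the
    mean of the two central values (the standard median).
    """
    dates, layers, valid = stack.as_layers()
    months = sorted({f"{d.year:04d}-{d.month:02d}" for d in dates})
    keys = np.array([f"{d.year:04d}-{d.month:02d}" for d in dates])
    h, w = valid.shape[1:]
    out_layers = {name: np.full((len(months), h, w), np.nan) for name in layers}
    out_valid = np.zeros((len(months), h, w), dtype=bool)
    for mi, month in enumerate(months):
        sel = keys == month
        v = valid[sel]
        any_valid = v.any(axis=0)
        out_valid[mi] = any_valid
        for name, arr in layers.items():
            sub = np.where(v, arr[sel], np.nan)
            med = np.full((h, w), np.nan)
            if any_valid.any():
                with np.errstate(all="ignore"):
                    med[any_valid] = np.nanmedian(sub[:, any_valid], axis=0)
            out_layers[name][mi] = med
    # NaN from zero denominators can survive inside observed months; validity
    # tracks observation availability, layer values carry their own NaN
    return CompositeStack(months=months, layers=out_layers, valid=out_valid,
                          geotransform=stack.geotransform, crs=stack.crs)


def month_mid_date(month: str) -> datetime.date:
    year, mon = (int(p) for p in month.split("-"))
    return datetime.date(year, mon, 15)
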