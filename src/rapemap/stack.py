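"""Raster containers: dated multispectral stacks, index stacks, composites.

Arrays are row-major with pixel (0, 0) at the top-left corner; map
coordinates follow a GDAL-style affine geotransform
``(x0, dx, rx, y0, ry, dy)`` so that ``x = x0 + col*dx + row*rx`` and
``y = y0 + col*ry + row*dy``.  Invalid pixels are carried as boolean masks;
float layers use NaN for no-data.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Iterator

import numpy as np

#: Spectral band order used everywhere in the package.
BANDS = ("blue", "green", "red", "nir")

#: Recognized sensor labels (Landsat TM / ETM+ / OLI / OLI-2 plus synthetic).
SENSORS = ("TM", "ETM+", "OLI", "OLI2", "SYNTH")

#: Default geotransform: degrees, ~30 m pixels, arbitrary but fixed origin.
DEFAULT_CRS = "EPSG:4326"


def degree_geotransform(pixel_size_m: float, lon0: float = 110.0,
                        lat0: float = 32.0) -> tuple[float, ...]:
    """Degree-based affine for a metric pixel size (small-area approximation)."""
    step = pixel_size_m / 111_320.0
    return (lon0, step, 0.0, lat0, 0.0, -step)


@dataclasses.dataclass
class SceneImage:
    """One dated acquisition: 4-band reflectance plus a validity mask."""

    date: datetime.date
    sensor: str
    bands: np.ndarray  # (4, H, W) float, reflectance fraction in [0, 1]
    valid: np.ndarray  # (H, W) bool; False where cloud/no observation

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BANDS):
            raise ValueError(f"bands must be ({len(BANDS)}, H, W), got {self.bands.shape}")
        if self.valid.shape != self.bands.shape[1:]:
            raise ValueError("valid mask shape does not match bands")
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def band(self, name: str) -> np.ndarray:
        return self.bands[BANDS.index(name)]


@dataclasses.dataclass
class SceneStack:
    """Ordered, co-registered collection of :class:`SceneImage`."""

    images: list[SceneImage]
    geotransform: tuple[float, ...] = degree_geotransform(30.0)
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("empty time series")
        shape = self.images[0].shape
        for img in self.images:
            if img.shape != shape:
                raise ValueError("all images must share the same grid shape")
        dates = [img.date for img in self.images]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("image dates must be non-decreasing")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[SceneImage]:
        return iter(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def dates(self) -> list[datetime.date]:
        return [img.date for img in self.images]

    def as_layers(self) -> tuple[list[datetime.date], dict[str, np.ndarray], np.ndarray]:
        """View as (dates, {band: (n, H, W)}, valid (n, H, W)) for compositing."""
        valid = np.stack([img.valid for img in self.images])
        layers = {
            name: np.stack([img.band(name) for img in self.images])
            for name in BANDS
        }
        return self.dates, layers, valid


@dataclasses.dataclass
class VIStack:
    """Per-image vegetation-index layers sharing the parent stack's dates."""

    dates: list[datetime.date]
    layers: dict[str, np.ndarray]  # name -> (n, H, W), NaN where invalid
    valid: np.ndarray  # (n, H, W) bool
    geotransform: tuple[float, ...] = degree_geotransform(30.0)
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        n = len(self.dates)
        for name, arr in self.layers.items():
            if arr.shape[0] != n:
                raise ValueError(f"layer {name!r} has {arr.shape[0]} images, expected {n}")
        if self.valid.shape[0] != n:
            raise ValueError("valid mask count does not match dates")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape[1:]

    def as_layers(self) -> tuple[list[datetime.date], dict[str, np.ndarray], np.ndarray]:
        return self.dates, self.layers, self.valid


@dataclasses.dataclass
class CompositeStack:
    """Monthly median composites keyed by ``YYYY-MM``.

    ``layers[name]`` has shape (n_months, H, W) with NaN where a month holds
    no valid observation; ``valid`` marks per-layer-set availability.
    """

    months: list[str]
    layers: dict[str, np.ndarray]
    valid: np.ndarray  # (n_months, H, W) bool
    geotransform: tuple[float, ...] = degree_geotransform(30.0)
    crs: str = DEFAULT_CRS

    def month_index(self, month: str) -> int:
        try:
            return self.months.index(month)
        except ValueError:
            raise KeyError(f"no composite for month {month!r}") from None

    def layer(self, name: str, month: str) -> np.ndarray:
        return self.layers[name][self.month_index(month)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape[1:]
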