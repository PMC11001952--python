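"""Synthetic multi-temporal scene and ancillary-data generators.

Every input the mapping chain consumes can be generated here with known
ground truth: class-structured landscapes whose rapeseed pixels show the
flowering spectral peak (green up, blue flat, NIR moderate), non-flowering
confuser crops, random cloud gaps, terrain slope, imperfect cropland masks,
environmental drivers functionally linked to the true flowering dates, SAR
backscatter bumps at flowering, and noisy reported area statistics.

Design notes
------------
Landscapes are smoothed Gaussian noise fields thresholded at class quantiles,
which yields contiguous "fields" (connected components) rather than
pixel-i.i.d. labels, so morphological post-processing is actually exercised.
Band trajectories are piecewise-Gaussian in time with class-specific
parameters; rapeseed additionally receives a flowering bump centred on its
per-pixel true peak day-of-year.  The cloud model is per-image i.i.d.
Bernoulli pixel dropout.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from . import seasons
from .stack import BANDS, SceneImage, SceneStack, degree_geotransform

# ---------------------------------------------------------------------------
# class codes and spectra
# ---------------------------------------------------------------------------

RAPESEED, CONFUSER, VEGETATION, BARE, WATER = 1, 2, 3, 4, 5
CLASS_NAMES = {
    RAPESEED: "rapeseed",
    CONFUSER: "confuser_crop",
    VEGETATION: "other_vegetation",
    BARE: "bare_built",
    WATER: "water",
}

# Baseline reflectance (blue, green, red, nir) per class outside flowering.
# Chosen so the canola index CI = nir*(red+green) stays well below the 0.07
# candidate threshold for every class (>5 sigma at the default noise level),
# while rapeseed's flowering bump pushes CI to ~0.19 at peak.  Rapeseed and
# the confuser crop (a winter cereal) are deliberately only ~1 noise-sigma
# apart per band outside flowering: like their real counterparts they are
# near-indistinguishable except at bloom, so multi-temporal fusion and the
# flowering window carry the discrimination, not the baseline spectra.
_BASE = {
    RAPESEED: (0.035, 0.075, 0.050, 0.300),
    CONFUSER: (0.030, 0.070, 0.045, 0.310),
    VEGETATION: (0.030, 0.070, 0.050, 0.360),
    BARE: (0.080, 0.100, 0.120, 0.200),
    WATER: (0.030, 0.040, 0.030, 0.050),
}

# Flowering bump added to rapeseed bands, scaled by a Gaussian in time of
# width FLOWER_WIDTH days around the per-pixel peak DOY: yellow petals raise
# green (and some red/NIR) while blue stays low.
_FLOWER_AMP = {"blue": 0.010, "green": 0.220, "red": 0.080, "nir": 0.120}
FLOWER_WIDTH = 8.0  # days (Gaussian sigma)

# Green-up bump (stem elongation/heading) shared by both crops: raises green
# and NIR a little, never enough to cross the CI threshold.
_CONFUSER_AMP = {"blue": 0.000, "green": 0.020, "red": 0.000, "nir": 0.030}
_CONFUSER_WIDTH = 20.0
_CONFUSER_LAG = 25.0  # days after the regional mean flowering peak

#: Remaining landscape split among non-rapeseed classes.
_OTHER_FRACTIONS = {CONFUSER: 0.30, VEGETATION: 0.40, BARE: 0.20, WATER: 0.10}

_PEAK_BASE = {seasons.WINTER: 75.0, seasons.SPRING: 195.0}


def default_dates(season: str, year: int) -> list[datetime.date]:
    """Default acquisition calendar: monthly mid-month images across the
    season image window, with an extra acquisition in the flowering month."""
    if season == seasons.WINTER:
        return [
            datetime.date(year - 1, 11, 15),
            datetime.date(year - 1, 12, 15),
            datetime.date(year, 1, 15),
            datetime.date(year, 2, 15),
            datetime.date(year, 3, 5),
            datetime.date(year, 3, 25),
            datetime.date(year, 4, 15),
            datetime.date(year, 5, 15),
        ]
    return [
        datetime.date(year, 4, 15),
        datetime.date(year, 5, 15),
        datetime.date(year, 6, 15),
        datetime.date(year, 7, 5),
        datetime.date(year, 7, 25),
        datetime.date(year, 8, 15),
    ]


@dataclasses.dataclass
class SceneConfig:
    """Configuration of one synthetic scene."""

    height: int = 128
    width: int = 128
    pixel_size: float = 30.0  # metres
    n_classes: int = 5
    rapeseed_fraction: float = 0.2
    season: str = seasons.WINTER
    year: int = 2021
    acquisition_dates: list[datetime.date] | None = None
    cloud_prob: float = 0.1
    noise_sd: float = 0.005  # reflectance units
    seed: int = 0
    doy_lat_gradient: float = 10.0  # days of peak-DOY spread top-to-bottom
    doy_jitter_sd: float = 3.0  # days, spatially smooth jitter

    def __post_init__(self) -> None:
        if not 0.0 <= self.rapeseed_fraction <= 1.0:
            raise ValueError("rapeseed_fraction must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.season not in seasons.SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.acquisition_dates is None:
            self.acquisition_dates = default_dates(self.season, self.year)
        if len(self.acquisition_dates) == 0:
            raise ValueError("empty time series")
        dates = list(self.acquisition_dates)
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("acquisition dates must be strictly increasing")


@dataclasses.dataclass
class SceneTruth:
    """Per-pixel ground truth for a generated scene."""

    class_map: np.ndarray  # (H, W) int, codes in CLASS_NAMES
    peak_flowering_doy: np.ndarray  # (H, W) float, NaN off rapeseed
    slope_deg: np.ndarray  # (H, W) float, >= 0
    cropland_truth: np.ndarray  # (H, W) bool
    season: str = seasons.WINTER
    year: int = 2021
    pixel_size: float = 30.0
    geotransform: tuple[float, ...] = degree_geotransform(30.0)

    @property
    def rapeseed_mask(self) -> np.ndarray:
        return self.class_map == RAPESEED

    def rapeseed_area_ha(self) -> float:
        return float(self.rapeseed_mask.sum()) * self.pixel_size**2 / 1e4


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _class_map(rng: np.random.Generator, cfg: SceneConfig,
               steep: np.ndarray) -> np.ndarray:
    """Threshold a smoothed noise field at class quantiles -> contiguous fields.

    Cropland classes (rapeseed, confuser) are drawn from non-steep pixels
    only — cultivation is banned on slopes above 25 degrees — with their
    thresholds chosen over the non-steep subset so the configured fractions
    of the *whole* scene are still met.
    """
    shape = (cfg.height, cfg.width)
    n_total = shape[0] * shape[1]
    sigma = max(2.0, min(shape) / 16.0)
    field = _smooth_field(rng, shape, sigma)

    nonsteep_sorted = np.sort(field[~steep])
    n_rape = int(round(cfg.rapeseed_fraction * n_total))
    rest = 1.0 - cfg.rapeseed_fraction
    n_conf = int(round(_OTHER_FRACTIONS[CONFUSER] * rest * n_total))
    n_rape = min(n_rape, nonsteep_sorted.size)
    n_conf = min(n_conf, nonsteep_sorted.size - n_rape)

    out = np.full(shape, VEGETATION, dtype=np.int16)
    rape_mask = np.zeros(shape, dtype=bool)
    conf_mask = np.zeros(shape, dtype=bool)
    if n_rape > 0:
        t_rape = nonsteep_sorted[n_rape - 1]
        rape_mask = ~steep & (field <= t_rape)
    if n_conf > 0:
        t_conf = nonsteep_sorted[n_rape + n_conf - 1]
        conf_mask = ~steep & (field <= t_conf) & ~rape_mask
    out[rape_mask] = RAPESEED
    out[conf_mask] = CONFUSER

    # split the remaining pixels among vegetation / bare / water by quantiles
    remaining = ~rape_mask & ~conf_mask
    others = [(VEGETATION, _OTHER_FRACTIONS[VEGETATION]),
              (BARE, _OTHER_FRACTIONS[BARE]),
              (WATER, _OTHER_FRACTIONS[WATER])]
    weights = np.array([w for _, w in others])
    edges = np.cumsum(weights / weights.sum())[:-1]
    vals = field[remaining]
    thresholds = np.quantile(vals, edges)
    bins = np.digitize(vals, thresholds, right=True)
    assigned = np.full(vals.shape, VEGETATION, dtype=np.int16)
    for idx, (cls, _) in enumerate(others):
        assigned[bins == idx] = cls
    out[remaining] = assigned
    return out


def _peak_doy_field(rng: np.random.Generator, cfg: SceneConfig,
                    class_map: np.ndarray) -> np.ndarray:
    """Smooth per-pixel peak-flowering DOY: latitude gradient plus jitter."""
    h, w = class_map.shape
    rows = np.arange(h, dtype=float)[:, None] / max(h - 1, 1)
    base = _PEAK_BASE[cfg.season] + cfg.doy_lat_gradient * (rows - 0.5)
    jitter = _smooth_field(rng, (h, w), sigma=max(2.0, min(h, w) / 10.0))
    doy = base + cfg.doy_jitter_sd * jitter
    lo, hi = seasons.DOY_RANGE[cfg.season]
    doy = np.clip(doy, lo + 20, hi - 20)
    doy = np.round(doy)
    doy = np.where(class_map == RAPESEED, doy, np.nan)
    return doy


def _band_image(cfg: SceneConfig, class_map: np.ndarray, peak_doy: np.ndarray,
                date: datetime.date, rng: np.random.Generator) -> np.ndarray:
    """Noise-free-then-noised (4, H, W) reflectance for one acquisition."""
    h, w = class_map.shape
    base = np.zeros((len(BANDS), h, w))
    for cls, refl in _BASE.items():
        sel = class_map == cls
        for b, value in enumerate(refl):
            base[b][sel] = value

    # signed day offset from each rapeseed pixel's peak-flowering date
    ref = datetime.date(cfg.year, 1, 1)
    day = (date - ref).days + 1  # DOY-like, negative for previous-year dates
    rape = class_map == RAPESEED
    if rape.any():
        delta = day - peak_doy[rape]
        weight = np.exp(-0.5 * (delta / FLOWER_WIDTH) ** 2)
        for b, name in enumerate(BANDS):
            base[b][rape] += _FLOWER_AMP[name] * weight
    crops = np.isin(class_map, (RAPESEED, CONFUSER))
    if crops.any():
        delta_c = day - (_PEAK_BASE[cfg.season] + _CONFUSER_LAG)
        weight_c = math.exp(-0.5 * (delta_c / _CONFUSER_WIDTH) ** 2)
        for b, name in enumerate(BANDS):
            base[b][crops] += _CONFUSER_AMP[name] * weight_c

    base += rng.normal(0.0, cfg.noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def generate_scene(config: SceneConfig) -> tuple[SceneStack, SceneTruth]:
    """Generate a dated 4-band reflectance stack with known ground truth.

    Rapeseed pixels exhibit, within about +/-10 days of their true peak DOY,
    elevated green and NIR and depressed blue such that the canola index
    crosses the 0.07 candidate threshold and NDYI rises; confuser-crop pixels
    never cross the CI threshold.  Per-image validity masks drop pixels with
    probability ``cloud_prob``.  Identical seeds give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    slope = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 8.0))
    slope = np.clip((slope - slope.min()) / (np.ptp(slope) + 1e-12), 0, 1) * 35.0
    class_map = _class_map(rng, cfg, steep=slope > 25.0)
    peak_doy = _peak_doy_field(rng, cfg, class_map)
    cropland = np.isin(class_map, (RAPESEED, CONFUSER))

    geotransform = degree_geotransform(cfg.pixel_size)
    truth = SceneTruth(
        class_map=class_map,
        peak_flowering_doy=peak_doy,
        slope_deg=slope,
        cropland_truth=cropland,
        season=cfg.season,
        year=cfg.year,
        pixel_size=cfg.pixel_size,
        geotransform=geotransform,
    )

    images = []
    for date in cfg.acquisition_dates:
        bands = _band_image(cfg, class_map, peak_doy, date, rng)
        valid = rng.random(class_map.shape) >= cfg.cloud_prob
        images.append(SceneImage(date=date, sensor="SYNTH", bands=bands, valid=valid))
    stack = SceneStack(images=images, geotransform=geotransform)
    return stack, truth


# ---------------------------------------------------------------------------
# environmental drivers
# ---------------------------------------------------------------------------

ENV_VARIABLES = (
    "canopy_surface_water",
    "canopy_water_evaporation",
    "potential_evaporation",
    "soil_moisture_0_10cm",
    "soil_moisture_10_40cm",
    "soil_temperature_0_10cm",
    "soil_temperature_10_40cm",
    "accumulated_air_temperature",
    "downward_shortwave_radiation",
    "total_precipitation_rate",
)

# DOY-generating function: logistic in the window-mean soil temperature plus
# a linear latitude term.  Warmer cells flower earlier; higher latitudes
# later.  Any smooth monotone function would do; this one is recorded here so
# recovery experiments can evaluate it exactly.
_DOY_FN = {
    seasons.WINTER: dict(base=35.0, amp=70.0, t0=9.0, scale=3.0, lat_coef=0.5),
    seasons.SPRING: dict(base=165.0, amp=60.0, t0=14.0, scale=3.0, lat_coef=0.5),
}


def doy_generating_function(mean_temp: np.ndarray, latitude: np.ndarray,
                            season: str) -> np.ndarray:
    """True peak-flowering DOY as a smooth function of temperature and latitude."""
    p = _DOY_FN[season]
    logistic = p["amp"] / (1.0 + np.exp((np.asarray(mean_temp) - p["t0"]) / p["scale"]))
    return p["base"] + logistic + p["lat_coef"] * np.asarray(latitude)


def _series_frame(rng: np.random.Generator, dates: list[datetime.date],
                  mean_temp: float, latitude: float) -> pd.DataFrame:
    """Daily 10-variable series whose temperature variables average to
    ``mean_temp`` (up to zero-mean daily weather noise)."""
    n = len(dates)
    t = np.linspace(-1.0, 1.0, n)
    seasonal = 3.0 * np.sin(np.pi * t)  # within-window temperature excursion
    temp = mean_temp + seasonal - seasonal.mean() + rng.normal(0, 0.8, n)
    rad = 180.0 - 2.0 * latitude + 30.0 * t + rng.normal(0, 8.0, n)
    frame = pd.DataFrame(
        {
            "canopy_surface_water": np.abs(rng.normal(0.1, 0.05, n)),
            "canopy_water_evaporation": np.abs(rng.normal(5.0, 2.0, n)),
            "potential_evaporation": np.clip(40.0 + 2.0 * temp + rng.normal(0, 5, n), 0, None),
            "soil_moisture_0_10cm": np.clip(rng.normal(25.0, 3.0, n), 0, None),
            "soil_moisture_10_40cm": np.clip(rng.normal(80.0, 6.0, n), 0, None),
            "soil_temperature_0_10cm": temp + rng.normal(0, 0.3, n),
            "soil_temperature_10_40cm": temp + 1.0 + rng.normal(0, 0.3, n),
            "accumulated_air_temperature": np.cumsum(np.clip(temp, 0, None)),
            "downward_shortwave_radiation": np.clip(rad, 0, None),
            "total_precipitation_rate": np.abs(rng.normal(2.0, 1.5, n)),
        },
        index=pd.DatetimeIndex(dates, name="date"),
    )
    return frame


def _invert_doy_fn(doy: np.ndarray, latitude: np.ndarray, season: str) -> np.ndarray:
    """Mean temperature such that the generating function returns ``doy``."""
    p = _DOY_FN[season]
    core = np.asarray(doy, dtype=float) - p["base"] - p["lat_coef"] * np.asarray(latitude)
    core = np.clip(core / p["amp"], 1e-6, 1 - 1e-6)
    return p["t0"] + p["scale"] * np.log(1.0 / core - 1.0)


def generate_env_cells(n_cells: int, season: str = seasons.WINTER, year: int = 2021,
                       noise_sd: float = 2.0, seed: int = 0) -> "EnvCollection":
    """Standalone coarse-cell environmental series for recovery experiments.

    Each cell draws a latitude and a window-mean temperature; its true peak
    DOY is :func:`doy_generating_function` of the two plus Gaussian noise of
    standard deviation ``noise_sd`` days.
    """
    rng = np.random.default_rng(seed)
    dates = seasons.window_dates(seasons.env_window(season, year))
    lat = rng.uniform(22.0, 45.0, n_cells)
    temp = 20.0 - 0.45 * lat + rng.normal(0, 1.5, n_cells)
    doy_fn = doy_generating_function(temp, lat, season)
    doy_true = doy_fn + rng.normal(0, noise_sd, n_cells)
    lon = rng.uniform(95.0, 120.0, n_cells)
    elev = np.abs(rng.normal(500.0, 400.0, n_cells))
    series = []
    for i in range(n_cells):
        frame = _series_frame(rng, dates, float(temp[i]), float(lat[i]))
        series.append(
            EnvSeries(cell_id=i, longitude=float(lon[i]), latitude=float(lat[i]),
                      elevation=float(elev[i]), data=frame)
        )
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "longitude": lon,
            "latitude": lat,
            "elevation": elev,
            "mean_temp": temp,
            "doy_fn": doy_fn,
            "doy_true": doy_true,
        }
    )
    return EnvCollection(series=series, truth=table, season=season, year=year)


def generate_env_series(truth: SceneTruth, grid_res: float = 0.005,
                        season: str | None = None, seed: int = 0,
                        noise_sd: float = 0.0) -> "EnvCollection":
    """Coarse-cell environmental series tied to a generated scene.

    The scene is tiled into ``grid_res``-degree cells; for every cell holding
    rapeseed pixels, the window-mean soil temperature is set by inverting the
    DOY-generating function at the cell's true mean peak DOY, so a regressor
    trained on these series can recover the scene phenology.
    """
    if grid_res <= 0:
        raise ValueError("grid_res must be positive")
    season = season or truth.season
    rng = np.random.default_rng(seed)
    x0, dx, _, y0, _, dy = truth.geotransform
    h, w = truth.class_map.shape
    rows, cols = np.nonzero(truth.rapeseed_mask)
    dates = seasons.window_dates(seasons.env_window(season, truth.year))
    series: list[EnvSeries] = []
    rows_out = []
    if rows.size:
        lon = x0 + (cols + 0.5) * dx
        lat = y0 + (rows + 0.5) * dy
        ci = np.floor(lon / grid_res).astype(int)
        cj = np.floor(lat / grid_res).astype(int)
        doy = truth.peak_flowering_doy[rows, cols]
        frame = pd.DataFrame({"ci": ci, "cj": cj, "doy": doy})
        grouped = frame.groupby(["ci", "cj"])["doy"].agg(["mean", "count"])
        for k, ((gi, gj), row) in enumerate(grouped.iterrows()):
            cell_lon = (gi + 0.5) * grid_res
            cell_lat = (gj + 0.5) * grid_res
            doy_cell = float(row["mean"]) + rng.normal(0.0, noise_sd)
            temp = float(_invert_doy_fn(doy_cell, cell_lat, season))
            data = _series_frame(rng, dates, temp, cell_lat)
            series.append(EnvSeries(cell_id=k, longitude=cell_lon, latitude=cell_lat,
                                    elevation=float(np.abs(rng.normal(400, 200))),
                                    data=data))
            rows_out.append((k, cell_lon, cell_lat, series[-1].elevation,
                             temp, float(row["mean"]), int(row["count"])))
    table = pd.DataFrame(
        rows_out,
        columns=["cell_id", "longitude", "latitude", "elevation", "mean_temp",
                 "doy_true", "n_pixels"],
    )
    return EnvCollection(series=series, truth=table, season=season, year=truth.year)


@dataclasses.dataclass
class EnvSeries:
    """Daily environmental drivers for one coarse grid cell."""

    cell_id: int
    longitude: float
    latitude: float
    elevation: float
    data: pd.DataFrame  # daily index, columns = ENV_VARIABLES

    def __post_init__(self) -> None:
        missing = set(ENV_VARIABLES) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing environmental variables: {sorted(missing)}")


@dataclasses.dataclass
class EnvCollection:
    """A set of :class:`EnvSeries` plus the generating-truth table."""

    series: list[EnvSeries]
    truth: pd.DataFrame
    season: str
    year: int

    def __len__(self) -> int:
        return len(self.series)


# ---------------------------------------------------------------------------
# SAR backscatter
# ---------------------------------------------------------------------------

def generate_sar_series(records, seed: int = 0, interval: int = 2,
                        base_db: float = -14.0, amp_db: float = 3.0,
                        width: float = 12.0, noise_sd: float = 0.5,
                        offset: float = 0.0,
                        window: tuple[int, int] | None = None) -> dict[int, pd.DataFrame]:
    """Per-record VV backscatter series peaking at the true flowering DOY.

    A single smooth Gaussian bump of ``amp_db`` over ``base_db`` is placed at
    each record's ``flowering_doy`` shifted by ``offset`` days, sampled every
    ``interval`` days, with additive Gaussian noise.  The VV peak coincides
    with peak flowering, which is what downstream peak detection exploits.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    rng = np.random.default_rng(seed)
    out: dict[int, pd.DataFrame] = {}
    doys = [r.flowering_doy for r in records if r.flowering_doy is not None]
    if window is None:
        lo = int(min(doys)) - 40 if doys else 1
        hi = int(max(doys)) + 40 if doys else 150
    else:
        lo, hi = window
    grid = np.arange(lo, hi + 1, interval, dtype=float)
    for rec in records:
        if rec.flowering_doy is None and rec.true_doy is None:
            continue
        # the SAR bump tracks the *true* flowering peak; recorded dates may
        # carry transcription errors that calibration is meant to catch
        doy0 = rec.true_doy if rec.true_doy is not None else rec.flowering_doy
        peak = doy0 + offset
        vv = base_db + amp_db * np.exp(-0.5 * ((grid - peak) / width) ** 2)
        vv = vv + rng.normal(0.0, noise_sd, grid.size)
        out[rec.id] = pd.DataFrame({"doy": grid, "vv": vv})
    return out


# ---------------------------------------------------------------------------
# reported statistics, cropland layers, DEM, sample points
# ---------------------------------------------------------------------------

def generate_statistics(truth_series: list[SceneTruth], reporting_noise: float = 0.1,
                        seed: int = 0, years: list[int] | None = None) -> pd.DataFrame:
    """Per-region reported planted areas with multiplicative reporting noise.

    Each truth raster is one administrative region; ``reported = true * (1 +
    eps)`` with ``eps ~ N(0, reporting_noise)``.  True areas are retained so
    tests can use them as oracle.
    """
    if reporting_noise < 0:
        raise ValueError("reporting_noise must be non-negative")
    if not truth_series:
        raise ValueError("at least one region required")
    rng = np.random.default_rng(seed)
    rows = []
    for i, truth in enumerate(truth_series):
        year = years[i] if years is not None else truth.year
        true_ha = truth.rapeseed_area_ha()
        factor = 1.0 + rng.normal(0.0, reporting_noise)
        rows.append((i, year, true_ha, true_ha * factor))
    return pd.DataFrame(rows, columns=["region", "year", "true_area_ha", "reported_area_ha"])


def generate_area_trend(n_years: int = 23, start_year: int = 2000,
                        base_ha: float = 1000.0, slope_ha: float = -15.0,
                        noise_sd: float = 40.0, seed: int = 0) -> pd.DataFrame:
    """A yearly planted-area series with a linear trend plus noise, for
    exercising Sen's-slope trend analysis."""
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    area = base_ha + slope_ha * (years - start_year) + rng.normal(0, noise_sd, n_years)
    return pd.DataFrame({"year": years, "area_ha": np.clip(area, 0, None)})


def generate_cropland_layers(truth: SceneTruth, error_rate: float = 0.02,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two imperfect binary cropland layers emulating independent land-cover
    products: each flips ``error_rate`` of the true cropland pixels (omission)
    and the same share of non-cropland pixels (commission)."""
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(2):
        flips = rng.random(truth.cropland_truth.shape) < error_rate
        layers.append(np.where(flips, ~truth.cropland_truth, truth.cropland_truth))
    return layers[0], layers[1]


def generate_dem(shape: tuple[int, int], pixel_size: float = 30.0,
                 relief: float = 300.0, seed: int = 0) -> np.ndarray:
    """Smooth synthetic elevation surface (metres) for slope computation."""
    rng = np.random.default_rng(seed)
    dem = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(2, min(shape) // 8))
    dem = (dem - dem.min()) / (np.ptp(dem) + 1e-12) * relief
    return dem + 100.0


def generate_pheno_records(truth: SceneTruth, n: int = 200, seed: int = 0,
                           outlier_frac: float = 0.15, outlier_shift: float = 10.0,
                           record_noise_sd: float = 1.0) -> list:
    """Sample labeled flowering-date records from a scene's rapeseed pixels.

    A fraction ``outlier_frac`` of records gets its recorded date shifted by
    ``+/- outlier_shift`` days to emulate mis-recorded field dates that the
    SAR-peak calibration step should drop.
    """
    from .phenology import PhenoRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(truth.rapeseed_mask)
    if rows.size == 0:
        return []
    n = min(n, rows.size)
    pick = rng.choice(rows.size, size=n, replace=False)
    x0, dx, _, y0, _, dy = truth.geotransform
    records = []
    for k, idx in enumerate(pick):
        r, c = int(rows[idx]), int(cols[idx])
        doy = float(truth.peak_flowering_doy[r, c])
        recorded = doy + rng.normal(0.0, record_noise_sd)
        if rng.random() < outlier_frac:
            recorded += outlier_shift * (1 if rng.random() < 0.5 else -1)
        lo, hi = seasons.DOY_RANGE[truth.season]
        recorded = float(np.clip(round(recorded), lo, hi))
        records.append(
            PhenoRecord(id=k, longitude=x0 + (c + 0.5) * dx, latitude=y0 + (r + 0.5) * dy,
                        year=truth.year, label="rapeseed", flowering_doy=recorded,
                        source="synthetic", true_doy=doy)
        )
    return records
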