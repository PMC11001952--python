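"""Flowering-phenology estimation: Whittaker smoothing of SAR series, peak
detection, record calibration, grid aggregation, and the environmental
random-forest regressor.

The chain mirrors how flowering dates are derived operationally: recorded
flowering dates at sample points are cross-checked against the day the SAR
VV backscatter peaks (the two coincide for rapeseed), records disagreeing by
more than five days are dropped, survivors are aggregated to a coarse grid,
and a random-forest regression maps daily environmental drivers (plus
latitude, longitude, elevation) to the per-cell peak-flowering day of year.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from . import seasons
from .synth import ENV_VARIABLES, EnvCollection, EnvSeries

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PhenoRecord:
    """A labeled sample point with an optional recorded flowering date."""

    id: int
    longitude: float
    latitude: float
    year: int
    label: str  # "rapeseed" | "nonrapeseed"
    flowering_doy: float | None = None
    source: str = "field"  # "field" | "interpreted" | "synthetic"
    true_doy: float | None = None  # generator truth, absent for real data

    def __post_init__(self) -> None:
        if self.flowering_doy is not None and not 1 <= self.flowering_doy <= 366:
            raise ValueError("flowering_doy must lie in [1, 366]")


@dataclasses.dataclass
class FloweringField:
    """Per-cell predicted peak flowering DOY for one season and year."""

    table: pd.DataFrame  # columns: cell_id, longitude, latitude, doy, plausible
    season: str
    year: int

    @property
    def mean_doy(self) -> float:
        return float(self.table["doy"].mean())


def whittaker_smooth(series: np.ndarray, lam: float = 10.0) -> np.ndarray:
    """Penalized least-squares smoother with a second-difference penalty.

    Minimizes ``sum((y - z)^2) + lam * sum((d2 z)^2)``.  ``lam = 0`` returns
    the input; as ``lam -> inf`` the output approaches the least-squares
    straight line (second differences vanish).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("series must be one-dimensional with length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values; interpolate gaps first")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if lam == 0:
        return y.copy()
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    a = sparse.identity(n, format="csc") + lam * (d2.T @ d2)
    return spsolve(a, y)


def detect_vv_peak(doys: np.ndarray, values: np.ndarray,
                   search_window: tuple[float, float] | None = None,
                   lam: float = 100.0) -> float:
    """DOY at which the smoothed VV series is maximal inside the window.

    Peak detection defaults to much heavier smoothing (``lam=100``) than the
    general-purpose smoother: the argmax of a shallow backscatter bump
    wanders by several days under dB-level noise unless the noise is
    strongly suppressed.  Ties take the earliest date.  Raises
    ``ValueError`` when fewer than three observations fall inside the window.
    """
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(doys, kind="stable")
    doys, values = doys[order], values[order]
    if search_window is not None:
        lo, hi = search_window
        inside = (doys >= lo) & (doys <= hi)
    else:
        inside = np.ones(doys.size, dtype=bool)
    if inside.sum() < 3:
        raise ValueError("insufficient observations")
    smoothed = whittaker_smooth(values, lam) if values.size >= 3 else values
    sub = np.where(inside, smoothed, -np.inf)
    return float(doys[int(np.argmax(sub))])


def calibrate_records(records: list[PhenoRecord], sar_peaks: dict[int, float],
                      tolerance: float = 5.0, drop_unmatched: bool = True
                      ) -> tuple[list[PhenoRecord], list[tuple[int, str]]]:
    """Keep records whose recorded date is within ``tolerance`` days of the
    SAR peak; a difference *greater than* five days (the default) drops the
    record.  Returns (kept, log of (id, reason)) and never adds records;
    applying it twice with the same peaks changes nothing.
    """
    kept: list[PhenoRecord] = []
    dropped: list[tuple[int, str]] = []
    for rec in records:
        if rec.flowering_doy is None:
            dropped.append((rec.id, "no recorded flowering date"))
            continue
        if rec.id not in sar_peaks:
            if drop_unmatched:
                dropped.append((rec.id, "no matched SAR peak"))
                continue
            kept.append(rec)
            continue
        diff = abs(rec.flowering_doy - sar_peaks[rec.id])
        if diff > tolerance:
            dropped.append((rec.id, f"SAR peak differs by {diff:.1f} d > {tolerance:g} d"))
        else:
            kept.append(rec)
    log.info("calibration kept %d of %d records (%d dropped)",
             len(kept), len(records), len(dropped))
    return kept, dropped


def aggregate_to_grid(records: list[PhenoRecord], resolution: float = 0.25) -> pd.DataFrame:
    """Mean recorded DOY per occupied ``resolution``-degree cell.

    Aggregation to a coarse grid avoids local overfitting of the regressor to
    dense record clusters.  Returns cell centres, mean DOY, and record count.
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = [(r.longitude, r.latitude, r.flowering_doy) for r in records
            if r.flowering_doy is not None]
    frame = pd.DataFrame(rows, columns=["longitude", "latitude", "doy"])
    frame["ci"] = np.floor(frame["longitude"] / resolution).astype(int)
    frame["cj"] = np.floor(frame["latitude"] / resolution).astype(int)
    grouped = frame.groupby(["ci", "cj"]).agg(doy=("doy", "mean"), n=("doy", "size"))
    grouped = grouped.reset_index()
    grouped["longitude"] = (grouped["ci"] + 0.5) * resolution
    grouped["latitude"] = (grouped["cj"] + 0.5) * resolution
    grouped["cell_id"] = np.arange(len(grouped))
    return grouped[["cell_id", "longitude", "latitude", "doy", "n"]]


def build_features(series: list[EnvSeries], bin_days: int = 10) -> np.ndarray:
    """Fixed-length features: each daily variable resampled to ``bin_days``-
    mean bins across the window, concatenated with latitude, longitude, and
    elevation (13 variables total)."""
    if not series:
        raise ValueError("no environmental series")
    rows = []
    for s in series:
        n = len(s.data)
        nbins = -(-n // bin_days)  # ceil; the last bin may be partial
        feats = []
        for var in ENV_VARIABLES:
            vals = s.data[var].to_numpy()
            feats.extend(
                vals[k * bin_days: min((k + 1) * bin_days, n)].mean()
                for k in range(nbins)
            )
        feats.extend([s.latitude, s.longitude, s.elevation])
        rows.append(feats)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("environmental series have unequal window lengths")
    return np.asarray(rows, dtype=float)


@dataclasses.dataclass
class PhenologyModel:
    """Fitted random-forest regressor from environmental features to DOY."""

    rf: RandomForestRegressor
    bin_days: int
    season: str
    holdout_r2: float | None = None

    def predict(self, series: list[EnvSeries]) -> np.ndarray:
        return self.rf.predict(build_features(series, self.bin_days))

    def predict_field(self, env: EnvCollection) -> FloweringField:
        doy = self.predict(env.series)
        lo, hi = seasons.DOY_RANGE[self.season]
        table = pd.DataFrame({
            "cell_id": [s.cell_id for s in env.series],
            "longitude": [s.longitude for s in env.series],
            "latitude": [s.latitude for s in env.series],
            "doy": doy,
            "plausible": (doy >= lo) & (doy <= hi),
        })
        return FloweringField(table=table, season=self.season, year=env.year)


def fit_phenology_model(env: EnvCollection, targets: np.ndarray | None = None,
                        ntree: int = 100, mtry: str | int = "sqrt",
                        bin_days: int = 10, holdout: float = 0.0,
                        min_cells: int = 20, seed: int = 0) -> PhenologyModel:
    """Fit the environmental random-forest regressor for peak-flowering DOY.

    ``mtry`` defaults to the square root of the number of input features and
    ``ntree`` to 100 trees.  ``targets`` defaults to the collection's truth
    table ``doy_true`` column; set ``holdout`` to a fraction in (0, 1) to
    reserve cells for an out-of-sample R² stored on the model.
    """
    if targets is None:
        targets = env.truth["doy_true"].to_numpy()
    x = build_features(env.series, bin_days)
    y = np.asarray(targets, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("feature/target length mismatch")
    if x.shape[0] < min_cells:
        raise ValueError(f"need at least {min_cells} training cells, got {x.shape[0]}")
    rf = RandomForestRegressor(n_estimators=ntree, max_features=mtry, random_state=seed)
    holdout_r2 = None
    if holdout > 0:
        xtr, xte, ytr, yte = train_test_split(x, y, test_size=holdout, random_state=seed)
        rf.fit(xtr, ytr)
        holdout_r2 = float(r2_score(yte, rf.predict(xte)))
        log.info("phenology regressor held-out R^2 = %.3f (n_test=%d)", holdout_r2, yte.size)
    else:
        rf.fit(x, y)
    return PhenologyModel(rf=rf, bin_days=bin_days, season=env.season, holdout_r2=holdout_r2)


def flowering_window(peak_doy: float | np.ndarray, half_width: float = 15.0,
                     season_window: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Image-selection interval ``[peak - half_width, peak + half_width]``,
    clipped to the season's image window (in DOY) when given."""
    peak = np.asarray(peak_doy, dtype=float)
    lo = peak - half_width
    hi = peak + half_width
    if season_window is not None:
        lo = np.clip(lo, season_window[0], season_window[1])
        hi = np.clip(hi, season_window[0], season_window[1])
    if np.isscalar(peak_doy) or peak.ndim == 0:
        return float(lo), float(hi)
    return lo, hi
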