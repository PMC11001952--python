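"""Tiled random-forest classification and probability fusion across cloud gaps.

The mapping region is partitioned into tiles; each tile trains a local
random forest on samples gathered from its 3x3 neighborhood (100 trees,
``mtry = sqrt(n_features)``, 10-fold cross-validated).  Classification runs
per monthly composite, and the per-image rapeseed probabilities are fused by
averaging over the ``m`` cloud-free observations at each pixel:

    P_i = sum_j p_ij / m,    1 <= m <= n,

so cloud-free images supplement cloud-contaminated ones.  Pixels with
``P > 0.5`` (strict) are rapeseed.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .samples import SamplePool
from .stack import BANDS, CompositeStack

PROBABILITY_CUTOFF = 0.5
NTREE = 100

#: Per-pixel classification features, per monthly composite: the four band
#: composites plus all four vegetation-index composites.
FEATURE_NAMES = (*BANDS, "NDVI", "NDYI", "CI", "WRI")


@dataclasses.dataclass
class TileGrid:
    """A complete, non-overlapping tiling of a rectangular extent.

    Tiles are indexed ``(i, j)`` (row, column of the tile lattice); edge
    tiles may be partial.  ``bounds(tile_id)`` returns the half-open extent
    in the units of the parent extent (degrees in production, pixels for
    synthetic scenes).
    """

    extent: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    tile_size: float
    nx: int
    ny: int

    @property
    def tile_ids(self) -> list[tuple[int, int]]:
        return list(itertools.product(range(self.ny), range(self.nx)))

    def bounds(self, tile_id: tuple[int, int]) -> tuple[float, float, float, float]:
        i, j = tile_id
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise KeyError(f"tile {tile_id} outside grid")
        xmin = self.extent[0] + j * self.tile_size
        ymin = self.extent[1] + i * self.tile_size
        return (xmin, ymin, min(xmin + self.tile_size, self.extent[2]),
                min(ymin + self.tile_size, self.extent[3]))

    def neighborhood(self, tile_id: tuple[int, int]) -> list[tuple[int, int]]:
        """The tile and its existing neighbors in the 3x3 window around it."""
        i, j = tile_id
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise KeyError(f"tile {tile_id} outside grid")
        return [(a, b)
                for a in range(i - 1, i + 2) for b in range(j - 1, j + 2)
                if 0 <= a < self.ny and 0 <= b < self.nx]


def partition_tiles(extent: tuple[float, float, float, float],
                    tile_size: float) -> TileGrid:
    """Partition ``extent`` into ``tile_size`` tiles (2 degrees in
    production); edge tiles may be partial."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty extent")
    nx = int(np.ceil((xmax - xmin) / tile_size))
    ny = int(np.ceil((ymax - ymin) / tile_size))
    return TileGrid(extent=tuple(extent), tile_size=float(tile_size), nx=nx, ny=ny)


def gather_training(tile_id: tuple[int, int], grid: TileGrid,
                    pools: dict[tuple[int, int], SamplePool]) -> SamplePool:
    """Union of the sample pools of a tile and its 3x3 neighbors,
    de-duplicated by sample id."""
    frames = [pools[t].table for t in grid.neighborhood(tile_id) if t in pools]
    if not frames:
        raise ValueError("no training data")
    merged = pd.concat(frames, ignore_index=True).drop_duplicates(subset="id")
    if merged.empty:
        raise ValueError("no training data")
    return SamplePool(table=merged.reset_index(drop=True), block_id=tile_id)


@dataclasses.dataclass
class CVReport:
    """Per-fold cross-validation F1 scores for one tile classifier."""

    fold_f1: np.ndarray

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold": np.arange(1, self.fold_f1.size + 1),
                             "f1": self.fold_f1})


def train_tile_classifier(x: np.ndarray, y: np.ndarray, ntree: int = NTREE,
                          mtry: str | int = "sqrt", folds: int = 10,
                          seed: int = 0) -> tuple[RandomForestClassifier, CVReport]:
    """Fit a binary probability random forest and report 10-fold CV F1.

    Cross-validation characterizes sample quality; it is not used for model
    selection.  A single-class pool is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training pool contains a single class")
    clf = RandomForestClassifier(n_estimators=ntree, max_features=mtry,
                                 random_state=seed)
    n_folds = int(min(folds, counts.min()))
    if n_folds >= 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(clf, x, y, cv=cv, scoring="f1")
    else:
        scores = np.array([np.nan])
    clf.fit(x, y)
    return clf, CVReport(fold_f1=np.asarray(scores))


def classify_image(clf: RandomForestClassifier, features: np.ndarray,
                   valid_mask: np.ndarray) -> np.ndarray:
    """Per-pixel rapeseed probability for one image: (F, H, W) features ->
    (H, W) probability, NaN where invalid."""
    features = np.asarray(features, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if features.ndim != 3 or features.shape[1:] != valid_mask.shape:
        raise ValueError("feature/grid shape mismatch")
    if features.shape[0] != clf.n_features_in_:
        raise ValueError(f"classifier expects {clf.n_features_in_} features, "
                         f"got {features.shape[0]}")
    out = np.full(valid_mask.shape, np.nan)
    ok = valid_mask & np.all(np.isfinite(features), axis=0)
    if ok.any():
        x = features[:, ok].T
        proba = clf.predict_proba(x)
        rape_col = int(np.nonzero(clf.classes_ == 1)[0][0])
        out[ok] = proba[:, rape_col]
    return out


@dataclasses.dataclass
class ProbabilityMap:
    """Fused rapeseed probability with the count of contributing images."""

    p: np.ndarray  # (H, W) in [0, 1] where m >= 1, NaN where m == 0
    m: np.ndarray  # (H, W) int, number of cloud-free observations
    year: int | None = None
    season: str | None = None


def fuse(prob_maps: list[np.ndarray], year: int | None = None,
         season: str | None = None) -> ProbabilityMap:
    """Average per-image probabilities over the valid (cloud-free)
    observations at each pixel; pixels observed in no map are no-data."""
    if not prob_maps:
        raise ValueError("no probability maps to fuse")
    arr = np.stack([np.asarray(p, dtype=float) for p in prob_maps])
    finite = np.isfinite(arr)
    m = finite.sum(axis=0)
    total = np.where(finite, arr, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, total / np.maximum(m, 1), np.nan)
    return ProbabilityMap(p=p, m=m, year=year, season=season)


def binarize(pmap: ProbabilityMap, cutoff: float = PROBABILITY_CUTOFF) -> np.ndarray:
    """Strict thresholding: rapeseed iff ``P > cutoff``; no-data (m = 0)
    encodes as 255 in the uint8 output."""
    out = np.where(pmap.p > cutoff, 1, 0).astype(np.uint8)
    out[pmap.m == 0] = 255
    return out


# ---------------------------------------------------------------------------
# composite feature assembly (shared by the pipeline and ablations)
# ---------------------------------------------------------------------------

def month_features(band_comp: CompositeStack, vi_comp: CompositeStack,
                   month: str) -> tuple[np.ndarray, np.ndarray]:
    """Feature cube (8, H, W) and validity for one monthly composite."""
    layers = [band_comp.layer(b, month) for b in BANDS]
    layers += [vi_comp.layer(v, month) for v in ("NDVI", "NDYI", "CI", "WRI")]
    cube = np.stack(layers)
    valid = band_comp.valid[band_comp.month_index(month)] & np.all(
        np.isfinite(cube), axis=0)
    return cube, valid


def train_month_classifiers(band_comp: CompositeStack, vi_comp: CompositeStack,
                            pool: SamplePool, months: list[str] | None = None,
                            ntree: int = NTREE, mtry: str | int = "sqrt",
                            folds: int = 10, seed: int = 0
                            ) -> dict[str, tuple[RandomForestClassifier, CVReport]]:
    """One classifier per monthly composite, trained on the pool pixels that
    are cloud-free in that month.  Months where training is impossible (all
    samples cloudy, or one class missing) are skipped."""
    months = months or band_comp.months
    rows = pool.table["row"].to_numpy()
    cols = pool.table["col"].to_numpy()
    labels = pool.labels
    out: dict[str, tuple[RandomForestClassifier, CVReport]] = {}
    for month in months:
        cube, valid = month_features(band_comp, vi_comp, month)
        ok = valid[rows, cols]
        if ok.sum() < 10 or np.unique(labels[ok]).size < 2:
            continue
        x = cube[:, rows[ok], cols[ok]].T
        out[month] = train_tile_classifier(x, labels[ok], ntree=ntree,
                                           mtry=mtry, folds=folds, seed=seed)
    return out


def classify_months(classifiers: dict[str, tuple[RandomForestClassifier, CVReport]],
                    band_comp: CompositeStack, vi_comp: CompositeStack,
                    months: list[str] | None = None) -> list[np.ndarray]:
    """Per-month probability maps from a set of monthly classifiers."""
    months = months or list(classifiers)
    maps = []
    for month in months:
        if month not in classifiers:
            continue
        cube, valid = month_features(band_comp, vi_comp, month)
        maps.append(classify_image(classifiers[month][0], cube, valid))
    return maps
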