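"""Validation statistics, trend analysis, and robustness ablations.

Accuracy uses the standard remote-sensing confusion-matrix definitions:
user's accuracy ``UA = TP/(TP+FP)`` (commission), producer's accuracy
``PA = TP/(TP+FN)`` (omission), overall accuracy ``OA = (TP+TN)/N`` and
``F1 = 2 UA PA / (UA + PA)``.  Mapped areas are compared with reported
statistics through the squared Pearson correlation, RMSE and MAE.  Trends in
yearly planted area use Sen's slope (median of all pairwise slopes) with
Mann-Kendall significance.  Two ablations probe robustness: retraining over
every non-empty subset of monthly composites, and injecting label noise into
the training pool with and without spectral-angle purification.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, samples
from .postprocess import NODATA, CropMap
from .samples import SamplePool, build_reference, purify
from .stack import BANDS, CompositeStack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    n_nodata: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("no evaluable pixels")


def confusion(map_values: np.ndarray | CropMap, reference: np.ndarray,
              nodata: int = NODATA) -> ConfusionCounts:
    """Cross-tabulate a binary map against binary reference labels.

    No-data pixels are excluded from the counts and reported separately.
    """
    if isinstance(map_values, CropMap):
        map_values = map_values.values
    map_values = np.asarray(map_values)
    reference = np.asarray(reference)
    if map_values.shape != reference.shape:
        raise ValueError("map and reference shapes differ")
    ok = map_values != nodata
    n_nodata = int((~ok).sum())
    pred = map_values[ok] == 1
    truth = reference[ok].astype(bool)
    if pred.size == 0:
        raise ValueError("no evaluable pixels")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        n_nodata=n_nodata,
    )


@dataclasses.dataclass
class AccuracyMetrics:
    ua: float
    pa: float
    oa: float
    f1: float
    undefined: tuple[str, ...] = ()


def accuracy_metrics(c: ConfusionCounts) -> AccuracyMetrics:
    """UA, PA, OA and F1 from confusion counts.

    Zero-denominator ratios are flagged in ``undefined`` rather than silently
    coerced; by convention F1 is reported as 0 (and flagged) when TP = 0.
    """
    undefined = []
    if c.tp + c.fp > 0:
        ua = c.tp / (c.tp + c.fp)
    else:
        ua = 0.0
        undefined.append("UA")
    if c.tp + c.fn > 0:
        pa = c.tp / (c.tp + c.fn)
    else:
        pa = 0.0
        undefined.append("PA")
    oa = (c.tp + c.tn) / c.n
    if ua + pa > 0:
        f1 = 2 * ua * pa / (ua + pa)
    else:
        f1 = 0.0
        undefined.append("F1")
    if undefined:
        log.warning("undefined accuracy ratios reported as 0: %s", undefined)
    return AccuracyMetrics(ua=ua, pa=pa, oa=oa, f1=f1, undefined=tuple(undefined))


def f1_against_truth(map_values: np.ndarray | CropMap, reference: np.ndarray) -> float:
    return accuracy_metrics(confusion(map_values, reference)).f1


# ---------------------------------------------------------------------------
# area regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AreaRegression:
    r2: float  # NaN when undefined (zero variance in either series)
    rmse: float
    mae: float
    n: int


def area_regression(mapped: np.ndarray, reported: np.ndarray) -> AreaRegression:
    """Agreement between mapped and reported per-region areas.

    R^2 is the squared Pearson correlation; RMSE and MAE measure the actual
    discrepancy (a perfectly correlated but biased map has R^2 = 1 with
    RMSE > 0).  Zero variance in either series leaves R^2 undefined (NaN).
    """
    x = np.asarray(mapped, dtype=float)
    y = np.asarray(reported, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired regions")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("zero variance in an area series; R^2 undefined")
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return AreaRegression(r2=r2, rmse=rmse, mae=mae, n=x.size)


# ---------------------------------------------------------------------------
# separability t-test
# ---------------------------------------------------------------------------

def separability_ttest(vi_pre: np.ndarray, vi_flower: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value comparing an
    index between two phenophases (pre-flowering vs flowering); large |t|
    means the index fluctuates strongly between the stages."""
    a = np.asarray(vi_pre, dtype=float)
    b = np.asarray(vi_flower, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each phenophase sample needs >= 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        return (0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Sen's slope and Mann-Kendall
# ---------------------------------------------------------------------------

def mann_kendall(values: np.ndarray) -> tuple[int, float, float]:
    """Mann-Kendall trend test: returns (S, z, two-sided p).

    Normal approximation with the tie correction; no autocorrelation
    adjustment (the series here are ~23 annual values).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 observations")
    s = 0
    for i in range(n - 1):
        s += int(np.sign(y[i + 1:] - y[i]).sum())
    _, tie_counts = np.unique(y, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var_s <= 0:
        return s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(p)


@dataclasses.dataclass
class TrendResult:
    slope: float
    significant: bool
    p_value: float
    s: int


def sens_slope(values: np.ndarray, times: np.ndarray | None = None,
               alpha: float = 0.05) -> TrendResult:
    """Sen's slope: the median of all pairwise slopes
    ``(y_j - y_i)/(t_j - t_i)``, ``i < j``, with Mann-Kendall significance
    at level ``alpha`` (default 5%)."""
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 observations")
    t = np.arange(y.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    slopes = [
        (y[j] - y[i]) / (t[j] - t[i])
        for i, j in itertools.combinations(range(y.size), 2)
        if t[j] != t[i]
    ]
    slope = float(np.median(slopes))
    s, _, p = mann_kendall(y)
    return TrendResult(slope=slope, significant=bool(p < alpha), p_value=p, s=s)


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def combination_ablation(band_comp: CompositeStack, vi_comp: CompositeStack,
                         pool: SamplePool, truth_rapeseed: np.ndarray,
                         months: list[str] | None = None, seed: int = 0,
                         reuse_classifiers: bool = True) -> pd.DataFrame:
    """F1 for every non-empty subset of monthly composites.

    Seven winter months yield 2^7 - 1 = 127 scenarios and five spring months
    2^5 - 1 = 31.  With the per-month classifier design, retraining on a
    subset is identical to reusing the classifiers trained once per month,
    so they are cached by default (``reuse_classifiers=False`` retrains from
    scratch with identical results).
    """
    months = months or band_comp.months
    cache: dict[str, np.ndarray] = {}
    if reuse_classifiers:
        classifiers = classify.train_month_classifiers(band_comp, vi_comp, pool,
                                                       months=months, seed=seed)
        for month in months:
            if month in classifiers:
                cube, valid = classify.month_features(band_comp, vi_comp, month)
                cache[month] = classify.classify_image(classifiers[month][0], cube, valid)
    rows = []
    for k in range(1, len(months) + 1):
        for subset in itertools.combinations(months, k):
            if reuse_classifiers:
                maps = [cache[mo] for mo in subset if mo in cache]
            else:
                clfs = classify.train_month_classifiers(band_comp, vi_comp, pool,
                                                        months=list(subset), seed=seed)
                maps = classify.classify_months(clfs, band_comp, vi_comp,
                                                months=list(subset))
            if not maps:
                f1 = float("nan")
            else:
                fused = classify.fuse(maps)
                binary = classify.binarize(fused)
                f1 = f1_against_truth(binary, truth_rapeseed)
            rows.append(("+".join(subset), k, f1))
    return pd.DataFrame(rows, columns=["months", "n_months", "f1"])


def _train_eval_f1(pool: SamplePool, features: np.ndarray, valid: np.ndarray,
                   truth_rapeseed: np.ndarray, seed: int) -> float:
    clf, _ = classify.train_tile_classifier(
        pool.table[list(BANDS)].to_numpy(dtype=float), pool.labels,
        folds=5, seed=seed)
    prob = classify.classify_image(clf, features, valid)
    fused = classify.fuse([prob])
    return f1_against_truth(classify.binarize(fused), truth_rapeseed)


def noise_ablation(pool: SamplePool, confuser_spectra: np.ndarray,
                   features: np.ndarray, valid: np.ndarray,
                   truth_rapeseed: np.ndarray,
                   fractions: list[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                   with_purify: bool = True, n_reps: int = 3,
                   seed: int = 0) -> pd.DataFrame:
    """Classification F1 versus injected training-label noise.

    For each fraction, that share of rapeseed samples has its spectrum
    replaced by a confuser spectrum (label unchanged), the pool is optionally
    purified with the spectral angle mapper, a classifier is trained on the
    flowering-window spectra and evaluated against the scene truth.  Returns
    mean +/- sd over ``n_reps`` replicate draws; paired comparisons should
    use the same ``seed`` with and without purification.
    """
    fractions = list(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("noise fractions must lie in [0, 1]")
    confuser_spectra = np.asarray(confuser_spectra, dtype=float)
    rows = []
    for frac in fractions:
        f1s = []
        for rep in range(n_reps):
            rng = np.random.default_rng((seed, rep, int(frac * 1000)))
            noisy = pool.table.copy()
            rape_idx = np.nonzero(noisy["label"].to_numpy() == 1)[0]
            n_noise = int(round(frac * rape_idx.size))
            if n_noise:
                pick = rng.choice(rape_idx, size=n_noise, replace=False)
                src = rng.choice(confuser_spectra.shape[0], size=n_noise)
                noisy.loc[noisy.index[pick], list(BANDS)] = confuser_spectra[src]
            noisy_pool = SamplePool(table=noisy, block_id=pool.block_id)
            if with_purify:
                ref = build_reference(noisy_pool)
                noisy_pool = purify(noisy_pool, ref)
            f1s.append(_train_eval_f1(noisy_pool, features, valid,
                                      truth_rapeseed, seed=seed + rep))
        rows.append((frac, float(np.mean(f1s)), float(np.std(f1s)), with_purify))
    return pd.DataFrame(rows, columns=["fraction", "f1_mean", "f1_sd", "purified"])


def pool_purity(pool: SamplePool, noisy_ids: set[int]) -> float:
    """Share of rapeseed-labeled samples that are genuine (not injected)."""
    rape = pool.table[pool.table["label"] == 1]
    if rape.empty:
        return float("nan")
    genuine = (~rape["id"].isin(list(noisy_ids))).sum()
    return float(genuine / len(rape))
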