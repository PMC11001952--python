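"""End-to-end pipeline: scene simulation through validated crop map.

``run_pipeline`` executes the full chain on a synthetic scene with known
truth: simulate -> harmonize/indices/composites -> phenology (SAR-calibrated
records, environmental regressor, flowering window) -> candidate samples and
spectral-angle purification -> tiled per-month classification and
probability fusion -> cropland/slope masking and hole filling -> confusion
metrics and area regression.  Every stochastic stage consumes an explicit
named seed derived from the master seed, and a manifest (config hash, seeds,
per-stage checksums) suffices to reproduce any output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Any

import numpy as np
import yaml

from . import classify, evaluate, indices, phenology, samples, seasons, synth
from .postprocess import CropMap, apply_masks, fill_holes, union_cropland_mask

log = logging.getLogger(__name__)

_STAGES = ("scene", "phenology", "sar", "env", "samples", "classify", "statistics")


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips through YAML unchanged."""

    # scene
    height: int = 128
    width: int = 128
    pixel_size: float = 30.0
    rapeseed_fraction: float = 0.2
    season: str = seasons.WINTER
    year: int = 2021
    cloud_prob: float = 0.3
    noise_sd: float = 0.005
    seed: int = 42
    # phenology
    n_pheno_records: int = 200
    calibration_tolerance: float = 5.0
    pheno_grid_res: float = 0.005
    whittaker_lam: float = 100.0
    window_half_width: float = 15.0
    rfr_ntree: int = 100
    min_pheno_cells: int = 20
    # samples
    ci_threshold: float = samples.CI_THRESHOLD
    ci_guard: float = 0.05  # ambiguous band [guard, threshold): no negatives
    n_per_class: int = samples.N_PER_CLASS
    sam_form: str = "l2"
    sam_threshold_mode: str = "angle_std"
    # classify
    tile_size_px: int = 64
    rf_ntree: int = classify.NTREE
    cv_folds: int = 10
    fusion_cutoff: float = classify.PROBABILITY_CUTOFF
    # postprocess
    slope_limit: float = 25.0
    hole_threshold_ha: float | None = None  # season default when None
    cropland_error_rate: float = 0.02
    # evaluate
    n_stat_regions: int = 4
    reporting_noise: float = 0.1

    def __post_init__(self) -> None:
        if self.season not in seasons.SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if not 0.0 <= self.ci_threshold <= 1.0:
            raise ValueError("ci_threshold outside documented range")
        if not 0.0 < self.fusion_cutoff < 1.0:
            raise ValueError("fusion_cutoff must be in (0, 1)")

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds derived deterministically from the master."""
        return {name: (self.seed * 1009 + i * 9973) % (2**31 - 1)
                for i, name in enumerate(_STAGES)}

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _checksum(array: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(array).tobytes()).hexdigest()[:16]


@dataclasses.dataclass
class PipelineResult:
    crop_map: CropMap
    probability: classify.ProbabilityMap
    truth: synth.SceneTruth
    report: dict[str, Any]
    manifest: dict[str, Any]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full mapping chain on a synthetic scene; see module docs."""
    cfg = config
    seeds = cfg.stage_seeds()
    manifest: dict[str, Any] = {"config_hash": cfg.config_hash(), "seeds": seeds,
                                "checksums": {}, "counts": {}}

    # --- scene -------------------------------------------------------------
    scene_cfg = synth.SceneConfig(
        height=cfg.height, width=cfg.width, pixel_size=cfg.pixel_size,
        rapeseed_fraction=cfg.rapeseed_fraction, season=cfg.season,
        year=cfg.year, cloud_prob=cfg.cloud_prob, noise_sd=cfg.noise_sd,
        seed=seeds["scene"])
    stack, truth = synth.generate_scene(scene_cfg)
    manifest["checksums"]["class_map"] = _checksum(truth.class_map)
    log.info("scene: %dx%d, %d images, %.1f%% rapeseed", cfg.height, cfg.width,
             len(stack), 100 * truth.rapeseed_mask.mean())

    # --- indices and composites -------------------------------------------
    stack = indices.harmonize(stack)  # identity defaults; hook for real sensors
    vi = indices.compute_indices(stack)
    band_comp = indices.monthly_median_composite(stack)
    vi_comp = indices.monthly_median_composite(vi)

    # --- phenology ---------------------------------------------------------
    records = synth.generate_pheno_records(truth, n=cfg.n_pheno_records,
                                           seed=seeds["phenology"])
    sar = synth.generate_sar_series(records, seed=seeds["sar"])
    peaks = {}
    for rec_id, frame in sar.items():
        try:
            peaks[rec_id] = phenology.detect_vv_peak(
                frame["doy"].to_numpy(), frame["vv"].to_numpy(),
                lam=cfg.whittaker_lam)
        except ValueError:
            continue
    kept, dropped = phenology.calibrate_records(records, peaks,
                                                tolerance=cfg.calibration_tolerance)
    manifest["counts"]["records_in"] = len(records)
    manifest["counts"]["records_kept"] = len(kept)
    manifest["counts"]["records_dropped"] = len(dropped)

    env = synth.generate_env_series(truth, grid_res=cfg.pheno_grid_res,
                                    seed=seeds["env"])
    pheno_r2 = None
    if len(env) >= cfg.min_pheno_cells:
        model = phenology.fit_phenology_model(env, ntree=cfg.rfr_ntree,
                                              holdout=0.3, seed=seeds["env"])
        pheno_r2 = model.holdout_r2
        field = model.predict_field(env)
        peak_doy = field.mean_doy
    else:
        # tiny scenes: fall back to the calibrated record mean
        log.warning("only %d phenology cells (<%d); using record-mean peak",
                    len(env), cfg.min_pheno_cells)
        peak_doy = float(np.mean([r.flowering_doy for r in kept])) if kept else \
            synth._PEAK_BASE[cfg.season]
    window = phenology.flowering_window(peak_doy, half_width=cfg.window_half_width)
    manifest["counts"]["flowering_peak_doy"] = round(float(peak_doy), 2)

    # --- training samples --------------------------------------------------
    # per-image canola index inside the flowering window; a pixel is a
    # candidate if any cloud-free window acquisition reaches the threshold,
    # and its sample spectrum comes from that maximising acquisition
    win_idx = [i for i, d in enumerate(stack.dates)
               if d.year == cfg.year and window[0] <= seasons.date_to_doy(d)
               <= window[1]]
    if not win_idx:  # no acquisition in the window: use the nearest date
        doys = [seasons.date_to_doy(d) if d.year == cfg.year else -999
                for d in stack.dates]
        win_idx = [int(np.argmin([abs(d - peak_doy) for d in doys]))]
    ci_win = vi.layers["CI"][win_idx]  # (n_win, H, W), NaN where cloudy
    observed = np.isfinite(ci_win).any(axis=0)
    with np.errstate(all="ignore"):
        ci_layer = np.where(observed, np.nanmax(ci_win, axis=0), np.nan)
        best = np.nanargmax(np.where(np.isfinite(ci_win), ci_win, -np.inf),
                            axis=0)
    band_win = np.stack([np.stack([stack.images[i].band(b) for i in win_idx])
                         for b in indices.BANDS])  # (4, n_win, H, W)
    rr, cc = np.indices(ci_layer.shape)
    flower_bands = band_win[:, best, rr, cc]
    flower_bands[:, ~observed] = np.nan
    # ambiguous guard band: close to the threshold but never over it, often
    # an under-observed flowering pixel — unsafe as a non-rapeseed label
    ambiguous = observed & (ci_layer >= cfg.ci_guard) & (ci_layer < cfg.ci_threshold)

    grid = classify.partition_tiles((0, 0, cfg.width, cfg.height),
                                    cfg.tile_size_px)
    pools: dict[tuple[int, int], samples.SamplePool] = {}
    for tile_id in grid.tile_ids:
        xmin, ymin, xmax, ymax = (int(v) for v in grid.bounds(tile_id))
        tile_mask = np.zeros((cfg.height, cfg.width), dtype=bool)
        tile_mask[ymin:ymax, xmin:xmax] = True
        candidates = samples.ci_candidates(ci_layer, cfg.ci_threshold) & tile_mask
        pool = samples.stratified_sample(
            candidates, flower_bands, n_per_class=cfg.n_per_class,
            seed=seeds["samples"] + tile_id[0] * 31 + tile_id[1],
            valid_mask=tile_mask, exclude_mask=ambiguous, block_id=tile_id)
        if len(pool):
            pools[tile_id] = pool
    n_auto = sum(len(p) for p in pools.values())

    purified: dict[tuple[int, int], samples.SamplePool] = {}
    for tile_id, pool in pools.items():
        try:
            ref = samples.build_reference(pool, threshold_mode=cfg.sam_threshold_mode,
                                          form=cfg.sam_form)
            purified[tile_id] = samples.purify(pool, ref, form=cfg.sam_form)
        except ValueError:  # too few rapeseed samples in this tile
            purified[tile_id] = pool
    n_pure = sum(len(p) for p in purified.values())
    manifest["counts"]["samples_auto"] = n_auto
    manifest["counts"]["samples_after_sam"] = n_pure
    log.info("samples: %d auto, %d after purification", n_auto, n_pure)

    # --- tiled classification and fusion ------------------------------------
    prob_layers: list[np.ndarray] = []
    month_maps: dict[str, np.ndarray] = {
        m: np.full((cfg.height, cfg.width), np.nan) for m in band_comp.months}
    for tile_id in grid.tile_ids:
        try:
            train_pool = classify.gather_training(tile_id, grid, purified)
        except ValueError:
            continue
        classifiers = classify.train_month_classifiers(
            band_comp, vi_comp, train_pool, ntree=cfg.rf_ntree,
            folds=cfg.cv_folds, seed=seeds["classify"])
        xmin, ymin, xmax, ymax = (int(v) for v in grid.bounds(tile_id))
        for month, (clf, _) in classifiers.items():
            cube, valid = classify.month_features(band_comp, vi_comp, month)
            sub = classify.classify_image(clf, cube[:, ymin:ymax, xmin:xmax],
                                          valid[ymin:ymax, xmin:xmax])
            month_maps[month][ymin:ymax, xmin:xmax] = sub
    prob_layers = [month_maps[m] for m in band_comp.months
                   if np.isfinite(month_maps[m]).any()]
    if prob_layers:
        pmap = classify.fuse(prob_layers, year=cfg.year, season=cfg.season)
    else:
        # nothing classifiable (e.g. a scene without any rapeseed candidates):
        # the mapped result is "no rapeseed anywhere", not a failure
        log.warning("no classifiable months; emitting an empty rapeseed map")
        pmap = classify.ProbabilityMap(
            p=np.zeros((cfg.height, cfg.width)),
            m=np.ones((cfg.height, cfg.width), dtype=int),
            year=cfg.year, season=cfg.season)
    binary = classify.binarize(pmap, cutoff=cfg.fusion_cutoff)
    manifest["checksums"]["probability"] = _checksum(
        np.nan_to_num(pmap.p, nan=-1.0))

    # --- post-processing ----------------------------------------------------
    crop = CropMap(values=binary, season=cfg.season, year=cfg.year,
                   pixel_area=cfg.pixel_size**2)
    layer_a, layer_b = synth.generate_cropland_layers(
        truth, error_rate=cfg.cropland_error_rate, seed=seeds["scene"] + 1)
    cropland = union_cropland_mask(layer_a, layer_b)
    before = int(crop.rapeseed_mask.sum())
    crop = apply_masks(crop, cropland, truth.slope_deg, slope_limit=cfg.slope_limit)
    masked = int(crop.rapeseed_mask.sum())
    crop = fill_holes(crop, cfg.hole_threshold_ha)
    after = int(crop.rapeseed_mask.sum())
    manifest["counts"]["rapeseed_px_raw"] = before
    manifest["counts"]["rapeseed_px_masked"] = masked
    manifest["counts"]["rapeseed_px_final"] = after
    manifest["checksums"]["crop_map"] = _checksum(crop.values)
    log.info("postprocess: %d -> %d (masks) -> %d (hole fill) rapeseed px",
             before, masked, after)

    # --- evaluation ----------------------------------------------------------
    counts = evaluate.confusion(crop, truth.rapeseed_mask)
    metrics = evaluate.accuracy_metrics(counts)
    report: dict[str, Any] = {
        "ua": metrics.ua, "pa": metrics.pa, "oa": metrics.oa, "f1": metrics.f1,
        "flowering_peak_doy": float(peak_doy),
        "phenology_holdout_r2": pheno_r2,
        "mapped_area_ha": crop.rapeseed_area_ha(),
        "true_area_ha": truth.rapeseed_area_ha(),
    }

    # per-region area agreement on quadrant "administrative regions"
    if cfg.n_stat_regions >= 2:
        region_truths, mapped_areas = _quadrant_regions(crop, truth,
                                                        cfg.n_stat_regions)
        stats_table = synth.generate_statistics(
            region_truths, reporting_noise=cfg.reporting_noise,
            seed=seeds["statistics"])
        reg = evaluate.area_regression(np.asarray(mapped_areas),
                                       stats_table["reported_area_ha"].to_numpy())
        report["area_r2"] = reg.r2
        report["area_rmse_ha"] = reg.rmse
        report["area_mae_ha"] = reg.mae

    return PipelineResult(crop_map=crop, probability=pmap, truth=truth,
                          report=report, manifest=manifest)


def _quadrant_regions(crop: CropMap, truth: synth.SceneTruth, n_regions: int
                      ) -> tuple[list[synth.SceneTruth], list[float]]:
    """Split the scene into row bands acting as reporting regions."""
    h = truth.class_map.shape[0]
    edges = np.linspace(0, h, n_regions + 1).astype(int)
    region_truths, mapped = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sub = synth.SceneTruth(
            class_map=truth.class_map[a:b], peak_flowering_doy=truth.peak_flowering_doy[a:b],
            slope_deg=truth.slope_deg[a:b], cropland_truth=truth.cropland_truth[a:b],
            season=truth.season, year=truth.year, pixel_size=truth.pixel_size,
            geotransform=truth.geotransform)
        region_truths.append(sub)
        mapped.append(float((crop.values[a:b] == 1).sum()) * crop.pixel_area / 1e4)
    return region_truths, mapped
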