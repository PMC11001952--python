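# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `rapemap`.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The mapping model

The chain assumes a binary target (rapeseed vs everything else) whose only
strong spectral handle is the flowering signal: during bloom, green
reflectance rises sharply while blue stays low, so the canola index
CI = ρNIR (ρRed + ρGreen) crosses a fixed threshold (0.07) only for
flowering rapeseed, and NDYI rises.  Outside bloom, rapeseed is assumed
near-indistinguishable from co-occurring crops.  Three consequences shape
the design:

- **Flowering time must be predicted, not assumed.**  Peak-flowering day of
  year (DOY) varies with climate; it is regressed on daily environmental
  drivers (10 variables: canopy surface water, canopy water evaporation,
  potential evaporation, soil moisture and temperature at 0–10 and
  10–40 cm, accumulated air temperature, downward shortwave radiation,
  precipitation rate) plus latitude, longitude and elevation, using a
  random forest (100 trees, `max_features="sqrt"`).  Daily series are
  compressed to 10-day-mean bins so the feature vector has a fixed length
  regardless of season; the winter window [Nov 1, Feb 1) gives 10 bins per
  variable, 103 features in all.  Training targets come from recorded
  flowering dates cross-checked against the day the SAR VV backscatter
  peaks — the VV peak coincides with peak flowering — keeping only records
  within 5 days of the SAR peak, aggregated to a coarse grid (mean DOY per
  cell) to avoid local overfitting.
- **Labels must be generated, not collected.**  Training pixels for the
  classifier are labeled by thresholding per-image CI inside the ±15-day
  flowering window (a pixel is a candidate if *any* cloud-free window
  acquisition reaches 0.07, and its sample spectrum is taken from that
  maximising acquisition).  Up to 2000 pixels per class per tile are drawn
  uniformly without replacement.  The pool is then purified with the
  spectral angle mapper (SAM): the reference spectrum is the mean of the
  rapeseed samples above the 90th CI percentile, and samples whose angle
  to it exceeds the standard deviation of all rapeseed angles are dropped.
- **Classification must survive cloud gaps.**  The region is tiled; each
  tile trains on samples from its 3×3 neighborhood.  One random-forest
  classifier per monthly median composite (features: the four band
  composites plus NDVI/NDYI/CI/WRI) produces a per-month probability map;
  fusion averages the probabilities over the m cloud-free months at each
  pixel, and P > 0.5 (strict) is rapeseed.  Post-processing removes
  rapeseed outside the merged cropland layers or on slope > 25° (strict,
  Horn's 3×3 method on the DEM), then fills fully-enclosed background
  holes below 1 ha (winter) / 5 ha (spring); at 30 m those thresholds are
  11 and 56 pixels (nearest-integer of ha·10⁴/pixel-area).

### Deliberate departures from common conventions

- The SAM angle uses L2 norms, arccos(⟨u,r⟩/(‖u‖₂‖r‖₂)), the standard
  scale-invariant form.  A variant with unsquared denominator sums
  (√Σuᵢ·√Σrᵢ) circulates in parts of the applied literature; it is not
  scale-invariant and is provided only behind `form="printed"`.
- Accuracy metrics use the standard remote-sensing definitions
  UA = TP/(TP+FP), PA = TP/(TP+FN), OA = (TP+TN)/N,
  F1 = 2·UA·PA/(UA+PA).  Published variants that set UA = (TP+TN)/N are
  internally inconsistent with a distinct F1 and are not implemented.
- The area-opening tool often cited for map cleanup removes small
  *objects*; the intent here is hole *filling*, which is what
  `fill_holes` does.  A small-object-removal pass with the same
  thresholds exists (`remove_small_objects`) but is off by default.

## The synthetic study conditions

`rapemap.synth` generates every input with known truth.  The defaults are
the study conditions used throughout the tests and the acceptance script;
they are fixed, not tuned per experiment.

- **Landscape**: smoothed Gaussian noise thresholded at class quantiles →
  contiguous fields of five classes (rapeseed, confuser crop, other
  vegetation, bare/built, water; 20% rapeseed by default, the rest split
  30/40/20/10).  Cropland classes are drawn from non-steep (≤25°) pixels
  only, with thresholds computed on that subset so the configured
  whole-scene fractions still hold — cultivation on steep terrain is
  banned, and truth is kept consistent with that rule.
- **Spectra**: class-specific baselines with piecewise-Gaussian temporal
  bumps.  Rapeseed and the confuser are ~1 noise-sigma apart per band
  outside flowering and share the same green-up bump, so non-flowering
  months carry only weak signal; rapeseed additionally receives the
  flowering bump (green +0.22, red +0.08, NIR +0.12, blue +0.01; Gaussian
  width 8 days around the per-pixel peak DOY).  At the default noise
  (σ = 0.005 reflectance, i.i.d. per band) the confuser's CI stays below
  0.07 with >5σ margin, while rapeseed CI within ±10 days of its peak is
  ≥0.07 — these margins are the generator's contract with the
  threshold-based sampler.
- **Phenology truth**: per-pixel peak DOY = seasonal base (winter: DOY 75,
  spring: 195) + a 10-day north–south gradient + smooth 3-day jitter.
- **Environmental link**: per-cell mean soil temperature is the inverse of
  a fixed DOY-generating function (logistic in temperature plus 0.5·lat;
  parameters in `synth._DOY_FN`), so a regressor on the daily series can
  recover the scene phenology.  The standalone cell generator draws
  latitude and temperature first and adds Gaussian DOY noise (default sd
  2 days) for recovery experiments.
- **SAR**: VV series = −14 dB + 3 dB Gaussian bump (width 12 d) at the
  *true* peak, sampled every 2 days, noise sd 0.5 dB.  Recorded dates in
  the sample points carry small errors plus, for 15% of records, a ±10-day
  transcription error that the 5-day calibration rule must catch.  Peak
  detection smooths with a Whittaker penalty of λ = 100 — heavier than the
  general-purpose default (λ = 10) because the argmax of a shallow bump
  wanders by several days under dB-level noise; with 2-day sampling this
  pairing recovers peaks within ±2 days in ≥95% of records (measured in
  the test suite).
- **Clouds**: per-image i.i.d. Bernoulli pixel dropout (default 10%; the
  demo pipeline uses 30%).
- **Statistics**: reported area = true area × (1 + ε), ε ~ N(0, 0.1) by
  default; yearly trend series use a linear decline plus noise.

What the generator does **not** emulate: atmospheric and BRDF effects,
topographic illumination, SAR speckle physics, mixed pixels at field
boundaries, intercropping, spatially correlated cloud structure, and
class spectra drawn from real libraries.  Passing tests therefore
demonstrate the *internal* correctness and cloud-robustness of the chain
under its stated assumptions, not performance on real imagery.

## Numerical and design choices

- **Whittaker smoother**: second-order difference penalty, solved as the
  sparse system (I + λD′D)z = y; λ = 0 returns the input, λ → ∞ tends to
  the least-squares line.
- **Zero denominators** in index ratios yield no-data (NaN), never 0 — a
  0 would silently mimic a valid index value.  Median compositing uses
  valid observations only; even counts average the central pair.
- **Harmonization** ships identity coefficients with a per-sensor,
  per-band (gain, offset) slot; cross-sensor calibration constants belong
  to the calibration literature and are supplied by the user.
- **Ties and strictness**: VV-peak ties take the earliest date; CI ≥ 0.07
  is inclusive; fusion cutoff P > 0.5 and slope limit > 25° are strict;
  hole areas strictly below threshold are filled.
- **Negative-label guard band**: pixels whose window-maximum CI lies in
  [0.05, 0.07) are excluded from the *non-rapeseed* sampling space.  Under
  heavy cloud, a flowering pixel whose near-peak acquisition is lost
  often lands just below the threshold; labeling it non-rapeseed poisons
  the classifiers.  The positive threshold is untouched.
- **Per-month classifiers**: the per-image probabilities of the fusion are
  realized as one classifier per monthly composite.  Because months do not
  interact in training, the combination ablation can train each month once
  and fuse subsets — identical to retraining per subset, at 1/60th the
  cost (a from-scratch mode exists).
- **Purification threshold**: "std of the angles of all rapeseed samples
  to the reference" (the default) grows with contamination, which is what
  makes it an effective noise filter; on nearly clean pools it over-trims,
  visible as reduced accuracy at zero injected noise in the ablation.  The
  alternative `threshold_mode="band_std"` uses the mean per-band standard
  deviation of the contributing spectra.
- **Mann–Kendall** significance uses the normal approximation with tie
  correction and no autocorrelation adjustment — the series here are ~23
  annual values.
- **Seeds**: every stochastic stage consumes a named seed derived
  deterministically from the master seed; the run manifest (config hash,
  seeds, per-stage checksums) reproduces any output bit-exactly.
- **Raster I/O** uses plain TIFF plus a JSON sidecar carrying
  geotransform/CRS/nodata; points travel as GeoJSON, tables as CSV,
  configuration as YAML.  Grid or CRS mismatches raise; nothing is
  silently resampled.  The synthetic scenes use a degree-based
  geotransform (~30 m pixels) so coarse-grid aggregation in degrees works
  unchanged.

## Problem sizes

Tests and the acceptance script run on scaled scenes chosen to exercise
every code path: 64×64 scenes for module-level experiments and the
combination ablation, a 128×128 demo scene with 30% cloud for end-to-end
recovery, 300 cells for phenology-regressor recovery, 200 records for the
SAR Monte-Carlo, 20 regions for the statistics regression, and 23-year
series for trend analysis.

## Known limitations

- The confuser crop is a single spectral class; real scenes contain many,
  with seasonally shifting spectra.
- Sample spectra feed the purifier from one (maximising) flowering
  acquisition; multi-date SAM purification is not implemented.
- The per-month classifier design assumes monthly composites are the
  fusion unit; per-raw-image fusion would need per-acquisition classifiers.
- Tiles share a single flowering window per scene (the cell-mean peak);
  strongly heterogeneous phenology within a scene would need per-tile
  windows.
- No vectorization/parcel delineation, no atmospheric correction, no
  cloud *detection* (validity masks are inputs).
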