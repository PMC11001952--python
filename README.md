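# rapemap

Phenology-driven rapeseed mapping from multi-temporal multispectral
satellite imagery.

Rapeseed (*Brassica napus*) is one of the few crops that can be recognized
from space by a single, short-lived event: the bright-yellow bloom raises
green reflectance while blue stays low, a signature captured by simple band
ratios for roughly two weeks per season.  Mapping it over large, cloudy
regions therefore requires knowing *when* each place flowers, labeling
training pixels automatically from the flowering signal, and classifying
robustly when any individual acquisition may be lost to cloud.  `rapemap`
implements that chain as a tested, reusable library for remote-sensing
researchers and crop-mapping practitioners, together with a synthetic-scene
generator so every stage can be validated against known ground truth
without downloading any satellite data.

## Method

For each acquisition with blue/green/red/NIR surface reflectance
(ρ<sub>Blue</sub>, ρ<sub>Green</sub>, ρ<sub>Red</sub>, ρ<sub>NIR</sub>),
four vegetation indices are computed:

- NDVI = (ρ<sub>NIR</sub> − ρ<sub>Red</sub>) / (ρ<sub>NIR</sub> + ρ<sub>Red</sub>)
- NDYI = (ρ<sub>Green</sub> − ρ<sub>Blue</sub>) / (ρ<sub>Green</sub> + ρ<sub>Blue</sub>)
- CI (canola index) = ρ<sub>NIR</sub> × (ρ<sub>Red</sub> + ρ<sub>Green</sub>)
- WRI = ((ρ<sub>NIR</sub> − ρ<sub>Green</sub>) / (ρ<sub>NIR</sub> + ρ<sub>Green</sub>)) × (ρ<sub>Blue</sub> / (ρ<sub>Green</sub> + ρ<sub>Red</sub>))

The pipeline then proceeds in five stages:

1. **Flowering phenology.**  Recorded flowering dates at sample points are
   cross-checked against the day the SAR VV backscatter peaks (the two
   coincide for rapeseed); records disagreeing by more than 5 days are
   dropped.  Survivors are aggregated to a coarse grid and a random-forest
   regression (100 trees, mtry = √p) maps daily environmental drivers —
   soil moisture and temperature, radiation, precipitation, evaporation,
   plus latitude, longitude, elevation — to the per-cell peak-flowering
   day of year, which defines a ±15-day image-selection window.
2. **Automatic training samples.**  Pixels whose CI reaches 0.07 in any
   cloud-free flowering-window acquisition become rapeseed candidates;
   up to 2000 pixels per class per tile are drawn by stratified random
   sampling.  The pool is purified with the spectral angle mapper:
   α = arccos(⟨u, r⟩ / (‖u‖‖r‖)) against a reference rapeseed spectrum,
   removing samples whose angle exceeds a data-driven threshold.
3. **Tiled classification and fusion.**  Each tile trains local random
   forests on samples gathered from its 3×3 neighborhood, classifies every
   monthly median composite, and fuses the per-image rapeseed
   probabilities over the m cloud-free observations at each pixel:
   P = (Σ<sub>j</sub> p<sub>j</sub>) / m.  Pixels with P > 0.5 are rapeseed.
4. **Post-processing.**  Rapeseed outside the union of two cropland layers
   or on slopes steeper than 25° is removed, then background holes smaller
   than 1 ha (winter) / 5 ha (spring) fully enclosed by rapeseed are filled.
5. **Evaluation.**  User's/producer's/overall accuracy and F1 from the
   confusion matrix; R², RMSE, MAE of mapped versus reported areas; Sen's
   slope with Mann–Kendall significance for planted-area trends; and two
   robustness ablations (monthly image combinations, training-label noise
   with/without purification).

## Worked example

Run the full chain on the default synthetic demo scene (128×128 pixels at
30 m, 20% rapeseed, 8 acquisitions across the winter season, 30% cloud):

```bash
rapemap run --out demo/
```

which prints (seed 42, the default):

```json
{
 "ua": 0.9978593272171253,
 "pa": 0.9957277998169057,
 "oa": 0.9987181834828786,
 "f1": 0.9967924240109974,
 "flowering_peak_doy": 76.78104040046951,
 "phenology_holdout_r2": 0.9301536159718141,
 "mapped_area_ha": 294.3,
 "true_area_ha": 294.93,
 "area_r2": 0.9875740617046902,
 "area_rmse_ha": 10.980766188921594,
 "area_mae_ha": 8.616888959452377
}
```

Reading the numbers: the pipeline estimated the regional flowering peak at
day-of-year ≈ 77 (truth: mid-March ± a latitude gradient), the
environmental regressor explained 93% of held-out flowering-date variance,
and the final map recovers the true rapeseed extent with F1 ≈ 0.997 —
user's and producer's accuracy both >0.995 — despite 30% of every image
being cloud-masked.  Mapped area (294.3 ha) agrees with the true planted
area (294.9 ha), and per-region mapped areas track the noisily "reported"
statistics with R² ≈ 0.99.  `demo/` holds the binary map, the fused
probability map, the run manifest (config hash, per-stage seeds and
checksums) and the report.

The same stages are available individually (`rapemap simulate | indices |
phenology | samples | classify | postprocess | evaluate`) and as library
functions (`rapemap.pipeline.run_pipeline`, `rapemap.evaluate.sens_slope`,
...).

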