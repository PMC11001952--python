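"""Generator contracts: determinism, class fractions, spectral behaviour,
environmental/SAR/statistics links to known truth."""

import numpy as np
import pytest

from rapemap import evaluate, indices, seasons, synth
from rapemap.phenology import PhenoRecord


def _stack_array(stack):
    return np.stack([img.bands for img in stack])


class TestGenerateScene:
    def test_identical_seed_gives_bit_identical_output(self):
        cfg = dict(height=32, width=32, seed=1)
        s1, t1 = synth.generate_scene(synth.SceneConfig(**cfg))
        s2, t2 = synth.generate_scene(synth.SceneConfig(**cfg))
        assert np.array_equal(_stack_array(s1), _stack_array(s2))
        assert np.array_equal(t1.class_map, t2.class_map)
        assert np.array_equal(t1.peak_flowering_doy, t2.peak_flowering_doy,
                              equal_nan=True)

    def test_zero_rapeseed_fraction_has_no_rapeseed_and_no_ci_crossing(self):
        cfg = synth.SceneConfig(height=64, width=64, rapeseed_fraction=0.0, seed=3)
        stack, truth = synth.generate_scene(cfg)
        assert truth.rapeseed_mask.sum() == 0
        vi = indices.compute_indices(stack)
        assert np.nanmax(vi.layers["CI"]) < 0.07

    def test_rapeseed_fraction_recovered_in_truth(self):
        cfg = synth.SceneConfig(height=200, width=200, rapeseed_fraction=0.2, seed=7)
        _, truth = synth.generate_scene(cfg)
        assert truth.rapeseed_mask.mean() == pytest.approx(0.2, abs=0.03)

    def test_reflectance_bounded_and_finite(self, small_scene):
        stack, _ = small_scene
        arr = _stack_array(stack)
        assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_empty_time_series_rejected(self):
        with pytest.raises(ValueError, match="empty time series"):
            synth.SceneConfig(height=8, width=8, acquisition_dates=[])

    def test_rapeseed_flowering_raises_ci_above_threshold(self, small_scene):
        """Within the flowering window the canola index crosses 0.07 and the
        yellowness index rises relative to pre-flowering."""
        stack, truth = small_scene
        vi = indices.compute_indices(stack)
        rape = truth.rapeseed_mask
        doy_peak = truth.peak_flowering_doy
        # image nearest the scene's mean peak (mid-March acquisitions)
        mean_peak = np.nanmean(doy_peak)
        days = [abs(seasons.date_to_doy(d) - mean_peak) if d.year == truth.year
                else 999 for d in vi.dates]
        flower_i = int(np.argmin(days))
        in_window = rape & (np.abs(doy_peak -
                                   seasons.date_to_doy(vi.dates[flower_i])) <= 10)
        ci_flower = vi.layers["CI"][flower_i][in_window]
        ndyi_flower = vi.layers["NDYI"][flower_i][in_window]
        ci_pre = vi.layers["CI"][0][in_window]  # November: pre-flowering
        ndyi_pre = vi.layers["NDYI"][0][in_window]
        assert np.nanmin(ci_flower) >= 0.07
        assert np.nanmean(ndyi_flower) > np.nanmean(ndyi_pre)
        assert np.nanmax(ci_pre) < 0.07

    def test_confuser_never_crosses_ci_threshold(self, small_scene):
        stack, truth = small_scene
        vi = indices.compute_indices(stack)
        conf = truth.class_map == synth.CONFUSER
        assert np.nanmax(vi.layers["CI"][:, conf]) < 0.07

    def test_cloud_probability_controls_mask_density(self):
        cfg = synth.SceneConfig(height=64, width=64, cloud_prob=0.3, seed=9)
        stack, _ = synth.generate_scene(cfg)
        invalid = np.mean([1.0 - img.valid.mean() for img in stack])
        assert invalid == pytest.approx(0.3, abs=0.03)

    def test_separability_welch_t_on_default_config(self, small_scene):
        """Flowering vs pre-flowering CI separability is highly significant,
        the design property that makes CI-threshold sampling possible."""
        stack, truth = small_scene
        vi = indices.compute_indices(stack)
        rape = truth.rapeseed_mask
        ci_pre = vi.layers["CI"][0][rape]
        mean_peak = np.nanmean(truth.peak_flowering_doy)
        days = [abs(seasons.date_to_doy(d) - mean_peak) if d.year == truth.year
                else 999 for d in vi.dates]
        ci_flower = vi.layers["CI"][int(np.argmin(days))][rape]
        t, p = evaluate.separability_ttest(ci_pre[np.isfinite(ci_pre)],
                                           ci_flower[np.isfinite(ci_flower)])
        assert p < 0.01 and abs(t) > 10

    def test_no_rapeseed_on_steep_slopes(self, small_scene):
        _, truth = small_scene
        assert not (truth.rapeseed_mask & (truth.slope_deg > 25.0)).any()


class TestEnvSeries:
    def test_winter_window_length_matches_calendar(self):
        env = synth.generate_env_cells(3, season="winter", year=2021, seed=0)
        assert len(env.series[0].data) == 92  # Nov(30) + Dec(31) + Jan(31)

    def test_spring_window_length_matches_calendar(self):
        env = synth.generate_env_cells(3, season="spring", year=2021, seed=0)
        assert len(env.series[0].data) == 91  # Apr(30) + May(31) + Jun(30)

    def test_noiseless_doy_equals_generating_function(self):
        env = synth.generate_env_cells(20, noise_sd=0.0, seed=4)
        np.testing.assert_allclose(env.truth["doy_true"], env.truth["doy_fn"])

    def test_doy_noise_variance_matches_configuration(self):
        env = synth.generate_env_cells(50, noise_sd=2.0, seed=3)
        resid = env.truth["doy_true"] - env.truth["doy_fn"]
        assert float(resid.var(ddof=1)) == pytest.approx(4.0, rel=0.3)

    def test_scene_linked_series_cover_rapeseed_cells(self, small_scene):
        _, truth = small_scene
        env = synth.generate_env_series(truth, grid_res=0.002, seed=0)
        assert len(env) >= 20
        assert set(env.truth.columns) >= {"cell_id", "doy_true", "latitude"}

    def test_invalid_grid_resolution_rejected(self, small_scene):
        _, truth = small_scene
        with pytest.raises(ValueError):
            synth.generate_env_series(truth, grid_res=0.0)


class TestSarSeries:
    def _records(self, doys):
        return [PhenoRecord(id=i, longitude=0.0, latitude=0.0, year=2021,
                            label="rapeseed", flowering_doy=float(d),
                            source="synthetic") for i, d in enumerate(doys)]

    def test_noiseless_bump_peaks_at_true_doy(self):
        sar = synth.generate_sar_series(self._records([80]), seed=0,
                                        noise_sd=0.0, interval=1)
        frame = sar[0]
        assert frame.loc[frame["vv"].idxmax(), "doy"] == 80

    def test_offset_shifts_the_peak(self):
        sar = synth.generate_sar_series(self._records([80]), seed=0,
                                        noise_sd=0.0, offset=6.0, interval=1)
        frame = sar[0]
        assert frame.loc[frame["vv"].idxmax(), "doy"] == 86

    def test_non_integer_seed_rejected(self):
        with pytest.raises(TypeError):
            synth.generate_sar_series(self._records([80]), seed="abc")


class TestStatistics:
    def _truths(self, n, seed0=0):
        out = []
        for s in range(n):
            rng = np.random.default_rng(seed0 + s)
            cfg = synth.SceneConfig(height=48, width=48,
                                    rapeseed_fraction=float(rng.uniform(0.05, 0.4)),
                                    seed=seed0 + s)
            out.append(synth.generate_scene(cfg)[1])
        return out

    def test_zero_noise_reports_true_area(self):
        truths = self._truths(3)
        table = synth.generate_statistics(truths, reporting_noise=0.0, seed=1)
        np.testing.assert_allclose(table["reported_area_ha"], table["true_area_ha"])

    def test_reported_area_is_true_times_drawn_factor(self):
        truths = self._truths(1)
        table = synth.generate_statistics(truths, reporting_noise=0.1, seed=11)
        eps = np.random.default_rng(11).normal(0.0, 0.1)
        expected = table["true_area_ha"][0] * (1.0 + eps)
        assert table["reported_area_ha"][0] == pytest.approx(expected)

    def test_reported_regresses_on_true_with_high_r2(self):
        truths = self._truths(20)
        table = synth.generate_statistics(truths, reporting_noise=0.1, seed=5)
        reg = evaluate.area_regression(table["true_area_ha"].to_numpy(),
                                      table["reported_area_ha"].to_numpy())
        assert reg.r2 > 0.9

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_statistics(self._truths(1), reporting_noise=-0.1)


class TestAncillary:
    def test_cropland_layers_flip_configured_share(self, small_scene):
        _, truth = small_scene
        a, b = synth.generate_cropland_layers(truth, error_rate=0.02, seed=1)
        assert (a != truth.cropland_truth).mean() == pytest.approx(0.02, abs=0.01)
        assert not np.array_equal(a, b)

    def test_pheno_records_carry_scene_truth(self, small_scene):
        _, truth = small_scene
        recs = synth.generate_pheno_records(truth, n=50, seed=0, outlier_frac=0.0,
                                            record_noise_sd=0.0)
        assert len(recs) == 50
        for rec in recs[:5]:
            assert rec.flowering_doy == pytest.approx(rec.true_doy, abs=0.5)
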