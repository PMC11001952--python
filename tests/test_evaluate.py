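"""Confusion metrics, area regression, Welch t, Sen's slope, and ablations."""

import itertools

import numpy as np
import pytest

from rapemap import evaluate, synth
from rapemap.evaluate import ConfusionCounts


class TestConfusion:
    def test_perfect_map_has_no_errors(self):
        truth = np.array([[1, 0], [0, 1]], dtype=bool)
        c = evaluate.confusion(truth.astype(np.uint8), truth)
        assert c.fp == 0 and c.fn == 0 and c.tp == 2 and c.tn == 2

    def test_crafted_mismatches_match_hand_tally(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:3, :3] = True  # 9 positives
        mapped = np.zeros((10, 10), dtype=np.uint8)
        mapped[:3, :2] = 1  # 6 of the positives
        mapped[5, 5:7] = 1  # 2 false alarms
        c = evaluate.confusion(mapped, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (6, 2, 3, 89)

    def test_all_nodata_is_an_error(self):
        with pytest.raises(ValueError, match="no evaluable"):
            evaluate.confusion(np.full((3, 3), 255, dtype=np.uint8),
                               np.zeros((3, 3), dtype=bool))

    def test_nodata_counted_separately(self):
        mapped = np.array([[1, 255], [0, 255]], dtype=np.uint8)
        truth = np.array([[1, 1], [0, 0]], dtype=bool)
        c = evaluate.confusion(mapped, truth)
        assert c.n == 2 and c.n_nodata == 2


class TestAccuracyMetrics:
    def test_hand_worked_tally(self):
        m = evaluate.accuracy_metrics(ConfusionCounts(tp=8, tn=89, fp=2, fn=1))
        assert m.ua == pytest.approx(0.800, abs=5e-4)
        assert m.pa == pytest.approx(0.8889, abs=5e-5)
        assert m.oa == pytest.approx(0.970, abs=5e-4)
        assert m.f1 == pytest.approx(0.8421, abs=5e-5)

    def test_perfect_map_scores_one(self):
        m = evaluate.accuracy_metrics(ConfusionCounts(tp=10, tn=90, fp=0, fn=0))
        assert (m.ua, m.pa, m.oa, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_no_true_positives_flagged_not_silent(self):
        m = evaluate.accuracy_metrics(ConfusionCounts(tp=0, tn=5, fp=3, fn=2))
        assert m.ua == 0.0 and m.f1 == 0.0 and "F1" in m.undefined

    def test_f1_between_ua_and_pa(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 100, 4)
            m = evaluate.accuracy_metrics(ConfusionCounts(int(tp), int(tn),
                                                          int(fp), int(fn)))
            assert min(m.ua, m.pa) - 1e-12 <= m.f1 <= max(m.ua, m.pa) + 1e-12


class TestAreaRegression:
    def test_identical_series(self):
        reg = evaluate.area_regression(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert reg.r2 == pytest.approx(1.0)
        assert reg.rmse == 0.0 and reg.mae == 0.0

    def test_hand_worked_three_point_series(self):
        reg = evaluate.area_regression(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))
        assert reg.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert reg.mae == pytest.approx(2.0 / 3.0)
        assert np.isnan(reg.r2)  # zero variance in the reported series

    def test_correlation_is_not_agreement(self):
        x = np.array([1.0, 2, 3, 4])
        reg = evaluate.area_regression(x, 2 * x + 1)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.rmse > 0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            evaluate.area_regression(np.array([1.0]), np.array([2.0]))


class TestWelch:
    def test_identical_constant_groups_degenerate(self):
        a = np.full(5, 2.0)
        assert evaluate.separability_ttest(a, a) == (0.0, 1.0)

    def test_well_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        t, p = evaluate.separability_ttest(rng.normal(0, 1, 200),
                                           rng.normal(5, 1, 200))
        assert abs(t) > 30 and p < 0.01

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 60)
        t1, p1 = evaluate.separability_ttest(a, b)
        t2, p2 = evaluate.separability_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_matches_textbook_formula_to_1e10(self):
        """The implementation agrees with the hand-coded Welch statistic and
        Welch-Satterthwaite p-value on random draws."""
        from scipy import stats
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1.5, int(rng.integers(5, 50)))
            b = rng.normal(0.5, 0.7, int(rng.integers(5, 50)))
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            t, p = evaluate.separability_ttest(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestSensSlope:
    def test_exact_linear_series_recovered_exactly(self):
        t = np.arange(10.0)
        res = evaluate.sens_slope(2 * t + 1)
        assert res.slope == 2.0 and res.significant

    def test_constant_series_no_trend(self):
        res = evaluate.sens_slope(np.full(8, 3.0))
        assert res.slope == 0.0 and not res.significant

    def test_hand_enumerated_median(self):
        res = evaluate.sens_slope(np.array([1.0, 2.0, 4.0]),
                                  times=np.array([0.0, 1.0, 2.0]))
        assert res.slope == pytest.approx(1.5)  # median of {1, 1.5, 2}

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            evaluate.sens_slope(np.array([1.0, 2.0]))

    def test_matches_exhaustive_pairwise_median_oracle(self):
        """Sen's slope equals brute-force enumeration of all pairwise slopes
        for every random series of length 3..8."""
        rng = np.random.default_rng(3)
        for n in range(3, 9):
            for _ in range(20):
                y = rng.normal(size=n)
                slopes = [(y[j] - y[i]) / (j - i)
                          for i, j in itertools.combinations(range(n), 2)]
                res = evaluate.sens_slope(y)
                assert res.slope == pytest.approx(np.median(slopes), abs=1e-12)

    def test_detects_generated_decline(self):
        table = synth.generate_area_trend(n_years=23, slope_ha=-15.0,
                                          noise_sd=30.0, seed=0)
        res = evaluate.sens_slope(table["area_ha"].to_numpy(),
                                  times=table["year"].to_numpy())
        assert res.slope < 0 and res.significant


class TestMannKendall:
    def test_monotone_series_significant(self):
        s, z, p = evaluate.mann_kendall(np.arange(10.0))
        assert s == 45 and p < 0.01

    def test_tie_correction_handles_constant(self):
        s, z, p = evaluate.mann_kendall(np.full(6, 1.0))
        assert s == 0 and p == 1.0


class TestAblations:
    def test_seven_month_combination_count(self, composites, flower_pool,
                                           small_scene):
        band_comp, vi_comp = composites
        _, truth = small_scene
        curve = evaluate.combination_ablation(band_comp, vi_comp, flower_pool,
                                              truth.rapeseed_mask, seed=0)
        assert len(curve) == 127  # 2^7 - 1 scenarios

    def test_single_month_subset_is_one_row(self, composites, flower_pool,
                                            small_scene):
        band_comp, vi_comp = composites
        _, truth = small_scene
        curve = evaluate.combination_ablation(band_comp, vi_comp, flower_pool,
                                              truth.rapeseed_mask,
                                              months=["2021-03"], seed=0)
        assert len(curve) == 1

    def test_all_months_outperform_single_sowing_month(self, composites,
                                                       flower_pool, small_scene):
        band_comp, vi_comp = composites
        _, truth = small_scene
        curve = evaluate.combination_ablation(band_comp, vi_comp, flower_pool,
                                              truth.rapeseed_mask, seed=0)
        full = curve[curve["n_months"] == curve["n_months"].max()]["f1"].iloc[0]
        sowing = curve[curve["months"] == "2020-11"]["f1"].iloc[0]
        assert full > sowing

    def test_noise_free_fraction_reproduces_clean_f1(self, flower_pool,
                                                     confuser_spectra,
                                                     flower_bands, small_scene):
        _, truth = small_scene
        valid = np.all(np.isfinite(flower_bands), axis=0)
        curve = evaluate.noise_ablation(flower_pool, confuser_spectra,
                                        flower_bands, valid,
                                        truth.rapeseed_mask,
                                        fractions=[0.0], with_purify=False,
                                        n_reps=2, seed=1)
        clean = evaluate._train_eval_f1(flower_pool, flower_bands, valid,
                                        truth.rapeseed_mask, seed=1)
        assert curve["f1_mean"].iloc[0] == pytest.approx(clean, abs=0.02)

    def test_invalid_fraction_rejected(self, flower_pool, confuser_spectra,
                                       flower_bands, small_scene):
        _, truth = small_scene
        valid = np.all(np.isfinite(flower_bands), axis=0)
        with pytest.raises(ValueError):
            evaluate.noise_ablation(flower_pool, confuser_spectra,
                                    flower_bands, valid, truth.rapeseed_mask,
                                    fractions=[1.5], seed=0)
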