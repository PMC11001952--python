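"""Candidate thresholding, stratified sampling, and SAM purification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rapemap import evaluate, samples
from rapemap.stack import BANDS


def _pool_from_spectra(spectra, labels):
    spectra = np.asarray(spectra, dtype=float)
    table = pd.DataFrame({
        "id": np.arange(len(spectra)),
        "row": np.zeros(len(spectra), dtype=int),
        "col": np.arange(len(spectra)),
        "label": labels,
        "provenance": "synthetic",
        **{b: spectra[:, i] for i, b in enumerate(BANDS)},
    })
    return samples.SamplePool(table=table)


class TestCiCandidates:
    def test_all_below_threshold_gives_empty_mask(self):
        assert samples.ci_candidates(np.full((5, 5), 0.05)).sum() == 0

    def test_crafted_layer_count(self):
        rng = np.random.default_rng(0)
        layer = np.full((10, 10), 0.01)
        pick = rng.choice(100, size=30, replace=False)
        layer.flat[pick] = 0.08
        assert samples.ci_candidates(layer).sum() == 30

    def test_threshold_is_inclusive(self):
        assert samples.ci_candidates(np.array([[0.07]])).sum() == 1

    def test_nodata_excluded(self):
        assert samples.ci_candidates(np.array([[np.nan, 0.2]])).sum() == 1


class TestStratifiedSample:
    def test_exhaustion_returns_all_candidates(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask.flat[:30] = True
        bands = np.full((4, 10, 10), 0.3)
        pool = samples.stratified_sample(mask, bands, n_per_class=2000, seed=0)
        assert (pool.labels == 1).sum() == 30
        assert (pool.labels == 0).sum() == 70

    def test_fixed_seed_reproducible(self, composites, flower_bands):
        _, vi_comp = composites
        mask = samples.ci_candidates(vi_comp.layer("CI", "2021-03"))
        a = samples.stratified_sample(mask, flower_bands, n_per_class=50, seed=9)
        b = samples.stratified_sample(mask, flower_bands, n_per_class=50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_selection_is_uniform_over_candidates(self):
        """Each of 10^4 candidates is picked with probability ~n/N = 0.2."""
        mask = np.ones((100, 100), dtype=bool)
        bands = np.full((4, 100, 100), 0.3)
        hits = np.zeros(10_000)
        reps = 100
        for rep in range(reps):
            pool = samples.stratified_sample(mask, bands, n_per_class=2000,
                                             seed=rep)
            rape = pool.table[pool.table["label"] == 1]
            hits[rape["row"] * 100 + rape["col"]] += 1
        assert np.all(np.abs(hits / reps - 0.2) <= 0.05 + 3 * 0.04)
        assert hits.mean() / reps == pytest.approx(0.2, abs=0.01)

    def test_empty_class_warns(self):
        mask = np.ones((4, 4), dtype=bool)  # complement empty
        bands = np.full((4, 4, 4), 0.3)
        with pytest.warns(UserWarning):
            pool = samples.stratified_sample(mask, bands, n_per_class=5, seed=0)
        assert (pool.labels == 0).sum() == 0


class TestSamAngle:
    def test_identity_is_zero(self):
        assert samples.sam_angle(np.ones(4), np.ones(4)) == pytest.approx(0.0)

    def test_orthogonal_is_right_angle(self):
        assert samples.sam_angle(np.array([1.0, 0.0]),
                                 np.array([0.0, 1.0])) == pytest.approx(np.pi / 2)

    def test_45_degrees_closed_form(self):
        assert samples.sam_angle(np.array([1.0, 1.0]),
                                 np.array([1.0, 0.0])) == pytest.approx(np.pi / 4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            samples.sam_angle(np.zeros(3), np.ones(3))

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=1000))
    def test_scale_invariance_and_symmetry(self, c, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.01, 1.0, 4)
        r = rng.uniform(0.01, 1.0, 4)
        assert samples.sam_angle(c * u, r) == pytest.approx(samples.sam_angle(u, r))
        assert samples.sam_angle(u, r) == pytest.approx(samples.sam_angle(r, u))

    def test_printed_form_is_not_scale_invariant(self):
        u = np.array([0.2, 0.3, 0.1, 0.4])
        r = np.array([0.3, 0.2, 0.2, 0.5])
        a1 = samples.sam_angle(u, r, form="printed")
        a2 = samples.sam_angle(4.0 * u, r, form="printed")
        assert a1 != pytest.approx(a2)


class TestReference:
    def test_identical_spectra_give_zero_threshold(self):
        spec = np.tile([0.1, 0.3, 0.15, 0.45], (20, 1))
        pool = _pool_from_spectra(spec, np.ones(20, dtype=int))
        ref = samples.build_reference(pool)
        np.testing.assert_allclose(ref.spectrum, spec[0])
        assert ref.angle_threshold == pytest.approx(0.0, abs=1e-12)

    def test_two_spectra_hand_case(self):
        spectra = np.array([[1.0, 0.0], [0.0, 1.0]])
        ref = samples.reference_from_spectra(spectra, ci_values=np.zeros(2),
                                             percentile=0.0)
        np.testing.assert_allclose(ref.spectrum, [0.5, 0.5])
        angles = samples.sam_angle(spectra, ref.spectrum)
        np.testing.assert_allclose(angles, np.pi / 4)
        assert ref.angle_threshold == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        pool = _pool_from_spectra(np.full((3, 4), 0.2), np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            samples.build_reference(pool)

    def test_threshold_reproducible(self, flower_pool):
        t1 = samples.build_reference(flower_pool).angle_threshold
        t2 = samples.build_reference(flower_pool).angle_threshold
        assert t1 == t2


class TestPurify:
    def test_sample_equal_to_reference_kept(self):
        spec = np.vstack([np.tile([0.1, 0.3, 0.15, 0.45], (10, 1))])
        pool = _pool_from_spectra(spec, np.ones(10, dtype=int))
        ref = samples.SamReference(spectrum=spec[0], angle_threshold=0.0)
        assert len(samples.purify(pool, ref)) == 10  # alpha = 0 is not > 0

    def test_orthogonal_sample_removed(self):
        spec = np.array([[0.0, 0.0, 0.0, 1.0], [1.0, 0.0, 0.0, 0.0]])
        pool = _pool_from_spectra(spec, np.ones(2, dtype=int))
        ref = samples.SamReference(spectrum=np.array([0.0, 0.0, 0.0, 1.0]),
                                   angle_threshold=0.1)
        out = samples.purify(pool, ref)
        assert len(out) == 1 and out.table["id"].iloc[0] == 0

    def test_nonrapeseed_untouched_and_never_grows(self, flower_pool):
        ref = samples.build_reference(flower_pool)
        out = samples.purify(flower_pool, ref)
        assert len(out) <= len(flower_pool)
        assert (out.labels == 0).sum() == (flower_pool.labels == 0).sum()

    def test_idempotent_for_fixed_reference(self, flower_pool):
        ref = samples.build_reference(flower_pool)
        once = samples.purify(flower_pool, ref)
        twice = samples.purify(once, ref)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_purification_raises_purity_of_contaminated_pool(
            self, flower_pool, confuser_spectra):
        """Injecting 20% confuser spectra into the rapeseed class and
        purifying strictly increases the share of genuine rapeseed."""
        rng = np.random.default_rng(13)
        table = flower_pool.table.copy()
        rape_idx = np.nonzero(table["label"].to_numpy() == 1)[0]
        n_noise = int(0.2 * rape_idx.size)
        pick = rng.choice(rape_idx, size=n_noise, replace=False)
        table.loc[table.index[pick], list(BANDS)] = confuser_spectra[
            rng.choice(confuser_spectra.shape[0], n_noise)]
        noisy_ids = set(table.iloc[pick]["id"].astype(int))
        noisy = samples.SamplePool(table=table)
        before = evaluate.pool_purity(noisy, noisy_ids)
        ref = samples.build_reference(noisy)
        after = evaluate.pool_purity(samples.purify(noisy, ref), noisy_ids)
        assert after > before
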