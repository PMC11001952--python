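"""Shared fixtures: one small synthetic scene reused across test modules."""

import numpy as np
import pytest

from rapemap import indices, samples, synth


@pytest.fixture(scope="session")
def small_scene():
    """64x64 winter scene with moderate cloud cover and known truth."""
    cfg = synth.SceneConfig(height=64, width=64, seed=7, cloud_prob=0.2)
    stack, truth = synth.generate_scene(cfg)
    return stack, truth


@pytest.fixture(scope="session")
def composites(small_scene):
    stack, _ = small_scene
    vi = indices.compute_indices(stack)
    band_comp = indices.monthly_median_composite(stack)
    vi_comp = indices.monthly_median_composite(vi)
    return band_comp, vi_comp


@pytest.fixture(scope="session")
def flower_bands(composites):
    band_comp, _ = composites
    return np.stack([band_comp.layer(b, "2021-03") for b in indices.BANDS])


@pytest.fixture(scope="session")
def flower_pool(composites, flower_bands):
    _, vi_comp = composites
    ci = vi_comp.layer("CI", "2021-03")
    candidates = samples.ci_candidates(ci)
    return samples.stratified_sample(candidates, flower_bands,
                                     n_per_class=400, seed=2)


@pytest.fixture(scope="session")
def confuser_spectra(small_scene, flower_bands):
    """Finite flowering-window spectra of true confuser-crop pixels."""
    _, truth = small_scene
    ok = np.all(np.isfinite(flower_bands), axis=0)
    rows, cols = np.nonzero((truth.class_map == synth.CONFUSER) & ok)
    rng = np.random.default_rng(5)
    pick = rng.choice(rows.size, size=200, replace=False)
    return flower_bands[:, rows[pick], cols[pick]].T
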