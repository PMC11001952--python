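"""Automatic training-sample generation and spectral-angle purification.

Candidate rapeseed pixels are flagged where the canola index of a
flowering-window image reaches 0.07 (inclusive).  Up to 2000 pixels per
class are drawn by stratified random sampling per classification block, and
the rapeseed pool is purified with the spectral angle mapper (SAM): samples
whose angle to a reference rapeseed spectrum exceeds a data-driven threshold
are discarded as noise.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .stack import BANDS

CI_THRESHOLD = 0.07
N_PER_CLASS = 2000


@dataclasses.dataclass
class SamplePool:
    """Labeled pixel samples with their flowering-window spectra.

    ``table`` columns: id, row, col, label (1 rapeseed / 0 non-rapeseed),
    provenance ("auto" | "manual" | "synthetic"), and one column per band.
    """

    table: pd.DataFrame
    block_id: object = None

    def __post_init__(self) -> None:
        required = {"id", "row", "col", "label", "provenance", *BANDS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        spectra = self.table[list(BANDS)].to_numpy(dtype=float)
        if spectra.size and not np.all(np.isfinite(spectra)):
            raise ValueError("sample spectra must be finite")
        if not self.table["label"].isin((0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def spectra(self, label: int | None = None) -> np.ndarray:
        table = self.table if label is None else self.table[self.table["label"] == label]
        return table[list(BANDS)].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SamplePool":
        return SamplePool(table=self.table[mask].reset_index(drop=True),
                          block_id=self.block_id)


@dataclasses.dataclass
class SamReference:
    """Reference rapeseed endmember and the angle threshold for purification."""

    spectrum: np.ndarray
    angle_threshold: float
    subregion_id: object = None

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.linalg.norm(self.spectrum) == 0:
            raise ValueError("degenerate reference spectrum")
        if self.angle_threshold < 0:
            raise ValueError("angle_threshold must be non-negative")


def ci_candidates(ci_layer: np.ndarray, threshold: float = CI_THRESHOLD) -> np.ndarray:
    """Binary candidate mask: CI >= threshold; no-data (NaN) excluded."""
    ci_layer = np.asarray(ci_layer, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(ci_layer) & (ci_layer >= threshold)


def stratified_sample(candidate_mask: np.ndarray, image_bands: np.ndarray,
                      n_per_class: int = N_PER_CLASS, seed: int = 0,
                      valid_mask: np.ndarray | None = None,
                      exclude_mask: np.ndarray | None = None,
                      block_id: object = None) -> SamplePool:
    """Draw up to ``n_per_class`` rapeseed pixels from the candidate mask and
    as many non-rapeseed pixels from its complement, uniformly without
    replacement; deterministic under a fixed seed.

    ``image_bands`` (4, H, W) supplies the flowering-window spectra attached
    to each sample.  ``exclude_mask`` removes pixels from the *non-rapeseed*
    sampling space only — used for the ambiguous guard band just below the
    candidate threshold, where poor flowering-window coverage makes a
    non-flowering label unsafe.  A class with zero candidates yields an
    empty class and a warning, not an error.
    """
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if image_bands.shape[1:] != candidate_mask.shape:
        raise ValueError("image/mask shape mismatch")
    ok = np.all(np.isfinite(image_bands), axis=0)
    if valid_mask is not None:
        ok &= np.asarray(valid_mask, dtype=bool)
    negative = ~candidate_mask & ok
    if exclude_mask is not None:
        negative &= ~np.asarray(exclude_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 0
    for label, mask in ((1, candidate_mask & ok), (0, negative)):
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            warnings.warn(f"no pixels available for class {label}", stacklevel=2)
            continue
        n = min(n_per_class, rr.size)
        pick = rng.choice(rr.size, size=n, replace=False)
        for idx in pick:
            r, c = int(rr[idx]), int(cc[idx])
            spec = image_bands[:, r, c]
            rows.append((next_id, r, c, label, "auto", *spec))
            next_id += 1
    table = pd.DataFrame(rows, columns=["id", "row", "col", "label", "provenance", *BANDS])
    return SamplePool(table=table, block_id=block_id)


def sam_angle(u: np.ndarray, r: np.ndarray, form: str = "l2") -> np.ndarray | float:
    """Spectral angle (radians) between spectra ``u`` and reference ``r``.

    ``form="l2"`` (default) is the standard SAM,
    ``arccos(<u, r> / (||u||_2 ||r||_2))``, which is scale-invariant.  The
    non-scale-invariant variant with unsquared denominator sums,
    ``arccos(sum(u*r) / (sqrt(sum(u)) sqrt(sum(r))))``, is available as
    ``form="printed"`` for compatibility; it requires non-negative spectra.
    ``u`` may be a single spectrum or an (n, nb) array.
    """
    u = np.asarray(u, dtype=float)
    r = np.asarray(r, dtype=float)
    single = u.ndim == 1
    u2 = np.atleast_2d(u)
    if u2.shape[1] != r.size:
        raise ValueError("spectra must have equal band counts")
    if np.linalg.norm(r) == 0 or np.any(np.linalg.norm(u2, axis=1) == 0):
        raise ValueError("degenerate spectrum")
    dot = u2 @ r
    if form == "l2":
        denom = np.linalg.norm(u2, axis=1) * np.linalg.norm(r)
    elif form == "printed":
        su, sr = u2.sum(axis=1), r.sum()
        if sr <= 0 or np.any(su <= 0):
            raise ValueError("printed form requires positive band sums")
        denom = np.sqrt(su) * np.sqrt(sr)
    else:
        raise ValueError(f"unknown SAM form {form!r}")
    ang = np.arccos(np.clip(dot / denom, -1.0, 1.0))
    return float(ang[0]) if single else ang


def build_reference(pool: SamplePool, percentile: float = 90.0,
                    threshold_mode: str = "angle_std", form: str = "l2",
                    min_samples: int = 10) -> SamReference:
    """Reference endmember and purification threshold from a sample pool.

    The reference is the mean spectrum of rapeseed samples whose canola index
    lies at or above the given percentile of the pool (the most confidently
    flowering pixels).  The angle threshold is, by default, the standard
    deviation of the angles of all rapeseed samples to that reference
    (``threshold_mode="angle_std"``); ``"band_std"`` instead uses the mean
    per-band standard deviation of the contributing spectra — the literal
    reading of "standard deviation of the reference spectrum".
    """
    spectra = pool.spectra(label=1)
    if spectra.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} rapeseed samples, "
                         f"got {spectra.shape[0]}")
    blue, green, red, nir = (spectra[:, BANDS.index(b)] for b in BANDS)
    ci_vals = nir * (red + green)
    ref = reference_from_spectra(spectra, ci_vals, percentile=percentile,
                                 threshold_mode=threshold_mode, form=form)
    ref.subregion_id = pool.block_id
    return ref


def reference_from_spectra(spectra: np.ndarray, ci_values: np.ndarray,
                           percentile: float = 90.0,
                           threshold_mode: str = "angle_std",
                           form: str = "l2") -> SamReference:
    """Array-level core of :func:`build_reference`: spectra (n, nb) with their
    CI scores -> mean spectrum of the top-percentile subset plus threshold."""
    spectra = np.asarray(spectra, dtype=float)
    ci_values = np.asarray(ci_values, dtype=float)
    cut = np.percentile(ci_values, percentile)
    top = spectra[ci_values >= cut]
    reference = top.mean(axis=0)
    if threshold_mode == "angle_std":
        angles = np.atleast_1d(sam_angle(spectra, reference, form=form))
        threshold = float(np.std(angles))
    elif threshold_mode == "band_std":
        threshold = float(top.std(axis=0).mean())
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return SamReference(spectrum=reference, angle_threshold=threshold)


def purify(pool: SamplePool, ref: SamReference, form: str = "l2") -> SamplePool:
    """Remove rapeseed samples whose spectral angle to the reference exceeds
    the threshold; non-rapeseed samples are untouched.  Never increases the
    pool and is idempotent for a fixed reference."""
    labels = pool.labels
    keep = np.ones(len(pool), dtype=bool)
    rape = labels == 1
    if rape.any():
        angles = sam_angle(pool.spectra(label=1), ref.spectrum, form=form)
        # arccos loses ~sqrt(ulp) precision near zero angle, so spectra
        # identical to the reference need ~1e-7 rad slack to survive a zero
        # threshold; physically negligible
        keep[np.nonzero(rape)[0][angles > ref.angle_threshold + 1e-7]] = False
    return pool.subset(keep)
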