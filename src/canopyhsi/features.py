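"""Spectral characterization: vegetation indices, profile statistics,
PCA of reflectance spectra, and t-SNE embedding.

Three classic narrowband indices are provided, each computed from the
nearest sensor bands to its nominal wavelengths:

* NDVI = (rho_NIR - rho_RED) / (rho_NIR + rho_RED), defaults 800/670 nm
* PRI  = (rho_531 - rho_570) / (rho_531 + rho_570)
* PSRI = (rho_680 - rho_500) / rho_750

Pixels where an index's denominator vanishes are flagged undefined (NaN)
rather than silently zeroed.  PCA is covariance based (bands share units of
reflectance, so no standardization) with a deterministic sign convention:
each loading column's largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .io import HyperspectralCube, SpectralAxis, nearest_band

__all__ = [
    "VegetationIndexMap",
    "SpectralPCAResult",
    "EmbeddingResult",
    "ndvi",
    "pri",
    "psri",
    "mean_cv_profile",
    "spectral_pca",
    "tsne_embed",
]


@dataclass
class VegetationIndexMap:
    values: np.ndarray        # NaN where undefined
    index_name: str
    bands_used: list          # (target nm, actual nm, band index)


@dataclass
class SpectralPCAResult:
    loadings: np.ndarray                  # (D, K), unit-norm columns
    explained_variance_ratio: np.ndarray  # (K,), nonincreasing
    scores: np.ndarray                    # (samples, K)
    mean: np.ndarray                      # (D,)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (samples, 2)
    perplexity: float
    seed: int


def _band_values(data, axis: SpectralAxis | None, targets: list):
    """Resolve band values for a cube, (spectrum, axis) pair, or bare spectrum.

    Returns (list of band arrays/scalars, bands_used records).
    """
    if isinstance(data, HyperspectralCube):
        axis = data.axis
        values = data.values
    else:
        values = np.asarray(data, dtype=float)
        if axis is None:
            raise ValueError("an explicit SpectralAxis is required for bare arrays")
    picked, used = [], []
    for nm in targets:
        idx = nearest_band(axis, nm)
        used.append((nm, float(axis.wavelengths_nm[idx]), idx))
        picked.append(np.asarray(values[..., idx], dtype=float))
    return picked, used


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def ndvi(data, axis: SpectralAxis | None = None, red_nm: float = 670.0,
         nir_nm: float = 800.0) -> VegetationIndexMap:
    """Normalized difference vegetation index from the nearest red/NIR bands."""
    (red, nir), used = _band_values(data, axis, [red_nm, nir_nm])
    return VegetationIndexMap(_normalized_difference(nir, red), "NDVI", used[::-1])


def pri(data, axis: SpectralAxis | None = None) -> VegetationIndexMap:
    """Photochemical reflectance index, (rho_531 - rho_570)/(rho_531 + rho_570)."""
    (r531, r570), used = _band_values(data, axis, [531.0, 570.0])
    return VegetationIndexMap(_normalized_difference(r531, r570), "PRI", used)


def psri(data, axis: SpectralAxis | None = None) -> VegetationIndexMap:
    """Plant senescence reflectance index, (rho_680 - rho_500)/rho_750."""
    (r680, r500, r750), used = _band_values(data, axis, [680.0, 500.0, 750.0])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(r750 != 0, (r680 - r500) / r750, np.nan)
    return VegetationIndexMap(values, "PSRI", used)


def mean_cv_profile(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band-wise mean and coefficient of variation (percent, n-1 sd).

    Bands whose mean is zero get a NaN CV (flagged, not silently zero).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need a (samples, bands) matrix with >= 2 samples")
    mean = spectra.mean(axis=0)
    sd = spectra.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    return mean, cv


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (in place safe)."""
    flips = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    return loadings * flips


def spectral_pca(spectra: np.ndarray, k: int) -> SpectralPCAResult:
    """Mean-centered covariance PCA of a (samples, D) spectra matrix."""
    spectra = np.asarray(spectra, dtype=float)
    n, d = spectra.shape
    if n <= k:
        raise ValueError("need more samples than components")
    if k > min(n - 1, d):
        raise ValueError(f"k={k} exceeds the data rank bound min({n - 1}, {d})")
    mean = spectra.mean(axis=0)
    centered = spectra - mean
    # economy SVD; eigenvalues of the covariance are s^2/(n-1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = centered.var(axis=0, ddof=1).sum()
    loadings = _fix_signs(vt[:k].T)
    scores = centered @ loadings
    ratio = (s[:k] ** 2 / (n - 1)) / total_var
    return SpectralPCAResult(loadings, ratio, scores, mean)


def tsne_embed(spectra: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> EmbeddingResult:
    """2-D t-SNE embedding of spectra; deterministic for a fixed seed."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[0] <= 3 * perplexity:
        raise ValueError("need more than 3 x perplexity samples")
    if np.allclose(spectra, spectra[0]):
        raise ValueError("degenerate input: all spectra identical")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(spectra)
    return EmbeddingResult(np.asarray(coords, dtype=float), perplexity, seed)
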