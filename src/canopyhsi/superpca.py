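"""Superpixelwise PCA (SuperPCA) feature extraction and patch building.

SuperPCA reduces a ``(M, N, D)`` cube to ``(M, N, B)`` by (1) projecting
every pixel spectrum onto the cube's first principal component to get a
single grayscale image, (2) segmenting that image into homogeneous
superpixels (entropy-rate segmentation by default), and (3) running an
independent PCA *within each superpixel*, keeping each segment's top-B
components.  Because segments are spectrally homogeneous, the per-segment
bases adapt to local covariance and denoise far better than one global
basis; with a single segment the procedure degenerates exactly to global
PCA.

The reduced cube is then cut into ``S x S x B`` patches centered on every
labeled pixel (zero padding of width ``(S-1)/2`` at the borders), each
labeled by its center pixel — the training/evaluation unit of the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .ers import entropy_rate_superpixels
from .features import _fix_signs, spectral_pca
from .io import HyperspectralCube, LabelMap

__all__ = [
    "SuperpixelMap",
    "ReducedCube",
    "PatchSet",
    "first_pc_image",
    "segment_superpixels",
    "superpca_reduce",
    "extract_patches",
    "boundary_recall",
    "undersegmentation_error",
]


@dataclass
class SuperpixelMap:
    """Complete partition of the image plane into connected segments."""

    segment_ids: np.ndarray

    def __post_init__(self):
        seg = np.asarray(self.segment_ids)
        if seg.ndim != 2 or not np.issubdtype(seg.dtype, np.integer):
            raise ValueError("segment ids must be a 2-D integer array")
        ids = np.unique(seg)
        if ids[0] != 0 or ids[-1] != ids.size - 1:
            raise ValueError("segment ids must be consecutive from 0")
        self.segment_ids = seg

    @property
    def n_segments(self) -> int:
        return int(self.segment_ids.max()) + 1


@dataclass
class ReducedCube:
    values: np.ndarray  # (M, N, B)
    b: int
    provenance: dict = field(default_factory=dict)


@dataclass
class PatchSet:
    """Spectral-spatial patches with center-pixel labels."""

    patches: np.ndarray  # (n, S, S, B)
    centers: np.ndarray  # (n, 2) as (row, col)
    labels: np.ndarray   # (n,) class ids (>= 1)
    s: int
    fingerprint: str = ""

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def b(self) -> int:
        return self.patches.shape[3]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, indices: np.ndarray) -> "PatchSet":
        indices = np.asarray(indices)
        return PatchSet(self.patches[indices], self.centers[indices],
                        self.labels[indices], self.s, self.fingerprint)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(Path(path), patches=self.patches, centers=self.centers,
                            labels=self.labels, s=self.s, fingerprint=self.fingerprint)

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        with np.load(Path(path), allow_pickle=False) as archive:
            return cls(archive["patches"], archive["centers"], archive["labels"],
                       int(archive["s"]), str(archive["fingerprint"]))


def first_pc_image(cube: HyperspectralCube) -> np.ndarray:
    """Per-pixel PC1 score of the pixelwise spectra, rescaled to [0, 1]."""
    m, n, d = cube.shape
    if d < 2:
        raise ValueError("need at least two bands")
    spectra = cube.values.reshape(-1, d).astype(float)
    if np.allclose(spectra.var(axis=0), 0):
        raise ValueError("constant cube: first principal component undefined")
    result = spectral_pca(spectra, k=1)
    scores = result.scores[:, 0].reshape(m, n)
    lo, hi = scores.min(), scores.max()
    return (scores - lo) / (hi - lo)


def segment_superpixels(pc1_image: np.ndarray, n_segments: int, method: str = "ers",
                        **kwargs) -> SuperpixelMap:
    """Segment the PC1 image into ~``n_segments`` superpixels.

    ``method`` is ``"ers"`` (entropy-rate segmentation, the default) or
    ``"slic"`` (k-means-in-feature-space fallback via scikit-image).
    """
    pc1_image = np.asarray(pc1_image, dtype=float)
    if not np.all(np.isfinite(pc1_image)):
        raise ValueError("segmentation input contains non-finite values")
    if not (1 <= n_segments <= pc1_image.size):
        raise ValueError("n_segments out of range")
    if n_segments == 1:
        return SuperpixelMap(np.zeros(pc1_image.shape, dtype=np.int32))
    if method == "ers":
        seg = entropy_rate_superpixels(pc1_image, n_segments, **kwargs)
    elif method == "slic":
        from skimage.segmentation import slic

        seg = slic(pc1_image, n_segments=n_segments, channel_axis=None,
                   start_label=0, enforce_connectivity=True,
                   compactness=kwargs.pop("compactness", 0.1), **kwargs)
        _, seg = np.unique(seg, return_inverse=True)
        seg = seg.reshape(pc1_image.shape)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return SuperpixelMap(seg.astype(np.int32))


def _top_loadings(spectra: np.ndarray, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-b PCA loadings (sign-fixed) and the mean of a pixel matrix."""
    mean = spectra.mean(axis=0)
    _, _, vt = np.linalg.svd(spectra - mean, full_matrices=False)
    k = min(b, vt.shape[0])
    loadings = vt[:k].T
    if k < b:  # degenerate segment: pad with zero directions
        loadings = np.hstack([loadings, np.zeros((loadings.shape[0], b - k))])
    return _fix_signs(loadings), mean


def superpca_reduce(cube: HyperspectralCube, segmap: SuperpixelMap, b: int,
                    center: bool = False) -> ReducedCube:
    """Project each superpixel's pixels onto its own top-``b`` PCA basis.

    The basis is the segment's top-b covariance eigenvectors (computed from
    mean-centered pixels); the projection is applied to the *raw* pixels by
    default, so the segment's mean spectrum stays encoded in the reduced
    features and reduced images remain comparable across separately
    processed acquisitions.  ``center=True`` projects the centered pixels
    instead (pure within-segment variation).  Segments with fewer than
    ``b`` pixels fall back to the global-image loadings (their own
    covariance is too rank-deficient to be meaningful).
    """
    m, n, d = cube.shape
    if not (1 <= b <= d):
        raise ValueError(f"target band count b={b} must lie in 1..{d}")
    if segmap.segment_ids.shape != (m, n):
        raise ValueError("segment map shape does not match cube")
    pixels = cube.values.reshape(-1, d).astype(float)
    seg = segmap.segment_ids.ravel()
    global_loadings, global_mean = _top_loadings(pixels, b)
    out = np.empty((m * n, b))
    per_segment_loadings = {}
    for sid in range(segmap.n_segments):
        members = np.flatnonzero(seg == sid)
        block = pixels[members]
        if members.size >= b:
            loadings, mean = _top_loadings(block, b)
        else:
            loadings, mean = global_loadings, global_mean
        per_segment_loadings[sid] = loadings
        out[members] = ((block - mean) if center else block) @ loadings
    return ReducedCube(out.reshape(m, n, b), b,
                       provenance={"n_segments": segmap.n_segments, "center": center,
                                   "loadings": per_segment_loadings})


def extract_patches(reduced: ReducedCube, labels: LabelMap, s: int) -> PatchSet:
    """One ``s x s x B`` patch per labeled pixel, zero-padded at borders."""
    if s % 2 == 0 or s < 3:
        raise ValueError("patch window s must be odd and >= 3")
    values = reduced.values
    m, n, b = values.shape
    if labels.labels.shape != (m, n):
        raise ValueError("label map shape does not match reduced cube")
    half = (s - 1) // 2
    padded = np.pad(values, ((half, half), (half, half), (0, 0)))
    windows = sliding_window_view(padded, (s, s), axis=(0, 1))  # (m, n, b, s, s)
    rows, cols = np.nonzero(labels.labels)
    patches = windows[rows, cols].transpose(0, 2, 3, 1).astype(np.float32)  # (n, s, s, b)
    centers = np.stack([rows, cols], axis=1)
    return PatchSet(np.ascontiguousarray(patches), centers,
                    labels.labels[rows, cols].astype(np.int64), s)


# ---------------------------------------------------------------------------
# segmentation quality measures


def boundary_recall(segment_ids: np.ndarray, true_labels: np.ndarray, tol: int = 1) -> float:
    """Fraction of ground-truth boundary pixels with a predicted boundary
    within ``tol`` pixels (Chebyshev distance)."""
    from scipy.ndimage import binary_dilation

    def boundaries(lab):
        bnd = np.zeros(lab.shape, dtype=bool)
        bnd[:-1, :] |= lab[:-1, :] != lab[1:, :]
        bnd[:, :-1] |= lab[:, :-1] != lab[:, 1:]
        return bnd

    true_bnd = boundaries(np.asarray(true_labels))
    if not true_bnd.any():
        return 1.0
    pred_bnd = boundaries(np.asarray(segment_ids))
    if tol > 0:
        pred_bnd = binary_dilation(pred_bnd, np.ones((2 * tol + 1, 2 * tol + 1), dtype=bool))
    return float((true_bnd & pred_bnd).sum() / true_bnd.sum())


def undersegmentation_error(segment_ids: np.ndarray, true_labels: np.ndarray) -> float:
    """Normalized leakage of superpixels across ground-truth regions.

    For each ground-truth region, superpixels overlapping it contribute the
    smaller of their in-region and out-of-region areas; the total is
    normalized by the image size.
    """
    seg = np.asarray(segment_ids).ravel()
    truth = np.asarray(true_labels).ravel()
    n = seg.size
    error = 0.0
    seg_sizes = np.bincount(seg)
    for region in np.unique(truth):
        in_region = np.bincount(seg[truth == region], minlength=seg_sizes.size)
        overlapping = np.flatnonzero(in_region)
        outside = seg_sizes[overlapping] - in_region[overlapping]
        error += np.minimum(in_region[overlapping], outside).sum()
    return float(error / n)
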