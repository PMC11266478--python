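"""ENVI raster I/O, reflectance calibration, and spectrum extraction.

Hyperspectral cubes travel through the package as :class:`HyperspectralCube`
objects: an ``(rows, cols, bands)`` array paired with a :class:`SpectralAxis`
of band-center wavelengths.  Cubes are stored on disk in the ENVI dialect
(an ASCII ``.hdr`` plus a raw binary file), the de-facto exchange format for
field spectrometer data; the reader handles BIL/BIP/BSQ interleaves and
float32/float64/uint16 samples, the writer emits BSQ float32.

Raw radiance is converted to reflectance against a near-Lambertian field
reference panel (a Spectralon-type standard of ~99% reflectance): with the
panel radiance taken at time ``t0`` and the target radiance at ``t1``, the
corrected reflectance per band is

    rho_corr(lambda) = phi_r(lambda, t1) * rho_s(lambda) / phi_i(lambda, t0)

where ``rho_s`` is the panel's own reflectance factor.  Scenes are reduced
to vegetation-only pixels with an NDVI threshold mask, and representative
spectra are taken as masked means (a pluggable strategy).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "SpectralAxis",
    "HyperspectralCube",
    "SceneMask",
    "LabelMap",
    "ReferencePanel",
    "RadiancePair",
    "read_envi",
    "write_envi",
    "read_label_raster",
    "write_label_raster",
    "calibrate_reflectance",
    "vegetation_mask",
    "representative_spectrum",
    "nearest_band",
]

# ENVI "data type" codes we accept; the writer always emits 4 (float32).
_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered band-center wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength axis must be a nonempty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    @classmethod
    def linspace(cls, lo_nm: float = 400.0, hi_nm: float = 1000.0, n_bands: int = 204) -> "SpectralAxis":
        return cls(np.linspace(lo_nm, hi_nm, n_bands))


def nearest_band(axis: SpectralAxis, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties break to the lower index.

    Logs a warning when the nearest band is more than 10 nm away, which
    usually means the requested feature is outside the sensor's range.
    """
    dist = np.abs(axis.wavelengths_nm - target_nm)
    idx = int(np.argmin(dist))  # argmin returns the first (lower) index on ties
    if dist[idx] > 10.0:
        log.warning(
            "nearest band to %.1f nm is %.1f nm away (band %d at %.1f nm)",
            target_nm, dist[idx], idx, axis.wavelengths_nm[idx],
        )
    return idx


@dataclass
class HyperspectralCube:
    """An ``(M, N, D)`` reflectance or radiance cube with its wavelength axis.

    ``kind`` is ``"reflectance"`` (unitless, nominally 0..1 with headroom for
    specular glint) or ``"radiance"`` (arbitrary sensor units).
    """

    values: np.ndarray
    axis: SpectralAxis
    kind: str = "reflectance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got shape {v.shape}")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValueError("cube has no pixels")
        if v.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"cube depth {v.shape[2]} does not match axis with {self.axis.n_bands} bands"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite values")
        if self.kind not in ("radiance", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and (v.min() < 0 or v.max() > 1.5):
            raise ValueError("reflectance values must lie in [0, 1.5]")
        self.values = v

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def spectra(self, mask: "SceneMask | None" = None) -> np.ndarray:
        """Pixels as a (n, D) matrix, optionally restricted to a mask."""
        if mask is None:
            return self.values.reshape(-1, self.values.shape[2])
        mask.check_against(self.values.shape[:2])
        return self.values[mask.keep]


@dataclass
class SceneMask:
    """Boolean vegetation mask; ``keep=True`` marks canopy pixels."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValueError("mask must be 2-D")

    def check_against(self, spatial_shape: tuple) -> None:
        if self.keep.shape != tuple(spatial_shape):
            raise ValueError(f"mask shape {self.keep.shape} != scene shape {tuple(spatial_shape)}")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class LabelMap:
    """Per-pixel integer class labels; 0 means background/unlabeled."""

    labels: np.ndarray
    class_names: list

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer array")
        z = len(self.class_names)
        if lab.min() < 0 or lab.max() > z:
            raise ValueError(f"labels must lie in 0..{z}")
        self.labels = lab

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ReferencePanel:
    """Per-band reflectance factor of the field standard (~0.99 nominal)."""

    rho_s: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.rho_s, dtype=float))
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("panel reflectance factors must lie in (0, 1]")
        self.rho_s = r

    @classmethod
    def nominal(cls, n_bands: int, rho: float = 0.99) -> "ReferencePanel":
        return cls(np.full(n_bands, rho))


@dataclass
class RadiancePair:
    """Target radiance (at t1) and panel incident-proxy radiance (at t0).

    Field protocol keeps the panel and target exposures within 15 minutes of
    each other so illumination can be treated as constant; a larger gap is
    allowed but warned about.
    """

    phi_r: np.ndarray
    phi_i: np.ndarray
    dt_minutes: float = 0.0

    def __post_init__(self):
        self.phi_r = np.atleast_1d(np.asarray(self.phi_r, dtype=float))
        self.phi_i = np.atleast_1d(np.asarray(self.phi_i, dtype=float))
        if self.phi_r.shape != self.phi_i.shape:
            raise ValueError("phi_r and phi_i must have matching shapes")
        if self.dt_minutes >= 15:
            warnings.warn(
                f"panel/target time gap {self.dt_minutes:.1f} min exceeds the 15-min "
                "illumination-stability window", stacklevel=2,
            )


def calibrate_reflectance(pair: RadiancePair, panel: ReferencePanel) -> np.ndarray:
    """Panel-referenced reflectance: ``phi_r * rho_s / phi_i`` per band.

    The panel's own reflectance factor ``rho_s`` corrects for its
    non-Lambertian departure from a perfect (unit) reflector.
    """
    bad = np.flatnonzero(pair.phi_i <= 0)
    if bad.size:
        raise ValueError(f"non-positive incident radiance at band(s) {bad.tolist()[:10]}")
    rho_s = panel.rho_s
    if rho_s.size not in (1, pair.phi_i.size):
        raise ValueError("panel/radiance band counts disagree")
    return pair.phi_r * rho_s / pair.phi_i


# ---------------------------------------------------------------------------
# ENVI I/O


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' lines; brace-delimited values may span lines."""
    fields: dict = {}
    body = text.replace("\r\n", "\n")
    i = 0
    lines = body.split("\n")
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            while "}" not in val and i < len(lines):
                val += " " + lines[i].strip()
                i += 1
            val = val.strip("{} ").strip()
        fields[key] = val
    return fields


def read_envi(header_path: str | Path) -> HyperspectralCube:
    """Read an ENVI cube (``.hdr`` + binary), any of BIL/BIP/BSQ interleave.

    Values are always returned as an (rows, cols, bands) array in ascending
    band order, independent of the file's interleave.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"ENVI header missing required field {required!r}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    samples = int(fields["samples"])   # columns
    lines = int(fields["lines"])       # rows
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code} (supported: 4, 5, 12)")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields["interleave"].strip().lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")

    wavelengths = np.array([float(w) for w in fields["wavelength"].split(",") if w.strip()])
    if wavelengths.size != bands:
        raise ValueError(f"header lists {wavelengths.size} wavelengths but bands = {bands}")

    data_path = header_path.with_suffix(".dat")
    if not data_path.exists():
        candidates = [header_path.with_suffix(ext) for ext in (".img", ".raw", "")]
        data_path = next((c for c in candidates if c.exists() and c != header_path), data_path)
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary file holds {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands} {interleave})"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)
    kind = fields.get("canopyhsi kind", "reflectance")
    meta = {"source": str(header_path)}
    return HyperspectralCube(np.ascontiguousarray(cube, dtype=dtype.newbyteorder("=")),
                             SpectralAxis(wavelengths), kind=kind, metadata=meta)


def write_envi(cube: HyperspectralCube, header_path: str | Path,
               interleave: str = "bsq") -> None:
    """Write a cube as float32 ENVI (header + ``.dat`` binary)."""
    header_path = Path(header_path)
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    rows, cols, bands = cube.shape
    values = cube.values.astype(np.float32)
    if interleave == "bsq":
        raw = values.transpose(2, 0, 1)
    elif interleave == "bil":
        raw = values.transpose(0, 2, 1)
    else:
        raw = values
    wl = ", ".join(f"{w:.4f}" for w in cube.axis.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {canopyhsi export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"canopyhsi kind = {cube.kind}\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(raw).tofile(header_path.with_suffix(".dat"))


def write_label_raster(labels: np.ndarray, path: str | Path, class_names: list | None = None) -> None:
    """Store a label or mask raster as a compressed numpy archive."""
    np.savez_compressed(
        Path(path), labels=np.asarray(labels),
        class_names=np.array(class_names if class_names is not None else [], dtype=object),
    )


def read_label_raster(path: str | Path) -> LabelMap:
    with np.load(Path(path), allow_pickle=True) as archive:
        labels = archive["labels"]
        names = list(archive["class_names"])
    if not names:
        names = [str(i + 1) for i in range(int(labels.max()))]
    return LabelMap(labels, names)


# ---------------------------------------------------------------------------
# Masking and spectrum extraction


def vegetation_mask(cube: HyperspectralCube, red_nm: float = 670.0, nir_nm: float = 800.0,
                    threshold: float = 0.4) -> SceneMask:
    """Keep pixels whose NDVI exceeds ``threshold``.

    Separates canopy from water/soil/panel background: vegetation has a deep
    red absorption and a bright NIR plateau (NDVI well above 0.4), while the
    background archetypes are spectrally flat or blue-shifted (NDVI near or
    below zero).
    """
    if cube.kind != "reflectance":
        raise ValueError("vegetation masking requires a reflectance cube")
    if not (-1.0 < threshold < 1.0):
        raise ValueError("NDVI threshold must lie in (-1, 1)")
    wl = cube.axis.wavelengths_nm
    for nm in (red_nm, nir_nm):
        if not (wl[0] <= nm <= wl[-1]):
            raise ValueError(f"wavelength {nm} nm outside axis range [{wl[0]}, {wl[-1]}]")
    red = cube.values[:, :, nearest_band(cube.axis, red_nm)].astype(float)
    nir = cube.values[:, :, nearest_band(cube.axis, nir_nm)].astype(float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, 0.0)
    return SceneMask(ndvi > threshold)


def representative_spectrum(
    cube: HyperspectralCube,
    mask: SceneMask,
    strategy: str | Callable[[np.ndarray], np.ndarray] = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Band-wise (center, spread) of the kept pixels.

    ``strategy`` selects the center statistic: ``"mean"`` (default) or
    ``"median"``, or any callable mapping an (n, D) matrix to a D-vector.
    The spread is always the band-wise sample standard deviation.
    """
    mask.check_against(cube.shape[:2])
    if mask.n_kept == 0:
        raise ValueError("mask keeps no pixels")
    spectra = cube.spectra(mask).astype(float)
    if callable(strategy):
        center = np.asarray(strategy(spectra), dtype=float)
    elif strategy == "mean":
        center = spectra.mean(axis=0)
    elif strategy == "median":
        center = np.median(spectra, axis=0)
    else:
        raise ValueError(f"unknown extraction strategy {strategy!r}")
    sd = spectra.std(axis=0, ddof=1) if spectra.shape[0] > 1 else np.zeros(spectra.shape[1])
    return center, sd
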