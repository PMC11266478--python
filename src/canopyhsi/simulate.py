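"""Synthetic labeled hyperspectral canopy scenes.

Field campaigns that image crop plots under factorial fertilization designs
are expensive and the resulting cubes rarely public, so every downstream
stage of this package is exercised against a parametric simulator instead.
A scene is a grid (or Voronoi mosaic) of spatially contiguous single-class
plots over a water/soil background, imaged on a 204-band 400-1000 nm axis.

Each of the 14 nutrient treatments (one balanced reference plus N/P/K
gradients and compound deficits, coded A..N) owns an *endmember*: a smooth
vegetation reflectance curve built from the canonical canopy features —

* a green reflectance peak near 550 nm,
* the chlorophyll-absorption "red valley" near 680 nm,
* a logistic red edge rising to a near-infrared plateau, and
* a leaf-water absorption dip near 960 nm.

Treatments perturb the template along directions motivated by stress
physiology: nitrogen starvation raises green/red reflectance (chlorosis)
and lowers the NIR plateau (mesophyll breakdown); phosphorus level shifts
the plateau; potassium level modulates the water dip and green-peak width.
The perturbation magnitude is a single ``separability`` knob so class
overlap can be swept from identical (0) to well separated.  Pixels add
pixel-level multiplicative lognormal biological variability and band-level
additive Gaussian sensor noise.  No radiative-transfer realism is claimed:
plots have hard borders and no mixed pixels or BRDF effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .io import HyperspectralCube, LabelMap, SceneMask, SpectralAxis

__all__ = [
    "EndmemberParams",
    "TreatmentSpec",
    "SceneConfig",
    "make_endmember",
    "background_spectra",
    "default_treatments",
    "generate_scene",
    "generate_dataset",
    "TREATMENT_NAMES",
]

# 14 factorial NPK treatments: letter code -> (N, P, K) levels, 2 = normal.
TREATMENT_NAMES = [
    ("A", (0, 0, 2)), ("B", (0, 2, 2)), ("C", (1, 2, 2)), ("D", (2, 0, 2)),
    ("E", (2, 1, 2)), ("F", (2, 2, 2)), ("G", (2, 3, 2)), ("H", (2, 2, 0)),
    ("I", (2, 2, 1)), ("J", (2, 2, 3)), ("K", (3, 2, 2)), ("L", (1, 1, 2)),
    ("M", (1, 2, 1)), ("N", (2, 1, 1)),
]

# Fixed Gaussian widths (nm) of the red-valley and water-dip absorptions.
_RED_VALLEY_WIDTH = 25.0
_WATER_DIP_WIDTH = 45.0


@dataclass(frozen=True)
class EndmemberParams:
    """Shape parameters of one class's noiseless reflectance curve."""

    base_vis: float = 0.08
    green_peak_amp: float = 0.06
    green_peak_width_nm: float = 35.0
    red_valley_depth: float = 0.05
    red_edge_pos_nm: float = 710.0
    red_edge_width_nm: float = 15.0
    nir_plateau: float = 0.45
    water_dip_depth: float = 0.05


@dataclass(frozen=True)
class TreatmentSpec:
    class_id: int
    name: str
    endmember: EndmemberParams
    within_class_sd: float = 0.05


@dataclass
class SceneConfig:
    """Full description of one synthetic acquisition; (config, seed) is
    reproducible bit-for-bit."""

    height: int = 64
    width: int = 64
    n_bands: int = 204
    wavelength_range_nm: tuple = (400.0, 1000.0)
    treatments: list = field(default_factory=list)
    background_fraction: float = 0.2
    plot_layout: str = "grid"
    sensor_noise_sd: float = 0.01
    separability: float = 1.0
    seed: int = 0

    def axis(self) -> SpectralAxis:
        lo, hi = self.wavelength_range_nm
        return SpectralAxis.linspace(lo, hi, self.n_bands)

    def resolved_treatments(self) -> list:
        if self.treatments:
            return self.treatments
        return default_treatments(self.separability, self.seed)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def make_endmember(params: EndmemberParams, axis: SpectralAxis) -> np.ndarray:
    """Evaluate an endmember curve on ``axis``; values clipped to [0, 1].

    The curve is a sum of the vegetation features described in the module
    docstring; parameter choices that would break the vegetation ordering
    (green peak above red valley, NIR plateau above the visible baseline)
    are the caller's responsibility.
    """
    wl = axis.wavelengths_nm
    if wl[0] > 420.0 or wl[-1] < 980.0:
        raise ValueError("endmember axis must span roughly 400-1000 nm")
    spectrum = (
        params.base_vis
        + params.green_peak_amp * _gauss(wl, 550.0, params.green_peak_width_nm)
        - params.red_valley_depth * _gauss(wl, 680.0, _RED_VALLEY_WIDTH)
        + params.nir_plateau / (1.0 + np.exp(-(wl - params.red_edge_pos_nm) / params.red_edge_width_nm))
        - params.water_dip_depth * _gauss(wl, 960.0, _WATER_DIP_WIDTH)
    )
    return np.clip(spectrum, 0.0, 1.0)


def background_spectra(axis: SpectralAxis) -> dict:
    """The two non-vegetation archetypes: water (monotone decreasing) and
    soil (monotone increasing, low curvature)."""
    wl = axis.wavelengths_nm
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    water = 0.10 * np.exp(-2.5 * t) + 0.01
    soil = 0.12 + 0.20 * t
    return {"water": water, "soil": soil}


def default_treatments(separability: float = 1.0, seed: int = 0) -> list:
    """The 14-treatment roster with physiologically oriented offsets.

    ``separability`` scales every inter-class parameter difference; at 0 all
    14 endmembers coincide with the balanced reference F.  A small seeded
    jitter (also proportional to ``separability``) breaks residual symmetry
    between treatments that share NPK deviations.
    """
    if separability < 0:
        raise ValueError("separability must be >= 0")
    rng = np.random.default_rng(seed)
    base = EndmemberParams()
    specs = []
    for class_id, (letter, (n, p, k)) in enumerate(TREATMENT_NAMES, start=1):
        dn, dp, dk = n - 2, p - 2, k - 2  # deviation from the balanced level
        jitter = rng.normal(0.0, 1.0, size=4)
        params = replace(
            base,
            # chlorosis under N shortage: brighter green/red, darker NIR
            green_peak_amp=base.green_peak_amp + separability * (-dn * 0.012 + 0.003 * jitter[0]),
            red_valley_depth=base.red_valley_depth + separability * (dn * 0.008 + 0.002 * jitter[1]),
            nir_plateau=base.nir_plateau + separability * (dn * 0.020 + dp * 0.012 + 0.006 * jitter[2]),
            water_dip_depth=base.water_dip_depth + separability * (-dk * 0.010 + 0.002 * jitter[3]),
            green_peak_width_nm=base.green_peak_width_nm + separability * dk * 2.0,
        )
        code = f"N{n}P{p}K{k}"
        specs.append(TreatmentSpec(class_id=class_id, name=f"{letter} ({code})", endmember=params))
    return specs


def _plot_grid(height: int, width: int, n_classes: int, bg_rows: int,
               bg_rem: int) -> np.ndarray:
    """Row-major grid of contiguous plots below a background band."""
    labels = np.zeros((height, width), dtype=np.int32)
    top = bg_rows + (1 if bg_rem else 0)
    plot_h = height - top
    if plot_h <= 0:
        raise ValueError("background fraction leaves no room for plots")
    # choose a grid with at least n_classes cells, close to the scene aspect
    rows = max(1, int(np.floor(np.sqrt(n_classes * plot_h / width))))
    cols = int(np.ceil(n_classes / rows))
    while rows * cols < n_classes:
        cols += 1
    row_edges = np.linspace(top, height, rows + 1).astype(int)
    col_edges = np.linspace(0, width, cols + 1).astype(int)
    cell = 0
    for r in range(rows):
        for c in range(cols):
            cls = cell % n_classes + 1
            labels[row_edges[r]:row_edges[r + 1], col_edges[c]:col_edges[c + 1]] = cls
            cell += 1
    # exact background pixel count: first bg_rows full rows plus bg_rem pixels;
    # the rest of the partial row joins the plot directly below it
    labels[:bg_rows, :] = 0
    if bg_rem:
        labels[bg_rows, bg_rem:] = labels[top, bg_rem:]
        labels[bg_rows, :bg_rem] = 0
    return labels


def _plot_voronoi(height: int, width: int, n_classes: int, bg_rows: int,
                  bg_rem: int, rng: np.random.Generator) -> np.ndarray:
    top = bg_rows + (1 if bg_rem else 0)
    sites = rng.uniform([top, 0], [height, width], size=(2 * n_classes, 2))
    rr, cc = np.mgrid[0:height, 0:width]
    d2 = (rr[..., None] - sites[:, 0]) ** 2 + (cc[..., None] - sites[:, 1]) ** 2
    labels = (np.argmin(d2, axis=2) % n_classes + 1).astype(np.int32)
    labels[:bg_rows, :] = 0
    if bg_rem:
        labels[bg_rows, :bg_rem] = 0
    return labels  # voronoi cells already cover the partial row's remainder


def generate_scene(config: SceneConfig, seed: int | None = None):
    """Render one labeled scene.

    Returns ``(cube, label_map, mask)``.  Pixel spectra are
    ``endmember * exp(sigma * N(0,1)) + N(0, noise_sd)`` clipped to [0, 1];
    the multiplicative factor is shared across bands within a pixel
    (canopy-brightness variability), the additive term is band independent
    (sensor noise).  Background pixels alternate water/soil archetypes and
    carry label 0; the mask keeps exactly the labeled pixels.
    """
    treatments = config.resolved_treatments()
    if not treatments:
        raise ValueError("scene config lists no treatments")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    axis = config.axis()
    height, width = config.height, config.width

    n_bg = int(round(config.background_fraction * height * width))
    bg_rows, bg_rem = divmod(n_bg, width)
    n_classes = len(treatments)
    if config.plot_layout == "grid":
        labels = _plot_grid(height, width, n_classes, bg_rows, bg_rem)
    elif config.plot_layout == "voronoi":
        labels = _plot_voronoi(height, width, n_classes, bg_rows, bg_rem, rng)
    else:
        raise ValueError(f"unknown plot layout {config.plot_layout!r}")

    endmembers = {t.class_id: make_endmember(t.endmember, axis) for t in treatments}
    sds = {t.class_id: t.within_class_sd for t in treatments}
    bg = background_spectra(axis)

    cube = np.empty((height, width, axis.n_bands), dtype=np.float64)
    # background: alternate the two archetypes in a checker pattern
    bg_mask = labels == 0
    checker = (np.add.outer(np.arange(height), np.arange(width)) % 2).astype(bool)
    cube[bg_mask & checker] = bg["water"]
    cube[bg_mask & ~checker] = bg["soil"]

    for t in treatments:
        sel = labels == t.class_id
        n_pix = int(sel.sum())
        if n_pix == 0:
            continue
        factor = np.exp(sds[t.class_id] * rng.standard_normal(n_pix)) if sds[t.class_id] > 0 else np.ones(n_pix)
        cube[sel] = endmembers[t.class_id][None, :] * factor[:, None]
    if config.sensor_noise_sd > 0:
        cube += rng.normal(0.0, config.sensor_noise_sd, size=cube.shape)
    np.clip(cube, 0.0, 1.0, out=cube)

    names = [t.name for t in treatments]
    meta = {"simulator": "canopyhsi", "seed": str(config.seed if seed is None else seed)}
    return (
        HyperspectralCube(cube, axis, kind="reflectance", metadata=meta),
        LabelMap(labels, names),
        SceneMask(labels > 0),
    )


def generate_dataset(config: SceneConfig, n_scenes: int, year_shift: float = 0.0):
    """A multi-scene collection emulating a two-season campaign.

    Scenes are drawn with independent child seeds; even-indexed scenes are
    "year 1", odd-indexed "year 2", and year-2 cubes get a global
    multiplicative illumination drift ``(1 + year_shift)`` to emulate
    inter-season covariate shift.  Returns a list of
    ``(cube, label_map, mask, year)`` tuples.
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_scenes) % (2**31)
    scenes = []
    for i in range(n_scenes):
        cube, labels, mask = generate_scene(config, seed=int(child_seeds[i]))
        year = 1 if i % 2 == 0 else 2
        if year == 2 and year_shift != 0.0:
            shifted = np.clip(cube.values * (1.0 + year_shift), 0.0, 1.0)
            cube = HyperspectralCube(shifted, cube.axis, kind="reflectance",
                                     metadata=dict(cube.metadata, year_shift=str(year_shift)))
        cube.metadata["year"] = str(year)
        scenes.append((cube, labels, mask, year))
    return scenes


def write_manifest(config: SceneConfig, path: str | Path, n_scenes: int = 1,
                   year_shift: float = 0.0) -> None:
    """Record the generating configuration so a dataset can be regenerated."""
    def plain(obj):
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    cfg = asdict(config)
    cfg["wavelength_range_nm"] = list(config.wavelength_range_nm)
    cfg["treatments"] = [asdict(t) for t in config.resolved_treatments()]
    doc = plain({"config": cfg, "n_scenes": n_scenes, "year_shift": year_shift})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
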