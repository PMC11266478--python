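"""End-to-end study protocols on synthetic scenes.

These helpers wire the full pipeline — scene simulation, SuperPCA
reduction, patch extraction, model training and evaluation — into the
study designs used throughout the package: the stratified 70/30 protocol,
the 5/95 small-sample protocol comparing SHCFTT against SVM / 1-D CNN /
3-D CNN, and the component-ablation sweep.  They are what the example
scripts and the acceptance checks run.

Patch sets are subsampled to a fixed number of pixels per class before
splitting: adjacent pixels of a plot are nearly duplicate samples, so a
modest per-class quota keeps runs CPU-friendly without changing what the
comparison measures.
"""

from __future__ import annotations

import numpy as np

from .evaluate import SplitSpec, evaluate_model, metric_triple, split
from .io import HyperspectralCube, LabelMap
from .nn import ModelConfig
from .simulate import SceneConfig, generate_scene
from .superpca import PatchSet, extract_patches, first_pc_image, segment_superpixels, superpca_reduce
from .train import TrainConfig, baseline_cnn1d, baseline_svm, baseline_cnn3d, train_shcftt

__all__ = [
    "build_patchset",
    "subsample_per_class",
    "single_treatment_scenes",
    "build_experiment_data",
    "concat_patchsets",
    "standard_protocol",
    "small_sample_comparison",
]


def build_patchset(cube: HyperspectralCube, labels: LabelMap, *, b: int = 30, s: int = 13,
                   n_segments: int = 14, seg_method: str = "ers") -> PatchSet:
    """SuperPCA-reduce a labeled cube and cut it into labeled patches."""
    pc1 = first_pc_image(cube)
    segmap = segment_superpixels(pc1, n_segments, method=seg_method)
    reduced = superpca_reduce(cube, segmap, b)
    patches = extract_patches(reduced, labels, s)
    patches.fingerprint = f"s={s};b={b};k={segmap.n_segments};seg={seg_method}"
    return patches


def single_treatment_scenes(base: SceneConfig | None = None, *, seed: int = 0,
                            scenes_per_class: int = 1) -> list:
    """One scene per treatment (x replicates): the field-campaign geometry.

    Each acquisition images a single treatment's plot over background, so
    spectral-spatial patches are class-homogeneous — the multi-plot mosaic
    of :func:`canopyhsi.simulate.generate_scene` is kept for segmentation
    and masking studies.  Returns ``(cube, labels, mask)`` triples whose
    label maps carry the treatment's global class id.
    """
    from dataclasses import replace as dc_replace

    base = base or SceneConfig()
    roster = base.resolved_treatments()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(roster) * scenes_per_class) % (2**31)
    scenes = []
    for rep in range(scenes_per_class):
        for i, treatment in enumerate(roster):
            config = SceneConfig(
                height=base.height, width=base.width, n_bands=base.n_bands,
                wavelength_range_nm=base.wavelength_range_nm,
                treatments=[dc_replace(treatment, class_id=1)],
                background_fraction=base.background_fraction,
                plot_layout=base.plot_layout, sensor_noise_sd=base.sensor_noise_sd,
                separability=base.separability,
                seed=int(child_seeds[rep * len(roster) + i]))
            cube, labels, mask = generate_scene(config)
            relabeled = labels.labels.copy()
            relabeled[relabeled == 1] = treatment.class_id
            scenes.append((cube, LabelMap(relabeled, [t.name for t in roster]), mask))
    return scenes


def concat_patchsets(patchsets: list) -> PatchSet:
    return PatchSet(
        np.concatenate([p.patches for p in patchsets]),
        np.concatenate([p.centers for p in patchsets]),
        np.concatenate([p.labels for p in patchsets]),
        patchsets[0].s,
    )


def build_experiment_data(scenes: list, *, b: int = 30, s: int = 13,
                          n_segments: int = 4, seg_method: str = "ers",
                          per_scene: int | None = None, seed: int = 0):
    """Reduce each scene independently (as each field image would be) and
    pool labeled patches plus the matching raw center-pixel spectra.

    Returns ``(PatchSet, spectra)`` with aligned rows; ``per_scene`` caps
    the labeled pixels kept per scene.
    """
    rng = np.random.default_rng(seed)
    patch_parts, spectra_parts = [], []
    for cube, labels, _ in scenes:
        part = build_patchset(cube, labels, b=b, s=s, n_segments=n_segments,
                              seg_method=seg_method)
        if per_scene is not None and len(part) > per_scene:
            part = part.subset(np.sort(rng.choice(len(part), per_scene, replace=False)))
        patch_parts.append(part)
        spectra_parts.append(cube.values[part.centers[:, 0], part.centers[:, 1]])
    return concat_patchsets(patch_parts), np.concatenate(spectra_parts)


def subsample_per_class(patches: PatchSet, per_class: int, seed: int = 0) -> PatchSet:
    rng = np.random.default_rng(seed)
    keep = []
    for cls in patches.classes:
        members = np.flatnonzero(patches.labels == cls)
        if members.size > per_class:
            members = rng.choice(members, per_class, replace=False)
        keep.append(members)
    return patches.subset(np.sort(np.concatenate(keep)))


def standard_protocol(scene_config: SceneConfig | None = None, *, seed: int = 0,
                      model_config: ModelConfig | None = None,
                      hp: TrainConfig | None = None, per_class: int = 60,
                      train_fraction: float = 0.70, scene_split: bool = False) -> dict:
    """Train SHCFTT under a stratified train/test split of pooled
    single-treatment scenes.

    With ``scene_split=True`` the test set comes from an independent
    replicate scene per treatment instead of held-out pixels of the same
    scenes — the leakage-free protocol for generalization questions (two
    patches of one plot are nearly duplicates, so pixelwise splits are
    optimistic).  Returns train/test OA, AA and Kappa x100 plus the
    problem sizes used.
    """
    scene_config = scene_config or SceneConfig(seed=seed)
    model_config = model_config or ModelConfig()
    hp = hp or TrainConfig(epochs=25, seed=seed)
    if scene_split:
        scenes = single_treatment_scenes(scene_config, seed=seed, scenes_per_class=2)
        n_scenes = len(scenes) // 2
        train_patches, _ = build_experiment_data(
            scenes[:n_scenes], b=model_config.b, s=model_config.s,
            per_scene=per_class, seed=seed)
        test_patches, _ = build_experiment_data(
            scenes[n_scenes:], b=model_config.b, s=model_config.s,
            per_scene=max(1, per_class // 2), seed=seed + 1)
        train_set, test_set = train_patches, test_patches
        n_classes = scenes[0][1].n_classes
        scenes = scenes[:n_scenes]
    else:
        scenes = single_treatment_scenes(scene_config, seed=seed)
        patches, _ = build_experiment_data(scenes, b=model_config.b, s=model_config.s,
                                           per_scene=per_class, seed=seed)
        n_classes = scenes[0][1].n_classes
        train_set, test_set = split(patches, SplitSpec(train_fraction, seed=seed))
    model_config = ModelConfig(**{**vars(model_config), "n_classes": n_classes})
    model = train_shcftt(train_set, model_config, hp, seed=seed)
    return {
        "train": evaluate_model(model, train_set.patches, train_set.labels, n_classes),
        "test": evaluate_model(model, test_set.patches, test_set.labels, n_classes),
        "n_train": len(train_set),
        "n_test": len(test_set),
        "model": model,
    }


def small_sample_comparison(scene_config: SceneConfig | None = None, *, seed: int = 0,
                            model_config: ModelConfig | None = None,
                            hp: TrainConfig | None = None, per_class: int = 200,
                            train_fraction: float = 0.05, n_segments: int = 2,
                            max_test_eval: int | None = 400) -> dict:
    """The 5/95 small-sample shoot-out: SVM and 1-D CNN on center-pixel
    spectra versus 3-D CNN and SHCFTT on spectral-spatial patches.

    All four models see the same train/test pixel split; the spectral
    models consume each pixel's raw reflectance spectrum, the spatial
    models the SuperPCA patch.  Returns test OA per model.
    """
    scene_config = scene_config or SceneConfig(seed=seed)
    model_config = model_config or ModelConfig()
    # small-sample recipe: small batches, cosine decay, longer schedule
    hp = hp or TrainConfig(learning_rate=2e-3, batch_size=16, epochs=150,
                           cosine_lr=True, seed=seed)
    scenes = single_treatment_scenes(scene_config, seed=seed)
    patches, spectra = build_experiment_data(scenes, b=model_config.b, s=model_config.s,
                                             n_segments=n_segments,
                                             per_scene=per_class, seed=seed)
    n_classes = scenes[0][1].n_classes
    from .evaluate import split_indices
    train_idx, test_idx = split_indices(patches.labels, SplitSpec(train_fraction, seed=seed))
    if max_test_eval and test_idx.size > max_test_eval:
        rng = np.random.default_rng(seed)
        test_idx = np.sort(rng.choice(test_idx, max_test_eval, replace=False))
    train_set, test_set = patches.subset(train_idx), patches.subset(test_idx)
    train_spectra, test_spectra = spectra[train_idx], spectra[test_idx]
    model_config = ModelConfig(**{**vars(model_config), "n_classes": n_classes})

    svm = baseline_svm(train_spectra, train_set.labels, seed=seed)
    cnn1d = baseline_cnn1d(train_spectra, train_set.labels, hp=hp, seed=seed)
    cnn3d = baseline_cnn3d(train_set, model_config, hp=hp, seed=seed)
    shcftt = train_shcftt(train_set, model_config, hp, seed=seed)

    def test_oa(model, inputs):
        return metric_triple(test_set.labels, model.predict(inputs), n_classes)["OA"]

    return {
        "svm": test_oa(svm, test_spectra),
        "cnn1d": test_oa(cnn1d, test_spectra),
        "cnn3d": test_oa(cnn3d, test_set.patches),
        "shcftt": test_oa(shcftt, test_set.patches),
        "n_train": len(train_set),
        "n_test": len(test_set),
    }
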