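"""Metrics, split protocols, the ablation harness and classification maps.

Accuracy is reported from the confusion matrix ``x`` (rows = truth,
columns = prediction):

* overall accuracy   OA = trace(x) / total,
* average accuracy   AA = mean over classes of per-class recall
  ``x_ii / sum_j x_ij``,
* Cohen's kappa      (p_o - p_e) / (1 - p_e) with ``p_o = OA`` and
  ``p_e = sum_i row_i * col_i / total^2`` — chance-corrected agreement,
  conventionally reported x100.

Split protocols mirror common practice for per-pixel hyperspectral
classification: a stratified 70/30 train/test split, a 5/95 small-sample
split, and stratified 10-fold cross-validation.  The sampling unit is the
labeled pixel/patch; note that neighboring patches overlap spatially, so
pixelwise splits are optimistic about generalization to new scenes — use
scene-level splits for that question.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HyperspectralCube, LabelMap
from .nn import ModelConfig
from .superpca import PatchSet, ReducedCube, SuperpixelMap, extract_patches, first_pc_image, segment_superpixels, superpca_reduce
from .train import TrainConfig, TrainedModel, train_shcftt

__all__ = [
    "ConfusionMatrix",
    "SplitSpec",
    "AblationCase",
    "ABLATION_CASES",
    "confusion",
    "overall_accuracy",
    "average_accuracy",
    "kappa",
    "split",
    "split_indices",
    "cross_validate",
    "evaluate_model",
    "run_ablation",
    "classification_map",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("confusion counts must be nonnegative")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, n: int, class_names: list | None = None) -> ConfusionMatrix:
    """Counts[i, j] = number of class-(i+1) samples predicted as class j+1."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n):
            raise ValueError(f"{name} labels out of range 1..{n}")
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts, class_names or [str(i + 1) for i in range(n)])


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def average_accuracy(cm: ConfusionMatrix) -> float:
    """Macro-averaged per-class recall."""
    row_sums = cm.counts.sum(axis=1)
    empty = np.flatnonzero(row_sums == 0)
    if empty.size:
        names = [cm.class_names[i] if i < len(cm.class_names) else str(i + 1)
                 for i in empty[:5]]
        raise ValueError(f"class(es) {names} have no true samples")
    return float(np.mean(np.diag(cm.counts) / row_sums))


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa on the 0..1 scale (callers multiply by 100 to report)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    p_e = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        return float("nan")  # degenerate single-cell matrix
    return float((p_o - p_e) / (1.0 - p_e))


def metric_triple(y_true, y_pred, n: int) -> dict:
    cm = confusion(y_true, y_pred, n)
    return {"OA": overall_accuracy(cm), "AA": average_accuracy(cm),
            "Kappa_x100": 100.0 * kappa(cm)}


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must lie in (0, 1)")


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index arrays; deterministic per seed.

    Stratified splits round the per-class train count to the nearest
    integer (so proportions hold within one sample per class) and require
    at least one sample on each side per class.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        order = rng.permutation(labels.size)
        n_train = int(round(spec.train_fraction * labels.size))
        return np.sort(order[:n_train]), np.sort(order[n_train:])
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot stratify")
        n_train = int(round(spec.train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        shuffled = rng.permutation(members)
        train_parts.append(shuffled[:n_train])
        test_parts.append(shuffled[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def split(patches: PatchSet, spec: SplitSpec) -> tuple[PatchSet, PatchSet]:
    train_idx, test_idx = split_indices(patches.labels, spec)
    return patches.subset(train_idx), patches.subset(test_idx)


def cross_validate(patches: PatchSet, k: int, model_factory, seed: int = 0) -> dict:
    """Stratified k-fold CV; ``model_factory(train_patchset, seed)`` must
    return a fitted model with ``predict``.

    Returns per-fold metric dicts plus their mean and standard deviation.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("need k >= 2 folds")
    counts = np.bincount(patches.labels)
    small = np.flatnonzero((counts > 0) & (counts < k))
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} smaller than k={k}")
    n_classes = int(patches.classes.size)
    folds = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(skf.split(patches.patches, patches.labels)):
        model = model_factory(patches.subset(train_idx), seed + fold)
        y_pred = model.predict(patches.patches[test_idx])
        folds.append(metric_triple(patches.labels[test_idx], y_pred, n_classes))
    summary = {
        metric: {"mean": float(np.mean([f[metric] for f in folds])),
                 "sd": float(np.std([f[metric] for f in folds], ddof=1))}
        for metric in folds[0]
    }
    return {"folds": folds, "summary": summary}


def evaluate_model(model: TrainedModel, inputs: np.ndarray, labels: np.ndarray,
                   n_classes: int) -> dict:
    return metric_triple(labels, model.predict(inputs), n_classes)


# ---------------------------------------------------------------------------
# ablation harness


@dataclass(frozen=True)
class AblationCase:
    name: str
    use_superpca: bool
    use_cbam: bool
    use_cnn: bool
    use_tokenizer_te: bool


# The seven component combinations of the ablation design.
ABLATION_CASES = [
    AblationCase("Case 1", True, False, True, True),
    AblationCase("Case 2", False, True, True, True),
    AblationCase("Case 3", False, False, True, True),
    AblationCase("Case 4", True, False, True, False),
    AblationCase("Case 5", True, True, True, False),
    AblationCase("Case 6", True, False, False, True),
    AblationCase("SHCFTT", True, True, True, True),
]


def _reduce_for_case(cube: HyperspectralCube, use_superpca: bool, b: int,
                     n_segments: int, seg_method: str) -> ReducedCube:
    pc1 = first_pc_image(cube)
    if use_superpca:
        segmap = segment_superpixels(pc1, n_segments, method=seg_method)
    else:
        segmap = SuperpixelMap(np.zeros(pc1.shape, dtype=np.int32))  # global PCA
    return superpca_reduce(cube, segmap, b)


def run_ablation(scenes, *,
                 cases: list | None = None, config: ModelConfig | None = None,
                 hp: TrainConfig | None = None, split_spec: SplitSpec | None = None,
                 n_segments: int = 8, seg_method: str = "ers", seeds=(0,),
                 per_scene: int | None = None,
                 max_train_eval: int | None = None,
                 max_test_eval: int | None = None) -> list:
    """Train/evaluate each ablation case under a small-sample protocol.

    ``scenes`` is one ``(cube, labels)`` pair or a list of such pairs (or
    longer tuples, extra elements ignored); each scene is reduced
    independently and the labeled patches pooled.

    Disabled components use documented substitutes: no SuperPCA -> global
    PCA to the same band count; no CNN -> per-position linear projection of
    the raw reduced patch; no tokenizer/transformer -> a two-layer fully
    connected head on the flat feature map; no CBAM -> gates fixed at 1.
    Results are averaged over ``seeds``.  Returns one dict per case with
    train/test OA, AA and Kappa x100.
    """
    if isinstance(scenes, tuple):
        scenes = [scenes]
    cases = cases or ABLATION_CASES
    config = config or ModelConfig()
    hp = hp or TrainConfig(epochs=40, early_stop_train_acc=1.0)
    split_spec = split_spec or SplitSpec(train_fraction=0.05)
    n_classes = scenes[0][1].n_classes

    known = {c.name for c in ABLATION_CASES}
    for case in cases:
        if case.name not in known:
            raise ValueError(f"unknown ablation case {case.name!r}")

    # the two data variants (with / without SuperPCA) are shared across cases
    reductions = {}
    for use_superpca in {c.use_superpca for c in cases}:
        rng = np.random.default_rng(0)  # same pixel subsample for both variants
        parts = []
        for scene in scenes:
            cube, labels = scene[0], scene[1]
            reduced = _reduce_for_case(cube, use_superpca, config.b, n_segments, seg_method)
            part = extract_patches(reduced, labels, config.s)
            if per_scene is not None and len(part) > per_scene:
                part = part.subset(np.sort(rng.choice(len(part), per_scene, replace=False)))
            parts.append(part)
        pooled = parts[0] if len(parts) == 1 else PatchSet(
            np.concatenate([p.patches for p in parts]),
            np.concatenate([p.centers for p in parts]),
            np.concatenate([p.labels for p in parts]), config.s)
        reductions[use_superpca] = pooled

    results = []
    for case in cases:
        per_seed = []
        for seed in seeds:
            patches = reductions[case.use_superpca]
            spec = SplitSpec(split_spec.train_fraction, split_spec.stratified, seed=seed)
            train_set, test_set = split(patches, spec)
            if max_train_eval and len(train_set) > max_train_eval:
                rng = np.random.default_rng(seed)
                train_set = train_set.subset(np.sort(rng.choice(len(train_set), max_train_eval, False)))
            if max_test_eval and len(test_set) > max_test_eval:
                rng = np.random.default_rng(seed + 1)
                test_set = test_set.subset(np.sort(rng.choice(len(test_set), max_test_eval, False)))
            case_config = ModelConfig(**{**vars(config), "n_classes": n_classes,
                                         "use_cbam": case.use_cbam,
                                         "use_cnn": case.use_cnn,
                                         "use_tokenizer_te": case.use_tokenizer_te})
            model = train_shcftt(train_set, case_config,
                                 TrainConfig(hp.learning_rate, hp.batch_size, hp.epochs,
                                             hp.early_stop_train_acc, seed=seed),
                                 seed=seed)
            per_seed.append({
                "train": evaluate_model(model, train_set.patches, train_set.labels, n_classes),
                "test": evaluate_model(model, test_set.patches, test_set.labels, n_classes),
            })
        results.append({
            "case": case.name,
            "train": {m: float(np.mean([r["train"][m] for r in per_seed])) for m in per_seed[0]["train"]},
            "test": {m: float(np.mean([r["test"][m] for r in per_seed])) for m in per_seed[0]["test"]},
        })
    return results


def classification_map(model: TrainedModel, reduced: ReducedCube, labels: LabelMap,
                       s: int | None = None) -> np.ndarray:
    """Predicted class for every labeled pixel; background stays 0."""
    s = s or getattr(getattr(model.model, "config", None), "s", None)
    if s is None:
        raise ValueError("patch window s must be given for non-patch models")
    patches = extract_patches(reduced, labels, s)
    if patches.b != getattr(model.model, "config", ModelConfig(b=patches.b)).b:
        raise ValueError("model and reduced cube disagree on band count")
    out = np.zeros(labels.labels.shape, dtype=np.int32)
    predictions = model.predict(patches.patches)
    out[patches.centers[:, 0], patches.centers[:, 1]] = predictions
    return out
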