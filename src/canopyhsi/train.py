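"""Training loops, the SVM baseline, and checkpointing.

All network models (SHCFTT and the CNN baselines) share one Adam training
loop with seeded initialization and shuffling, so a (data, config, seed)
triple reproduces weights and predictions bit-for-bit.  Trained models are
wrapped in a small sklearn-flavoured interface (``predict`` /
``predict_proba`` / ``classes_``) so the evaluation protocols can treat
the SVM and the networks uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (CNN1DBaseline, CNN3DBaseline, ModelConfig, Module, SHCFTT,
                 config_from_dict, config_to_dict)
from .superpca import PatchSet

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "train_shcftt",
    "baseline_svm",
    "baseline_cnn1d",
    "baseline_cnn3d",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, cross-entropy)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    early_stop_train_acc: float | None = None  # stop once training accuracy reaches this
    cosine_lr: bool = False  # cosine-decay the learning rate over `epochs`
    weight_decay: float = 0.0  # decoupled (AdamW-style) weight decay
    normalize_inputs: bool = False  # per-feature-band standardization from the train set
    seed: int = 0


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class TrainedModel:
    """A fitted classifier over original (1-based) class ids."""

    def __init__(self, model, classes: np.ndarray, log: list, kind: str,
                 input_stats: tuple | None = None):
        self.model = model
        self.classes_ = np.asarray(classes)
        self.log = log
        self.kind = kind
        self.input_stats = input_stats  # (mean, sd) per feature band, or None

    def _transform(self, inputs: np.ndarray) -> np.ndarray:
        if self.input_stats is None:
            return inputs
        mean, sd = self.input_stats
        return (inputs - mean) / sd

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        if self.kind == "svm":
            return self.model.predict_proba(inputs)
        return self.model.predict_proba(self._transform(inputs))

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        if self.kind == "svm":
            return self.model.predict(inputs)
        probs = self.predict_proba(inputs)
        return self.classes_[np.argmax(probs, axis=1)]  # ties -> lowest class id


def _fit_network(model: Module, inputs: np.ndarray, labels: np.ndarray,
                 hp: TrainConfig, kind: str) -> TrainedModel:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    index_of = {c: i for i, c in enumerate(classes)}
    y0 = np.array([index_of[c] for c in labels])
    stats = None
    if hp.normalize_inputs:
        axes = tuple(range(inputs.ndim - 1))
        mean = inputs.mean(axis=axes, dtype=np.float64).astype(np.float32)
        sd = (inputs.std(axis=axes, dtype=np.float64) + 1e-8).astype(np.float32)
        stats = (mean, sd)
        inputs = (inputs - mean) / sd
    rng = np.random.default_rng(hp.seed)
    optimizer = Adam(model.parameters(), lr=hp.learning_rate,
                     weight_decay=hp.weight_decay)
    n = inputs.shape[0]
    log = []
    for epoch in range(hp.epochs):
        if hp.cosine_lr:
            optimizer.lr = hp.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / hp.epochs))
        order = rng.permutation(n)
        total_loss, correct = 0.0, 0
        for start in range(0, n, hp.batch_size):
            batch = order[start:start + hp.batch_size]
            optimizer.zero_grad()
            loss = model.loss(inputs[batch], y0[batch])
            loss.backward()
            optimizer.step()
            total_loss += float(loss.data) * batch.size
            correct += int((np.argmax(model.last_logits, axis=1) == y0[batch]).sum())
        acc = correct / n  # running accuracy over the epoch's own forward passes
        log.append({"epoch": epoch, "loss": total_loss / n, "train_acc": acc})
        if hp.early_stop_train_acc is not None and acc >= hp.early_stop_train_acc:
            break
    return TrainedModel(model, classes, log, kind, input_stats=stats)


def train_shcftt(patches: PatchSet, config: ModelConfig | None = None,
                 hp: TrainConfig | None = None, seed: int = 0) -> TrainedModel:
    """Train SHCFTT on a patch set; deterministic given ``seed``."""
    hp = hp or TrainConfig(seed=seed)
    n_classes = int(np.unique(patches.labels).size)
    if config is None:
        config = ModelConfig(s=patches.s, b=patches.b, n_classes=n_classes)
    model = SHCFTT(config, seed=seed)
    return _fit_network(model, patches.patches, patches.labels, hp, "shcftt")


def baseline_cnn3d(patches: PatchSet, config: ModelConfig | None = None,
                   hp: TrainConfig | None = None, seed: int = 0) -> TrainedModel:
    hp = hp or TrainConfig(seed=seed)
    if config is None:
        config = ModelConfig(s=patches.s, b=patches.b,
                             n_classes=int(np.unique(patches.labels).size))
    model = CNN3DBaseline(config, seed=seed)
    return _fit_network(model, patches.patches, patches.labels, hp, "cnn3d")


def baseline_cnn1d(spectra: np.ndarray, labels: np.ndarray,
                   hp: TrainConfig | None = None, seed: int = 0) -> TrainedModel:
    """Spectral 1-D CNN on raw reflectance; inputs are standardized per band."""
    from dataclasses import replace as dc_replace
    hp = dc_replace(hp, normalize_inputs=True) if hp else TrainConfig(
        seed=seed, normalize_inputs=True)
    model = CNN1DBaseline(spectra.shape[1], int(np.unique(labels).size), seed=seed)
    return _fit_network(model, np.asarray(spectra, dtype=np.float32),
                        np.asarray(labels), hp, "cnn1d")


def baseline_svm(spectra: np.ndarray, labels: np.ndarray, seed: int = 0,
                 grid: dict | None = None) -> TrainedModel:
    """RBF SVM with a small (C, gamma) grid search on the training split."""
    from sklearn.model_selection import GridSearchCV
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    labels = np.asarray(labels)
    grid = grid or {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.1]}
    pipeline = make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    counts = np.bincount(np.unique(labels, return_inverse=True)[1])
    cv = max(2, min(3, int(counts.min())))
    search = GridSearchCV(pipeline, grid, cv=cv, n_jobs=1)
    search.fit(np.asarray(spectra), labels)
    return TrainedModel(search.best_estimator_, np.unique(labels),
                        [{"best_params": search.best_params_}], "svm")


def save_checkpoint(trained: TrainedModel, path: str | Path, seed: int | None = None) -> None:
    """Single-file archive of weights + architecture config + classes."""
    if trained.kind == "svm":
        raise ValueError("checkpoints are for network models; persist the SVM with joblib")
    meta = {
        "kind": trained.kind,
        "seed": seed,
        "config": config_to_dict(trained.model.config) if hasattr(trained.model, "config") else None,
        "n_bands": getattr(trained.model, "n_bands", None),
        "version": "0.1.0",
    }
    state = {f"param::{k}": v for k, v in trained.model.state_dict().items()}
    if trained.input_stats is not None:
        state["stats::mean"], state["stats::sd"] = trained.input_stats
    np.savez_compressed(Path(path), classes=trained.classes_,
                        meta=json.dumps(meta), **state)


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        classes = archive["classes"]
        state = {k[len("param::"):]: archive[k] for k in archive.files
                 if k.startswith("param::")}
        stats = ((archive["stats::mean"], archive["stats::sd"])
                 if "stats::mean" in archive.files else None)
    seed = meta.get("seed") or 0
    if meta["kind"] == "shcftt":
        model = SHCFTT(config_from_dict(meta["config"]), seed=seed)
    elif meta["kind"] == "cnn3d":
        model = CNN3DBaseline(config_from_dict(meta["config"]), seed=seed)
    elif meta["kind"] == "cnn1d":
        model = CNN1DBaseline(int(meta["n_bands"]), int(classes.size), seed=seed)
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model.load_state_dict(state)
    return TrainedModel(model, classes, [], meta["kind"], input_stats=stats)
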