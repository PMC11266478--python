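"""The SHCFTT classifier and its building blocks.

SHCFTT (SuperPCA - HybridSN-style CNN - CBAM - Feature-Tokenization
Transformer) classifies each ``S x S x B`` spectral-spatial patch of a
SuperPCA-reduced cube into one of Z treatment classes:

1. a stack of three valid-mode, stride-1 3-D convolutions (8/16/32 kernels
   of size 3x3x7, 3x3x5, 3x3x3 over height x width x spectral), each with
   batch normalization and the configured activation;
2. the spectral and channel axes are merged and one 3x3 2-D convolution
   with 64 kernels follows, gated by a CBAM block (channel attention from
   shared-MLP avg/max descriptors, then spatial attention from a 7x7
   convolution over channelwise avg/max maps);
3. the flattened (u*v) x z feature map G is pooled into w semantic tokens
   T = A^T G, where A = softmax over spatial positions of G Wa and Wa is
   Gaussian-initialized — every token is a convex combination of feature
   rows;
4. a learnable classification token is prepended, position embeddings are
   added, and one pre-norm transformer encoder block (multi-head
   self-attention + MLP, both with residual connections) refines the
   sequence; the encoded classification token feeds a linear softmax head.

Every component can be switched off independently (with documented
substitutes) which is what the ablation harness in
:mod:`canopyhsi.evaluate` exercises.  The 1-D and 3-D CNN baselines live
here too; all models run on the numpy autodiff engine in
:mod:`canopyhsi.autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concatenate, conv_nd, cross_entropy_logits

__all__ = [
    "ModelConfig",
    "shape_ledger",
    "SHCFTT",
    "CNN1DBaseline",
    "CNN3DBaseline",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the stack above.

    ``s`` (patch window) and ``b`` (reduced band count) must survive the
    valid-mode convolution stack — see :func:`shape_ledger`.
    """

    s: int = 13
    b: int = 30
    n_classes: int = 14
    conv3d_channels: tuple = (8, 16, 32)
    conv3d_kernels: tuple = ((3, 3, 7), (3, 3, 5), (3, 3, 3))
    conv2d_channels: int = 64
    conv2d_kernel: tuple = (3, 3)
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    n_tokens: int = 4
    n_heads: int = 4
    d_k: int = 16
    mlp_dim: int | None = None     # defaults to 4*z
    activation: str = "relu"
    dropout: float = 0.1
    use_cnn: bool = True
    use_cbam: bool = True
    use_tokenizer_te: bool = True

    @property
    def z(self) -> int:
        return self.conv2d_channels

    def resolved_mlp_dim(self) -> int:
        return self.mlp_dim if self.mlp_dim is not None else 4 * self.z


def shape_ledger(config: ModelConfig) -> list:
    """Trace (spatial, spectral, channels) through the conv stack.

    Raises ``ValueError`` naming the first layer whose valid-mode
    convolution would underflow.
    """
    spatial, spectral = config.s, config.b
    ledger = [("input", spatial, spectral, 1)]
    for i, ((kh, kw, kr), ch) in enumerate(zip(config.conv3d_kernels, config.conv3d_channels), 1):
        if kh != kw:
            raise ValueError("square spatial kernels expected")
        spatial_next, spectral_next = spatial - kh + 1, spectral - kr + 1
        if spatial_next < 1 or spectral_next < 1:
            raise ValueError(
                f"conv3d layer {i} ({kh}x{kw}x{kr}) underflows: spatial {spatial}, "
                f"spectral {spectral}")
        spatial, spectral = spatial_next, spectral_next
        ledger.append((f"conv3d_{i}", spatial, spectral, ch))
    k2 = config.conv2d_kernel[0]
    if spatial - k2 + 1 < 1:
        raise ValueError(f"conv2d ({k2}x{k2}) underflows: spatial {spatial}")
    spatial = spatial - k2 + 1
    ledger.append(("conv2d", spatial, 1, config.conv2d_channels))
    return ledger


def _activation(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "sigmoid":
        return x.sigmoid()
    raise ValueError(f"unknown activation {name!r}")


class Module:
    """Minimal parameter container with a flat, ordered registry."""

    def __init__(self):
        self._params: dict = {}
        self._children: dict = {}

    def compute_dtype(self):
        for p in self.parameters().values():
            return p.data.dtype
        return np.float32

    def param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def add(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.w = self.param("w", rng.normal(0.0, scale, (d_in, d_out)))
        self.b = self.param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class ConvNd(Module):
    def __init__(self, c_in: int, c_out: int, kernel: tuple, rng: np.random.Generator,
                 pad: int | tuple = 0):
        super().__init__()
        fan_in = c_in * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.w = self.param("w", rng.normal(0.0, scale, (c_out, c_in) + tuple(kernel)))
        self.b = self.param("b", np.zeros(c_out))
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.w, self.b, pad=self.pad)


class BatchNorm(Module):
    """Per-channel normalization over batch and spatial axes (axis 1 = C)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.param("gamma", np.ones(channels))
        self.beta = self.param("beta", np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            inv = (var + self.eps).power(-0.5)
            normalized = centered * inv
        else:
            mean = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            normalized = (x - mean) * inv
        return normalized * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.param("gamma", np.ones(dim))
        self.beta = self.param("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).power(-0.5) * self.gamma + self.beta


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel attention: a shared two-layer MLP over the global average- and
    max-pooled channel descriptors, summed and squashed by a sigmoid.
    Spatial attention: a ``k x k`` same-padded convolution over the
    channelwise average/max maps, squashed by a sigmoid.  Both gates lie in
    (0, 1); ``identity=True`` freezes them at 1 (the ablation substitute).
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16,
                 spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.w1 = self.param("w1", rng.normal(0.0, np.sqrt(2.0 / channels), (channels, hidden)))
        self.w2 = self.param("w2", rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, channels)))
        self.spatial = self.add("spatial", ConvNd(
            2, 1, (spatial_kernel, spatial_kernel), rng, pad=(spatial_kernel - 1) // 2))

    def __call__(self, x: Tensor, identity: bool = False) -> Tensor:
        if identity:
            return x
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))                      # (N, C)
        mx = x.max(axis=3).max(axis=2)                 # (N, C)
        gate = ((avg @ self.w1).relu() @ self.w2 + (mx @ self.w1).relu() @ self.w2).sigmoid()
        x = x * gate.reshape(n, c, 1, 1)
        ch_avg = x.mean(axis=1, keepdims=True)         # (N, 1, H, W)
        ch_max = x.max(axis=1, keepdims=True)
        spatial_gate = self.spatial(concatenate([ch_avg, ch_max], axis=1)).sigmoid()
        return x * spatial_gate


def tokenize(g: Tensor, wa: Tensor) -> Tensor:
    """Semantic tokens ``T = A^T G`` with ``A = softmax_positions(G Wa)``.

    ``g``: (N, uv, z); ``wa``: (z, w).  The softmax runs over the spatial
    (uv) axis, so each token's attention column is a probability
    distribution over positions and each token a convex combination of
    feature rows.
    """
    attention = (g @ wa).softmax(axis=-2)   # (N, uv, w), columns sum to 1
    return attention.transpose((0, 2, 1)) @ g


class Tokenizer(Module):
    def __init__(self, z: int, n_tokens: int, rng: np.random.Generator):
        super().__init__()
        # Gaussian initialization of the token-attention weights
        self.wa = self.param("wa", rng.normal(0.0, 1.0 / np.sqrt(z), (z, n_tokens)))
        self.last_attention: np.ndarray | None = None

    def __call__(self, g: Tensor) -> Tensor:
        attention = (g @ self.wa).softmax(axis=-2)
        self.last_attention = attention.data
        return attention.transpose((0, 2, 1)) @ g


class MultiHeadSelfAttention(Module):
    def __init__(self, z: int, heads: int, d_k: int, rng: np.random.Generator):
        super().__init__()
        self.heads, self.d_k = heads, d_k
        scale = 1.0 / np.sqrt(z)
        self.wq = self.param("wq", rng.normal(0.0, scale, (z, heads * d_k)))
        self.wk = self.param("wk", rng.normal(0.0, scale, (z, heads * d_k)))
        self.wv = self.param("wv", rng.normal(0.0, scale, (z, heads * d_k)))
        self.wo = self.param("wo", rng.normal(0.0, 1.0 / np.sqrt(heads * d_k), (heads * d_k, z)))
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        n, t = x.shape[0], x.shape[1]
        h, dk = self.heads, self.d_k

        def split(y: Tensor) -> Tensor:  # (N, T, h*dk) -> (N, h, T, dk)
            return y.reshape(n, t, h, dk).transpose((0, 2, 1, 3))

        q, k, v = split(x @ self.wq), split(x @ self.wk), split(x @ self.wv)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
        attention = scores.softmax(axis=-1)            # rows sum to 1
        self.last_attention = attention.data
        mixed = attention @ v                          # (N, h, T, dk)
        merged = mixed.transpose((0, 2, 1, 3)).reshape(n, t, h * dk)
        return merged @ self.wo


class TransformerBlock(Module):
    """Pre-norm encoder block: x + MSA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, z: int, heads: int, d_k: int, mlp_dim: int,
                 rng: np.random.Generator, activation: str = "relu"):
        super().__init__()
        self.norm1 = self.add("norm1", LayerNorm(z))
        self.attn = self.add("attn", MultiHeadSelfAttention(z, heads, d_k, rng))
        self.norm2 = self.add("norm2", LayerNorm(z))
        self.fc1 = self.add("fc1", Linear(z, mlp_dim, rng))
        self.fc2 = self.add("fc2", Linear(mlp_dim, z, rng))
        self.activation = activation

    def __call__(self, x: Tensor, dropout=None) -> Tensor:
        attended = self.attn(self.norm1(x))
        if dropout is not None:
            attended = dropout(attended)
        x = x + attended
        hidden = _activation(self.fc1(self.norm2(x)), self.activation)
        out = self.fc2(hidden)
        if dropout is not None:
            out = dropout(out)
        return x + out


class _Dropout:
    """Seeded inverted dropout; a no-op when rate is 0 or at eval time."""

    def __init__(self, rate: float, rng: np.random.Generator, training: bool):
        self.rate, self.rng, self.training = rate, rng, training

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask.astype(np.float32)


class SHCFTT(Module):
    """The full spectral-spatial CNN + tokenizer + transformer classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        if config.use_cnn:
            ledger = shape_ledger(config)  # validates (s, b) against the stack
            self.ledger = ledger
            final_spatial = ledger[-1][1]
            self.n_positions = final_spatial ** 2
        else:
            self.ledger = [("input", config.s, config.b, 1)]
            self.n_positions = config.s ** 2
        rng = np.random.default_rng(seed)
        self.rng = rng
        z = config.z

        if config.use_cnn:
            c_prev = 1
            for i, (ch, kernel) in enumerate(zip(config.conv3d_channels, config.conv3d_kernels), 1):
                self.add(f"conv3d_{i}", ConvNd(c_prev, ch, kernel, rng))
                self.add(f"bn3d_{i}", BatchNorm(ch))
                c_prev = ch
            merged_planes = config.conv3d_channels[-1] * self.ledger[-2][2]
            self.add("conv2d", ConvNd(merged_planes, z, config.conv2d_kernel, rng))
            self.add("bn2d", BatchNorm(z))
            self.add("cbam", CBAM(z, rng, config.cbam_reduction, config.cbam_spatial_kernel))
        else:
            # ablation substitute: per-position linear projection of the raw
            # reduced spectrum to a z-dim feature
            self.add("project", Linear(config.b, z, rng))

        if config.use_tokenizer_te:
            self.add("tokenizer", Tokenizer(z, config.n_tokens, rng))
            self.cls_token = self.param("cls_token", rng.normal(0.0, 0.02, (1, 1, z)))
            self.pos_embedding = self.param(
                "pos_embedding", rng.normal(0.0, 0.02, (config.n_tokens + 1, z)))
            self.add("encoder", TransformerBlock(
                z, config.n_heads, config.d_k, config.resolved_mlp_dim(), rng,
                config.activation))
            self.add("head", Linear(z, config.n_classes, rng))
        else:
            # ablation substitute: two-layer fully connected head on flat G
            flat = self.n_positions * z
            self.add("fc_hidden", Linear(flat, config.resolved_mlp_dim(), rng))
            self.add("fc_out", Linear(config.resolved_mlp_dim(), config.n_classes, rng))

    # -- forward -----------------------------------------------------------

    def feature_map(self, patches: np.ndarray, training: bool = False) -> Tensor:
        """Patches (N, S, S, B) -> flat feature map G (N, u*v, z)."""
        config = self.config
        n = patches.shape[0]
        x = Tensor(np.ascontiguousarray(patches[:, None], dtype=self.compute_dtype()))
        if not config.use_cnn:
            g = x.reshape(n, config.s * config.s, config.b)
            return self._children["project"](g)
        for i in range(1, len(config.conv3d_channels) + 1):
            x = self._children[f"conv3d_{i}"](x)
            x = self._children[f"bn3d_{i}"](x, training)
            x = _activation(x, config.activation)
        _, spatial, spectral, channels = self.ledger[len(config.conv3d_channels)]
        # merge channel and spectral axes into conv2d input planes
        x = x.transpose((0, 1, 4, 2, 3)).reshape(n, channels * spectral, spatial, spatial)
        x = self._children["conv2d"](x)
        x = self._children["bn2d"](x, training)
        x = _activation(x, config.activation)
        x = self._children["cbam"](x, identity=not config.use_cbam)
        side = x.shape[2]
        return x.reshape(n, self.config.z, side * side).transpose((0, 2, 1))

    def forward(self, patches: np.ndarray, training: bool = False) -> Tensor:
        """Patches (N, S, S, B) -> logits (N, Z)."""
        config = self.config
        g = self.feature_map(patches, training)
        n = g.shape[0]
        if not config.use_tokenizer_te:
            flat = g.reshape(n, self.n_positions * config.z)
            hidden = _activation(self._children["fc_hidden"](flat), config.activation)
            return self._children["fc_out"](hidden)
        tokens = self._children["tokenizer"](g)
        cls = self.cls_token + Tensor(np.zeros((n, 1, config.z), dtype=self.compute_dtype()))
        sequence = concatenate([cls, tokens], axis=1) + self.pos_embedding
        dropout = _Dropout(config.dropout, self.rng, training)
        encoded = self._children["encoder"](sequence, dropout)
        return self._children["head"](encoded[:, 0, :])

    def loss(self, patches: np.ndarray, labels0: np.ndarray) -> Tensor:
        logits = self.forward(patches, training=True)
        self.last_logits = logits.data
        return cross_entropy_logits(logits, labels0)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for start in range(0, patches.shape[0], batch_size):
            logits = self.forward(patches[start:start + batch_size], training=False)
            probs.append(logits.softmax(axis=-1).data)
        return np.concatenate(probs, axis=0)


class CNN1DBaseline(Module):
    """Spectral-only 1-D CNN over per-pixel reflectance vectors."""

    def __init__(self, n_bands: int, n_classes: int, seed: int = 0,
                 channels: tuple = (8, 16), kernels: tuple = (7, 5), hidden: int = 64):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_bands = n_bands
        length = n_bands
        c_prev = 1
        for i, (ch, k) in enumerate(zip(channels, kernels), 1):
            k = min(k, length)  # short spectra: clamp the kernel, keep the depth
            self.add(f"conv_{i}", ConvNd(c_prev, ch, (k,), rng))
            self.add(f"bn_{i}", BatchNorm(ch))
            length = length - k + 1
            c_prev = ch
        self.n_layers = len(channels)
        self.add("fc1", Linear(c_prev * length, hidden, rng))
        self.add("fc2", Linear(hidden, n_classes, rng))
        self.rng = rng

    def forward(self, spectra: np.ndarray, training: bool = False) -> Tensor:
        n = spectra.shape[0]
        x = Tensor(np.ascontiguousarray(spectra[:, None], dtype=self.compute_dtype()))
        for i in range(1, self.n_layers + 1):
            x = self._children[f"conv_{i}"](x)
            x = self._children[f"bn_{i}"](x, training).relu()
        flat = x.reshape(n, int(np.prod(x.shape[1:])))
        return self._children["fc2"](self._children["fc1"](flat).relu())

    def loss(self, spectra: np.ndarray, labels0: np.ndarray) -> Tensor:
        logits = self.forward(spectra, training=True)
        self.last_logits = logits.data
        return cross_entropy_logits(logits, labels0)

    def predict_proba(self, spectra: np.ndarray, batch_size: int = 512) -> np.ndarray:
        probs = []
        for start in range(0, spectra.shape[0], batch_size):
            logits = self.forward(spectra[start:start + batch_size], training=False)
            probs.append(logits.softmax(axis=-1).data)
        return np.concatenate(probs, axis=0)


class CNN3DBaseline(Module):
    """Spectral-spatial 3-D CNN over patches, without attention modules.

    ``head`` selects the classifier head: ``"gap"`` (default) global-average
    pools the final feature volume per channel before a linear layer — the
    small-sample-friendly choice — while ``"flatten"`` uses a two-layer
    fully connected head on the flattened volume.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, hidden: int = 128,
                 head: str = "gap"):
        super().__init__()
        self.config = config
        self.head = head
        ledger = shape_ledger(config)
        rng = np.random.default_rng(seed)
        c_prev = 1
        for i, (ch, kernel) in enumerate(zip(config.conv3d_channels, config.conv3d_kernels), 1):
            self.add(f"conv_{i}", ConvNd(c_prev, ch, kernel, rng))
            self.add(f"bn_{i}", BatchNorm(ch))
            c_prev = ch
        _, spatial, spectral, channels = ledger[len(config.conv3d_channels)]
        if head == "gap":
            self.add("fc_out", Linear(channels, config.n_classes, rng))
        elif head == "flatten":
            flat = channels * spatial * spatial * spectral
            self.add("fc1", Linear(flat, hidden, rng))
            self.add("fc2", Linear(hidden, config.n_classes, rng))
        else:
            raise ValueError(f"unknown head {head!r}")
        self.rng = rng

    def forward(self, patches: np.ndarray, training: bool = False) -> Tensor:
        n = patches.shape[0]
        x = Tensor(np.ascontiguousarray(patches[:, None], dtype=self.compute_dtype()))
        for i in range(1, len(self.config.conv3d_channels) + 1):
            x = self._children[f"conv_{i}"](x)
            x = self._children[f"bn_{i}"](x, training).relu()
        if self.head == "gap":
            pooled = x.mean(axis=(2, 3, 4))
            return self._children["fc_out"](pooled)
        flat = x.reshape(n, int(np.prod(x.shape[1:])))
        return self._children["fc2"](self._children["fc1"](flat).relu())

    def loss(self, patches: np.ndarray, labels0: np.ndarray) -> Tensor:
        logits = self.forward(patches, training=True)
        self.last_logits = logits.data
        return cross_entropy_logits(logits, labels0)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for start in range(0, patches.shape[0], batch_size):
            logits = self.forward(patches[start:start + batch_size], training=False)
            probs.append(logits.softmax(axis=-1).data)
        return np.concatenate(probs, axis=0)


def config_to_dict(config: ModelConfig) -> dict:
    return asdict(config)


def config_from_dict(doc: dict) -> ModelConfig:
    doc = dict(doc)
    for key in ("conv3d_channels", "conv2d_kernel"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    if "conv3d_kernels" in doc:
        doc["conv3d_kernels"] = tuple(tuple(k) for k in doc["conv3d_kernels"])
    return ModelConfig(**doc)
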