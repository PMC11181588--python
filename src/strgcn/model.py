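"""The spatial-temporal residual graph convolutional network (STRGCN).

The model stacks two ST-Conv blocks, each a sandwich of a causal
single-channel temporal convolution, a first-order spatial graph convolution
(the renormalized propagation operator of the channel graph), a channel
attention gate, a second causal temporal convolution, and layer
normalization.  An additive residual shortcut wraps each block; flattened
features feed a linear softmax classifier.  Ablation variants remove the
graph stage (TRCN) or both temporal stages (SRGCN).

Feature maps are ``(batch, n_nodes, time, features)`` arrays; the node axis
indexes EEG channels of the graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, softmax

VARIANTS = ("STRGCN", "TRCN", "SRGCN")

#: Default per-block feature sizes (input, after-temporal, after-graph,
#: block output).  Deliberately modest: classification performance is
#: insensitive to these widths while CPU cost is not.
DEFAULT_BLOCKS = ((1, 8, 8, 8), (8, 8, 8, 8))

#: Default kernel width and stride per temporal-conv layer (two per block,
#: outer to inner).  Strides > 1 shrink the time axis layer by layer so the
#: classifier head sees a compact summary rather than the raw sample grid.
DEFAULT_KERNELS = (8, 8, 4, 2)
DEFAULT_STRIDES = (4, 4, 2, 2)


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``temporal_kernel`` and ``temporal_stride`` may be a single int (shared
    by every temporal layer) or a tuple with one entry per temporal layer
    (two layers per ST-Conv block, outermost first).
    """

    n_nodes: int
    window_len: int
    temporal_kernel: int | tuple = DEFAULT_KERNELS
    temporal_stride: int | tuple = DEFAULT_STRIDES
    block_feature_sizes: tuple = DEFAULT_BLOCKS
    attention_reduction: int = 4
    variant: str = "STRGCN"
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_feature_sizes) < 1:
            raise ValueError("need at least one ST-Conv block")
        if min(self.kernels()) < 1:
            raise ValueError("temporal_kernel must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def n_blocks(self) -> int:
        return len(self.block_feature_sizes)

    def _per_layer(self, v) -> tuple:
        n = 2 * self.n_blocks
        if np.isscalar(v):
            return (int(v),) * n
        v = tuple(int(x) for x in v)
        if len(v) != n:
            raise ValueError(
                f"need one value per temporal layer ({n}), got {len(v)}")
        return v

    def kernels(self) -> tuple:
        return self._per_layer(self.temporal_kernel)

    def strides(self) -> tuple:
        return self._per_layer(self.temporal_stride)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Module:
    """Base class: parameter registry plus numpy/Tensor-agnostic call."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Identity(Module):
    def __call__(self, x, *args):
        return _as_tensor(x)


class CausalConv1d(Module):
    """Causal 1-D convolution over time with ReLU, shared across nodes.

    The same width-K kernel bank is applied to every node; output at time t
    uses inputs at times <= t only (left zero-padding of K-1 samples keeps
    the length at stride 1).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.stride = stride
        self.weight = _uniform(rng, (kernel, c_in, c_out), kernel * c_in)
        self.bias = _uniform(rng, (c_out,), kernel * c_in)

    def __call__(self, x, *args):
        x = _as_tensor(x)
        T = x.shape[2]
        if self.kernel > T:
            raise ValueError(
                f"kernel width {self.kernel} exceeds window length {T}")
        xp = x.pad_axis(2, self.kernel - 1)
        t_out = (T - 1) // self.stride + 1
        out = None
        for k in range(self.kernel):
            sl = xp[:, :, k: k + self.stride * (t_out - 1) + 1: self.stride, :]
            term = sl @ self.weight[k]
            out = term if out is None else out + term
        return (out + self.bias).relu()


class GraphConv(Module):
    """First-order graph convolution P X Theta (per time step) with ReLU."""

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.theta = _uniform(rng, (c_in, c_out), c_in)
        self.bias = _uniform(rng, (c_out,), c_in)

    def __call__(self, x, P):
        x = _as_tensor(x)
        P = _as_tensor(P)
        b, n, t, c = x.shape
        h = (P @ x.reshape(b, n, t * c)).reshape(b, n, t, c)
        return (h @ self.theta + self.bias).relu()


class ChannelAttention(Module):
    """Feature-wise gating from pooled descriptors.

    Average- and max-pooling over the node and time axes give two
    feature-length descriptors; both pass through a shared one-hidden-layer
    perceptron, are summed elementwise, and squashed by a logistic to (0, 1).
    The input is scaled per feature by the resulting attention weights.
    """

    def __init__(self, c: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        hidden = max(1, c // reduction)
        self.w1 = _uniform(rng, (c, hidden), c)
        self.b1 = _uniform(rng, (hidden,), c)
        # zero-initialized output layer: gates start neutral at sigmoid(0)=0.5
        # so an untrained gate passes features through undistorted
        self.w2 = Tensor(np.zeros((hidden, c)), requires_grad=True)
        self.b2 = Tensor(np.zeros(c), requires_grad=True)

    def _mlp(self, d: Tensor) -> Tensor:
        return (d @ self.w1 + self.b1).relu() @ self.w2 + self.b2

    def weights(self, x) -> Tensor:
        x = _as_tensor(x)
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=(1, 2))
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()

    def __call__(self, x, *args):
        x = _as_tensor(x)
        a = self.weights(x)
        b, c = a.shape
        return x * a.reshape(b, 1, 1, c)


class LayerNorm(Module):
    """Per-sample normalization over the whole (node, time, feature) layer
    with learnable per-feature gain and bias.

    Normalizing jointly over all non-batch axes removes only the global
    activation scale of each sample; relative amplitude differences between
    nodes — which carry the connectivity signal — survive.  (Normalizing per
    position across features alone would cancel them.)
    """

    def __init__(self, c: int, eps: float = 1e-5, axes: tuple = (1, 2, 3)):
        self.eps = eps
        self.axes = axes
        self.gain = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)

    def __call__(self, x, *args):
        x = _as_tensor(x)
        mu = x.mean(axis=self.axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=self.axes, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.bias


class STConvBlock(Module):
    """Temporal conv -> graph conv -> attention -> temporal conv -> LN.

    ``variant`` replaces the graph stage (TRCN) or both temporal stages
    (SRGCN) with identities; feature bookkeeping adapts accordingly.
    """

    def __init__(self, sizes: tuple, cfg: ModelConfig, block_index: int,
                 rng: np.random.Generator):
        c_in, c_t, c_g, c_out = sizes
        v = cfg.variant
        (k1, k2) = cfg.kernels()[2 * block_index: 2 * block_index + 2]
        (s1, s2) = cfg.strides()[2 * block_index: 2 * block_index + 2]
        if v == "SRGCN":
            self.t1 = Identity()
            self.gc = GraphConv(c_in, c_g, rng)
            self.att = ChannelAttention(c_g, cfg.attention_reduction, rng)
            self.t2 = Identity()
            self.c_out = c_g
        elif v == "TRCN":
            self.t1 = CausalConv1d(c_in, c_t, k1, s1, rng)
            self.gc = Identity()
            self.att = ChannelAttention(c_t, cfg.attention_reduction, rng)
            self.t2 = CausalConv1d(c_t, c_out, k2, s2, rng)
            self.c_out = c_out
        else:
            self.t1 = CausalConv1d(c_in, c_t, k1, s1, rng)
            self.gc = GraphConv(c_t, c_g, rng)
            self.att = ChannelAttention(c_g, cfg.attention_reduction, rng)
            self.t2 = CausalConv1d(c_g, c_out, k2, s2, rng)
            self.c_out = c_out
        self.ln = LayerNorm(self.c_out)
        self.c_in = c_in

    def __call__(self, x, P):
        h = self.t1(x)
        h = self.gc(h, P)
        h = self.att(h)
        h = self.t2(h)
        return self.ln(h)


class ResidualBlock(Module):
    """Additive identity shortcut around an ST-Conv block.

    A 1x1 linear map aligns feature counts when they differ; when the block
    shrinks the time axis (stride > 1) the shortcut is subsampled to match.
    """

    def __init__(self, block: STConvBlock, rng: np.random.Generator):
        self.block = block
        if block.c_in != block.c_out:
            # start the projected shortcut small so the block's own features
            # dominate early training; the projection grows if useful
            p = _uniform(rng, (block.c_in, block.c_out), block.c_in)
            p.data *= 0.1
            self.proj = p
        else:
            self.proj = None

    def __call__(self, x, P):
        x = _as_tensor(x)
        h = self.block(x, P)
        sc = x
        if self.proj is not None:
            sc = sc @ self.proj
        t_out = h.shape[2]
        if sc.shape[2] != t_out:
            step = sc.shape[2] // t_out
            sc = sc[:, :, : step * t_out: step, :]
        return h + sc


class STRGCN(Module):
    """The full classifier: residual ST-Conv blocks, flatten, linear head."""

    def __init__(self, cfg: ModelConfig):
        cfg = ModelConfig(**asdict(cfg)) if not isinstance(cfg, ModelConfig) \
            else cfg
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = [
            ResidualBlock(STConvBlock(sizes, cfg, b, rng), rng)
            for b, sizes in enumerate(cfg.block_feature_sizes)
        ]
        # every block feeds its own flatten layer: features are averaged
        # over the time axis (the class signal is a temporal statistic, not
        # a localized event) and flattened over nodes x features; the
        # classifier integrates the flattened features of all blocks
        self.flat_dims = [cfg.n_nodes * blk.block.c_out for blk in self.blocks]
        total = sum(self.flat_dims)
        self.head_w = [_uniform(rng, (d, cfg.n_classes), total)
                       for d in self.flat_dims]
        self.head_b = _uniform(rng, (cfg.n_classes,), total)
        self.flat_dim = total

    def features(self, X, P) -> list[Tensor]:
        """Per-block pre-flatten feature maps (after each residual block)."""
        h = _as_tensor(X)
        P = _as_tensor(P)
        out = []
        for blk in self.blocks:
            h = blk(h, P)
            out.append(h)
        return out

    def logits(self, X, P) -> Tensor:
        feats = self.features(X, P)
        b = feats[0].shape[0]
        out = self.head_b
        for h, w, d in zip(feats, self.head_w, self.flat_dims):
            out = out + h.mean(axis=2).reshape(b, d) @ w
        return out

    def predict_proba(self, X, P) -> np.ndarray:
        """Class probabilities (rows sum to 1) for ``(B, N, T, C)`` input."""
        return softmax(self.logits(X, P).data)

    def predict(self, X, P) -> np.ndarray:
        return self.predict_proba(X, P).argmax(axis=1)

    # -- weight (de)serialization ----------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match model parameterization")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.cfg)),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "STRGCN":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(**json.loads(str(z["__config__"])))
            model = build_variant(cfg)
            model.load_state_dict(
                {k: z[k] for k in z.files if k != "__config__"})
        return model


def build_variant(cfg: ModelConfig) -> STRGCN:
    """Instantiate the full model or an ablation variant from a config."""
    return STRGCN(cfg)
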