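"""Residual convolutional embedding network with spatial pyramid pooling and
L2-normalized output.

Topology: an initial large-kernel conv + 2x2 max pool, four stages of
bottleneck residual blocks (1x1 / 3x3 / 1x1 convs with a projection shortcut
where shape changes, ReLU after every conv), a spatial-pyramid-pooling layer
that max-pools the final feature map over 1x1, 2x2, ... grids and
concatenates (yielding a fixed-length vector for any input size), a fully
connected embedding layer, and row-wise L2 normalization so embeddings live
on the unit sphere.

Two presets are shipped.  ``paper``: initial conv of 128 7x7 kernels, stride
1x1, stage widths 256/512/1024/2048 with depths 3/4/6/3, stride 2x2 at the
first block of stages 2 and 3 and 2x1 at stage 4, SPP levels [1, 2, 4, 8]
(so the pooled vector has 2048 channels x 85 bins), and an 800-d embedding.
``desk``: the same topology shrunk for CPU-minute training -- 64x64 inputs,
widths 16/32/64/128, one block per stage, SPP levels [1, 2, 4], 32-d
embedding, and the non-square stride mapped to 2x2 (square desk inputs).

Everything is plain numpy with explicit forward/backward passes; given a
seed, construction and inference are strictly deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ArchitectureDescriptor",
    "EmbeddingBatch",
    "Backbone",
    "build_backbone",
    "spp_pool",
    "embed",
    "PRESETS",
]


@dataclass
class EmbeddingBatch:
    """L2-normalized embedding vectors with labels and pre-normalization
    row norms."""

    vectors: np.ndarray
    labels: np.ndarray
    norms: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.norms = np.asarray(self.norms, dtype=float)

    def __len__(self):
        return len(self.vectors)


@dataclass
class ArchitectureDescriptor:
    """Shapes of the embedding network; see module docstring for presets."""

    in_channels: int = 1
    input_size: int = 64
    conv1_filters: int = 16
    conv1_kernel: int = 7
    conv1_stride: Tuple[int, int] = (1, 1)
    pool_size: int = 2
    stage_widths: Sequence[int] = (16, 32, 64, 128)
    stage_depths: Sequence[int] = (1, 1, 1, 1)
    stage_strides: Sequence[Tuple[int, int]] = ((1, 1), (2, 2), (2, 2), (2, 2))
    spp_levels: Sequence[int] = (1, 2, 4)
    embed_dim: int = 32
    dtype: str = "float64"

    def __post_init__(self):
        if not (
            len(self.stage_widths) == len(self.stage_depths) == len(self.stage_strides)
        ):
            raise ValueError("stage widths, depths and strides must align")
        if self.embed_dim < 1 or self.conv1_filters < 1:
            raise ValueError("dimensions must be positive")
        if any(l < 1 for l in self.spp_levels):
            raise ValueError("SPP levels must be positive")
        self.stage_strides = [tuple(s) for s in self.stage_strides]
        self.conv1_stride = tuple(self.conv1_stride)

    @property
    def spp_bins(self) -> int:
        return int(sum(l * l for l in self.spp_levels))

    def to_json(self) -> str:
        d = dict(
            in_channels=self.in_channels,
            input_size=self.input_size,
            conv1_filters=self.conv1_filters,
            conv1_kernel=self.conv1_kernel,
            conv1_stride=list(self.conv1_stride),
            pool_size=self.pool_size,
            stage_widths=list(self.stage_widths),
            stage_depths=list(self.stage_depths),
            stage_strides=[list(s) for s in self.stage_strides],
            spp_levels=list(self.spp_levels),
            embed_dim=self.embed_dim,
            dtype=self.dtype,
        )
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureDescriptor":
        return cls(**json.loads(s))


PRESETS = {
    "desk": ArchitectureDescriptor(),
    "paper": ArchitectureDescriptor(
        in_channels=1,
        input_size=2048,
        conv1_filters=128,
        conv1_kernel=7,
        conv1_stride=(1, 1),
        pool_size=2,
        stage_widths=(256, 512, 1024, 2048),
        stage_depths=(3, 4, 6, 3),
        stage_strides=((1, 1), (2, 2), (2, 2), (2, 1)),
        spp_levels=(1, 2, 4, 8),
        embed_dim=800,
        dtype="float32",
    ),
}


# ---------------------------------------------------------------------------
# layers


def _im2col(x, kh, kw, sh, sw, ph, pw):
    N, C, H, W = x.shape
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
    return cols.reshape(N, C * kh * kw, Ho * Wo), (Ho, Wo)


def _col2im(gcols, x_shape, kh, kw, sh, sw, ph, pw, Ho, Wo):
    N, C, H, W = x_shape
    gxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=gcols.dtype)
    g6 = gcols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += g6[:, :, i, j]
    return gxp[:, :, ph : ph + H, pw : pw + W]


class Conv2d:
    def __init__(self, cin, cout, kernel, stride, rng, dtype):
        kh = kw = kernel
        fan_in = cin * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.W = (std * rng.standard_normal((cout, cin, kh, kw))).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.stride = tuple(stride)
        self.pad = (kh // 2, kw // 2)
        self.gW = None
        self.gb = None
        self._cache = None

    def forward(self, x, train=False):
        cout, cin, kh, kw = self.W.shape
        sh, sw = self.stride
        ph, pw = self.pad
        cols, (Ho, Wo) = _im2col(x, kh, kw, sh, sw, ph, pw)
        W2 = self.W.reshape(cout, -1)
        y = np.einsum("ok,nkp->nop", W2, cols) + self.b[None, :, None]
        if train:
            self._cache = (cols, x.shape, Ho, Wo)
        return y.reshape(x.shape[0], cout, Ho, Wo)

    def backward(self, gy):
        cols, x_shape, Ho, Wo = self._cache
        cout, cin, kh, kw = self.W.shape
        sh, sw = self.stride
        ph, pw = self.pad
        g2 = gy.reshape(gy.shape[0], cout, -1)
        self.gW = np.einsum("nop,nkp->ok", g2, cols).reshape(self.W.shape)
        self.gb = g2.sum(axis=(0, 2))
        gcols = np.einsum("ok,nop->nkp", self.W.reshape(cout, -1), g2)
        self._cache = None
        return _col2im(gcols, x_shape, kh, kw, sh, sw, ph, pw, Ho, Wo)

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy):
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2d:
    """Non-overlapping square max pool; odd trailing rows/cols are cropped."""

    def __init__(self, size=2):
        self.size = size
        self._cache = None

    def forward(self, x, train=False):
        s = self.size
        N, C, H, W = x.shape
        Ho, Wo = H // s, W // s
        xc = x[:, :, : Ho * s, : Wo * s]
        win = xc.reshape(N, C, Ho, s, Wo, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, Ho, Wo, s * s
        )
        idx = win.argmax(axis=-1)
        if train:
            self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        x_shape, idx = self._cache
        s = self.size
        N, C, H, W = x_shape
        Ho, Wo = H // s, W // s
        gwin = np.zeros((N, C, Ho, Wo, s * s), dtype=gy.dtype)
        np.put_along_axis(gwin, idx[..., None], gy[..., None], axis=-1)
        gx = np.zeros(x_shape, dtype=gy.dtype)
        gx[:, :, : Ho * s, : Wo * s] = (
            gwin.reshape(N, C, Ho, Wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
                N, C, Ho * s, Wo * s
            )
        )
        self._cache = None
        return gx


def _bin_edges(n: int, levels: int) -> np.ndarray:
    """Half-open adaptive partition: edge i = floor(i * n / levels)."""
    return (np.arange(levels + 1) * n) // levels


class SPP:
    """Spatial pyramid pooling: per level l, max over each of the l x l
    adaptive cells, concatenated level by level (cells row-major, channels
    fastest varying within a cell block)."""

    def __init__(self, levels):
        self.levels = list(levels)
        self._cache = None

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        if H < max(self.levels) or W < max(self.levels):
            raise ValueError("feature map smaller than the largest SPP level")
        outs = []
        cells = []
        for l in self.levels:
            re, ce = _bin_edges(H, l), _bin_edges(W, l)
            for bi in range(l):
                for bj in range(l):
                    r0, r1, c0, c1 = re[bi], re[bi + 1], ce[bj], ce[bj + 1]
                    region = x[:, :, r0:r1, c0:c1].reshape(N, C, -1)
                    amax = region.argmax(axis=-1)
                    outs.append(np.take_along_axis(region, amax[..., None], -1)[..., 0])
                    cells.append((r0, r1, c0, c1, amax))
        if train:
            self._cache = (x.shape, cells)
        return np.concatenate(outs, axis=1)  # (N, C * total_bins)

    def backward(self, gy):
        x_shape, cells = self._cache
        N, C = x_shape[0], x_shape[1]
        gx = np.zeros(x_shape, dtype=gy.dtype)
        for k, (r0, r1, c0, c1, amax) in enumerate(cells):
            g = gy[:, k * C : (k + 1) * C]
            region = np.zeros((N, C, (r1 - r0) * (c1 - c0)), dtype=gy.dtype)
            np.put_along_axis(region, amax[..., None], g[..., None], axis=-1)
            gx[:, :, r0:r1, c0:c1] += region.reshape(N, C, r1 - r0, c1 - c0)
        self._cache = None
        return gx


class Linear:
    def __init__(self, din, dout, rng, dtype):
        std = np.sqrt(2.0 / din)
        self.W = (std * rng.standard_normal((dout, din))).astype(dtype)
        self.b = np.zeros(dout, dtype=dtype)
        self.gW = None
        self.gb = None
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy):
        self.gW = gy.T @ self._x
        self.gb = gy.sum(axis=0)
        self._x = None
        return gy @ self.W


class L2Norm:
    """Row-wise projection onto the unit sphere."""

    eps = 1e-12

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n = np.maximum(np.sqrt(np.sum(x**2, axis=1)), self.eps)
        y = x / n[:, None]
        if train:
            self._cache = (y, n)
        return y, n

    def backward(self, gy):
        y, n = self._cache
        self._cache = None
        return (gy - y * np.sum(y * gy, axis=1)[:, None]) / n[:, None]


class Bottleneck:
    """1x1 -> 3x3 (strided) -> 1x1 conv stack with ReLU after every conv and
    a projection shortcut when shape changes."""

    def __init__(self, cin, cout, stride, rng, dtype):
        mid = max(cout // 4, 4)
        self.conv1 = Conv2d(cin, mid, 1, (1, 1), rng, dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid, mid, 3, stride, rng, dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid, cout, 1, (1, 1), rng, dtype)
        self.relu3 = ReLU()
        self.proj = (
            Conv2d(cin, cout, 1, stride, rng, dtype)
            if (cin != cout or tuple(stride) != (1, 1))
            else None
        )

    def forward(self, x, train=False):
        y = self.relu1.forward(self.conv1.forward(x, train), train)
        y = self.relu2.forward(self.conv2.forward(y, train), train)
        y = self.conv3.forward(y, train)
        sc = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu3.forward(y + sc, train)

    def backward(self, gy):
        g = self.relu3.backward(gy)
        gsc = self.proj.backward(g) if self.proj is not None else g
        gm = self.conv3.backward(g)
        gm = self.relu2.backward(gm)
        gm = self.conv2.backward(gm)
        gm = self.relu1.backward(gm)
        gm = self.conv1.backward(gm)
        return gm + gsc

    def convs(self):
        out = [self.conv1, self.conv2, self.conv3]
        if self.proj is not None:
            out.append(self.proj)
        return out


# ---------------------------------------------------------------------------
# network


class Backbone:
    """The embedding network: parameters plus descriptor.

    Acts as the trainable feature extractor of the alternating optimizer:
    ``forward`` caches activations, ``backward`` accumulates gradients from
    the loss gradient on the embeddings, and ``sgd_step`` applies momentum
    SGD.
    """

    trainable = True

    def __init__(self, descriptor: ArchitectureDescriptor, seed: int = 0):
        self.descriptor = descriptor
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        dt = np.dtype(descriptor.dtype)
        self.conv1 = Conv2d(
            descriptor.in_channels,
            descriptor.conv1_filters,
            descriptor.conv1_kernel,
            descriptor.conv1_stride,
            rng,
            dt,
        )
        self.relu1 = ReLU()
        self.pool = MaxPool2d(descriptor.pool_size)
        self.blocks: List[Bottleneck] = []
        cin = descriptor.conv1_filters
        for width, depth, stride in zip(
            descriptor.stage_widths, descriptor.stage_depths, descriptor.stage_strides
        ):
            for b in range(depth):
                self.blocks.append(
                    Bottleneck(cin, width, stride if b == 0 else (1, 1), rng, dt)
                )
                cin = width
        self.spp = SPP(descriptor.spp_levels)
        self.fc = Linear(cin * descriptor.spp_bins, descriptor.embed_dim, rng, dt)
        self.l2 = L2Norm()
        self._velocity = {}
        self.last_conv_map: Optional[np.ndarray] = None
        self._last_norms: Optional[np.ndarray] = None

    # -- forward / backward -------------------------------------------------
    def _prepare(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=self.descriptor.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != self.descriptor.in_channels:
            raise ValueError("expected a batch of single-channel images")
        return x

    def forward(self, images, train=True) -> np.ndarray:
        x = self._prepare(images)
        x = self.relu1.forward(self.conv1.forward(x, train), train)
        x = self.pool.forward(x, train)
        for blk in self.blocks:
            x = blk.forward(x, train)
        self.last_conv_map = x
        x = self.spp.forward(x, train)
        x = self.fc.forward(x, train)
        y, n = self.l2.forward(x, train)
        self._last_norms = n
        return y

    def backward(self, grad_embeddings) -> None:
        g = self.l2.backward(np.asarray(grad_embeddings, dtype=self.descriptor.dtype))
        g = self.fc.backward(g)
        g = self.spp.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        g = self.pool.backward(g)
        g = self.relu1.backward(g)
        self.conv1.backward(g)

    def embed(self, images) -> np.ndarray:
        """Inference-mode embedding (no activation caching)."""
        return self.forward(images, train=False)

    def embed_batchwise(self, images, labels=None, chunk: int = 32) -> EmbeddingBatch:
        x = self._prepare(images)
        outs, norms = [], []
        for i in range(0, len(x), chunk):
            outs.append(self.forward(x[i : i + chunk], train=False))
            norms.append(self._last_norms)
        vectors = np.concatenate(outs) if outs else np.empty((0, self.descriptor.embed_dim))
        nn = np.concatenate(norms) if norms else np.empty(0)
        if labels is None:
            labels = np.zeros(len(vectors), dtype=int)
        return EmbeddingBatch(vectors=vectors, labels=labels, norms=nn)

    # -- optimization -------------------------------------------------------
    def _layers_with_params(self):
        layers = [self.conv1]
        for blk in self.blocks:
            layers.extend(blk.convs())
        layers.append(self.fc)
        return layers

    def parameters(self):
        out = []
        for i, layer in enumerate(self._layers_with_params()):
            out.append((f"layer{i}.W", layer.W))
            out.append((f"layer{i}.b", layer.b))
        return out

    def sgd_step(self, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        for i, layer in enumerate(self._layers_with_params()):
            for pname in ("W", "b"):
                g = getattr(layer, "g" + pname)
                if g is None:
                    continue
                p = getattr(layer, pname)
                if weight_decay and pname == "W":
                    g = g + weight_decay * p
                key = (i, pname)
                v = self._velocity.get(key)
                v = momentum * v - lr * g if v is not None else -lr * g
                self._velocity[key] = v
                setattr(layer, pname, p + v.astype(p.dtype))
                setattr(layer, "g" + pname, None)

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> dict:
        arrays = {}
        for name, arr in self.parameters():
            arrays[name] = arr
        return arrays

    def save(self, path) -> None:
        np.savez(
            path,
            __descriptor__=np.frombuffer(
                self.descriptor.to_json().encode(), dtype=np.uint8
            ),
            __seed__=np.array([self.seed]),
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path) -> "Backbone":
        with np.load(path) as data:
            desc = ArchitectureDescriptor.from_json(
                bytes(data["__descriptor__"]).decode()
            )
            net = cls(desc, seed=int(data["__seed__"][0]))
            for i, layer in enumerate(net._layers_with_params()):
                layer.W = data[f"layer{i}.W"]
                layer.b = data[f"layer{i}.b"]
        return net


def build_backbone(config, seed: int = 0) -> Backbone:
    """Construct a seeded backbone from a preset name or a descriptor."""
    if isinstance(config, str):
        if config not in PRESETS:
            raise ValueError(f"unknown preset {config!r}; have {sorted(PRESETS)}")
        config = PRESETS[config]
    if not isinstance(config, ArchitectureDescriptor):
        raise ValueError("config must be a preset name or ArchitectureDescriptor")
    return Backbone(config, seed=seed)


def spp_pool(feature_map, levels) -> np.ndarray:
    """Spatial pyramid pooling of one C x H x W map: per level l, max-pool
    each of the l x l adaptive half-open cells per channel and concatenate.
    Output length is C * sum(l^2), independent of H and W."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError("feature_map must be C x H x W")
    levels = list(levels)
    if not levels or any(l < 1 for l in levels):
        raise ValueError("levels must be positive integers")
    C, H, W = fm.shape
    if H < max(levels) or W < max(levels):
        raise ValueError("feature map smaller than the largest pyramid level")
    return SPP(levels).forward(fm[None])[0]


def embed(images, params: Backbone, labels=None) -> EmbeddingBatch:
    """Embed a batch of preprocessed images: conv stages -> SPP -> FC ->
    L2 normalization.  Rows of the result have unit norm."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None]
    # Any input size is accepted as long as the final conv map is at least
    # max(spp_levels) on each side (SPP yields a fixed-length vector); too
    # small an input raises from the SPP layer.
    return params.embed_batchwise(x, labels=labels)
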