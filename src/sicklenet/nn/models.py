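"""The two pipeline networks: an encoder-decoder segmenter and a small
GAP-headed CNN classifier.

Both are written against the layer vocabulary in :mod:`sicklenet.nn.layers`
and expose ``forward``/``backward``/``params`` plus npz save/load. The
segmenter mirrors the U-Net family: per stage one 3x3 convolution + batch
normalization + ReLU, 2x2 max-pool downsampling, nearest-neighbor
upsampling, and copy-and-concatenate skip connections from encoder to
decoder; the final layer is a per-pixel 3-class softmax. The classifier
stacks three convolution stages, global-average-pools the last feature map
and feeds a 3-way softmax head — the structure the class-activation-map
analysis requires.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import layers
from .layers import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Param,
    global_avg_pool,
    global_avg_pool_backward,
    maxpool2,
    maxpool2_backward,
    relu,
    relu_backward,
    softmax,
    softmax_backward,
    upsample2,
    upsample2_backward,
)

N_CLASSES = 3


class _Net:
    """Shared parameter bookkeeping and npz persistence."""

    config: dict

    @property
    def params(self) -> list[Param]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def _bn_layers(self) -> list[BatchNorm2D]:
        return []

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "_Net":
        path = Path(path)
        config = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        net = cls(**config)
        with np.load(path) as data:
            for i, p in enumerate(net.params):
                p.data[...] = data[f"p{i}"]
            for i, bn in enumerate(net._bn_layers()):
                bn.running_mean[...] = data[f"rm{i}"]
                bn.running_var[...] = data[f"rv{i}"]
        return net


class SegNet(_Net):
    """Encoder-decoder semantic segmenter with skip connections.

    Parameters
    ----------
    depth:
        Number of down/up-sampling stages; input height/width must be
        divisible by ``2**depth``.
    base_filters:
        Filter count of the first stage; stage ``i`` uses
        ``base_filters * 2**i``.
    use_batchnorm, use_skip_connections:
        Architecture switches; both on by default.
    seed:
        Weight-initialization seed.
    """

    def __init__(self, depth: int = 2, base_filters: int = 8,
                 use_batchnorm: bool = True, use_skip_connections: bool = True,
                 seed: int = 0) -> None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.config = dict(depth=depth, base_filters=base_filters,
                           use_batchnorm=use_batchnorm,
                           use_skip_connections=use_skip_connections, seed=seed)
        self.depth = depth
        self.use_bn = use_batchnorm
        self.use_skip = use_skip_connections
        rng = np.random.default_rng(seed)

        self.enc_convs: list[Conv2D] = []
        self.enc_bns: list[BatchNorm2D | None] = []
        cin = 3
        widths = [base_filters * 2 ** i for i in range(depth)]
        for i, f in enumerate(widths):
            self.enc_convs.append(Conv2D(cin, f, 3, rng, f"enc{i}"))
            self.enc_bns.append(BatchNorm2D(f, name=f"enc{i}.bn") if use_batchnorm else None)
            cin = f
        fb = base_filters * 2 ** depth
        self.bott_conv = Conv2D(cin, fb, 3, rng, "bott")
        self.bott_bn = BatchNorm2D(fb, name="bott.bn") if use_batchnorm else None
        self.dec_convs: list[Conv2D] = []
        self.dec_bns: list[BatchNorm2D | None] = []
        cin = fb
        for i in reversed(range(depth)):
            f = widths[i]
            in_ch = cin + (f if use_skip_connections else 0)
            self.dec_convs.append(Conv2D(in_ch, f, 3, rng, f"dec{i}"))
            self.dec_bns.append(BatchNorm2D(f, name=f"dec{i}.bn") if use_batchnorm else None)
            cin = f
        self.head = Conv2D(cin, N_CLASSES, 1, rng, "head")
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            out += conv.params + (bn.params if bn else [])
        out += self.bott_conv.params + (self.bott_bn.params if self.bott_bn else [])
        for conv, bn in zip(self.dec_convs, self.dec_bns):
            out += conv.params + (bn.params if bn else [])
        out += self.head.params
        return out

    def _bn_layers(self) -> list[BatchNorm2D]:
        bns = [b for b in self.enc_bns if b] + ([self.bott_bn] if self.bott_bn else [])
        return bns + [b for b in self.dec_bns if b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 3) image batch -> (N, H, W, 3) per-pixel softmax."""
        x = np.ascontiguousarray(x, dtype=layers.DTYPE)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) input, got {x.shape}")
        if x.shape[1] % 2 ** self.depth or x.shape[2] % 2 ** self.depth:
            raise ValueError("spatial dimensions must be divisible by "
                             f"{2 ** self.depth}")
        cache: dict = {"skips": [], "pools": [], "pre_relu": []}
        h = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = conv.forward(h)
            if bn:
                h = bn.forward(h, train)
            cache["pre_relu"].append(h)
            h = relu(h)
            cache["skips"].append(h)
            h, pc = maxpool2(h)
            cache["pools"].append(pc)
        h = self.bott_conv.forward(h)
        if self.bott_bn:
            h = self.bott_bn.forward(h, train)
        cache["bott_pre"] = h
        h = relu(h)
        cache["dec_pre"] = []
        cache["skip_widths"] = []
        for j, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            h = upsample2(h)
            if self.use_skip:
                skip = cache["skips"][self.depth - 1 - j]
                cache["skip_widths"].append((h.shape[-1], skip.shape[-1]))
                h = np.concatenate([h, skip], axis=-1)
            h = conv.forward(h)
            if bn:
                h = bn.forward(h, train)
            cache["dec_pre"].append(h)
            h = relu(h)
        z = self.head.forward(h)
        q = softmax(z)
        cache["q"] = q
        self._cache = cache
        return q

    def backward(self, dq: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dq of the last forward."""
        cache = self._cache
        d = softmax_backward(dq.astype(layers.DTYPE), cache["q"])
        d = self.head.backward(d)
        skip_grads: list[np.ndarray | None] = [None] * self.depth
        for j in reversed(range(len(self.dec_convs))):
            conv, bn = self.dec_convs[j], self.dec_bns[j]
            d = relu_backward(d, cache["dec_pre"][j])
            if bn:
                d = bn.backward(d)
            d = conv.backward(d)
            if self.use_skip:
                up_w, _ = cache["skip_widths"][j]
                skip_grads[self.depth - 1 - j] = d[..., up_w:]
                d = d[..., :up_w]
            d = upsample2_backward(d)
        d = relu_backward(d, cache["bott_pre"])
        if self.bott_bn:
            d = self.bott_bn.backward(d)
        d = self.bott_conv.backward(d)
        for i in reversed(range(self.depth)):
            d = maxpool2_backward(d, cache["pools"][i])
            if skip_grads[i] is not None:
                d = d + skip_grads[i]
            d = relu_backward(d, cache["pre_relu"][i])
            if self.enc_bns[i]:
                d = self.enc_bns[i].backward(d)
            d = self.enc_convs[i].backward(d)


class SmallCNN(_Net):
    """Three-stage CNN with global-average-pool + fully-connected softmax head.

    Operates natively on 32x32x3 crops. The last convolutional feature map
    (8x8xK) together with the head weight matrix (3xK) is exactly what the
    class-activation-map computation consumes.
    """

    def __init__(self, base_filters: int = 8, use_batchnorm: bool = True,
                 seed: int = 0) -> None:
        self.config = dict(base_filters=base_filters,
                           use_batchnorm=use_batchnorm, seed=seed)
        rng = np.random.default_rng(seed)
        f = base_filters
        self.widths = [f, 2 * f, 4 * f]
        self.convs = [Conv2D(3, f, 3, rng, "c0"),
                      Conv2D(f, 2 * f, 3, rng, "c1"),
                      Conv2D(2 * f, 4 * f, 3, rng, "c2")]
        self.bns = [BatchNorm2D(w, name=f"c{i}.bn") if use_batchnorm else None
                    for i, w in enumerate(self.widths)]
        self.fc = Dense(4 * f, N_CLASSES, rng, "fc")
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for conv, bn in zip(self.convs, self.bns):
            out += conv.params + (bn.params if bn else [])
        return out + self.fc.params

    def _bn_layers(self) -> list[BatchNorm2D]:
        return [b for b in self.bns if b]

    @property
    def head_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(w, b): w is (3, K) class-by-channel, b length-3 bias."""
        return self.fc.W.data.T.copy(), self.fc.b.data.copy()

    def forward(self, x: np.ndarray, train: bool = False,
                return_features: bool = False):
        x = np.ascontiguousarray(x, dtype=layers.DTYPE)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) input, got {x.shape}")
        cache: dict = {"pre_relu": [], "pools": []}
        h = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            h = conv.forward(h)
            if bn:
                h = bn.forward(h, train)
            cache["pre_relu"].append(h)
            h = relu(h)
            if i < 2:
                h, pc = maxpool2(h)
                cache["pools"].append(pc)
        feats = h
        cache["spatial"] = feats.shape[1:3]
        v = global_avg_pool(feats)
        z = self.fc.forward(v)
        q = softmax(z)
        cache["q"] = q
        self._cache = cache
        if return_features:
            return q, feats
        return q

    def backward(self, dq: np.ndarray) -> None:
        cache = self._cache
        d = softmax_backward(dq.astype(layers.DTYPE), cache["q"])
        d = self.fc.backward(d)
        d = global_avg_pool_backward(d, cache["spatial"])
        for i in reversed(range(3)):
            if i < 2:
                d = maxpool2_backward(d, cache["pools"][i])
            d = relu_backward(d, cache["pre_relu"][i])
            if self.bns[i]:
                d = self.bns[i].backward(d)
            d = self.convs[i].backward(d)
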