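"""Multi-stream encoder-decoder segmentation network.

A 2D U-Net with a fixed depth of five downsampling blocks (four 2x2 max
poolings in between) and four upsampling blocks. Each block is two 3x3
convolutions, each followed by batch normalization and ReLU. For multimodal
inputs (``n_modalities`` > 1) each modality gets its own encoder stream and
the per-level features of all streams are concatenated before entering the
decoder and the skip connections, so the fused feature width at level l is
``n_modalities`` times the single-stream width. The decoder upsamples
bilinearly, concatenates the fused skip features, and ends in a 1x1
convolution to two channels (background/foreground) with a softmax.

Spatial input sizes must be divisible by 16 (four pooling halvings).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .layers import (BatchNorm2d, BilinearUp2, Conv2d, MaxPool2, ReLU,
                     Softmax)

DEPTH = 5          # encoder blocks
N_POOL = 4         # pooling operations -> divisibility by 16
N_CLASSES = 2


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters.

    ``base_channels`` is the feature width of the first encoder block; the
    width doubles at every level. Depth is fixed (5 down / 4 up blocks).
    """

    n_modalities: int = 1
    base_channels: int = 32

    def __post_init__(self):
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def level_widths(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** i for i in range(DEPTH))


def check_spatial_shape(shape) -> None:
    h, w = shape[-2], shape[-1]
    if h % 16 or w % 16:
        raise ValueError(
            f"spatial shape {(h, w)} must be divisible by 16 "
            f"(four pooling halvings)")


class ConvBlock:
    """(Conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.layers = [Conv2d(cin, cout, 3, rng, dtype), BatchNorm2d(cout, dtype=dtype),
                       ReLU(),
                       Conv2d(cout, cout, 3, rng, dtype), BatchNorm2d(cout, dtype=dtype),
                       ReLU()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, d):
        for lay in reversed(self.layers):
            d = lay.backward(d)
        return d

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def buffers(self):
        return [b for lay in self.layers for b in lay.buffers()]


class MultiStreamUNet:
    """The segmentation network; see module docstring.

    ``forward`` returns per-pixel class probabilities (B, 2, H, W);
    ``backward`` consumes dL/dprobabilities and fills parameter gradients.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        m, widths = spec.n_modalities, spec.level_widths
        self.enc = []    # [stream][level] -> ConvBlock
        self.pools = []  # [stream][level 0..3] -> MaxPool2
        for _ in range(m):
            blocks, pools = [], []
            cin = 1
            for lvl in range(DEPTH):
                blocks.append(ConvBlock(cin, widths[lvl], rng, dtype))
                cin = widths[lvl]
                if lvl < N_POOL:
                    pools.append(MaxPool2())
            self.enc.append(blocks)
            self.pools.append(pools)
        self.ups = [BilinearUp2() for _ in range(N_POOL)]
        self.dec = []
        d_ch = m * widths[-1]
        for lvl in (3, 2, 1, 0):
            self.dec.append(ConvBlock(d_ch + m * widths[lvl], widths[lvl],
                                      rng, dtype))
            d_ch = widths[lvl]
        self.head = Conv2d(widths[0], N_CLASSES, 1, rng, dtype)
        self.softmax = Softmax()
        self._fused_channels = None

    # ---- parameter plumbing -------------------------------------------
    def params(self):
        out = []
        for blocks in self.enc:
            for b in blocks:
                out.extend(b.params())
        for b in self.dec:
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    def buffers(self):
        out = []
        for blocks in self.enc:
            for b in blocks:
                out.extend(b.buffers())
        for b in self.dec:
            out.extend(b.buffers())
        return out

    def param_count(self) -> int:
        return sum(w.size for w, _ in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": w for i, (w, _) in enumerate(self.params())}
        state.update({f"b{i}": b for i, b in enumerate(self.buffers())})
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, (w, _) in enumerate(self.params()):
            w[...] = state[f"p{i}"]
        for i, b in enumerate(self.buffers()):
            b[...] = state[f"b{i}"]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for w, _ in self.params():
            h.update(np.ascontiguousarray(w).tobytes())
        for b in self.buffers():
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("input must be (batch, channels, H, W)")
        m = self.spec.n_modalities
        if x.shape[1] != m:
            raise ValueError(f"expected {m} input channels, got {x.shape[1]}")
        check_spatial_shape(x.shape)
        feats = []  # [stream][level]
        for s in range(m):
            f = x[:, s:s + 1]
            per_level = []
            for lvl in range(DEPTH):
                f = self.enc[s][lvl].forward(f, train)
                per_level.append(f)
                if lvl < N_POOL:
                    f = self.pools[s][lvl].forward(f, train)
            feats.append(per_level)
        fused = [np.concatenate([feats[s][lvl] for s in range(m)], axis=1)
                 for lvl in range(DEPTH)]
        self._fused_channels = [feats[0][lvl].shape[1] for lvl in range(DEPTH)]
        d = fused[-1]
        self._dec_in_channels = []
        for i, lvl in enumerate((3, 2, 1, 0)):
            u = self.ups[i].forward(d, train)
            self._dec_in_channels.append(u.shape[1])
            d = self.dec[i].forward(np.concatenate([u, fused[lvl]], axis=1),
                                    train)
        z = self.head.forward(d, train)
        return self.softmax.forward(z, train)

    def backward(self, dldp: np.ndarray) -> None:
        m = self.spec.n_modalities
        dz = self.softmax.backward(dldp)
        dd = self.head.backward(dz)
        dfused = [None] * DEPTH
        for i, lvl in zip((3, 2, 1, 0), (0, 1, 2, 3)):
            dcat = self.dec[i].backward(dd)
            cu = self._dec_in_channels[i]
            du, dskip = dcat[:, :cu], dcat[:, cu:]
            dfused[lvl] = dskip if dfused[lvl] is None else dfused[lvl] + dskip
            dd = self.ups[i].backward(du)
        dfused[DEPTH - 1] = dd if dfused[DEPTH - 1] is None \
            else dfused[DEPTH - 1] + dd
        w = self._fused_channels
        for s in range(m):
            dslice = [dfused[lvl][:, s * w[lvl]:(s + 1) * w[lvl]]
                      for lvl in range(DEPTH)]
            g = self.enc[s][DEPTH - 1].backward(dslice[DEPTH - 1])
            for lvl in range(N_POOL - 1, -1, -1):
                g = self.pools[s][lvl].backward(g) + dslice[lvl]
                g = self.enc[s][lvl].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities for a batch or single image."""
        single = (np.asarray(x).ndim == 3)
        xb = np.asarray(x)[None] if single else np.asarray(x)
        p = self.forward(xb, train=False)
        return p[0] if single else p


def build_model(spec: ModelSpec, rng, dtype=np.float32,
                input_shape=None) -> MultiStreamUNet:
    """Construct the network; deterministic given a seeded generator."""
    if input_shape is not None:
        check_spatial_shape(input_shape)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return MultiStreamUNet(spec, rng, dtype=dtype)


def predict(model: MultiStreamUNet, image: np.ndarray) -> np.ndarray:
    """Probability map (2, H, W) for one multi-channel image, eval mode."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("image must be (channels, H, W)")
    check_spatial_shape(image.shape)
    return model.predict_proba(image)
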