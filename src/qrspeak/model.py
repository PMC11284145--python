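"""The dual-input feature-pyramid QRS detection network.

The network maps a preprocessed two-channel signal of length ``l`` to
three per-sample QRS-probability heat maps of lengths ``l``, ``ceil(l/2)``
and ``ceil(l/4)`` (effective rates 250, 125 and 62.5 Hz).

Architecture (default configuration, 26,976 trainable parameters):

* stem: dense convolution k=19, 2 -> 32 channels, instance norm, relu;
* three encoder stages at 32, 64 and 128 channels, two residual blocks
  each; a residual block is one depthwise k=19 convolution + instance
  norm + relu inside an identity skip; stages are joined by k=1,
  stride-2 downsampling convolutions (which also adjust the channels),
  each with instance norm + relu;
* decoder (feature pyramid): k=1 lateral convolutions reduce each stage
  to a common width of 24 channels; the top-down pathway upsamples by
  nearest neighbour and adds; each merged map is smoothed by a depthwise
  k=19 convolution;
* location head, shared across the three scales: convolution k=5 to a
  single channel, sigmoid, and a stride-1 moving-average pool of width 9.

Convolutions followed by a normalization layer carry no bias (the norm
would cancel it); the lateral and smoothing convolutions are not
normalized and carry biases.  The head convolution is bias-free so that
an untrained head responds around 0.5.  With these conventions the
default parameter count is exactly 26,976; the count is validated in the
test suite and is independent of the input length.

The receptive field of the deepest head output is 391 samples at 250 Hz,
about 1.6 s - wide enough to cover the longest interval between normal
heartbeats, which is what makes a purely convolutional detector viable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .records import RecordError

MIN_INPUT_LEN = 32


@dataclass(frozen=True)
class ModelConfig:
    kernel_size: int = 19
    channels: tuple[int, int, int] = (32, 64, 128)
    head_kernel: int = 5
    pool_size: int = 9
    in_channels: int = 2
    depthwise: bool = True
    fpn_channels: int = 24
    blocks_per_stage: int = 2

    def validate(self) -> None:
        if self.kernel_size % 2 == 0 or self.head_kernel % 2 == 0:
            raise RecordError("kernel sizes must be odd")
        if self.pool_size % 2 == 0:
            raise RecordError("pool size must be odd")
        if not (len(self.channels) == 3 and
                self.channels[0] < self.channels[1] < self.channels[2]):
            raise RecordError("channels must be a strictly increasing triple")
        if self.in_channels not in (1, 2):
            raise RecordError("in_channels must be 1 or 2")
        if self.fpn_channels < 1 or self.blocks_per_stage < 1:
            raise RecordError("fpn_channels and blocks_per_stage must be >= 1")


#: Named configurations.  ``default`` reproduces the published detector;
#: ``desk`` is a reduced-width preset for CPU-bound experimentation with
#: the same topology; ``mwsk``/``mwlk``/``mwsc`` are the kernel-size and
#: single-channel variants.
PRESETS: dict[str, ModelConfig] = {
    "default": ModelConfig(),
    "desk": ModelConfig(channels=(8, 16, 32), fpn_channels=8),
    "mwsk": ModelConfig(kernel_size=9),
    "mwlk": ModelConfig(kernel_size=29),
    "mwsc": ModelConfig(in_channels=1),
}


class _ResBlock(nn.Layer):
    """y = relu(x + IN(dwconv(x))); channels are preserved."""

    def __init__(self, c, k, depthwise, rng, name):
        if depthwise:
            self.conv = nn.DepthwiseConv1d(c, k, bias=False, rng=rng, name=name)
        else:
            self.conv = nn.Conv1d(c, c, k, bias=False, rng=rng, name=name)
        self.norm = nn.InstanceNorm()
        self.relu = nn.ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        y = self.norm.forward(self.conv.forward(x))
        return self.relu.forward(x + y)

    def backward(self, gy):
        g = self.relu.backward(gy)
        gx = self.conv.backward(self.norm.backward(g))
        return g + gx


class _ConvNormRelu(nn.Layer):
    def __init__(self, cin, cout, k, stride, rng, name):
        self.conv = nn.Conv1d(cin, cout, k, stride=stride, bias=False,
                              rng=rng, name=name)
        self.norm = nn.InstanceNorm()
        self.relu = nn.ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.relu.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, gy):
        return self.conv.backward(self.norm.backward(self.relu.backward(gy)))


class QRSNet:
    """Fully convolutional QRS heat-map network (see module docstring)."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k, (c1, c2, c3), d = cfg.kernel_size, cfg.channels, cfg.fpn_channels

        self.stem = _ConvNormRelu(cfg.in_channels, c1, k, 1, rng, "stem")
        self.stage1 = [_ResBlock(c1, k, cfg.depthwise, rng, f"s1b{i}")
                       for i in range(cfg.blocks_per_stage)]
        self.down1 = _ConvNormRelu(c1, c2, 1, 2, rng, "down1")
        self.stage2 = [_ResBlock(c2, k, cfg.depthwise, rng, f"s2b{i}")
                       for i in range(cfg.blocks_per_stage)]
        self.down2 = _ConvNormRelu(c2, c3, 1, 2, rng, "down2")
        self.stage3 = [_ResBlock(c3, k, cfg.depthwise, rng, f"s3b{i}")
                       for i in range(cfg.blocks_per_stage)]
        self.lats = [nn.Conv1d(c, d, 1, bias=True, rng=rng, name=f"lat{i}")
                     for i, c in enumerate((c1, c2, c3))]
        self.smooths = [nn.DepthwiseConv1d(d, k, bias=True, rng=rng,
                                           name=f"smooth{i}")
                        for i in range(3)]
        self.head = nn.Conv1d(d, 1, cfg.head_kernel, bias=False, rng=rng,
                              name="head")
        self.sigmoids = [nn.Sigmoid() for _ in range(3)]
        self.pool = nn.BoxPool(cfg.pool_size)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        ps += self.stem.params()
        for blk in self.stage1 + self.stage2 + self.stage3:
            ps += blk.params()
        ps += self.down1.params() + self.down2.params()
        for lat in self.lats:
            ps += lat.params()
        for sm in self.smooths:
            ps += sm.params()
        ps += self.head.params()
        return ps

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Run the network on ``x`` of shape ``(batch, in_channels, l)``.

        Returns three heat maps of shapes ``(batch, l)``, ``(batch,
        ceil(l/2))`` and ``(batch, ceil(l/4))``, all values in [0, 1].
        Inputs whose length is not a multiple of 4 are zero-padded on the
        right internally and the outputs cropped back.
        """
        if x.ndim != 3 or x.shape[1] != self.cfg.in_channels:
            raise RecordError(
                f"expected (batch, {self.cfg.in_channels}, l) input, got {x.shape}"
            )
        L = x.shape[2]
        if L < MIN_INPUT_LEN:
            raise RecordError(f"input length {L} below minimum {MIN_INPUT_LEN}")
        pad = (-L) % 4
        self._true_lens = [L, -(-L // 2), -(-L // 4)]
        x = np.asarray(x, dtype=nn.DTYPE)
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))

        c1 = self.stem.forward(x)
        for blk in self.stage1:
            c1 = blk.forward(c1)
        c2 = self.down1.forward(c1)
        for blk in self.stage2:
            c2 = blk.forward(c2)
        c3 = self.down2.forward(c2)
        for blk in self.stage3:
            c3 = blk.forward(c3)

        p3 = self.lats[2].forward(c3)
        p2 = self.lats[1].forward(c2) + nn.upsample_nearest(p3, c2.shape[2])
        p1 = self.lats[0].forward(c1) + nn.upsample_nearest(p2, c1.shape[2])
        self._plens = [p1.shape[2], p2.shape[2], p3.shape[2]]

        maps = []
        for i, p in enumerate((p1, p2, p3)):
            h = self.smooths[i].forward(p)
            # shared head: remember each application's cache separately
            h = self._head_forward(i, h)
            h = self.sigmoids[i].forward(h)
            h = self.pool.forward(h)
            maps.append(h[:, 0, : self._true_lens[i]])
        return maps

    def _head_forward(self, i, h):
        # The head is weight-shared; keep one cache per scale for backward.
        if not hasattr(self, "_head_caches"):
            self._head_caches = [None, None, None]
        out = self.head.forward(h)
        self._head_caches[i] = (self.head._xp, self.head._L)
        return out

    def backward(self, grad_maps: list[np.ndarray]) -> None:
        """Accumulate parameter gradients given per-map loss gradients."""
        gps = []
        for i in range(3):
            g = np.zeros((grad_maps[i].shape[0], 1, self._plens[i]), dtype=nn.DTYPE)
            g[:, 0, : self._true_lens[i]] = grad_maps[i]
            g = self.pool.backward(g)
            g = self.sigmoids[i].backward(g)
            self.head._xp, self.head._L = self._head_caches[i]
            g = self.head.backward(g)
            g = self.smooths[i].backward(g)
            gps.append(g)

        gp1, gp2, gp3 = gps
        gc1 = self.lats[0].backward(gp1)
        gp2 = gp2 + nn.upsample_nearest_backward(gp1, self._plens[1])
        gc2 = self.lats[1].backward(gp2)
        gp3 = gp3 + nn.upsample_nearest_backward(gp2, self._plens[2])
        gc3 = self.lats[2].backward(gp3)

        for blk in reversed(self.stage3):
            gc3 = blk.backward(gc3)
        gc2 = gc2 + self.down2.backward(gc3)
        for blk in reversed(self.stage2):
            gc2 = blk.backward(gc2)
        gc1 = gc1 + self.down1.backward(gc2)
        for blk in reversed(self.stage1):
            gc1 = blk.backward(gc1)
        self.stem.backward(gc1)

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise RecordError(f"missing parameter in checkpoint: {p.name}")
            if state[p.name].shape != p.value.shape:
                raise RecordError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]


def build_model(cfg: ModelConfig | str = "default", seed: int = 0) -> QRSNet:
    """Construct a :class:`QRSNet` from a config or preset name."""
    if isinstance(cfg, str):
        try:
            cfg = PRESETS[cfg]
        except KeyError:
            raise RecordError(f"unknown preset: {cfg!r}") from None
    return QRSNet(cfg, seed=seed)


def count_parameters(model: QRSNet) -> int:
    """Number of trainable scalars in the model."""
    return sum(p.size for p in model.parameters())


def receptive_field_s(cfg: ModelConfig = ModelConfig(), fs: float = 250.0) -> float:
    """Analytic receptive field (seconds) of the deepest head output.

    ``RF = 1 + sum (k_i - 1) * jump_i`` along the longest path: stem and
    stage-1 blocks at jump 1, stage-2 blocks at jump 2, stage-3 blocks,
    smoothing, head and pool at jump 4.  The k=1 downsampling
    convolutions add nothing.
    """
    k, hk, ps = cfg.kernel_size, cfg.head_kernel, cfg.pool_size
    n = cfg.blocks_per_stage
    rf = 1
    rf += (k - 1) * 1              # stem
    rf += n * (k - 1) * 1          # stage 1
    rf += n * (k - 1) * 2          # stage 2
    rf += n * (k - 1) * 4          # stage 3
    rf += (k - 1) * 4              # smoothing on the deepest map
    rf += (hk - 1) * 4             # head
    rf += (ps - 1) * 4             # average pool
    return rf / fs


def flops_per_second(cfg: ModelConfig = ModelConfig(), fs: float = 250.0) -> float:
    """Approximate multiply-accumulates per second of input (diagnostic)."""
    k, (c1, c2, c3), d, n = (cfg.kernel_size, cfg.channels,
                             cfg.fpn_channels, cfg.blocks_per_stage)
    L = fs
    f = k * cfg.in_channels * c1 * L                      # stem
    for c, frac in ((c1, 1), (c2, 0.5), (c3, 0.25)):
        f += n * k * c * L * frac                         # depthwise blocks
    f += c1 * c2 * L / 2 + c2 * c3 * L / 4                # downsamples
    f += (c1 * d * L + c2 * d * L / 2 + c3 * d * L / 4)   # laterals
    f += k * d * (L + L / 2 + L / 4)                      # smoothing
    f += cfg.head_kernel * d * (L + L / 2 + L / 4)        # head
    return float(f)


def save_checkpoint(model: QRSNet, path) -> Path:
    """Serialize weights (npz) plus the config as JSON alongside."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.cfg), indent=2))
    return path


def load_checkpoint(path) -> QRSNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfgpath = path.with_suffix(".json")
    if cfgpath.exists():
        raw = json.loads(cfgpath.read_text())
        raw["channels"] = tuple(raw["channels"])
        cfg = ModelConfig(**raw)
    else:
        cfg = ModelConfig()
    model = QRSNet(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
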