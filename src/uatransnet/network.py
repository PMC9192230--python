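"""U-shaped encoder-decoder with attention bottleneck and multiscale skips.

The encoder stacks residual blocks (three 3x3 convolutions with GroupNorm
and an additive shortcut) and 2x2 max pooling, doubling the channel width
at each scale.  The bottleneck optionally applies the MGAM attention module
— which is the identity at initialization, so an attention model starts out
exactly equal to its attention-free twin.  The decoder reconstructs the
full-resolution probability map through one of two skip-fusion schemes:

* ``residual`` — each stage concatenates the encoder skip with the
  bilinearly upsampled previous decoder feature and passes it through a
  residual block (conv transform + additive shortcut).
* ``dense`` — each stage receives *all* previous decoder-stage outputs,
  upsampled to its resolution, concatenated with the encoder skip, so
  features are reused rather than relearned.

A 1-channel sigmoid head emits per-pixel tumor probability.  Upsampling is
bilinear with aligned corners throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .engine import Tensor, concat, max_pool2, upsample_bilinear
from .nn import Conv2d, GroupNorm, Linear, Module
from .mgam import MGAM

__all__ = ["NetworkConfig", "ResBlock", "CascadeFuse", "ResidualSkip",
           "DenseSkip", "SegmentationModel", "Classifier", "build_model",
           "build_classifier", "TEST_SCALE", "PAPER_SCALE"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs; widths double per scale from `base_width`."""

    depth: int = 3
    base_width: int = 8
    gn_groups: int = 8
    skip_mode: str = "residual"
    use_mgam: bool = True
    n_heads: int = 1
    image_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < self.gn_groups:
            raise ValueError("base_width must be >= gn_groups")
        if self.base_width % self.gn_groups:
            raise ValueError("base_width must be divisible by gn_groups")
        if self.skip_mode not in ("residual", "dense"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        h, w = self.image_size
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(f"image size {h}x{w} not divisible by 2^depth")


# reduced preset for CPU runs; larger preset sized near the reference
# 15-20M-parameter operating point
TEST_SCALE = NetworkConfig()
PAPER_SCALE = NetworkConfig(depth=4, base_width=36, gn_groups=4,
                            image_size=(256, 256))


class ResBlock(Module):
    """Three 3x3 conv + GroupNorm + ReLU stages with an additive shortcut."""

    def __init__(self, c_in: int, c_out: int, gn_groups: int, rng):
        if c_out % gn_groups:
            raise ValueError(f"channels {c_out} not divisible by {gn_groups} groups")
        self.convs = [Conv2d(c_in if i == 0 else c_out, c_out, 3, rng)
                      for i in range(3)]
        self.norms = [GroupNorm(c_out, gn_groups) for _ in range(3)]
        self.shortcut = None if c_in == c_out else Conv2d(c_in, c_out, 1, rng)

    def forward(self, x):
        y = x
        for conv, norm in zip(self.convs, self.norms):
            y = norm(conv(y)).relu()
        s = x if self.shortcut is None else self.shortcut(x)
        return y + s


class CascadeFuse(Module):
    """Upsample all scales to the finest, concatenate, mix with one conv."""

    def __init__(self, in_channels: list[int], c_out: int, gn_groups: int, rng):
        if len(in_channels) < 2:
            raise ValueError("cascade fusion needs at least two maps")
        self.mix = Conv2d(sum(in_channels), c_out, 3, rng)
        self.norm = GroupNorm(c_out, gn_groups)

    def forward(self, maps):
        if not maps:
            raise ValueError("no maps to fuse")
        target = max((m.shape[-2], m.shape[-1]) for m in maps)
        ups = [m if (m.shape[-2], m.shape[-1]) == target
               else upsample_bilinear(m, target) for m in maps]
        return self.norm(self.mix(concat(ups, axis=1))).relu()


class ResidualSkip(Module):
    """Decoder stage: conv transform of (skip ⊕ upsampled prev) + shortcut."""

    def __init__(self, skip_ch: int, prev_ch: int, c_out: int, gn_groups: int, rng):
        self.block = ResBlock(skip_ch + prev_ch, c_out, gn_groups, rng)

    def forward(self, skip, prev):
        up = upsample_bilinear(prev, (skip.shape[-2], skip.shape[-1]))
        return self.block(concat([skip, up], axis=1))


class DenseSkip(Module):
    """Decoder stage fed by all previous decoder outputs plus the skip."""

    def __init__(self, skip_ch: int, history_ch: list[int], c_out: int,
                 gn_groups: int, rng):
        if not history_ch:
            raise ValueError("dense stage needs a nonempty history")
        self.block = ResBlock(skip_ch + sum(history_ch), c_out, gn_groups, rng)

    def forward(self, skip, history):
        if not history:
            raise ValueError("dense stage needs a nonempty history")
        size = (skip.shape[-2], skip.shape[-1])
        ups = [upsample_bilinear(hm, size) for hm in history]
        return self.block(concat([skip] + ups, axis=1))


class SegmentationModel(Module):
    """Full network; forward maps (N,1,H,W) to probabilities of same shape."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        rng_backbone, rng_mgam = [np.random.default_rng(s) for s in ss.spawn(2)]
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth + 1)]
        self.encoder = []
        c_prev = 1
        for wd in widths[:-1]:
            self.encoder.append(ResBlock(c_prev, wd, cfg.gn_groups, rng_backbone))
            c_prev = wd
        self.bottleneck = ResBlock(c_prev, widths[-1], cfg.gn_groups, rng_backbone)
        h, w = cfg.image_size
        bh, bw = h // 2 ** cfg.depth, w // 2 ** cfg.depth
        self.mgam = (MGAM(widths[-1], (bh, bw), rng_mgam, cfg.n_heads)
                     if cfg.use_mgam else None)
        self.decoder = []
        if cfg.skip_mode == "residual":
            prev_ch = widths[-1]
            for i in reversed(range(cfg.depth)):
                self.decoder.append(ResidualSkip(widths[i], prev_ch, widths[i],
                                                 cfg.gn_groups, rng_backbone))
                prev_ch = widths[i]
        else:
            hist_ch = [widths[-1]]
            for i in reversed(range(cfg.depth)):
                self.decoder.append(DenseSkip(widths[i], list(hist_ch), widths[i],
                                              cfg.gn_groups, rng_backbone))
                hist_ch.append(widths[i])
        self.head = Conv2d(widths[0], 1, 1, rng_backbone)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        y = x
        for block in self.encoder:
            y = block(y)
            skips.append(y)
            y = max_pool2(y)
        y = self.bottleneck(y)
        if self.mgam is not None:
            y = self.mgam(y)
        if self.cfg.skip_mode == "residual":
            for stage, skip in zip(self.decoder, reversed(skips)):
                y = stage(skip, y)
        else:
            history = [y]
            for stage, skip in zip(self.decoder, reversed(skips)):
                y = stage(skip, history)
                history.append(y)
        return self.head(y).sigmoid()

    def predict(self, images: np.ndarray, batch: int = 8,
                threshold: float | None = None) -> np.ndarray:
        """Probability maps (or binary masks if `threshold` given) for a
        stack of (N,H,W) or (N,1,H,W) images; no gradients recorded."""
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        outs = []
        for i in range(0, len(arr), batch):
            outs.append(self.forward(Tensor(arr[i:i + batch])).data)
        probs = np.concatenate(outs, axis=0)[:, 0]
        return probs if threshold is None else (probs >= threshold).astype(np.uint8)


class Classifier(Module):
    """Res-Block stack + max pooling + fully connected sigmoid head.

    Emits one probability per image (e.g. effective vs difficult case).
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        widths = [cfg.base_width * 2 ** min(i, 3) for i in range(cfg.depth)]
        self.blocks = []
        c_prev = 1
        for wd in widths:
            self.blocks.append(ResBlock(c_prev, wd, cfg.gn_groups, rng))
            c_prev = wd
        self.fc = Linear(c_prev, 1, rng)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        y = x
        for block in self.blocks:
            y = max_pool2(block(y))
        y = y.mean(axis=(2, 3))            # global average pool -> (N, C)
        return self.fc(y).sigmoid()

    def predict(self, images: np.ndarray, batch: int = 16) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        outs = []
        for i in range(0, len(arr), batch):
            outs.append(self.forward(Tensor(arr[i:i + batch])).data)
        return np.concatenate(outs, axis=0)[:, 0]


def build_model(cfg: NetworkConfig = TEST_SCALE, seed: int = 0) -> SegmentationModel:
    """Construct the segmentation network and log its parameter count."""
    model = SegmentationModel(cfg, seed)
    import logging
    logging.getLogger(__name__).info(
        "built model %s: %d parameters", asdict(cfg), model.n_parameters())
    return model


def build_classifier(cfg: NetworkConfig = TEST_SCALE, seed: int = 0) -> Classifier:
    return Classifier(cfg, seed)
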