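"""Staged residual backbone with group normalization and SPM insertion.

The trunk is a bottleneck ResNet whose per-stage blocks are reordered into
Start / Middle / End phases.  The Start block drops the activation after the
residual addition, so negative signals survive on the identity path — a
guard against information loss when training on very small datasets.  Middle
blocks use pre-activation ordering, with the first normalization of the
first Middle block in a stage elided (the Start block's output is already
un-activated raw sum).  The End block appends a final normalization and
activation so each stage hands on a normalized, activated signal.  This
reordering leaves the parameter count identical to the plain ordering.

All normalization is group normalization, whose statistics are per-sample
and therefore independent of batch size — the property that makes training
at batch sizes of a few images viable.  When ``spm_insertion`` is enabled, a
strip-pooling attention block follows every bottleneck whose 3×3 convolution
runs at 512 (×width) channels, i.e. every block of the final stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .grad import Conv2d, GroupNorm, Module, ReLU, Sequential, Tensor, maxpool2d_3x3s2
from .pooling import StripPoolingModule

_BLOCKS = {"toy": (1, 1, 1, 1), 50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}
_MID_WIDTHS = (64, 128, 256, 512)
_OUT_WIDTHS = (256, 512, 1024, 2048)
#: per-stage (stride, dilation) for each supported output stride; the stem
#: contributes a fixed stride of 4.
_STAGE_GEOMETRY = {
    32: ((1, 1), (2, 1), (2, 1), (2, 1)),
    16: ((1, 1), (1, 1), (4, 1), (1, 2)),
    8: ((1, 1), (1, 1), (2, 2), (1, 2)),
}


@dataclass
class BackboneConfig:
    depth: int | str = 101
    gn_groups: int = 32
    width_multiplier: float = 1.0
    output_stride: int = 16
    spm_insertion: bool = True
    block_style: str = "staged"          # "staged" (IResNet ordering) or "plain"
    spm_gate: str = "sigmoid"
    spm_fusion: str = "sum"
    blocks_per_stage: tuple | None = None  # overrides the depth preset

    def __post_init__(self):
        if self.depth not in _BLOCKS:
            raise ValueError(f"depth must be one of {sorted(map(str, _BLOCKS))}, got {self.depth}")
        if self.output_stride not in _STAGE_GEOMETRY:
            raise ValueError(f"output_stride must be 8, 16 or 32, got {self.output_stride}")
        if self.block_style not in ("staged", "plain"):
            raise ValueError(f"block_style must be 'staged' or 'plain', got {self.block_style}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def stage_blocks(self) -> tuple:
        return tuple(self.blocks_per_stage) if self.blocks_per_stage else _BLOCKS[self.depth]

    def width(self, base: int) -> int:
        return max(int(round(base * self.width_multiplier)), 1)


def toy_backbone_config(**overrides) -> BackboneConfig:
    """Desk-scale trunk: one block per stage at one-eighth width."""
    cfg = dict(depth="toy", width_multiplier=0.125, gn_groups=8)
    cfg.update(overrides)
    return BackboneConfig(**cfg)


class BackboneFeatures(NamedTuple):
    layer1: Tensor
    layer2: Tensor
    layer3: Tensor
    layer4: Tensor


class StartBlock(Module):
    """Bottleneck whose residual sum is *not* activated (identity path kept raw)."""

    def __init__(self, cin, mid, cout, stride, dilation, groups, rng):
        self.conv1 = Conv2d(cin, mid, 1, rng=rng)
        self.gn1 = GroupNorm(groups, mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, padding=dilation,
                            dilation=dilation, rng=rng)
        self.gn2 = GroupNorm(groups, mid)
        self.conv3 = Conv2d(mid, cout, 1, rng=rng)
        self.gn3 = GroupNorm(groups, cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, rng=rng)
            self.proj_gn = GroupNorm(groups, cout)
        else:
            self.proj = None

    def forward(self, x):
        y = self.gn1(self.conv1(x)).relu()
        y = self.gn2(self.conv2(y)).relu()
        y = self.gn3(self.conv3(y))
        s = self.proj_gn(self.proj(x)) if self.proj is not None else x
        return y + s


class PreActBlock(Module):
    """Pre-activation bottleneck (Middle phase); the End phase appends GN+ReLU."""

    def __init__(self, channels, mid, dilation, groups, rng,
                 drop_first_norm=False, trailing=False):
        from .grad import Identity
        self.gn1 = Identity() if drop_first_norm else GroupNorm(groups, channels)
        self.conv1 = Conv2d(channels, mid, 1, rng=rng)
        self.gn2 = GroupNorm(groups, mid)
        self.conv2 = Conv2d(mid, mid, 3, padding=dilation, dilation=dilation, rng=rng)
        self.gn3 = GroupNorm(groups, mid)
        self.conv3 = Conv2d(mid, channels, 1, rng=rng)
        self.trail = Sequential(GroupNorm(groups, channels), ReLU()) if trailing else None

    def forward(self, x):
        y = self.conv1(self.gn1(x).relu())
        y = self.conv2(self.gn2(y).relu())
        y = self.conv3(self.gn3(y).relu())
        out = x + y
        return self.trail(out) if self.trail is not None else out


class PlainBottleneck(Module):
    """Classic post-activation bottleneck: ReLU after the residual addition."""

    def __init__(self, cin, mid, cout, stride, dilation, groups, rng):
        self.body = StartBlock(cin, mid, cout, stride, dilation, groups, rng)

    def forward(self, x):
        return self.body(x).relu()


class _Stage(Module):
    def __init__(self, cin, mid, cout, n_blocks, stride, dilation, cfg: BackboneConfig,
                 with_spm: bool, rng):
        g = cfg.gn_groups
        units: list[Module] = []
        if cfg.block_style == "plain":
            units.append(PlainBottleneck(cin, mid, cout, stride, dilation, g, rng))
            if with_spm:
                units.append(self._spm(cout, cfg, rng))
            for _ in range(n_blocks - 1):
                units.append(PlainBottleneck(cout, mid, cout, 1, dilation, g, rng))
                if with_spm:
                    units.append(self._spm(cout, cfg, rng))
        else:
            units.append(StartBlock(cin, mid, cout, stride, dilation, g, rng))
            if with_spm:
                units.append(self._spm(cout, cfg, rng))
            if n_blocks == 1:
                units.append(ReLU())     # single-block stage: activate, params match plain
            else:
                for i in range(1, n_blocks):
                    units.append(PreActBlock(cout, mid, dilation, g, rng,
                                             drop_first_norm=(i == 1),
                                             trailing=(i == n_blocks - 1)))
                    if with_spm:
                        units.append(self._spm(cout, cfg, rng))
        self.units = units

    @staticmethod
    def _spm(channels, cfg: BackboneConfig, rng):
        return StripPoolingModule(channels, gn_groups=cfg.gn_groups,
                                  gate=cfg.spm_gate, fusion=cfg.spm_fusion, rng=rng)

    def forward(self, x):
        for u in self.units:
            x = u(x)
        return x


class IResNetBackbone(Module):
    """Four-stage trunk returning the per-stage feature maps.

    Under the default output stride of 16 the stage strides are 4, 4, 16, 16,
    so the decoder's two ×4 upsamplings (from the stage-4 features via the
    stage-2 skip) restore full resolution exactly.
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        w = config.width
        stem_ch = w(64)
        self.stem_conv = Conv2d(3, stem_ch, 7, stride=2, padding=3, rng=rng)
        self.stem_gn = GroupNorm(config.gn_groups, stem_ch)
        geometry = _STAGE_GEOMETRY[config.output_stride]
        blocks = config.stage_blocks()
        cin = stem_ch
        self.stages = []
        for i, (n, (stride, dil)) in enumerate(zip(blocks, geometry)):
            mid, cout = w(_MID_WIDTHS[i]), w(_OUT_WIDTHS[i])
            with_spm = config.spm_insertion and _MID_WIDTHS[i] == 512
            self.stages.append(_Stage(cin, mid, cout, n, stride, dil, config, with_spm, rng))
            cin = cout
        self.out_channels = tuple(w(c) for c in _OUT_WIDTHS)

    def forward(self, x) -> BackboneFeatures:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        b, c, h, wd = x.shape
        if h % 16 or wd % 16:
            raise ValueError(
                f"input spatial dims must be divisible by 16, got {h}×{wd}; "
                f"pad to {-(-h // 16) * 16}×{-(-wd // 16) * 16} first")
        y = maxpool2d_3x3s2(self.stem_gn(self.stem_conv(x)).relu())
        feats = []
        for stage in self.stages:
            y = stage(y)
            feats.append(y)
        return BackboneFeatures(*feats)


def count_parameters(model_or_config) -> int:
    """Exact count of trainable scalars."""
    if isinstance(model_or_config, Module):
        return model_or_config.parameter_count()
    return IResNetBackbone(model_or_config, np.random.default_rng(0)).parameter_count()
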