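"""The full encoder-decoder segmentation network.

The encoder is the staged residual trunk; its final-stage features feed two
parallel attention branches — a strip-pooling module and a mixed pooling
module, each behind its own 1×1 channel reduction — whose outputs are fused
element-wise.  The decoder lifts the fused encoding ×4 bilinearly, joins it
with a channel-reduced stage-2 skip, refines with three 3×3 convolutions,
projects to the three class planes, and lifts ×4 again to input resolution.
During training an auxiliary head on the stage-1 features provides a second
supervision signal ("loss reuse") so the loss keeps carrying gradient on
very small datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .backbone import BackboneConfig, IResNetBackbone, toy_backbone_config
from .grad import (
    Conv2d,
    GroupNorm,
    Module,
    ReLU,
    Sequential,
    Tensor,
    concatenate,
    upsample_bilinear,
)
from .pooling import MixedPoolingModule, StripPoolingModule

NUM_CLASSES = 3


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    skip_channels: int = 48          # width of the reduced stage-2 skip
    decoder_channels: int = 256      # width of the three 3×3 refinement convs
    aux_channels: int = 64           # width of the auxiliary head's 3×3 conv
    encoder_fusion: str = "sum"      # "sum" or "concat" of the SPM/MPM branches
    use_spm: bool = True
    use_mpm: bool = True
    mpm_grid_sizes: tuple = (1, 2, 3)

    def __post_init__(self):
        if self.encoder_fusion not in ("sum", "concat"):
            raise ValueError(f"encoder_fusion must be 'sum' or 'concat', got {self.encoder_fusion}")


def toy_model_config(**overrides) -> ModelConfig:
    """Desk-scale model matching :func:`toy_backbone_config` widths."""
    cfg = dict(backbone=toy_backbone_config(), skip_channels=8,
               decoder_channels=32, aux_channels=16)
    cfg.update(overrides)
    return ModelConfig(**cfg)


class EncoderOutputs(NamedTuple):
    encoded: Tensor   # fused SPM/MPM encoding at stride 16
    skip: Tensor      # stage-2 features at stride 4
    layer1: Tensor    # stage-1 features for the auxiliary head


class ModelOutputs(NamedTuple):
    main: Tensor
    aux: Tensor | None


def _conv_gn_relu(cin, cout, k, groups, rng, padding=0):
    return Sequential(Conv2d(cin, cout, k, padding=padding, rng=rng),
                      GroupNorm(groups, cout), ReLU())


class SPINet(Module):
    """Strip-pooling improved encoder-decoder segmentation network."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        bcfg = self.config.backbone
        g = bcfg.gn_groups
        self.backbone = IResNetBackbone(bcfg, rng)
        c4 = self.backbone.out_channels[3]           # 2048 × width
        mid = max(c4 // 2, 1)                        # 1024 × width
        self.encoded_channels = mid
        if self.config.use_spm:
            self.spm_reduce = _conv_gn_relu(c4, mid, 1, g, rng)
            self.spm = StripPoolingModule(mid, gn_groups=g, gate=bcfg.spm_gate,
                                          fusion=bcfg.spm_fusion, rng=rng)
        else:
            self.spm_reduce = _conv_gn_relu(c4, mid, 1, g, rng)
            self.spm = None
        if self.config.use_mpm:
            self.mpm = MixedPoolingModule(c4, mid, grid_sizes=self.config.mpm_grid_sizes,
                                          gn_groups=g, gate=bcfg.spm_gate,
                                          spm_fusion=bcfg.spm_fusion, rng=rng)
        else:
            self.mpm_reduce = _conv_gn_relu(c4, mid, 1, g, rng)
            self.mpm = None
        if self.config.encoder_fusion == "concat":
            self.fuse_proj = _conv_gn_relu(2 * mid, mid, 1, g, rng)

        # decoder
        dch = self.config.decoder_channels
        head_in = max(c4 // 4, 1)                    # 512 × width
        self.pre_up = _conv_gn_relu(mid, head_in, 1, g, rng)
        c2 = self.backbone.out_channels[1]
        self.skip_reduce = _conv_gn_relu(c2, self.config.skip_channels, 1, g, rng)
        self.refine = Sequential(
            _conv_gn_relu(head_in + self.config.skip_channels, dch, 3, g, rng, padding=1),
            _conv_gn_relu(dch, dch, 3, g, rng, padding=1),
            _conv_gn_relu(dch, dch, 3, g, rng, padding=1))
        self.classify = Conv2d(dch, NUM_CLASSES, 1, rng=rng)

        # auxiliary head on stage-1 features (training only)
        c1 = self.backbone.out_channels[0]
        self.aux_head = Sequential(_conv_gn_relu(c1, self.config.aux_channels, 3, g, rng, padding=1),
                                   Conv2d(self.config.aux_channels, NUM_CLASSES, 1, rng=rng))

    # -- encoder -----------------------------------------------------------
    def encoder_forward(self, x) -> EncoderOutputs:
        feats = self.backbone(x)
        l4 = feats.layer4
        branches = []
        if self.spm is not None:
            branches.append(self.spm(self.spm_reduce(l4)))
        else:
            branches.append(self.spm_reduce(l4))
        if self.mpm is not None:
            branches.append(self.mpm(l4))
        else:
            branches.append(self.mpm_reduce(l4))
        if self.config.encoder_fusion == "sum":
            encoded = branches[0] + branches[1]
        else:
            encoded = self.fuse_proj(concatenate(branches, axis=1))
        return EncoderOutputs(encoded=encoded, skip=feats.layer2, layer1=feats.layer1)

    # -- decoder -----------------------------------------------------------
    def decoder_forward(self, encoded, skip) -> Tensor:
        eh, ew = encoded.shape[2], encoded.shape[3]
        sh, sw = skip.shape[2], skip.shape[3]
        if (sh, sw) != (4 * eh, 4 * ew):
            raise ValueError(
                f"skip stride must be 4× finer than the encoding: got encoded "
                f"{eh}×{ew} vs skip {sh}×{sw}")
        y = upsample_bilinear(self.pre_up(encoded), sh, sw)
        y = concatenate([y, self.skip_reduce(skip)], axis=1)
        y = self.classify(self.refine(y))
        return upsample_bilinear(y, 4 * sh, 4 * sw)

    def forward(self, x, train_mode: bool = False) -> ModelOutputs:
        enc = self.encoder_forward(x)
        main = self.decoder_forward(enc.encoded, enc.skip)
        if not train_mode:
            return ModelOutputs(main=main, aux=None)
        l1 = enc.layer1
        aux = upsample_bilinear(self.aux_head(l1), 4 * l1.shape[2], 4 * l1.shape[3])
        return ModelOutputs(main=main, aux=aux)


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Map uint8 H×W×3 pixels to a float32 (3,H,W) plane stack in [-1, 1]."""
    arr = np.asarray(img, dtype=np.float32) / 127.5 - 1.0
    return arr.transpose(2, 0, 1)


def predict_mask(model: SPINet, img: np.ndarray) -> np.ndarray:
    """Segment one RGB image into class indices {0,1,2}.

    Inputs whose sides are not multiples of 16 are reflection-padded, and the
    prediction is cropped back.  Per-pixel argmax breaks ties toward the
    lowest class index (background).
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    ph, pw = (-h) % 16, (-w) % 16
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = normalize_image(img)[None]
    logits = model.forward(Tensor(x), train_mode=False).main.data[0]
    return logits.argmax(axis=0)[:h, :w].astype(np.uint8)
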