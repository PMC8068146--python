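"""Strip pooling and the SPM / MPM attention blocks.

Strip pooling averages a feature map along one full spatial axis with a
1×N or N×1 kernel, producing a per-row (or per-column) profile that carries
long-range context in that direction — exactly the structure of long narrow
planting gaps.  The Strip Pooling Module (SPM) turns the two profiles into a
multiplicative gate on its input; the Mixed Pooling Module (MPM) combines
pyramid-style square average pooling (for compact gaps) with an SPM (for
elongated ones).
"""

from __future__ import annotations

import numpy as np

from .grad import (
    Conv2d,
    DepthwiseConv1d,
    GroupNorm,
    Identity,
    Module,
    Sequential,
    ReLU,
    Tensor,
    adaptive_avg_pool,
    upsample_bilinear,
)


def strip_pool(x, direction: str):
    """Average a (B,C,H,W) map along full rows or columns.

    ``horizontal`` yields the per-row profile y^h of length H (each entry is
    the mean over the W columns of that row); ``vertical`` yields the
    per-column profile y^v of length W.
    """
    if direction == "horizontal":
        return x.mean(axis=3) if isinstance(x, Tensor) else np.asarray(x).mean(axis=-1)
    if direction == "vertical":
        return x.mean(axis=2) if isinstance(x, Tensor) else np.asarray(x).mean(axis=-2)
    raise ValueError(f"direction must be 'horizontal' or 'vertical', got {direction!r}")


class StripPoolingModule(Module):
    """Gate a feature map with fused horizontal/vertical strip-pool profiles.

    Pipeline: strip-pool both directions → per-direction depthwise 1-D
    convolution (kernel 3) along the profile → broadcast each profile back to
    H×W → fuse the two expanded maps (element-wise sum by default, product
    behind a flag) → 1×1 convolution + group normalization + gating
    activation (sigmoid by default) → element-wise multiplication with the
    input.  Output shape equals input shape.
    """

    def __init__(self, channels: int, gn_groups: int = 32, gate: str = "sigmoid",
                 fusion: str = "sum", normalize: bool = True,
                 rng: np.random.Generator | None = None):
        if gate not in ("sigmoid", "relu", "identity"):
            raise ValueError(f"gate must be 'sigmoid', 'relu' or 'identity', got {gate!r}")
        if fusion not in ("sum", "mul"):
            raise ValueError(f"fusion must be 'sum' or 'mul', got {fusion!r}")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.gate = gate
        self.fusion = fusion
        self.conv_h = DepthwiseConv1d(channels, 3, rng=rng)
        self.conv_v = DepthwiseConv1d(channels, 3, rng=rng)
        self.conv_fuse = Conv2d(channels, channels, 1, rng=rng)
        self.norm = GroupNorm(gn_groups, channels) if normalize else Identity()

    def set_identity(self) -> None:
        """Make the 1-D and 1×1 convolutions pass profiles through unchanged
        (kernel centers 1, biases 0); useful for oracle checks."""
        self.conv_h.weight.data[:] = np.array([0.0, 1.0, 0.0])
        self.conv_h.bias.data[:] = 0.0
        self.conv_v.weight.data[:] = np.array([0.0, 1.0, 0.0])
        self.conv_v.bias.data[:] = 0.0
        self.conv_fuse.weight.data[:] = np.eye(self.channels)[:, :, None, None]
        if self.conv_fuse.bias is not None:
            self.conv_fuse.bias.data[:] = 0.0

    def forward(self, x):
        b, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"SPM built for {self.channels} channels, got {c}")
        yh = self.conv_h(strip_pool(x, "horizontal"))    # (B,C,H)
        yv = self.conv_v(strip_pool(x, "vertical"))      # (B,C,W)
        yh = yh.reshape(b, c, h, 1)                      # broadcast H×1 -> H×W
        yv = yv.reshape(b, c, 1, w)                      # broadcast 1×W -> H×W
        fused = yh + yv if self.fusion == "sum" else yh * yv
        a = self.norm(self.conv_fuse(fused))
        if self.gate == "sigmoid":
            a = a.sigmoid()
        elif self.gate == "relu":
            a = a.relu()
        return x * a


class MixedPoolingModule(Module):
    """Pyramid average pooling fused with an SPM on reduced channels.

    Pipeline: 1×1 convolution reducing ``in_channels`` to ``mid_channels``
    (2048→1024 at full width) → adaptive average pooling at three grid sizes,
    each followed by a channel-reducing 1×1 convolution and bilinear
    upsampling back to H×W, fused by summation → a 3×3 convolution against
    pooling aliasing → an SPM → a final 1×1 convolution back to
    ``mid_channels``.  Spatial size is preserved.
    """

    def __init__(self, in_channels: int, mid_channels: int | None = None,
                 grid_sizes=(1, 2, 3), gn_groups: int = 32, gate: str = "sigmoid",
                 spm_fusion: str = "sum", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        mid = mid_channels or in_channels // 2
        branch = max(mid // 4, 1)
        self.in_channels, self.mid_channels, self.branch_channels = in_channels, mid, branch
        self.grid_sizes = tuple(grid_sizes)
        self.reduce = Sequential(Conv2d(in_channels, mid, 1, rng=rng),
                                 GroupNorm(gn_groups, mid), ReLU())
        # one normalization group per branch: per-group statistics degenerate on
        # the coarse pooled grids (a 1×1 map with one channel per group has
        # nothing to normalize over and would zero the branch gradient)
        self.branches = [Sequential(Conv2d(mid, branch, 1, rng=rng),
                                    GroupNorm(1, branch), ReLU())
                         for _ in self.grid_sizes]
        self.smooth = Sequential(Conv2d(branch, branch, 3, padding=1, rng=rng),
                                 GroupNorm(gn_groups, branch), ReLU())
        self.spm = StripPoolingModule(branch, gn_groups=gn_groups, gate=gate,
                                      fusion=spm_fusion, rng=rng)
        self.project = Sequential(Conv2d(branch, mid, 1, rng=rng),
                                  GroupNorm(gn_groups, mid), ReLU())

    def pyramid(self, reduced):
        """Sum of the pooled/convolved/upsampled branches (exposed for testing)."""
        _, _, h, w = reduced.shape
        out = None
        for grid, conv in zip(self.grid_sizes, self.branches):
            gh, gw = min(grid, h), min(grid, w)
            y = upsample_bilinear(conv(adaptive_avg_pool(reduced, gh, gw)), h, w)
            out = y if out is None else out + y
        return out

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(f"MPM built for {self.in_channels} channels, got {x.shape[1]}")
        reduced = self.reduce(x)
        fused = self.smooth(self.pyramid(reduced))
        return self.project(self.spm(fused))


def pyramid_pooling_reference_param_count(channels: int, grid_sizes=(1, 2, 3, 6)) -> int:
    """Parameter count of a PSPNet-style pyramid pooling head at `channels`.

    Branch 1×1 convolutions to channels/4 with group norm, plus the 3×3
    fusion convolution from the concatenated (2×channels) map back to
    channels/4.  Used as the reference in the SPM-is-cheaper check.
    """
    c4 = channels // 4
    branches = len(grid_sizes) * (channels * c4 + c4 + 2 * c4)
    fusion = (channels + len(grid_sizes) * c4) * c4 * 9 + c4 + 2 * c4
    return branches + fusion
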