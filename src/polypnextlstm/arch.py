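"""PolypNextLSTM: pruned ConvNeXt-Tiny encoder, bidirectional ConvLSTM
temporal bottleneck, UNet-style decoder.

The encoder is ConvNeXt-Tiny with the fourth stage and classification
layers removed: a stride-4 patch embedding into 96 channels, then stages
of (3, 3, 9) ConvNeXt blocks at widths (96, 192, 384) separated by
2x2-stride-2 downsampling layers.  The three stage outputs form a feature
pyramid (skips at /4 and /8, bottleneck at /16).  Each clip frame is
encoded independently; temporal structure is only seen by the fusion
module, a bidirectional ConvLSTM whose forward and backward 192-channel
hidden states are concatenated back to 384 channels per frame.  The
decoder upsamples with 2x2-stride-2 transposed convolutions, merging the
encoder skips through DoubleConv blocks, and ends with upsampling to
48 then 24 channels and a 1x1 convolution to a single logit map per frame.

Input/output contract: clips of shape B x F x 3 x H x W (H, W divisible
by 16) map to logits of shape B x F x 1 x H x W — one mask per frame.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat, count_parameters

__all__ = [
    "ModelConfig",
    "ConvNextBlock",
    "PatchEmbed",
    "Downsample",
    "ReducedConvNeXt",
    "UnprunedConvNeXt",
    "BiConvLSTM",
    "DoubleConv",
    "Decoder",
    "PolypNextLSTM",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_summary",
]


@dataclass
class ModelConfig:
    """Hyper-parameters of the network (defaults are the published ones)."""

    in_channels: int = 3
    stage_widths: tuple[int, int, int] = (96, 192, 384)
    stage_depths: tuple[int, int, int] = (3, 3, 9)
    lstm_hidden: int = 192
    lstm_kernel: int = 3
    lstm_padding: int = 1
    decoder_tail_widths: tuple[int, int] = (48, 24)
    layer_scale_init: float = 1e-6
    pretrained_backbone: bool = False
    seed: int = 0

    def __post_init__(self):
        if tuple(self.stage_depths) != (3, 3, 9):
            raise ValueError("stage_depths must be (3, 3, 9)")
        if 2 * self.lstm_hidden != self.stage_widths[2]:
            raise ValueError(
                "lstm_hidden must be half the bottleneck width so the "
                "concatenated bidirectional output restores it"
            )
        if self.pretrained_backbone:
            raise NotImplementedError(
                "pretrained backbone weights require a separately downloaded "
                "checkpoint; load one via load_checkpoint instead"
            )


class ConvNextBlock(nn.Module):
    """Residual block: depthwise 7x7 conv, channel layer norm, 1x1 conv to
    4C with GELU, 1x1 conv back to C, learnable per-channel scale."""

    def __init__(self, channels: int, layer_scale_init: float = 1e-6):
        super().__init__()
        self.dwconv = nn.Conv2d(channels, channels, 7, padding=3,
                                groups=channels, init="trunc")
        self.norm = nn.LayerNorm2d(channels)
        self.pwconv1 = nn.Conv2d(channels, 4 * channels, 1, init="trunc")
        self.act = nn.GELU()
        self.pwconv2 = nn.Conv2d(4 * channels, channels, 1, init="trunc")
        self.gamma = nn.Parameter(
            np.full(channels, layer_scale_init, dtype=np.float32)
        )
        self._ls_init = layer_scale_init

    def reset_parameters(self, rng):
        self.gamma.data = np.full_like(self.gamma.data, self._ls_init)

    def forward(self, x):
        y = self.pwconv2(self.act(self.pwconv1(self.norm(self.dwconv(x)))))
        return x + self.gamma.reshape(1, -1, 1, 1) * y


class PatchEmbed(nn.Module):
    """First encoder layer: 4x4-stride-4 conv then channel layer norm."""

    def __init__(self, in_channels: int = 3, width: int = 96):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, width, 4, stride=4, init="trunc")
        self.norm = nn.LayerNorm2d(width)

    def forward(self, x):
        return self.norm(self.proj(x))


class Downsample(nn.Module):
    """Between-stage reduction: layer norm then 2x2-stride-2 conv."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.norm = nn.LayerNorm2d(cin)
        self.conv = nn.Conv2d(cin, cout, 2, stride=2, init="trunc")

    def forward(self, x):
        return self.conv(self.norm(x))


class ReducedConvNeXt(nn.Module):
    """Three-stage ConvNeXt-Tiny encoder (no stage 4, no classifier).

    ``forward`` returns the feature pyramid (skip4, skip8, bottleneck):
    stage outputs after each stage's blocks, before downsampling.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        w, d = cfg.stage_widths, cfg.stage_depths
        ls = cfg.layer_scale_init
        self.patch_embed = PatchEmbed(cfg.in_channels, w[0])
        self.stage1 = nn.Sequential(*[ConvNextBlock(w[0], ls) for _ in range(d[0])])
        self.down1 = Downsample(w[0], w[1])
        self.stage2 = nn.Sequential(*[ConvNextBlock(w[1], ls) for _ in range(d[1])])
        self.down2 = Downsample(w[1], w[2])
        self.stage3 = nn.Sequential(*[ConvNextBlock(w[2], ls) for _ in range(d[2])])

    def forward(self, x):
        s4 = self.stage1(self.patch_embed(x))
        s8 = self.stage2(self.down1(s4))
        s16 = self.stage3(self.down2(s8))
        return s4, s8, s16


class UnprunedConvNeXt(nn.Module):
    """Original four-stage ConvNeXt-Tiny feature extractor ((3,3,9,3)
    blocks at widths 96/192/384/768, classification layers omitted).
    Exists to verify the pruning saving; not used by the segmenter."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.reduced = ReducedConvNeXt(cfg)
        w = cfg.stage_widths[2]
        self.down3 = Downsample(w, 2 * w)
        self.stage4 = nn.Sequential(
            *[ConvNextBlock(2 * w, cfg.layer_scale_init) for _ in range(3)]
        )

    def forward(self, x):
        _, _, s16 = self.reduced(x)
        return self.stage4(self.down3(s16))


class BiConvLSTM(nn.Module):
    """Bidirectional ConvLSTM over the frame axis of a B x F x C x h x w
    bottleneck.  One cell scans frames first-to-last, an independent cell
    scans last-to-first; per frame the two 192-channel hidden states are
    concatenated (forward half first) to restore the input width.  Hidden
    and cell states start at zero."""

    def __init__(self, channels: int = 384, hidden: int = 192,
                 kernel: int = 3, padding: int = 1):
        super().__init__()
        self.channels = channels
        self.fwd = nn.ConvLSTMCell(channels, hidden, kernel, padding)
        self.bwd = nn.ConvLSTMCell(channels, hidden, kernel, padding)

    def forward(self, x: Tensor) -> Tensor:
        b, f, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(
                f"fusion expects {self.channels} channels, got {c}"
            )
        if f == 0:
            raise ValueError("empty clip: at least one frame required")
        frames = [x.narrow(1, t, 1).reshape(b, c, h, w) for t in range(f)]
        hf, cf = self.fwd.init_state(b, h, w)
        fwd_states = []
        for t in range(f):
            hf, cf = self.fwd(frames[t], hf, cf)
            fwd_states.append(hf)
        hb, cb = self.bwd.init_state(b, h, w)
        bwd_states = [None] * f
        for t in reversed(range(f)):
            hb, cb = self.bwd(frames[t], hb, cb)
            bwd_states[t] = hb
        per_frame = [
            concat([fwd_states[t], bwd_states[t]], axis=1).reshape(b, 1, c, h, w)
            for t in range(f)
        ]
        return concat(per_frame, axis=1)


class DoubleConv(nn.Module):
    """Two 3x3 conv + batch norm + ReLU layers; the first halves channels."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, padding=1),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
            nn.Conv2d(cout, cout, 3, padding=1),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        )

    def forward(self, x):
        return self.block(x)


class Decoder(nn.Module):
    """UNet-style decoder over the flattened (B*F) batch.

    384 -> up -> 192, concat /8 skip -> DoubleConv(384->192)
        -> up -> 96, concat /4 skip -> DoubleConv(192->96)
        -> up -> 48 -> up -> 24 -> 1x1 conv -> 1 logit channel.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        w = cfg.stage_widths
        t = cfg.decoder_tail_widths
        self.up1 = nn.ConvTranspose2d(w[2], w[1])
        self.conv1 = DoubleConv(w[2], w[1])
        self.up2 = nn.ConvTranspose2d(w[1], w[0])
        self.conv2 = DoubleConv(2 * w[0], w[0])
        self.up3 = nn.ConvTranspose2d(w[0], t[0])
        self.up4 = nn.ConvTranspose2d(t[0], t[1])
        self.out = nn.Conv2d(t[1], 1, 1)

    @staticmethod
    def _check(stage: str, x, skip):
        if x.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder {stage}: upsampled map {x.shape[2:]} does not match "
                f"skip {skip.shape[2:]}"
            )

    def forward(self, skip4, skip8, fused):
        x = self.up1(fused)
        self._check("skip8 merge", x, skip8)
        x = self.conv1(concat([x, skip8], axis=1))
        x = self.up2(x)
        self._check("skip4 merge", x, skip4)
        x = self.conv2(concat([x, skip4], axis=1))
        return self.out(self.up4(self.up3(x)))


class PolypNextLSTM(nn.Module):
    """Full network: many-to-many video segmentation.

    Encoder and decoder run on the flattened (B*F) batch — frames are
    processed independently — while the bidirectional ConvLSTM is the only
    module that sees the frame axis.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.encoder = ReducedConvNeXt(self.cfg)
        self.fusion = BiConvLSTM(self.cfg.stage_widths[2], self.cfg.lstm_hidden,
                                 self.cfg.lstm_kernel, self.cfg.lstm_padding)
        self.decoder = Decoder(self.cfg)

    def forward(self, clip: Tensor) -> Tensor:
        if clip.ndim != 5:
            raise ValueError(f"expected B x F x C x H x W input, got {clip.shape}")
        b, f, c, h, w = clip.shape
        if f < 1:
            raise ValueError("empty clip: at least one frame required")
        for dim, name in ((h, "height"), (w, "width")):
            if dim % 16:
                raise ValueError(f"{name} {dim} not divisible by 16")
        flat = clip.reshape(b * f, c, h, w)
        s4, s8, s16 = self.encoder(flat)
        bott = s16.reshape(b, f, *s16.shape[1:])
        fused = self.fusion(bott).reshape(b * f, *s16.shape[1:])
        logits = self.decoder(s4, s8, fused)
        return logits.reshape(b, f, 1, h, w)


def build_model(cfg: ModelConfig | None = None) -> PolypNextLSTM:
    """Construct the network with seeded weight initialization."""
    cfg = cfg or ModelConfig()
    model = PolypNextLSTM(cfg)
    model.initialize(np.random.default_rng(cfg.seed))
    return model


def save_checkpoint(path, model: nn.Module, cfg: ModelConfig | None = None,
                    extra: dict | None = None) -> None:
    """Single-file archive: weights keyed by module path + JSON config."""
    meta = {"config": asdict(cfg) if cfg else None, "extra": extra or {}}
    arrays = dict(model.state_dict())
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path):
    """Returns (model, config, extra) rebuilt from a checkpoint file."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    cfg_dict = meta["config"] or {}
    for key in ("stage_widths", "stage_depths", "decoder_tail_widths"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ModelConfig(**cfg_dict)
    model = PolypNextLSTM(cfg)
    model.load_state_dict(arrays)
    return model, cfg, meta["extra"]


def parameter_summary(model: nn.Module) -> dict:
    """Per-submodule trainable parameter counts (top-level children)."""
    total = count_parameters(model)
    per_child = {name: count_parameters(child)
                 for name, child in model._children()}
    per_child["total"] = total
    per_child["total_millions"] = round_millions(total)
    return per_child


def round_millions(n_params: int) -> float:
    """Parameter count in millions, rounded half-up to two decimals."""
    import decimal

    return float(
        (decimal.Decimal(n_params) / decimal.Decimal(10**6)).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
        )
    )
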