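"""Residual 2D U-Net with contextual aggregation layers.

The network is a fully convolutional encoder–decoder producing a per-pixel
lesion score in [0, 1] for each trans-axial PET slice.  The encoder stacks
four residual blocks joined by stride-2 convolutions; the decoder mirrors
them with stride-2 transposed convolutions and four long-range skip
connections.  Two contextual aggregation branches carry the two deepest
decoder feature maps straight to full resolution with stride-4 and stride-8
transposed convolutions; their output is fused (channel concatenation) with
the last residual block's output before a final convolution and sigmoid.

Inputs whose height or width is not divisible by 16 are reflect-padded up to
the next multiple and the score map is cropped back, so the output always
matches the input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .phantom import OrganMask, SliceStack

DOWN_FACTOR = 16  # four stride-2 stages


@dataclass(frozen=True)
class ModelConfig:
    n_down_blocks: int = 4
    n_up_blocks: int = 4
    base_channels: int = 32
    channel_growth: int = 2
    agg_strides: tuple[int, int] = (4, 8)
    norm_kind: str = "batch"
    activation_kind: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_down_blocks != 4 or self.n_up_blocks != 4:
            raise ValueError("the architecture is defined with exactly four "
                             "encoder and four decoder residual blocks")
        if tuple(sorted(self.agg_strides)) != (4, 8):
            raise ValueError("aggregation strides must be {4, 8}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "agg_strides" in d:
            d["agg_strides"] = tuple(d["agg_strides"])
        return cls(**d)


class ResUNet(nn.Module):
    """The residual U-Net graph; see the module docstring for topology."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        g = config.channel_growth
        chans = [c, c * g, c * g ** 2, c * g ** 3, c * g ** 4]

        self.enc = [nn.ResBlock(1, chans[0], rng)]
        self.down = []
        for i in range(3):
            self.down.append(nn.Conv2d(chans[i], chans[i + 1], 3, stride=2,
                                       rng=rng))
            self.enc.append(nn.ResBlock(chans[i + 1], chans[i + 1], rng))
        self.down.append(nn.Conv2d(chans[3], chans[4], 3, stride=2, rng=rng))

        # decoder: deepest first; after upsampling, concat the encoder skip
        self.up = []
        self.dec = []
        for i in range(4):
            c_in = chans[4 - i]
            c_out = chans[3 - i]
            self.up.append(nn.ConvTranspose2d(c_in, c_out, 2, rng=rng))
            self.dec.append(nn.ResBlock(2 * c_out, c_out, rng))

        # aggregation: decoder outputs at 1/8 (stride 8) and 1/4 (stride 4)
        self.agg8 = nn.ConvTranspose2d(chans[3], c, 8, rng=rng)
        self.agg4 = nn.ConvTranspose2d(chans[2], c, 4, rng=rng)
        self.final = nn.Conv2d(3 * c, 1, 3, rng=rng)
        self.sigmoid = nn.Sigmoid()
        self._cache = None

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) with H, W divisible by 16 → scores (N, 1, H, W)."""
        skips = []
        h = x
        for i in range(4):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.down[i].forward(h)
        dec_outs = []
        for i in range(4):
            h = self.up[i].forward(h)
            h = np.concatenate([h, skips[3 - i]], axis=1)
            h = self.dec[i].forward(h)
            dec_outs.append(h)
        a8 = self.agg8.forward(dec_outs[0])
        a4 = self.agg4.forward(dec_outs[1])
        fused = np.concatenate([dec_outs[3], a4, a8], axis=1)
        out = self.sigmoid.forward(self.final.forward(fused))
        self._split = [dec_outs[3].shape[1], a4.shape[1]]
        self._skip_chans = [s.shape[1] for s in skips]
        return out

    def backward(self, gout: np.ndarray) -> None:
        g = self.sigmoid.backward(gout)
        g = self.final.backward(g)
        c0, c1 = self._split
        g_d4 = g[:, :c0]
        g_a4 = self.agg4.backward(g[:, c0:c0 + c1])
        g_a8 = self.agg8.backward(g[:, c0 + c1:])

        g_skips = [None] * 4
        g_h = None
        for i in range(3, -1, -1):
            g_dec = g_d4 if i == 3 else g_h
            if i == 1:
                g_dec = g_dec + g_a4
            if i == 0:
                g_dec = g_dec + g_a8
            g_cat = self.dec[i].backward(g_dec)
            c_up = self.up[i].weight.value.shape[1]
            g_skips[3 - i] = g_cat[:, c_up:]
            g_h = self.up[i].backward(np.ascontiguousarray(g_cat[:, :c_up]))
        for i in range(3, -1, -1):
            g_h = self.down[i].backward(g_h)
            g_h = self.enc[i].backward(g_h + g_skips[i])

    # -- inference ---------------------------------------------------------
    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        """Score a batch of 2D slices (N, H, W), honoring the padding contract."""
        self.set_training(False)
        x = np.asarray(slices, dtype=nn.DTYPE)[:, None]
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % DOWN_FACTOR
        pw = (-w) % DOWN_FACTOR
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        out = self.forward(x)[:, 0, :h, :w]
        return out.astype(np.float64)


def normalize_masked(voxels: np.ndarray, liver_mask: np.ndarray) -> np.ndarray:
    """Zero outside-liver pixels and scale the study to unit maximum.

    The per-study max normalization plays the role of the fixed 8-bit
    intensity window used on disk: network inputs are always in [0, 1]
    regardless of the absolute activity calibration.
    """
    masked = voxels * liver_mask
    peak = masked.max()
    if peak > 0:
        masked = masked / peak
    return masked


def build_model(config: ModelConfig) -> ResUNet:
    """Construct the residual U-Net; identical config (incl. seed) gives
    identical initial weights."""
    return ResUNet(config)


def save_model(model: ResUNet, path) -> None:
    """Serialize weights + batch-norm buffers + config to one .npz file."""
    import json

    state = nn.get_state(model)
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez(path, config=json.dumps(model.config.to_dict()), **arrays)


def load_model(path) -> ResUNet:
    import json

    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["config"])))
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
        model = build_model(config)
        nn.set_state(model, state)
    model.set_training(False)
    return model


def predict_study(model: ResUNet, stack: SliceStack, liver: OrganMask,
                  batch_size: int = 8) -> np.ndarray:
    """Score every slice of a study, masking outside-liver pixels to zero
    before inference.  Slices are independent; output aligns with the stack."""
    if stack.shape != liver.mask.shape:
        raise ValueError("stack and liver mask are not aligned")
    masked = normalize_masked(stack.voxels, liver.mask)
    scores = np.empty(stack.shape, np.float64)
    for start in range(0, stack.n_slices, batch_size):
        batch = masked[start:start + batch_size]
        scores[start:start + batch.shape[0]] = model.predict_slices(batch)
    return scores
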