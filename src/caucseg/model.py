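"""Assembly of the CAUC segmentation network and its ablation variants.

The full model (variant V5) is a four-level encoder/decoder:

* stem: standard 3x3 convolution to 64 channels;
* encoder: LCB blocks at filter allocations 16/32/64/128, each followed by
  2x2 max pooling and channel-wise dropout (rates 0.2/0.2/0.5/0.5);
* middle: one 3x3 depthwise-separable convolution with 256 filters;
* decoder: four stages of parameter-free x2 upsampling, channel dropout
  (0.5/0.5/0.2/0.2), an attention-gated skip from the matching encoder level,
  concatenation, and an LCB at 128/64/32/16 filters;
* feature fusion: every decoder LCB output passes a CBAM, is upsampled to the
  input grid, and the four refined maps (128+64+32+16 = 240 channels) are
  concatenated before a 3x3 output convolution to the 5 class logits and a
  per-pixel softmax.

Ablation variants: V4 drops the CBAM fusion (head on the last LCB), V3 drops
the attention gates (plain skips), V2 drops both, and V1 is a plain double-conv
U-Net baseline with conventional width doubling.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .blocks import (
    AGSpec,
    AttentionGate,
    CBAM,
    CBAMSpec,
    ConvBNReLU,
    DepthwiseConv2d,
    DepthwiseSeparableConv,
    LCB,
    LCBSpec,
)
from .nn import autograd as ag
from .nn.layers import Conv2d, Dropout, Module, RngState

VARIANTS = {
    "V1": "wo-CBAM_AG_LCB",
    "V2": "wo-CBAM_AG",
    "V3": "wo-AG",
    "V4": "wo-CBAM",
    "V5": "full",
}

_ENCODER_FILTERS = (16, 32, 64, 128)
# Drop-channel rates: 10% at the shallow (top) LCB levels, 20% at the deep
# (bottom) levels, mirrored on the decoder side.
_ENCODER_DROP = (0.1, 0.1, 0.2, 0.2)
_DECODER_DROP = (0.2, 0.2, 0.1, 0.1)
_STEM_FILTERS = 64
_MIDDLE_FILTERS = 256
#: AG projection widths per decoder stage (the 16-channel gate uses 16).
_AG_INTER = (128, 64, 32, 16)


class CAUCNet(Module):
    """The segmentation network; NHWC in, per-pixel class probabilities out."""

    def __init__(self, input_size=224, num_classes=5, variant="V5", seed=0,
                 cbam_spec=CBAMSpec()):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        if input_size % 16:
            raise ValueError(f"input_size must be divisible by 16, got {input_size}")
        self.input_size = input_size
        self.num_classes = num_classes
        self.variant = variant
        self.seed = seed
        self.rng_state = RngState(seed)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xCA0C)))
        if variant == "V1":
            self._build_plain_unet(rng, num_classes)
            return
        self.use_ag = variant in ("V4", "V5")
        self.use_cbam = variant in ("V3", "V5")

        self.stem = ConvBNReLU(3, _STEM_FILTERS, rng, 3)
        enc_in = _STEM_FILTERS
        self.enc_lcbs, self.enc_drops = [], []
        for n, rate in zip(_ENCODER_FILTERS, _ENCODER_DROP):
            self.enc_lcbs.append(LCB(LCBSpec(N=n, Ni=enc_in), rng, self.rng_state))
            self.enc_drops.append(Dropout(rate, self.rng_state, channelwise=True))
            enc_in = n
        self.middle = DepthwiseSeparableConv(_ENCODER_FILTERS[-1], _MIDDLE_FILTERS, rng)

        self.dec_lcbs, self.dec_drops, self.gates = [], [], []
        deeper_ch = _MIDDLE_FILTERS
        for n, rate, inter in zip(reversed(_ENCODER_FILTERS), _DECODER_DROP, _AG_INTER):
            self.dec_drops.append(Dropout(rate, self.rng_state, channelwise=True))
            if self.use_ag:
                self.gates.append(AttentionGate(AGSpec(x_channels=n, inter_channels=inter), rng))
            self.dec_lcbs.append(LCB(LCBSpec(N=n, Ni=deeper_ch + n), rng, self.rng_state))
            deeper_ch = n

        if self.use_cbam:
            self.cbams = [CBAM(c, rng, cbam_spec) for c in reversed(_ENCODER_FILTERS)]
            head_in = sum(_ENCODER_FILTERS)
        else:
            self.cbams = []
            head_in = _ENCODER_FILTERS[0]
        self.head = Conv2d(head_in, num_classes, 3, rng, zero_init=True)

    def _build_plain_unet(self, rng, num_classes):
        """V1: conventional double-conv U-Net (widths 32..256, middle 512)."""
        widths = (32, 64, 128, 256)
        self.enc_blocks = []
        c_in = 3
        for w in widths:
            self.enc_blocks.append((ConvBNReLU(c_in, w, rng), ConvBNReLU(w, w, rng)))
            c_in = w
        self.enc_blocks = [m for pair in self.enc_blocks for m in pair]
        self.middle = ConvBNReLU(widths[-1], 2 * widths[-1], rng)
        self.dec_blocks = []
        deeper = 2 * widths[-1]
        for w in reversed(widths):
            self.dec_blocks.append(ConvBNReLU(deeper + w, w, rng))
            self.dec_blocks.append(ConvBNReLU(w, w, rng))
            deeper = w
        self.head = Conv2d(widths[0], num_classes, 3, rng, zero_init=True)

    # ------------------------------------------------------------------ #

    def logits(self, x, record=None):
        """Forward pass up to the class logits (pre-softmax)."""
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (B, H, W, 3) input, got {x.shape}")
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} input, got {x.shape[1]}x{x.shape[2]}")
        if self.variant == "V1":
            return self._logits_plain(x)

        def rec(name, t):
            if record is not None:
                record[name] = tuple(t.shape[1:])
            return t

        h = rec("E1", self.stem(x))
        skips = []
        stage = 1
        for lcb, drop in zip(self.enc_lcbs, self.enc_drops):
            h = rec(f"E{stage + 1}", lcb(h))
            skips.append(h)
            h = rec(f"E{stage + 2}", ag.max_pool2d(h))
            h = rec(f"E{stage + 3}", drop(h))
            stage += 3
        m = rec("M", self.middle(h))

        deeper = m
        up_rows = ("D1", "D5", "D10", "D15")
        drop_rows = ("D2", "D6", "D11", "D16")
        ag_rows = ("D3", "D7", "D12", "D17")
        cat_rows = ("D3c", "D8", "D13", "D18")
        out_rows = ("D4", "D9", "D14", "D19")
        dec_outputs = []
        for i, (lcb, drop) in enumerate(zip(self.dec_lcbs, self.dec_drops)):
            up = rec(up_rows[i], ag.upsample_nearest(deeper, 2))
            up = rec(drop_rows[i], drop(up))
            skip = skips[-(i + 1)]
            if self.use_ag:
                skip = self.gates[i](skip, deeper)
            rec(ag_rows[i], skip)
            h = rec(cat_rows[i], ag.concat([up, skip]))
            h = rec(out_rows[i], lcb(h))
            dec_outputs.append(h)
            deeper = h

        if self.use_cbam:
            branches = []
            for i, (out, cb) in enumerate(zip(dec_outputs, self.cbams)):
                refined = cb(out)
                scale = 2 ** (3 - i)
                if scale > 1:
                    refined = ag.upsample_nearest(refined, scale)
                branches.append(rec(f"F{i + 1}", refined))
            fused = rec("F5", ag.concat(branches))
            logits = rec("F6", self.head(fused))
        else:
            logits = self.head(dec_outputs[-1])
        return logits

    def _logits_plain(self, x):
        h = x
        skips = []
        for i in range(0, len(self.enc_blocks), 2):
            h = self.enc_blocks[i + 1](self.enc_blocks[i](h))
            skips.append(h)
            h = ag.max_pool2d(h)
        h = self.middle(h)
        for i in range(0, len(self.dec_blocks), 2):
            h = ag.upsample_nearest(h, 2)
            h = ag.concat([h, skips[-(i // 2 + 1)]])
            h = self.dec_blocks[i + 1](self.dec_blocks[i](h))
        return self.head(h)

    def forward(self, x, record=None):
        probs = ag.softmax(self.logits(x, record=record))
        if record is not None and self.variant != "V1":
            record["F7"] = tuple(probs.shape[1:])
        return probs


# ---------------------------------------------------------------------- #
# Graph-level queries

def build_cauc(input_size=224, num_classes=5, seed=0):
    """Construct the full model (variant V5)."""
    return CAUCNet(input_size=input_size, num_classes=num_classes, variant="V5", seed=seed)


def build_variant(variant, input_size=224, num_classes=5, seed=0):
    return CAUCNet(input_size=input_size, num_classes=num_classes, variant=variant, seed=seed)


def forward(model, image_batch):
    """Run inference on a batch of RGB images scaled to [0, 1].

    Returns per-pixel class probabilities (B, H, W, M); channel sums are 1.
    """
    x = np.asarray(image_batch, dtype=np.float32)
    if x.max() > 1.0 + 1e-6:
        raise ValueError("images must be scaled to [0, 1]")
    model.eval()
    return model(ag.Tensor(x)).data


def count_parameters(model, include_bn=True):
    """Total parameter count (framework-style summary).

    With ``include_bn`` the count covers convolution kernels, biases,
    normalization scale/shift and moving statistics, and attention MLP weights
    — what a framework model summary reports as total params.
    """
    return model.weight_count(include_bn=include_bn, include_bias=True,
                              include_stats=include_bn)


def layer_census(model):
    """Count convolution layers by spatial kernel size.

    Each depthwise-separable layer's 3x3 stage counts once (its internal 1x1
    pointwise stage is part of the same layer); attention-MLP dense layers are
    not convolutions.
    """
    census = {}
    for m in model.modules():
        if isinstance(m, DepthwiseConv2d):
            k = m.kernel_size
        elif isinstance(m, Conv2d) and not getattr(m, "census_exempt", False):
            k = m.kernel_size
        else:
            continue
        census[k] = census.get(k, 0) + 1
    return census


def shape_report(model, batch_size=1):
    """Run a recording forward pass; returns an ordered (stage, (H, W, C)) list."""
    model.eval()
    record = {}
    x = ag.Tensor(np.zeros((batch_size, model.input_size, model.input_size, 3),
                           dtype=np.float32))
    model(x, record=record)
    return list(record.items())


def expected_stage_shapes(input_size=224):
    """The packaged stage-shape contract, rescaled to ``input_size``."""
    text = resources.files("caucseg.data").joinpath("cauc_stage_shapes.json").read_text()
    table = {k: tuple(v) for k, v in json.loads(text).items() if not k.startswith("_")}
    if input_size != 224:
        f = input_size / 224
        table = {k: (int(h * f), int(w * f), c) for k, (h, w, c) in table.items()}
    return table


# ---------------------------------------------------------------------- #
# Checkpoints

def architecture_descriptor(model):
    return {"variant": model.variant, "input_size": model.input_size,
            "num_classes": model.num_classes, "seed": model.seed,
            "parameters": count_parameters(model)}


def save_checkpoint(model, path):
    """Serialize weights (npz) with an embedded JSON architecture descriptor."""
    state = model.state_dict()
    state["__arch__"] = np.frombuffer(
        json.dumps(architecture_descriptor(model)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    with np.load(path) as data:
        arch = json.loads(bytes(data["__arch__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__arch__"}
    model = CAUCNet(input_size=arch["input_size"], num_classes=arch["num_classes"],
                    variant=arch["variant"], seed=arch["seed"])
    model.load_state_dict(state)
    return model, arch
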