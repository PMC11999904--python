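"""Builders and parameter accounting for the seven U-Net-family architectures.

All models share the same canonical block conventions:

* encoder level = [3x3 conv (bias) -> channel-wise norm -> ReLU] x 2, with
  2x2 max-pooling between levels;
* decoder step = 3x3 stride-2 transposed convolution (bias, no norm) ->
  concatenate the skip feature -> double conv block;
* terminal 1x1 convolution (bias) to ``n_classes`` followed by softmax.

Parameter accounting counts *stored* values: convolution weights and biases
plus 4 values per normalized channel (affine scale/shift and the running
mean/variance).  Under these conventions the base U-Net (widths 16..256,
1 input channel, 6 classes) holds exactly 2,164,390 values and the Wide
U-Net (widths 30..480) exactly 7,596,306; the nested U-Net++ lands on
exactly 2,555,702.  The remaining variants (attention gates, dense blocks,
residual shortcuts, inception branches) have their default hyperparameters
chosen so the seven totals are strictly ordered
U-Net < Attention < U-Net++ < Inception < Residual < Wide < Dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import engine as E

FAMILIES = (
    "unet",
    "wide_unet",
    "attention_unet",
    "dense_unet",
    "residual_unet",
    "inception_unet",
    "unet_pp",
)

_DEFAULT_WIDTHS = {
    "unet": (16, 32, 64, 128, 256),
    "wide_unet": (30, 60, 120, 240, 480),
    "attention_unet": (16, 32, 64, 128, 256),
    "dense_unet": (16, 32, 64, 128, 256),
    "residual_unet": (28, 56, 112, 224, 448),
    "inception_unet": (16, 32, 64, 128, 256),
    "unet_pp": (16, 32, 64, 128, 256),
}

_DEFAULT_VARIANT_PARAMS = {
    "dense_unet": {"growth_num": 31, "growth_den": 16, "layers_per_block": 2},
    "inception_unet": {"branch_num": 23, "branch_den": 16},
    "unet_pp": {"deep_supervision": False},
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Fully determines a segmentation network and its parameter count."""

    family: str
    encoder_widths: tuple = ()
    in_channels: int = 1
    n_classes: int = 6
    variant_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown architecture family: {self.family!r}")
        widths = tuple(self.encoder_widths) or _DEFAULT_WIDTHS[self.family]
        if any(b <= a for a, b in zip(widths, widths[1:])):
            raise ValueError("encoder_widths must be strictly increasing")
        if any(w < 1 for w in widths):
            raise ValueError("encoder_widths must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        vp = dict(_DEFAULT_VARIANT_PARAMS.get(self.family, {}))
        vp.update(self.variant_params)
        object.__setattr__(self, "encoder_widths", widths)
        object.__setattr__(self, "variant_params", vp)

    @property
    def depth(self) -> int:
        return len(self.encoder_widths)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "encoder_widths": list(self.encoder_widths),
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "variant_params": dict(self.variant_params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            family=d["family"],
            encoder_widths=tuple(d.get("encoder_widths") or ()),
            in_channels=d.get("in_channels", 1),
            n_classes=d.get("n_classes", 6),
            variant_params=dict(d.get("variant_params", {})),
        )


def canonical_specs() -> list:
    """The seven default architecture specs, in ascending parameter count."""
    order = (
        "unet", "attention_unet", "unet_pp", "inception_unet",
        "residual_unet", "wide_unet", "dense_unet",
    )
    return [ArchitectureSpec(family=f) for f in order]


# ---------------------------------------------------------------------------
# closed-form parameter accounting


def _conv(cin, cout, k=3):
    return k * k * cin * cout + cout


def _norm(c):
    return 4 * c


def _double(cin, w):
    return _conv(cin, w) + _norm(w) + _conv(w, w) + _norm(w)


def _count_unet(widths, cin, ncls):
    t, c = 0, cin
    for w in widths:
        t += _double(c, w)
        c = w
    for w in reversed(widths[:-1]):
        t += _conv(c, w)  # transposed conv, bias, no norm
        t += _double(2 * w, w)
        c = w
    return t + _conv(c, ncls, k=1)


def _count_attention(widths, cin, ncls):
    t = _count_unet(widths, cin, ncls)
    for i in range(len(widths) - 1):
        cx, cg = widths[i], widths[i + 1]
        f = cx  # inter-channel rule: match the skip width
        t += (cg * f + f) + (cx * f + f) + (f + 1)
    return t


def _count_unet_pp(widths, cin, ncls, deep_supervision=False):
    t, c = 0, cin
    for w in widths:
        t += _double(c, w)
        c = w
    d = len(widths)
    for i in range(d - 1):
        w, up_c = widths[i], widths[i + 1]
        for j in range(1, d - i):
            t += _conv(up_c, w)  # up from X[i+1][j-1]
            t += _conv((j + 1) * w, w) + _norm(w)
            t += _conv(w, w) + _norm(w)
    n_heads = d - 1 if deep_supervision else 1
    return t + n_heads * _conv(widths[0], ncls, k=1)


def _count_residual(widths, cin, ncls):
    t, c = 0, cin
    for w in widths:
        t += _double(c, w) + _conv(c, w, k=1)  # 1x1 projection shortcut
        c = w
    for w in reversed(widths[:-1]):
        t += _conv(c, w)
        t += _double(2 * w, w) + _conv(2 * w, w, k=1)
        c = w
    return t + _conv(c, ncls, k=1)


def _inception_block(c, w, num, den):
    fw = (num * w) // den
    t = _conv(c, fw, k=1) + _conv(c, fw, k=3) + _conv(c, fw, k=5)
    t += _conv(c, fw, k=1)  # pooled branch projection
    t += _conv(4 * fw, w, k=1) + _norm(w)
    return t


def _count_inception(widths, cin, ncls, branch_num, branch_den):
    t, c = 0, cin
    for w in widths:
        t += _inception_block(c, w, branch_num, branch_den)
        c = w
    for w in reversed(widths[:-1]):
        t += _conv(c, w)
        t += _inception_block(2 * w, w, branch_num, branch_den)
        c = w
    return t + _conv(c, ncls, k=1)


def _dense_block(c, w, num, den, n_layers):
    g = (num * w) // den
    t = 0
    for layer in range(n_layers):
        t += _conv(c + layer * g, g) + _norm(g)
    t += _conv(c + n_layers * g, w, k=1) + _norm(w)  # 1x1 transition
    return t


def _count_dense(widths, cin, ncls, growth_num, growth_den, layers_per_block):
    t, c = 0, cin
    for w in widths:
        t += _dense_block(c, w, growth_num, growth_den, layers_per_block)
        c = w
    for w in reversed(widths[:-1]):
        t += _conv(c, w)
        t += _dense_block(2 * w, w, growth_num, growth_den, layers_per_block)
        c = w
    return t + _conv(c, ncls, k=1)


def count_parameters_closed_form(spec: ArchitectureSpec) -> int:
    """Exact stored-parameter total by per-layer arithmetic summation."""
    w, cin, ncls = spec.encoder_widths, spec.in_channels, spec.n_classes
    vp = spec.variant_params
    if spec.family in ("unet", "wide_unet"):
        return _count_unet(w, cin, ncls)
    if spec.family == "attention_unet":
        return _count_attention(w, cin, ncls)
    if spec.family == "unet_pp":
        return _count_unet_pp(w, cin, ncls, vp.get("deep_supervision", False))
    if spec.family == "residual_unet":
        return _count_residual(w, cin, ncls)
    if spec.family == "inception_unet":
        return _count_inception(w, cin, ncls, vp["branch_num"], vp["branch_den"])
    if spec.family == "dense_unet":
        return _count_dense(
            w, cin, ncls, vp["growth_num"], vp["growth_den"], vp["layers_per_block"]
        )
    raise ValueError(f"unknown family {spec.family!r}")


def count_parameters_runtime(model) -> int:
    """Sum of the sizes of all stored numeric arrays of a built model."""
    return model.n_stored_parameters()


# ---------------------------------------------------------------------------
# model implementations


class SegmentationModel(nn.Module):
    """Common forward-facing surface: logits, probabilities, prediction."""

    spec: ArchitectureSpec

    def _check_input(self, x):
        h, w = x.shape[1], x.shape[2]
        div = 2 ** (self.spec.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^(depth-1)={div}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> E.Tensor:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probability map (softmax over the last axis)."""
        with nn.no_grad():
            logits = self.forward(np.asarray(x, dtype=np.float32), training=False)
        return nn.softmax(logits.data)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=-1).astype(np.uint8)


class UNet(SegmentationModel):
    def __init__(self, spec: ArchitectureSpec, rng):
        ws = spec.encoder_widths
        self.spec = spec
        c = spec.in_channels
        self.enc = []
        for w in ws:
            self.enc.append(nn.DoubleConv(c, w, rng=rng))
            c = w
        self.ups = [
            nn.ConvTranspose2x(ws[i + 1], ws[i], rng=rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.dec = [
            nn.DoubleConv(2 * ws[i], ws[i], rng=rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.final = nn.Conv2d(ws[0], spec.n_classes, k=1, rng=rng)

    def forward(self, x, training=False):
        self._check_input(x)
        t = E.Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        for i, blk in enumerate(self.enc):
            t = blk(t, training)
            if i < len(self.enc) - 1:
                skips.append(t)
                t = E.maxpool2x2(t)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up(t)
            t = dec(E.concat([skip, t]), training)
        return self.final(t)


class _AttentionGate(nn.Module):
    """Additive attention gate: the coarser decoder feature gates the skip."""

    def __init__(self, cx, cg, f, rng):
        self.wg = nn.Conv2d(cg, f, k=1, rng=rng)
        self.wx = nn.Conv1x1Strided(cx, f, stride=2, rng=rng)
        self.psi = nn.Conv2d(f, 1, k=1, rng=rng)

    def __call__(self, skip, gate):
        a = E.relu(E.add(self.wg(gate), self.wx(skip)))
        m = E.sigmoid(self.psi(a))
        return E.mul(skip, E.upsample2x(m))


class AttentionUNet(UNet):
    def __init__(self, spec, rng):
        super().__init__(spec, rng)
        ws = spec.encoder_widths
        self.gates = [
            _AttentionGate(ws[i], ws[i + 1], ws[i], rng)
            for i in reversed(range(len(ws) - 1))
        ]

    def forward(self, x, training=False):
        self._check_input(x)
        t = E.Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        for i, blk in enumerate(self.enc):
            t = blk(t, training)
            if i < len(self.enc) - 1:
                skips.append(t)
                t = E.maxpool2x2(t)
        for up, dec, gate, skip in zip(
            self.ups, self.dec, self.gates, reversed(skips)
        ):
            attended = gate(skip, t)  # gate from the pre-upsample feature
            t = up(t)
            t = dec(E.concat([attended, t]), training)
        return self.final(t)


class UNetPP(SegmentationModel):
    """Nested U-Net with dense skip pathways X[i][j]."""

    def __init__(self, spec, rng):
        ws = spec.encoder_widths
        self.spec = spec
        d = len(ws)
        c = spec.in_channels
        self.enc = []
        for w in ws:
            self.enc.append(nn.DoubleConv(c, w, rng=rng))
            c = w
        # column-major order so X[i+1][j-1] is always available
        self.node_keys = [(i, j) for j in range(1, d) for i in range(d - j)]
        self.node_ups = [
            nn.ConvTranspose2x(ws[i + 1], ws[i], rng=rng) for i, j in self.node_keys
        ]
        self.node_convs = [
            nn.DoubleConv((j + 1) * ws[i], ws[i], rng=rng) for i, j in self.node_keys
        ]
        self.deep_supervision = spec.variant_params.get("deep_supervision", False)
        n_heads = d - 1 if self.deep_supervision else 1
        self.heads = [
            nn.Conv2d(ws[0], spec.n_classes, k=1, rng=rng) for _ in range(n_heads)
        ]

    def forward(self, x, training=False):
        self._check_input(x)
        t = E.Tensor(np.asarray(x, dtype=np.float32))
        d = self.spec.depth
        grid = {}
        for i, blk in enumerate(self.enc):
            t = blk(t, training)
            grid[(i, 0)] = t
            if i < d - 1:
                t = E.maxpool2x2(t)
        for (i, j), up, conv in zip(self.node_keys, self.node_ups, self.node_convs):
            upped = up(grid[(i + 1, j - 1)])
            cat = E.concat([grid[(i, jj)] for jj in range(j)] + [upped])
            grid[(i, j)] = conv(cat, training)
        if self.deep_supervision:
            outs = [h(grid[(0, j + 1)]) for j, h in enumerate(self.heads)]
            acc = outs[0]
            for o in outs[1:]:
                acc = E.add(acc, o)
            return E.mul(acc, E.Tensor(np.float32(1.0 / len(outs)).reshape(1, 1, 1, 1)))
        return self.heads[0](grid[(0, d - 1)])


class _ResBlock(nn.Module):
    """Double conv with a 1x1 projection shortcut."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.ConvBNReLU(cin, cout, rng=rng)
        self.c2 = nn.Conv2d(cout, cout, rng=rng)
        self.b2 = nn.BatchNorm2d(cout)
        self.sc = nn.Conv2d(cin, cout, k=1, rng=rng)

    def __call__(self, x, training):
        h = self.b2(self.c2(self.c1(x, training)), training)
        return E.relu(E.add(h, self.sc(x)))


class ResidualUNet(UNet):
    def __init__(self, spec, rng):
        ws = spec.encoder_widths
        self.spec = spec
        c = spec.in_channels
        self.enc = []
        for w in ws:
            self.enc.append(_ResBlock(c, w, rng))
            c = w
        self.ups = [
            nn.ConvTranspose2x(ws[i + 1], ws[i], rng=rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.dec = [
            _ResBlock(2 * ws[i], ws[i], rng) for i in reversed(range(len(ws) - 1))
        ]
        self.final = nn.Conv2d(ws[0], spec.n_classes, k=1, rng=rng)


class _InceptionBlock(nn.Module):
    """Parallel 1x1 / 3x3 / 5x5 / pooled branches, concatenated and projected."""

    def __init__(self, cin, cout, num, den, rng):
        fw = (num * cout) // den
        self.b1 = nn.Conv2d(cin, fw, k=1, rng=rng)
        self.b3 = nn.Conv2d(cin, fw, k=3, rng=rng)
        self.b5 = nn.Conv2d(cin, fw, k=5, rng=rng)
        self.bp = nn.Conv2d(cin, fw, k=1, rng=rng)
        self.proj = nn.Conv2d(4 * fw, cout, k=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x, training):
        branches = [
            self.b1(x), self.b3(x), self.b5(x), self.bp(E.avgpool3x3(x))
        ]
        return E.relu(self.bn(self.proj(E.concat(branches)), training))


class InceptionUNet(UNet):
    def __init__(self, spec, rng):
        ws = spec.encoder_widths
        num = spec.variant_params["branch_num"]
        den = spec.variant_params["branch_den"]
        self.spec = spec
        c = spec.in_channels
        self.enc = []
        for w in ws:
            self.enc.append(_InceptionBlock(c, w, num, den, rng))
            c = w
        self.ups = [
            nn.ConvTranspose2x(ws[i + 1], ws[i], rng=rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.dec = [
            _InceptionBlock(2 * ws[i], ws[i], num, den, rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.final = nn.Conv2d(ws[0], spec.n_classes, k=1, rng=rng)


class _DenseBlock(nn.Module):
    """Densely connected conv layers followed by a 1x1 transition."""

    def __init__(self, cin, cout, num, den, n_layers, rng):
        g = (num * cout) // den
        self.layers = [
            nn.ConvBNReLU(cin + layer * g, g, rng=rng) for layer in range(n_layers)
        ]
        self.trans = nn.ConvBNReLU(cin + n_layers * g, cout, k=1, rng=rng)

    def __call__(self, x, training):
        feats = [x]
        for layer in self.layers:
            cat = feats[0] if len(feats) == 1 else E.concat(feats)
            feats.append(layer(cat, training))
        return self.trans(E.concat(feats), training)


class DenseUNet(UNet):
    def __init__(self, spec, rng):
        ws = spec.encoder_widths
        vp = spec.variant_params
        args = (vp["growth_num"], vp["growth_den"], vp["layers_per_block"])
        self.spec = spec
        c = spec.in_channels
        self.enc = []
        for w in ws:
            self.enc.append(_DenseBlock(c, w, *args, rng))
            c = w
        self.ups = [
            nn.ConvTranspose2x(ws[i + 1], ws[i], rng=rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.dec = [
            _DenseBlock(2 * ws[i], ws[i], *args, rng)
            for i in reversed(range(len(ws) - 1))
        ]
        self.final = nn.Conv2d(ws[0], spec.n_classes, k=1, rng=rng)


_BUILDERS = {
    "unet": UNet,
    "wide_unet": UNet,
    "attention_unet": AttentionUNet,
    "unet_pp": UNetPP,
    "residual_unet": ResidualUNet,
    "inception_unet": InceptionUNet,
    "dense_unet": DenseUNet,
}


def build_model(spec: ArchitectureSpec, seed: int = 0) -> SegmentationModel:
    """Instantiate the network described by ``spec`` with He-initialized weights."""
    rng = np.random.default_rng(seed)
    return _BUILDERS[spec.family](spec, rng)


def save_model(model: SegmentationModel, path) -> None:
    """Persist spec + every stored array (weights and running statistics)."""
    import json

    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, spec=json.dumps(model.spec.to_dict()), **arrays)


def load_model(path) -> SegmentationModel:
    """Rebuild a model saved by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as blob:
        spec = ArchitectureSpec.from_dict(json.loads(str(blob["spec"])))
        model = build_model(spec, seed=0)
        arrays = model.state_arrays()
        keys = sorted(k for k in blob.files if k.startswith("arr_"))
        if len(keys) != len(arrays):
            raise ValueError(
                f"checkpoint has {len(keys)} arrays, model needs {len(arrays)}"
            )
        for key, target in zip(keys, arrays):
            stored = blob[key]
            if stored.shape != target.shape:
                raise ValueError(f"shape mismatch for {key}")
            target[...] = stored
    return model
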