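"""Encoder families for the outcome and occlusion classifiers.

All encoders map a (N, C, *spatial) array to a channel-major feature map.
Families:

* ``custom3d`` / ``custom2d`` — a light CNN with four conv blocks
  (8/16/32/64 filters, batch norm + ReLU, strides 1,2,1,2, cubic kernels
  of size 3 with padding 1); ~73 K parameters in 3D with one input channel.
* ``inception3d`` — four stacked 3D inception modules (parallel 1/3/5
  kernels plus a pool-projection branch, outputs concatenated), with a
  stride-2 average pool after the first module; default filter counts
  4, 16, 16, 16 per branch.
* ``resnet3d-18/34/50`` — the standard residual topology with every 2D
  convolution, batch norm and pooling operator replaced by its 3D
  equivalent (7³ stem of stride 2, 3³ max pool of stride 2, four stages).
* ``resnet2d-18/34/50`` and ``efficientnet2d-b0/b1/b2`` — 2D encoders for
  MIP images and MIL slice instances; the EfficientNet-style family uses
  MBConv blocks (depthwise separable convolutions, squeeze-excitation,
  SiLU) with the usual width/depth scaling.  Weights may be injected from
  a local file; otherwise they are randomly initialized, and can be frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

# ---------------------------------------------------------------------------
# spec + registry
# ---------------------------------------------------------------------------

FAMILIES_3D = ("custom3d", "inception3d", "resnet3d-18", "resnet3d-34", "resnet3d-50")
FAMILIES_2D = ("custom2d", "resnet2d-18", "resnet2d-34", "resnet2d-50",
               "efficientnet2d-b0", "efficientnet2d-b1", "efficientnet2d-b2")


@dataclass
class EncoderSpec:
    family: str
    in_channels: int = 1
    frozen: bool = False
    pretrained_weights: str | None = None  # local .npz path, never downloaded

    def __post_init__(self):
        if self.family not in FAMILIES_3D + FAMILIES_2D:
            raise ValueError(f"unknown encoder family {self.family!r}")

    @property
    def is_3d(self) -> bool:
        return self.family in FAMILIES_3D


def count_parameters(model: nn.Module, trainable_only: bool = True) -> int:
    """Total number of scalar parameters, by enumeration over tensors."""
    return model.num_parameters(trainable_only=trainable_only)


# ---------------------------------------------------------------------------
# custom CNN (3D and 2D variants share the layout)
# ---------------------------------------------------------------------------

def _conv_block(conv_cls, cin, cout, stride, rng, kernel=3, padding=1, bias=True):
    return [conv_cls(cin, cout, kernel, stride=stride, padding=padding,
                     bias=bias, rng=rng),
            nn.BatchNorm(cout), nn.ReLU()]


def build_custom_cnn(in_channels: int = 1, ndim: int = 3,
                     rng: np.random.Generator | None = None) -> nn.Sequential:
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    rng = rng or np.random.default_rng()
    conv = nn.Conv3d if ndim == 3 else nn.Conv2d
    layers = []
    filters = (8, 16, 32, 64)
    strides = (1, 2, 1, 2)
    cin = in_channels
    for f, s in zip(filters, strides):
        layers += _conv_block(conv, cin, f, s, rng)
        cin = f
    layers[0].skip_input_grad = True  # raw-data input: gradient unused
    enc = nn.Sequential(*layers)
    enc.out_channels = 64
    return enc


def build_custom_cnn3d(in_channels: int = 1, rng=None) -> nn.Sequential:
    return build_custom_cnn(in_channels, ndim=3, rng=rng)


def build_custom_cnn2d(in_channels: int = 1, rng=None) -> nn.Sequential:
    return build_custom_cnn(in_channels, ndim=2, rng=rng)


# ---------------------------------------------------------------------------
# inception encoder
# ---------------------------------------------------------------------------

class InceptionModule(nn.Module):
    """Parallel 1/3/5-kernel conv branches plus max-pool + 1-kernel
    projection, each with `filters` output channels, concatenated."""

    def __init__(self, in_channels: int, filters: int, ndim: int = 3, rng=None):
        super().__init__()
        if filters < 1:
            raise ValueError("filters must be positive")
        conv = nn.Conv3d if ndim == 3 else nn.Conv2d
        mk = lambda k, p: nn.Sequential(
            *(_conv_block(conv, in_channels, filters, 1, rng, kernel=k,
                          padding=p, bias=False)))
        self.b1 = mk(1, 0)
        self.b3 = mk(3, 1)
        self.b5 = mk(5, 2)
        self.bpool = nn.Sequential(
            nn.MaxPool(3, stride=1, padding=1, ndim=ndim),
            *(_conv_block(conv, in_channels, filters, 1, rng, kernel=1,
                          padding=0, bias=False)))
        self.out_channels = 4 * filters
        self._splits = filters

    def forward(self, x):
        outs = [self.b1(x), self.b3(x), self.b5(x), self.bpool(x)]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        f = self._splits
        gs = [grad[:, i * f:(i + 1) * f] for i in range(4)]
        gx = self.b1.backward(np.ascontiguousarray(gs[0]))
        for branch, g in zip((self.b3, self.b5, self.bpool), gs[1:]):
            gx = gx + branch.backward(np.ascontiguousarray(g))
        return gx


def build_inception_encoder3d(filters_per_im=(4, 16, 16, 16), in_channels: int = 1,
                              rng=None) -> nn.Sequential:
    filters_per_im = tuple(filters_per_im)
    if len(filters_per_im) != 4 or any(f < 1 for f in filters_per_im):
        raise ValueError("filters_per_im must be four positive counts")
    rng = rng or np.random.default_rng()
    layers = [InceptionModule(in_channels, filters_per_im[0], rng=rng),
              nn.AvgPool(2, stride=2, ndim=3)]
    cin = 4 * filters_per_im[0]
    for f in filters_per_im[1:]:
        layers.append(InceptionModule(cin, f, rng=rng))
        cin = 4 * f
    enc = nn.Sequential(*layers)
    enc.out_channels = cin
    return enc


# ---------------------------------------------------------------------------
# ResNets (ndim-generic)
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, cin, cout, stride, ndim, rng):
        super().__init__()
        conv = nn.Conv3d if ndim == 3 else nn.Conv2d
        self.main = nn.Sequential(
            conv(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng),
            nn.BatchNorm(cout), nn.ReLU(),
            conv(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng),
            nn.BatchNorm(cout))
        self.shortcut = None
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                conv(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm(cout))
        self.relu = nn.ReLU()

    def forward(self, x):
        out = self.main(x)
        sc = x if self.shortcut is None else self.shortcut(x)
        return self.relu(out + sc)

    def backward(self, grad):
        g = self.relu.backward(grad)
        gx = self.main.backward(g)
        gsc = g if self.shortcut is None else self.shortcut.backward(g)
        return gx + gsc


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin, cout, stride, ndim, rng):
        super().__init__()
        conv = nn.Conv3d if ndim == 3 else nn.Conv2d
        self.main = nn.Sequential(
            conv(cin, cout, 1, bias=False, rng=rng), nn.BatchNorm(cout), nn.ReLU(),
            conv(cout, cout, 3, stride=stride, padding=1, bias=False, rng=rng),
            nn.BatchNorm(cout), nn.ReLU(),
            conv(cout, cout * 4, 1, bias=False, rng=rng), nn.BatchNorm(cout * 4))
        self.shortcut = None
        if stride != 1 or cin != cout * 4:
            self.shortcut = nn.Sequential(
                conv(cin, cout * 4, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm(cout * 4))
        self.relu = nn.ReLU()

    forward = _BasicBlock.forward
    backward = _BasicBlock.backward


_RESNET_LAYOUT = {
    18: (_BasicBlock, (2, 2, 2, 2)),
    34: (_BasicBlock, (3, 4, 6, 3)),
    50: (_Bottleneck, (3, 4, 6, 3)),
}


def build_resnet(depth: int, in_channels: int = 1, ndim: int = 3,
                 rng=None) -> nn.Sequential:
    if depth not in _RESNET_LAYOUT:
        raise ValueError(f"unsupported ResNet depth {depth}")
    rng = rng or np.random.default_rng()
    block_cls, blocks = _RESNET_LAYOUT[depth]
    conv = nn.Conv3d if ndim == 3 else nn.Conv2d
    layers = [conv(in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng),
              nn.BatchNorm(64), nn.ReLU(),
              nn.MaxPool(3, stride=2, padding=1, ndim=ndim)]
    layers[0].skip_input_grad = True  # raw-data input: gradient unused
    cin = 64
    for stage, (width, n_blocks) in enumerate(zip((64, 128, 256, 512), blocks)):
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(block_cls(cin, width, stride, ndim, rng))
            cin = width * block_cls.expansion
    enc = nn.Sequential(*layers)
    enc.out_channels = cin
    return enc


def build_resnet3d(depth: int, in_channels: int = 1, rng=None) -> nn.Sequential:
    return build_resnet(depth, in_channels, ndim=3, rng=rng)


# ---------------------------------------------------------------------------
# EfficientNet-style 2D encoder
# ---------------------------------------------------------------------------

class _MBConv(nn.Module):
    def __init__(self, cin, cout, kernel, stride, expand, rng):
        super().__init__()
        mid = cin * expand
        layers = []
        if expand != 1:
            layers += [nn.Conv2d(cin, mid, 1, bias=False, rng=rng),
                       nn.BatchNorm(mid), nn.SiLU()]
        layers += [nn.Conv2d(mid, mid, kernel, stride=stride, padding=kernel // 2,
                             groups=mid, bias=False, rng=rng),
                   nn.BatchNorm(mid), nn.SiLU(),
                   nn.SEBlock(mid, reduction=4 * expand, rng=rng),
                   nn.Conv2d(mid, cout, 1, bias=False, rng=rng),
                   nn.BatchNorm(cout)]
        self.body = nn.Sequential(*layers)
        self.residual = stride == 1 and cin == cout

    def forward(self, x):
        out = self.body(x)
        return out + x if self.residual else out

    def backward(self, grad):
        gx = self.body.backward(grad)
        return gx + grad if self.residual else gx


_EFFNET_BASE = [  # (expand, channels, repeats, stride, kernel)
    (1, 16, 1, 1, 3), (6, 24, 2, 2, 3), (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3), (6, 112, 3, 1, 5), (6, 192, 4, 2, 5), (6, 320, 1, 1, 3)]
_EFFNET_SCALE = {"b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2)}


def _round_ch(c, width):
    c *= width
    new = max(8, int(c + 4) // 8 * 8)
    if new < 0.9 * c:
        new += 8
    return int(new)


def build_efficientnet2d(variant: str = "b0", in_channels: int = 3,
                         rng=None) -> nn.Sequential:
    if variant not in _EFFNET_SCALE:
        raise ValueError(f"unsupported EfficientNet variant {variant!r}")
    rng = rng or np.random.default_rng()
    width, depth = _EFFNET_SCALE[variant]
    stem = _round_ch(32, width)
    layers = [nn.Conv2d(in_channels, stem, 3, stride=2, padding=1, bias=False,
                        rng=rng), nn.BatchNorm(stem), nn.SiLU()]
    layers[0].skip_input_grad = True  # raw-data input: gradient unused
    cin = stem
    for expand, ch, reps, stride, kernel in _EFFNET_BASE:
        cout = _round_ch(ch, width)
        for r in range(int(np.ceil(reps * depth))):
            layers.append(_MBConv(cin, cout, kernel, stride if r == 0 else 1,
                                  expand, rng))
            cin = cout
    head = _round_ch(1280, width)
    layers += [nn.Conv2d(cin, head, 1, bias=False, rng=rng),
               nn.BatchNorm(head), nn.SiLU()]
    enc = nn.Sequential(*layers)
    enc.out_channels = head
    return enc


# ---------------------------------------------------------------------------
# spec-driven construction
# ---------------------------------------------------------------------------

def build_encoder(spec: EncoderSpec, rng=None) -> nn.Sequential:
    """Build any registered encoder family from its spec; optionally load
    weights from a local npz file and/or freeze."""
    fam = spec.family
    if fam == "custom3d":
        enc = build_custom_cnn3d(spec.in_channels, rng=rng)
    elif fam == "custom2d":
        enc = build_custom_cnn2d(spec.in_channels, rng=rng)
    elif fam == "inception3d":
        enc = build_inception_encoder3d(in_channels=spec.in_channels, rng=rng)
    elif fam.startswith("resnet3d"):
        enc = build_resnet(int(fam.split("-")[1]), spec.in_channels, ndim=3, rng=rng)
    elif fam.startswith("resnet2d"):
        enc = build_resnet(int(fam.split("-")[1]), spec.in_channels, ndim=2, rng=rng)
    elif fam.startswith("efficientnet2d"):
        enc = build_efficientnet2d(fam.split("-")[1], spec.in_channels, rng=rng)
    else:  # pragma: no cover - guarded by EncoderSpec
        raise ValueError(fam)
    if spec.pretrained_weights is not None:
        data = np.load(spec.pretrained_weights)
        enc.load_state([data[k] for k in sorted(data.files, key=lambda s: int(s))])
    if spec.frozen:
        enc.freeze()
    return enc


def build_2d_encoder(spec: EncoderSpec, rng=None) -> nn.Sequential:
    if spec.is_3d:
        raise ValueError(f"{spec.family} is not a 2D encoder family")
    return build_encoder(spec, rng=rng)
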