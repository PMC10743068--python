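"""Classifier assembly: whole-volume baselines, hemisphere-Siamese mergers,
MIL slice-bag models and MIP occlusion classifiers.

Every classifier ends in a linear layer with one output unit followed by a
sigmoid, so outputs are probabilities in (0, 1).  Weight-shared Siamese
branches are evaluated by concatenating the two branches along the batch
axis through a single encoder pass, which keeps the explicit
forward/backward caches valid and shares every weight exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoders import EncoderSpec, build_encoder
from .volume import SliceBag

ARCHITECTURES = ("baseline", "baseline_mirror", "siamese_after", "siamese_before",
                 "siamese_tangle", "mil", "occlusion_single",
                 "occlusion_siamese_flip", "occlusion_siamese_hemi",
                 "occlusion_siamese_after")


@dataclass
class ClassifierSpec:
    architecture: str
    encoder: EncoderSpec
    pooling: str = "GMP"          # GMP or GAP
    mil_sigma: str | None = None  # mean | max | attention, for mil only

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.pooling not in ("GMP", "GAP"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if (self.mil_sigma is not None) != (self.architecture == "mil"):
            raise ValueError("mil_sigma must be given exactly for the mil architecture")
        if self.mil_sigma not in (None, "mean", "max", "attention"):
            raise ValueError(f"unknown MIL aggregator {self.mil_sigma!r}")


def _pool_mode(pooling: str) -> str:
    return "max" if pooling == "GMP" else "avg"


class _Head(nn.Module):
    """linear(features -> 1) + sigmoid."""

    def __init__(self, in_features: int, rng=None):
        super().__init__()
        self.linear = nn.Linear(in_features, 1, rng=rng)
        self.sigmoid = nn.Sigmoid()

    def forward(self, x):
        return self.sigmoid(self.linear(x))[:, 0]

    def backward(self, grad):
        return self.linear.backward(self.sigmoid.backward(grad[:, None]))


class _Classifier(nn.Module):
    """Common predict helper plus frozen-encoder handling: a frozen encoder
    always runs in eval mode (fixed batch-norm statistics, no caches kept
    for it during training) and its backward pass is skipped."""

    def _encode(self, x):
        if self.encoder.frozen and self.encoder.training:
            self.encoder.eval()
        return self.encoder(x)

    def _encoder_backward(self, g):
        if self.encoder.frozen:
            return None
        return self.encoder.backward(g)

    def predict_proba(self, inputs) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            if isinstance(inputs, np.ndarray):
                return np.asarray(self.forward(inputs), dtype=np.float64)
            return np.array([self.forward(x).item() for x in inputs])
        finally:
            self.train(was_training)


# ---------------------------------------------------------------------------
# whole-volume baselines
# ---------------------------------------------------------------------------

class BaselineClassifier(_Classifier):
    """encoder -> global pool -> linear(1) -> sigmoid.  With
    ``mirror_input`` the forward subtracts the MSP-mirrored volume first
    (the Baseline-Mirror variant): the model then sees an anti-symmetric
    input that is all-zero for a perfectly symmetric brain."""

    def __init__(self, encoder: nn.Module, pooling: str = "GMP",
                 mirror_input: bool = False, rng=None):
        super().__init__()
        self.encoder = encoder
        self.pool = nn.GlobalPool(_pool_mode(pooling))
        self.head = _Head(encoder.out_channels, rng=rng)
        self.mirror_input = mirror_input

    def forward(self, x):
        if x.ndim != 5:
            raise ValueError("expected a (N, 1, LR, PA, IS) batch")
        if self.mirror_input:
            x = x - x[:, :, ::-1]
        return self.head(self.pool(self._encode(x)))

    def backward(self, grad):
        g = self.pool.backward(self.head.backward(grad))
        gx = self._encoder_backward(g)
        if self.mirror_input and gx is not None:
            gx = gx - gx[:, :, ::-1]
        return gx


# ---------------------------------------------------------------------------
# hemisphere-Siamese variants
# ---------------------------------------------------------------------------

def _split_lr(x):
    """Split a (N, C, LR, ...) batch at the MSP along the LR axis; the right
    half is mirrored so homologous voxels share indices.  Odd extents drop
    the central plane."""
    n = x.shape[2]
    if n < 3:
        raise ValueError("LR extent too small to split")
    h = n // 2 if n % 2 == 0 else (n - 1) // 2
    left = x[:, :, :h]
    right = x[:, :, ::-1][:, :, :h]
    return np.ascontiguousarray(left), np.ascontiguousarray(right)


class SiameseClassifier(_Classifier):
    """Weight-shared hemisphere encoder with one of three mergers.

    * ``after``  — |pool(E(L)) − pool(E(R))| on pooled feature vectors;
    * ``before`` — |E(L) − E(R)| element-wise on the feature maps, then an
      optional post-merge trunk, then pooling;
    * ``tangle`` — channel-interleave E(L), E(R) into pairs and compare
      with a learned grouped convolution (groups = channels), then pool.
    """

    def __init__(self, encoder: nn.Module, merge: str, pooling: str = "GMP",
                 trunk: nn.Module | None = None, rng=None, split_fn=_split_lr):
        super().__init__()
        if merge not in ("after", "before", "tangle"):
            raise ValueError(f"unknown merge {merge!r}")
        self.encoder = encoder
        self.merge = merge
        self.split_fn = split_fn
        self.pool = nn.GlobalPool(_pool_mode(pooling))
        feat = encoder.out_channels
        if merge == "tangle":
            c = encoder.out_channels
            self.tangle = nn.Sequential(
                nn.Conv(2 * c, c, 3, ndim=3, padding=1, groups=c, rng=rng),
                nn.BatchNorm(c), nn.ReLU())
            feat = c
        if merge == "before" and trunk is not None:
            self.trunk = trunk
            feat = trunk.out_channels
        else:
            self.trunk = None
        self.head = _Head(feat, rng=rng)

    def forward(self, x):
        left, right = self.split_fn(x)
        n = left.shape[0]
        fm = self._encode(np.concatenate([left, right], axis=0))
        fl, fr = fm[:n], fm[n:]
        if self.merge == "after":
            pl = self.pool(np.concatenate([fl, fr], axis=0))
            merged = np.abs(pl[:n] - pl[n:])
            self._cache = (np.sign(pl[:n] - pl[n:]), None)
            return self.head(merged)
        if self.merge == "before":
            diff = fl - fr
            merged = np.abs(diff)
            self._cache = (np.sign(diff), None)
            if self.trunk is not None:
                merged = self.trunk(merged)
            return self.head(self.pool(merged))
        # tangle: interleave channels pairwise -> grouped conv comparison
        nch = fl.shape[1]
        inter = np.empty((n, 2 * nch) + fl.shape[2:], dtype=fl.dtype)
        inter[:, 0::2] = fl
        inter[:, 1::2] = fr
        self._cache = (None, nch)
        return self.head(self.pool(self.tangle(inter)))

    def backward(self, grad):
        sign, nch = self._cache
        g = self.head.backward(grad)
        if self.merge == "after":
            gm = g * sign  # d|a-b| : +g to a, -g to b
            gp = self.pool.backward(np.concatenate([gm, -gm], axis=0))
            return self._enc_backward(gp)
        if self.merge == "before":
            g = self.pool.backward(g)
            if self.trunk is not None:
                g = self.trunk.backward(g)
            gm = g * sign
            return self._enc_backward(np.concatenate([gm, -gm], axis=0))
        g = self.tangle.backward(self.pool.backward(g))
        gl = np.ascontiguousarray(g[:, 0::2])
        gr = np.ascontiguousarray(g[:, 1::2])
        return self._enc_backward(np.concatenate([gl, gr], axis=0))

    def _enc_backward(self, g):
        return self._encoder_backward(g)


# ---------------------------------------------------------------------------
# MIL
# ---------------------------------------------------------------------------

class AttentionPooling(nn.Module):
    """Gated-softmax MIL attention: a_k ∝ exp(wᵀ tanh(V h_k)); returns
    Σ a_k h_k.  With w = 0 the weights are uniform and the aggregation
    reduces to mean pooling (a weighted mean)."""

    def __init__(self, in_features: int, hidden_dim: int = 64, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.V = nn.Param(rng.normal(0, np.sqrt(2.0 / in_features),
                                     (hidden_dim, in_features)))
        self.w = nn.Param(rng.normal(0, np.sqrt(1.0 / hidden_dim), hidden_dim))

    def weights(self, h: np.ndarray) -> np.ndarray:
        """Attention weights a (K,) for instance features h (K, F)."""
        t = np.tanh(h @ self.V.data.T)           # (K, H)
        s = t @ self.w.data                      # (K,)
        s = s - s.max()
        e = np.exp(s)
        return e / e.sum()

    def forward(self, h):
        t = np.tanh(h @ self.V.data.T)
        s = t @ self.w.data
        s = s - s.max()
        e = np.exp(s)
        a = e / e.sum()
        out = a @ h                              # (F,)
        if self.training:
            self._cache = (h, t, a)
        return out[None, :].astype(np.float32)   # (1, F)

    def backward(self, grad):
        h, t, a = self._cache
        g = grad[0]                              # (F,)
        # out = sum_k a_k h_k
        gh = a[:, None] * g[None, :]             # direct path
        ga = h @ g                               # (K,)
        # softmax backward
        gs = a * (ga - float(a @ ga))            # (K,)
        # s_k = w . tanh(V h_k)
        self.w.grad += t.T @ gs
        gt = gs[:, None] * self.w.data[None, :]  # (K, H)
        gpre = gt * (1.0 - t * t)
        self.V.grad += gpre.T @ h
        gh += gpre @ self.V.data
        return gh.astype(np.float32)


def mil_aggregate(instance_features: np.ndarray, sigma: str,
                  params: AttentionPooling | None = None) -> np.ndarray:
    """Permutation-invariant bag aggregation of (K, F) instance features."""
    h = np.asarray(instance_features)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("need a non-empty (K, F) feature array")
    if sigma == "mean":
        return h.mean(axis=0)
    if sigma == "max":
        return h.max(axis=0)
    if sigma == "attention":
        if params is None:
            raise ValueError("attention aggregation needs AttentionPooling params")
        return params.weights(h) @ h
    raise ValueError(f"unknown MIL aggregator {sigma!r}")


class _MeanMaxAgg(nn.Module):
    def __init__(self, mode: str):
        super().__init__()
        self.mode = mode

    def forward(self, h):
        if self.mode == "mean":
            out = h.mean(axis=0, keepdims=True)
            if self.training:
                self._cache = (h.shape, None)
        else:
            arg = h.argmax(axis=0)
            out = h.max(axis=0, keepdims=True)
            if self.training:
                self._cache = (h.shape, arg)
        return out.astype(np.float32)

    def backward(self, grad):
        shape, arg = self._cache
        if self.mode == "mean":
            return np.broadcast_to(grad / shape[0], shape).astype(np.float32).copy()
        gh = np.zeros(shape, dtype=np.float32)
        gh[arg, np.arange(shape[1])] = grad[0]
        return gh


class MILClassifier(_Classifier):
    """Instance encoder -> per-instance global pooling -> bag aggregation
    (mean / max / attention) -> linear(1) + sigmoid.  The input is one bag:
    a (K, C, rows, cols) array or a SliceBag."""

    def __init__(self, encoder: nn.Module, sigma: str, pooling: str = "GAP",
                 attention_hidden: int = 64, rng=None):
        super().__init__()
        self.encoder = encoder
        self.sigma = sigma
        self.pool = nn.GlobalPool(_pool_mode(pooling))
        feat = encoder.out_channels
        if sigma == "attention":
            self.agg = AttentionPooling(feat, attention_hidden, rng=rng)
        elif sigma in ("mean", "max"):
            self.agg = _MeanMaxAgg(sigma)
        else:
            raise ValueError(f"unknown MIL aggregator {sigma!r}")
        self.head = _Head(feat, rng=rng)

    def _bag_array(self, bag):
        arr = bag.as_array() if isinstance(bag, SliceBag) else np.asarray(bag)
        if arr.ndim != 4 or arr.shape[0] < 1:
            raise ValueError("a bag must be a non-empty (K, C, rows, cols) array")
        if arr.shape[1] != self.encoder.layers[0].in_channels:
            arr = np.repeat(arr, self.encoder.layers[0].in_channels, axis=1)
        return arr.astype(np.float32)

    def instance_features(self, bag) -> np.ndarray:
        return self.pool(self._encode(self._bag_array(bag)))

    def forward(self, bag):
        h = self.instance_features(bag)
        return self.head(self.agg(h))

    def backward(self, grad):
        gh = self.agg.backward(self.head.backward(np.atleast_1d(grad)))
        return self._encoder_backward(self.pool.backward(gh))


def slice_importance(model: MILClassifier, bag) -> np.ndarray:
    """Per-slice importance profile, aligned with the bag's kept_indices.

    * attention models — the attention weight a_k of each slice (sums to 1);
    * max models — the fraction of feature dimensions whose bag-level max
      came from slice k, with exact ties splitting the count equally.
    """
    if model.sigma == "mean":
        raise ValueError("slice importance is undefined for mean aggregation")
    was_training = model.training
    model.eval()
    try:
        h = model.instance_features(bag)
    finally:
        model.train(was_training)
    if model.sigma == "attention":
        return model.agg.weights(h).astype(np.float64)
    is_max = h == h.max(axis=0, keepdims=True)
    share = is_max / is_max.sum(axis=0, keepdims=True)
    return (share.sum(axis=1) / h.shape[1]).astype(np.float64)


# ---------------------------------------------------------------------------
# occlusion-from-MIP classifiers
# ---------------------------------------------------------------------------

class OcclusionClassifier(_Classifier):
    """Occlusion detectors on a single axial MIP image (N, C, PA, LR).

    Variants: ``single`` — plain encoder + pooling + head;
    ``siamese_flip`` — whole image vs its left-right flip, |diff| of the
    feature maps before pooling; ``siamese_hemi`` — the MIP cut at the
    midline, per-hemisphere branches, |diff| before pooling;
    ``siamese_after`` — whole image vs flip, |diff| of pooled vectors.
    """

    def __init__(self, encoder: nn.Module, variant: str, pooling: str = "GMP",
                 rng=None):
        super().__init__()
        if variant not in ("single", "siamese_flip", "siamese_hemi", "siamese_after"):
            raise ValueError(f"unknown occlusion variant {variant!r}")
        self.encoder = encoder
        self.variant = variant
        self.pool = nn.GlobalPool(_pool_mode(pooling))
        self.head = _Head(encoder.out_channels, rng=rng)

    def _branches(self, x):
        if self.variant == "siamese_hemi":
            # columns are LR; exact halves (even width), mirrored alignment
            w = x.shape[3]
            h = w // 2
            a = x[:, :, :, :h]
            b = x[:, :, :, ::-1][:, :, :, :h]
        else:
            a = x
            b = x[:, :, :, ::-1]
        return np.ascontiguousarray(a), np.ascontiguousarray(b)

    def forward(self, x):
        if x.ndim != 4:
            raise ValueError("expected a (N, C, rows, cols) batch of MIP images")
        c_expect = self.encoder.layers[0].in_channels
        if x.shape[1] != c_expect:
            x = np.repeat(x, c_expect, axis=1)
        if self.variant == "single":
            return self.head(self.pool(self._encode(x)))
        a, b = self._branches(x)
        n = a.shape[0]
        fm = self._encode(np.concatenate([a, b], axis=0))
        if self.variant == "siamese_after":
            p = self.pool(fm)
            merged = np.abs(p[:n] - p[n:])
            self._sign = np.sign(p[:n] - p[n:])
            return self.head(merged)
        diff = fm[:n] - fm[n:]
        self._sign = np.sign(diff)
        return self.head(self.pool(np.abs(diff)))

    def merged_features(self, x) -> np.ndarray:
        """The post-merge representation (before the head), for invariant
        inspection; eval mode."""
        was_training = self.training
        self.eval()
        try:
            c_expect = self.encoder.layers[0].in_channels
            if x.shape[1] != c_expect:
                x = np.repeat(x, c_expect, axis=1)
            if self.variant == "single":
                return self.pool(self.encoder(x))
            a, b = self._branches(x)
            n = a.shape[0]
            fm = self._encode(np.concatenate([a, b], axis=0))
            if self.variant == "siamese_after":
                p = self.pool(fm)
                return np.abs(p[:n] - p[n:])
            return np.abs(fm[:n] - fm[n:])
        finally:
            self.train(was_training)

    def backward(self, grad):
        g = self.head.backward(grad)
        if self.variant == "single":
            return self._encoder_backward(self.pool.backward(g))
        if self.variant == "siamese_after":
            gm = g * self._sign
            gp = self.pool.backward(np.concatenate([gm, -gm], axis=0))
            return self._encoder_backward(gp)
        gm = self.pool.backward(g) * self._sign
        return self._encoder_backward(np.concatenate([gm, -gm], axis=0))


# ---------------------------------------------------------------------------
# spec-driven assembly
# ---------------------------------------------------------------------------

def assemble(spec: ClassifierSpec, rng=None, **kwargs) -> _Classifier:
    """Build any classifier from its spec (encoder + merge + pooling +
    linear-sigmoid head)."""
    rng = rng if rng is not None else np.random.default_rng()
    arch = spec.architecture
    if arch in ("baseline", "baseline_mirror"):
        if not spec.encoder.is_3d:
            raise ValueError("baseline classifiers need a 3D encoder")
        enc = build_encoder(spec.encoder, rng=rng)
        return BaselineClassifier(enc, spec.pooling,
                                  mirror_input=arch == "baseline_mirror", rng=rng)
    if arch.startswith("siamese"):
        if not spec.encoder.is_3d:
            raise ValueError("hemisphere-Siamese classifiers need a 3D encoder")
        enc = build_encoder(spec.encoder, rng=rng)
        if (arch == "siamese_before" and spec.encoder.family == "inception3d"
                and "trunk" not in kwargs):
            # post-merge comparison trunk: two further inception modules
            from .encoders import InceptionModule
            trunk = nn.Sequential(InceptionModule(enc.out_channels, 16, rng=rng),
                                  InceptionModule(64, 16, rng=rng))
            trunk.out_channels = 64
            kwargs["trunk"] = trunk
        return SiameseClassifier(enc, arch.split("_")[1], spec.pooling,
                                 rng=rng, **kwargs)
    if arch == "mil":
        if spec.encoder.is_3d:
            raise ValueError("MIL classifiers need a 2D instance encoder")
        enc = build_encoder(spec.encoder, rng=rng)
        return MILClassifier(enc, spec.mil_sigma, spec.pooling, rng=rng, **kwargs)
    if arch.startswith("occlusion"):
        if spec.encoder.is_3d:
            raise ValueError("occlusion classifiers need a 2D encoder")
        enc = build_encoder(spec.encoder, rng=rng)
        variant = arch.removeprefix("occlusion_")
        return OcclusionClassifier(enc, variant, spec.pooling, rng=rng)
    raise ValueError(arch)  # pragma: no cover


def global_pool(feature_map: np.ndarray, mode: str) -> np.ndarray:
    """Pool a single (C, *spatial) feature map (1-3 spatial axes) to a
    per-channel vector; mode is GMP (max) or GAP (mean)."""
    fm = np.asarray(feature_map)
    if fm.ndim < 2 or fm.ndim > 4:
        raise ValueError("feature map must be (C, *spatial) with 1-3 spatial axes")
    flat = fm.reshape(fm.shape[0], -1)
    if flat.shape[1] == 0:
        raise ValueError("feature map has an empty spatial extent")
    if mode == "GMP":
        return flat.max(axis=1)
    if mode == "GAP":
        return flat.mean(axis=1)
    raise ValueError(f"unknown pooling mode {mode!r}")
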