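"""Network blocks and assembly of the pear detector and its ablation variants.

The detector is a one-stage CSP-Darknet backbone + path-aggregation (PANet)
neck + three-scale anchor head, in the small ("s") configuration: depth
multiple 0.33, width multiple 0.50.  On top of the stock wiring, four
variants progressively add the collaboration-perception modifications:

``baseline``
    stock backbone/PANet/head.
``SC``
    two parameter-free skip connections (stride-2 max-pool) that carry
    pre-fusion feature maps past the feature-extraction CSP blocks: one into
    the medium-resolution fusion point (bypassing one CSP2) and one into the
    low-resolution fusion point (bypassing, transitively, two CSP2s).
``TE``
    SC wiring, with the CSP2 of the low-resolution neck path (P3, stride 32)
    replaced by a transformer encoder (1x1 channel reduction + multi-head
    self-attention + convolutional feed-forward).
``TC``
    SC wiring, with the CSP2 of the medium-resolution path (P2, stride 16)
    replaced by CSP-FF: parallel convolutional and transformer paths fused
    by attentional feature fusion (AFF).
``FP``
    all of the above.

The neck paths are named after their resolution: P1 = stride 8 (high
resolution), P2 = stride 16, P3 = stride 32.

The model is assembled as an explicit layer table (module, input indices),
so tests can inspect the computation graph — e.g. count how many
feature-extraction modules a skip connection bypasses.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import yaml

from . import nn
from .nn import Module, Tensor

__all__ = [
    "ModelConfig", "Focus", "CBS", "CSP", "SPP", "TransformerEncoder",
    "AFF", "CSPFF", "Detector", "build_model", "count_params_flops",
    "VARIANTS", "COCO_ANCHORS",
]

VARIANTS = ("baseline", "SC", "TE", "TC", "FP")

# stock anchor priors (pixel w, h) per scale, defined at a 640-pixel input
COCO_ANCHORS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((10, 13), (16, 30), (33, 23)),        # stride 8
    ((30, 61), (62, 45), (59, 119)),       # stride 16
    ((116, 90), (156, 198), (373, 326)),   # stride 32
)


@dataclasses.dataclass
class ModelConfig:
    """Detector hyperparameters and ablation switch.

    ``anchors`` are given in pixels at ``anchor_ref_size`` (640); they are
    rescaled proportionally when ``input_size`` differs.
    """

    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    variant: str = "baseline"
    num_classes: int = 1
    input_size: int = 640
    te_heads: int = 4
    te_dropout: float = 0.1
    anchors: tuple = COCO_ANCHORS
    anchor_ref_size: int = 640
    n_residual_units: int | None = None  # override backbone CSP1 depth

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValueError("depth/width multiples must be positive")
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    # -- derived quantities -------------------------------------------------
    def width(self, c: int) -> int:
        """Channel count after the width multiple (divisible by 8)."""
        return max(int(math.ceil(c * self.width_multiple / 8)) * 8, 8)

    def depth(self, n: int) -> int:
        if self.n_residual_units is not None:
            n = self.n_residual_units
        return max(round(n * self.depth_multiple), 1)

    def scaled_anchors(self) -> np.ndarray:
        """Anchors in pixels at the configured input size, (3, 3, 2)."""
        s = self.input_size / self.anchor_ref_size
        return np.asarray(self.anchors, dtype=np.float64) * s

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["anchors"] = [[list(a) for a in scale] for scale in self.anchors]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        if "anchors" in d:
            d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in d["anchors"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


class CBS(Module):
    """Convolution + batch norm + SiLU, the elementary unit of the network."""

    def __init__(self, c1, c2, k=1, s=1, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Focus(Module):
    """Space-to-depth entry block: 2x2 pixel phases stacked on channels,
    then a convolution.  Lossless rearrangement before the conv."""

    def __init__(self, c1, c2, k=3, *, rng):
        super().__init__()
        self.conv = CBS(c1 * 4, c2, k, 1, rng=rng)

    @staticmethod
    def space_to_depth(x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"focus block requires even spatial size, got {h}x{w}")
        return nn.concat([x[..., ::2, ::2], x[..., 1::2, ::2],
                          x[..., ::2, 1::2], x[..., 1::2, 1::2]], axis=1)

    def forward(self, x):
        return self.conv(self.space_to_depth(x))


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=1.0, *, rng):
        super().__init__()
        c_ = max(int(c2 * e), 8)
        self.cv1 = CBS(c1, c_, 1, 1, rng=rng)
        self.cv2 = CBS(c_, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class CSP(Module):
    """Cross-stage-partial block: a feature-extraction path (``n``
    bottlenecks) and a cross-stage path, concatenated then mixed.  With
    ``shortcut=True`` the bottlenecks carry residual units (CSP1, backbone);
    with ``shortcut=False`` they do not (CSP2, neck)."""

    def __init__(self, c1, c2, n=1, shortcut=True, *, rng):
        super().__init__()
        if n < 1:
            raise ValueError("CSP requires n >= 1")
        c_ = c2 // 2
        self.cv1 = CBS(c1, c_, 1, 1, rng=rng)
        self.cv2 = CBS(c1, c_, 1, 1, rng=rng)
        self.cv3 = CBS(2 * c_, c2, 1, 1, rng=rng)
        self.m = [Bottleneck(c_, c_, shortcut, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


class SPP(Module):
    """Spatial pyramid pooling: identity plus three same-size max pools."""

    def __init__(self, c1, c2, kernels=(5, 9, 13), *, rng):
        super().__init__()
        c_ = c1 // 2
        self.kernels = kernels
        self.cv1 = CBS(c1, c_, 1, 1, rng=rng)
        self.cv2 = CBS(c_ * (len(kernels) + 1), c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        pools = [nn.max_pool2d(y, k, 1, k // 2) for k in self.kernels]
        return self.cv2(nn.concat([y] + pools, axis=1))


class MultiHeadSelfAttention(Module):
    """Spatial self-attention over flattened grid cells (no positional
    encoding, so the sublayer is equivariant to spatial permutation)."""

    def __init__(self, c, heads, *, rng):
        super().__init__()
        if c % heads:
            raise ValueError(
                f"channel count {c} not divisible by {heads} heads")
        self.heads = heads
        self.qkv = nn.Linear(c, 3 * c, rng=rng)
        self.proj = nn.Linear(c, c, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hd, dh = self.heads, c // self.heads
        t = x.reshape(n, c, h * w).transpose(0, 2, 1)        # tokens (n, hw, c)
        qkv = self.qkv(t).reshape(n, h * w, 3, hd, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                     # (n, hd, hw, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = att.softmax(axis=-1)
        o = (att @ v).transpose(0, 2, 1, 3).reshape(n, h * w, c)
        return self.proj(o).transpose(0, 2, 1).reshape(n, c, h, w)


class TransformerEncoder(Module):
    """Shape-preserving encoder block: multi-head self-attention sublayer
    followed by a convolutional feed-forward sublayer (two pointwise convs,
    expansion 4), each with a residual connection, batch-norm pre-applied,
    and dropout after the transform."""

    def __init__(self, c, heads=4, dropout=0.1, expansion=4, *, rng):
        super().__init__()
        self.dropout_p = dropout
        self.norm1 = nn.BatchNorm2d(c)
        self.attn = MultiHeadSelfAttention(c, heads, rng=rng)
        self.norm2 = nn.BatchNorm2d(c)
        self.ff1 = nn.Conv2d(c, c * expansion, 1, rng=rng)
        self.ff2 = nn.Conv2d(c * expansion, c, 1, rng=rng)
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        a = self.attn(self.norm1(x))
        x = x + nn.dropout(a, self.dropout_p, self._rng, self.training)
        f = self.ff2(self.ff1(self.norm2(x)).silu())
        return x + nn.dropout(f, self.dropout_p, self._rng, self.training)


class AFF(Module):
    """Attentional feature fusion of two same-shape maps X (convolutional,
    small receptive field) and Y (transformer, large receptive field):

        out = M(X + Y) * X + (1 - M(X + Y)) * Y

    where M is a sigmoid multi-scale channel attention: a global branch
    (spatial average pool -> pointwise bottleneck) plus a local branch
    (pointwise bottleneck at full resolution), summed before the sigmoid.
    The output is an elementwise convex combination of X and Y."""

    def __init__(self, c, reduction=4, *, rng):
        super().__init__()
        c_ = max(c // reduction, 4)
        self.local1 = CBS(c, c_, 1, 1, rng=rng)
        self.local2 = nn.Conv2d(c_, c, 1, bias=False, rng=rng)
        self.local_bn = nn.BatchNorm2d(c)
        self.glob1 = CBS(c, c_, 1, 1, rng=rng)
        self.glob2 = nn.Conv2d(c_, c, 1, bias=False, rng=rng)
        self.glob_bn = nn.BatchNorm2d(c)

    def attention(self, z: Tensor) -> Tensor:
        local = self.local_bn(self.local2(self.local1(z)))
        g = z.mean(axis=(2, 3), keepdims=True)
        glob = self.glob_bn(self.glob2(self.glob1(g)))
        return (local + glob).sigmoid()

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape != y.shape:
            raise ValueError(f"AFF shape mismatch: {x.shape} vs {y.shape}")
        m = self.attention(x + y)
        return m * x + (1.0 - m) * y


class CSPFF(Module):
    """Feature-fusion CSP: the two parallel paths of a CSP2 become a
    convolutional path (local features) and a transformer-encoder path
    (global features), fused by AFF, then a 1x1 channel-balancing conv."""

    def __init__(self, c1, c2, heads=4, dropout=0.1, *, rng):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = CBS(c1, c_, 1, 1, rng=rng)          # conv path entry
        self.cv2 = CBS(c1, c_, 1, 1, rng=rng)          # transformer path entry
        self.conv_path = Bottleneck(c_, c_, shortcut=False, rng=rng)
        self.te_path = TransformerEncoder(c_, heads, dropout, rng=rng)
        self.fuse = AFF(c_, rng=rng)
        self.cv3 = CBS(c_, c2, 1, 1, rng=rng)

    def forward(self, x):
        local = self.conv_path(self.cv1(x))
        glob = self.te_path(self.cv2(x))
        return self.cv3(self.fuse(local, glob))


class Upsample(Module):
    def forward(self, x):
        return nn.upsample_nearest2x(x)


class Concat(Module):
    def forward(self, xs):
        return nn.concat(xs, axis=1)


class SkipPool(Module):
    """Parameter-free stride-2 downsample used by the new skip connections."""

    def forward(self, x):
        return nn.max_pool2d(x, 2, 2, 0)


class ChannelReduce(Module):
    """1x1 CBS placed before a transformer encoder that replaces a
    channel-reducing CSP2."""

    def __init__(self, c1, c2, heads, dropout, *, rng):
        super().__init__()
        self.reduce = CBS(c1, c2, 1, 1, rng=rng)
        self.te = TransformerEncoder(c2, heads, dropout, rng=rng)

    def forward(self, x):
        return self.te(self.reduce(x))


class Detect(Module):
    """Anchor head: one 1x1 conv per scale emitting, per anchor and cell,
    4 box offsets, 1 objectness logit and ``nc`` class logits."""

    def __init__(self, channels: Sequence[int], nc: int, na: int = 3, *, rng):
        super().__init__()
        self.nc, self.na = nc, na
        self.convs = [nn.Conv2d(c, na * (5 + nc), 1, bias=True, rng=rng)
                      for c in channels]
        for conv in self.convs:  # bias prior: rare objects at init
            b = conv.bias.data.reshape(na, 5 + nc)
            b[:, 4] = -4.0
            b[:, 5:] = -1.0

    def forward(self, xs):
        out = []
        for x, conv in zip(xs, self.convs):
            n, _, h, w = x.shape
            y = conv(x).reshape(n, self.na, 5 + self.nc, h, w)
            out.append(y.transpose(0, 1, 3, 4, 2))  # (n, na, h, w, 5+nc)
        return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

# feature-extraction modules in the graph-inspection sense: the CSP-family
# blocks of the neck (what the new skip connections bypass), as opposed to
# plumbing (upsample/concat/pool) and plain downsampling convs
_EXTRACT = (CSP, CSPFF, ChannelReduce, TransformerEncoder)


@dataclasses.dataclass
class Layer:
    name: str
    module: Module
    f: int | list[int]          # input layer index/indices (-1 = previous)


class Detector(Module):
    """The assembled detector.  ``layers`` is the explicit computation
    graph; ``head_index`` points at the Detect layer; ``strides`` are the
    head output strides."""

    def __init__(self, cfg: ModelConfig, layers: list[Layer], head_index: int):
        super().__init__()
        self.cfg = cfg
        self.layers = layers
        self.head_index = head_index
        self.strides = (8, 16, 32)
        self._modules_list = [l.module for l in layers]  # for Module traversal

    # Module traversal hooks (layers live in a list of dataclasses)
    def modules(self):
        yield self
        for m in self._modules_list:
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            yield from layer.module.named_parameters(f"{prefix}{i}.{layer.name}.")

    def named_buffers(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            yield from layer.module.named_buffers(f"{prefix}{i}.{layer.name}.")

    def forward(self, x: Tensor) -> list[Tensor]:
        outputs: list[Tensor | list[Tensor] | None] = []
        for layer in self.layers:
            if isinstance(layer.f, list):
                inp = [x if j == -1 else outputs[j] for j in layer.f]
            else:
                inp = x if layer.f == -1 else outputs[layer.f]
            x = layer.module(inp)
            outputs.append(x)
        return x  # Detect output: list of per-scale tensors

    def scaled_anchors(self) -> np.ndarray:
        return self.cfg.scaled_anchors()

    # -- graph inspection ---------------------------------------------------
    def paths_between(self, src: int, dst: int) -> list[list[int]]:
        """All directed layer paths from ``src``'s output to ``dst``'s input."""
        paths = []

        def walk(i, acc):
            if i == dst:
                paths.append(acc)
                return
            for j, layer in enumerate(self.layers):
                fs = layer.f if isinstance(layer.f, list) else [layer.f]
                fs = [j - 1 if f == -1 else f for f in fs]
                if i in fs:
                    walk(j, acc + [j])

        walk(src, [])
        return paths

    def extraction_count(self, path: list[int]) -> int:
        """Feature-extraction modules traversed along a layer path (the
        destination fusion layer itself excluded)."""
        return sum(isinstance(self.layers[i].module, _EXTRACT)
                   for i in path[:-1])


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Assemble the detector for ``cfg.variant``.

    Layer indices (baseline, matching the stock small detector):
      0 Focus  1 CBS/2  2 CSP1  3 CBS/2  4 CSP1(P3 feat)  5 CBS/2
      6 CSP1(P4 feat)  7 CBS/2  8 SPP  9 CSP2
      10 CBS1x1  11 up  12 cat[11,6]  13 CSP2  14 CBS1x1  15 up
      16 cat[15,4]  17 CSP2 (P1 out, stride 8)  18 CBS/2
      19 cat[18,14]  20 CSP2 (P2 out, stride 16)  21 CBS/2
      22 cat[21,10]  23 CSP2 (P3 out, stride 32)  24 Detect
    """
    rng = np.random.default_rng(seed)
    w, d = cfg.width, cfg.depth
    sc = cfg.variant in ("SC", "TE", "TC", "FP")
    use_te = cfg.variant in ("TE", "FP")
    use_tc = cfg.variant in ("TC", "FP")
    L: list[Layer] = []

    def add(name, module, f=-1):
        L.append(Layer(name, module, f))
        return len(L) - 1

    c64, c128, c256, c512, c1024 = w(64), w(128), w(256), w(512), w(1024)

    # backbone
    add("focus", Focus(3, c64, rng=rng))
    add("cbs", CBS(c64, c128, 3, 2, rng=rng))
    add("csp1", CSP(c128, c128, d(3), True, rng=rng))
    add("cbs", CBS(c128, c256, 3, 2, rng=rng))
    i_p3 = add("csp1", CSP(c256, c256, d(9), True, rng=rng))
    add("cbs", CBS(c256, c512, 3, 2, rng=rng))
    i_p4 = add("csp1", CSP(c512, c512, d(9), True, rng=rng))
    add("cbs", CBS(c512, c1024, 3, 2, rng=rng))
    add("spp", SPP(c1024, c1024, rng=rng))
    add("csp2", CSP(c1024, c1024, d(3), False, rng=rng))

    # neck: top-down
    i_p5r = add("cbs", CBS(c1024, c512, 1, 1, rng=rng))
    add("up", Upsample())
    add("cat", Concat(), [-1, i_p4])
    add("csp2", CSP(c512 * 2, c512, d(3), False, rng=rng))
    i_p4r = add("cbs", CBS(c512, c256, 1, 1, rng=rng))
    add("up", Upsample())
    i_cat16 = add("cat", Concat(), [-1, i_p3])
    i_out8 = add("csp2", CSP(c256 * 2, c256, d(3), False, rng=rng))

    # neck: bottom-up with optional new skip connections
    add("cbs", CBS(c256, c256, 3, 2, rng=rng))
    cat19_src = [-1, i_p4r]
    cat19_c = c256 + c256
    if sc:
        i_skip_a = add("skip_pool", SkipPool(), i_cat16)
        cat19_src = [len(L) - 2, i_p4r, i_skip_a]
        cat19_c += c256 * 2
    i_cat19 = add("cat", Concat(), cat19_src)
    if use_tc:
        i_out16 = add("csp_ff", CSPFF(cat19_c, c512, cfg.te_heads,
                                      cfg.te_dropout, rng=rng))
    else:
        i_out16 = add("csp2", CSP(cat19_c, c512, d(3), False, rng=rng))
    add("cbs", CBS(c512, c512, 3, 2, rng=rng))
    cat22_src = [-1, i_p5r]
    cat22_c = c512 + c512
    if sc:
        i_skip_b = add("skip_pool", SkipPool(), i_cat19)
        cat22_src = [len(L) - 2, i_p5r, i_skip_b]
        cat22_c += cat19_c
    i_cat22 = add("cat", Concat(), cat22_src)
    if use_te:
        i_out32 = add("te", ChannelReduce(cat22_c, c1024, cfg.te_heads,
                                          cfg.te_dropout, rng=rng))
    else:
        i_out32 = add("csp2", CSP(cat22_c, c1024, d(3), False, rng=rng))
    head = add("detect",
               Detect([c256, c512, c1024], cfg.num_classes, rng=rng),
               [i_out8, i_out16, i_out32])
    det = Detector(cfg, L, head)
    det._fusion_points = {"P2": i_cat19, "P3": i_cat22}
    det._pre_fusion = {"P2": i_cat16, "P3": i_cat19}
    return det


def count_params_flops(detector: Detector, input_size: int | None = None
                       ) -> tuple[int, float]:
    """Exact parameter count and forward-pass FLOPs at 1x3xSxS input.

    FLOPs follow the 2 x multiply-accumulate convention over convolution and
    matrix-product layers (batch-norm and activations excluded), the
    convention under which the stock small baseline at 640 counts ~16.3e9.
    """
    size = input_size or detector.cfg.input_size
    was_training = detector.training
    detector.eval()
    x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    with nn.count_macs() as macs:
        detector(x)
    if was_training:
        detector.train()
    return detector.n_params(), 2.0 * macs[0]
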