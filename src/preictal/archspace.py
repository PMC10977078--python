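"""Channel-wise 5-block CNN search space.

The space is a constrained family of small networks for multichannel neural
time series, laid out as (channels × samples) maps.  Blocks 1–3 are temporal:
1-D convolutions along time with height-1 kernels, so no two channels are
ever mixed; blocks 4–5 are spatial: height-only kernels with width 1, mixing
channels but not time.  Each block is convolution → batch norm → activation →
max pool, followed by global average pooling and a 2-class softmax head.
All convolution strides are 1 (valid padding).

Per block the controller chooses, in order, (kernel extent, number of
filters, pooling extent):

* temporal blocks: filter width ∈ {1,2,8,16}, filters ∈ {4,8,16},
  pool width ∈ {1,4,8,16};
* spatial blocks: filter height ∈ {1,2,8,16}, filters ∈ {4,8,16},
  pool height ∈ {1,2,4}.

That is T = 15 free hyperparameters and (4·3·4)³ × (4·3·3)² = 143,327,232
distinct architectures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TEMPORAL_OPTIONS",
    "SPATIAL_OPTIONS",
    "FULL_OPTION_SETS",
    "BlockSpec",
    "ArchDescription",
    "decode_arch",
    "encode_arch",
    "decode_arch_string",
    "space_size",
    "propagate_shape",
    "parameter_count",
    "model_size_bytes",
    "build_model",
]

TEMPORAL_OPTIONS = ((1, 2, 8, 16), (4, 8, 16), (1, 4, 8, 16))
SPATIAL_OPTIONS = ((1, 2, 8, 16), (4, 8, 16), (1, 2, 4))

#: option sets for the 15 controller positions, in decode order
FULL_OPTION_SETS: tuple = tuple(
    opts for block in ([TEMPORAL_OPTIONS] * 3 + [SPATIAL_OPTIONS] * 2) for opts in block
)

N_BLOCKS = 5
N_TEMPORAL = 3


@dataclass(frozen=True)
class BlockSpec:
    """One convolutional block: kernel (kh × kw), filters, pool (ph × pw)."""

    kh: int
    kw: int
    n_filters: int
    ph: int
    pw: int
    temporal: bool


@dataclass(frozen=True)
class ArchDescription:
    """A fully decoded 5-block architecture."""

    blocks: tuple  # 5 × BlockSpec

    def __post_init__(self):
        if len(self.blocks) != N_BLOCKS:
            raise ValueError("ArchDescription needs exactly 5 blocks")
        for i, b in enumerate(self.blocks):
            temporal = i < N_TEMPORAL
            opts = TEMPORAL_OPTIONS if temporal else SPATIAL_OPTIONS
            k = b.kw if temporal else b.kh
            p = b.pw if temporal else b.ph
            if b.temporal != temporal:
                raise ValueError(f"block {i} temporal flag mismatch")
            if temporal and (b.kh != 1 or b.ph != 1):
                raise ValueError(f"temporal block {i} must have height-1 kernel/pool")
            if not temporal and (b.kw != 1 or b.pw != 1):
                raise ValueError(f"spatial block {i} must have width-1 kernel/pool")
            if k not in opts[0] or b.n_filters not in opts[1] or p not in opts[2]:
                raise ValueError(f"block {i} hyperparameters outside the option sets")


def decode_arch(actions, option_sets=None) -> ArchDescription:
    """Decode a controller action string α₁..α_T into an architecture.

    ``actions`` are option-set indices, 3 per block in the order
    (kernel, filters, pool).  Raises on a wrong length or an out-of-range
    index, naming the offending position.
    """
    option_sets = FULL_OPTION_SETS if option_sets is None else option_sets
    actions = list(actions)
    if len(actions) != len(option_sets):
        raise ValueError(
            f"expected {len(option_sets)} actions, got {len(actions)}"
        )
    values = []
    for t, (a, opts) in enumerate(zip(actions, option_sets)):
        a = int(a)
        if not 0 <= a < len(opts):
            raise ValueError(
                f"action index {a} out of range at position {t} "
                f"(options {opts})"
            )
        values.append(opts[a])
    blocks = []
    for i in range(N_BLOCKS):
        k, f, p = values[3 * i : 3 * i + 3]
        if i < N_TEMPORAL:
            blocks.append(BlockSpec(kh=1, kw=k, n_filters=f, ph=1, pw=p, temporal=True))
        else:
            blocks.append(BlockSpec(kh=k, kw=1, n_filters=f, ph=p, pw=1, temporal=False))
    return ArchDescription(tuple(blocks))


def _encode_actions(arch: ArchDescription) -> list:
    actions = []
    for i, b in enumerate(arch.blocks):
        opts = TEMPORAL_OPTIONS if i < N_TEMPORAL else SPATIAL_OPTIONS
        k = b.kw if i < N_TEMPORAL else b.kh
        p = b.pw if i < N_TEMPORAL else b.ph
        actions += [opts[0].index(k), opts[1].index(b.n_filters), opts[2].index(p)]
    return actions


def encode_arch(arch: ArchDescription) -> str:
    """Serialize as a single-line token string, e.g. ``'8x1f8p4x1|...'``."""
    toks = []
    for b in arch.blocks:
        toks.append(f"{b.kh}x{b.kw}f{b.n_filters}p{b.ph}x{b.pw}")
    return "|".join(toks)


def decode_arch_string(s: str) -> ArchDescription:
    """Inverse of :func:`encode_arch`."""
    import re

    blocks = []
    parts = s.split("|")
    if len(parts) != N_BLOCKS:
        raise ValueError(f"expected 5 block tokens, got {len(parts)}")
    for i, tok in enumerate(parts):
        m = re.fullmatch(r"(\d+)x(\d+)f(\d+)p(\d+)x(\d+)", tok)
        if not m:
            raise ValueError(f"malformed block token {tok!r}")
        kh, kw, f, ph, pw = map(int, m.groups())
        blocks.append(BlockSpec(kh, kw, f, ph, pw, temporal=i < N_TEMPORAL))
    return ArchDescription(tuple(blocks))


def arch_to_actions(arch: ArchDescription) -> list:
    """Action-string encoding (inverse of :func:`decode_arch`)."""
    return _encode_actions(arch)


def space_size(option_sets=None) -> int:
    option_sets = FULL_OPTION_SETS if option_sets is None else option_sets
    n = 1
    for opts in option_sets:
        n *= len(opts)
    return n


def propagate_shape(arch: ArchDescription, input_shape) -> list:
    """Per-block output shapes (filters, height, width) for a given input.

    ``input_shape`` is (channels, samples).  Valid convolutions subtract
    (k−1); pooling floor-divides.  Raises if any stage would shrink a
    dimension below 1, reporting the offending block.
    """
    h, w = int(input_shape[0]), int(input_shape[1])
    shapes = []
    for i, b in enumerate(arch.blocks):
        h2, w2 = h - b.kh + 1, w - b.kw + 1
        if h2 < 1 or w2 < 1:
            raise ValueError(
                f"block {i}: kernel {b.kh}x{b.kw} does not fit map {h}x{w}"
            )
        h3, w3 = h2 // b.ph, w2 // b.pw
        if h3 < 1 or w3 < 1:
            raise ValueError(
                f"block {i}: pool {b.ph}x{b.pw} reduces map {h2}x{w2} below 1"
            )
        h, w = h3, w3
        shapes.append((b.n_filters, h, w))
    return shapes


def parameter_count(arch: ArchDescription, n_classes: int = 2) -> dict:
    """Weight/parameter tally: conv weights kh·kw·in_f·out_f, dense + bias, BN."""
    in_f = 1
    conv_w = 0
    bn_params = 0
    for b in arch.blocks:
        conv_w += b.kh * b.kw * in_f * b.n_filters
        bn_params += 2 * b.n_filters  # folded scale + shift
        in_f = b.n_filters
    dense_w = in_f * n_classes
    return {
        "conv_weights": conv_w,
        "dense_weights": dense_w,
        "dense_bias": n_classes,
        "bn_params": bn_params,
        "total_weights": conv_w + dense_w,
    }


def model_size_bytes(
    arch: ArchDescription,
    Q: int,
    count_bn: bool = True,
    n_classes: int = 2,
    with_dense_bias: bool = True,
) -> int:
    """Serialized model size under the documented accounting policy.

    Weights (conv + dense) are stored at Q bits; dense biases and folded
    batch-norm scale/shift at 8 bits each.  Size is monotone in Q.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    counts = parameter_count(arch, n_classes=n_classes)
    n_weights = counts["total_weights"]
    size = -(-n_weights * Q // 8)  # ceil
    if with_dense_bias:
        size += counts["dense_bias"]  # 8-bit each
    if count_bn:
        size += counts["bn_params"]  # 8-bit each
    return size


def build_model(arch: ArchDescription, input_shape, quant=None, seed: int = 0):
    """Build a trainable network for this architecture.

    ``quant`` is a :class:`~preictal.quant.QuantConfig` or None for a float
    model.  The returned :class:`~preictal._nn.Network` exposes forward /
    backward passes; shapes are validated via :func:`propagate_shape`.
    """
    from preictal._nn import Network

    propagate_shape(arch, input_shape)  # raises on impossible shapes
    return Network(arch, input_shape, quant=quant, seed=seed)
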