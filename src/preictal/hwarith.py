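"""Bit-accurate emulation of the multiplier-free arithmetic units.

The always-on binary network computes ±1 dot products as XNOR followed by a
popcount; the verifier network computes 8-bit multiply-accumulates with a
radix-4 Booth shift-add unit.  Both are emulated here at the register level:

* :func:`popcount_shift` reproduces the 8-cycle shift-and-extract popcount
  chain: each cycle the register is shifted right by one bit and the extracted
  LSB is added into the spare positions freed on the left.
* :func:`booth_encode` / :func:`booth_mac` reproduce the radix-4 Booth MAC:
  the 8-bit multiplier is LSB-extended to 9 bits, sliced into four overlapping
  3-bit groups, each mapped to a digit in {−2,−1,0,1,2}; the four Booth
  products (shift/negate of the multiplicand) are accumulated across a chain
  of computation units.

Everything network-scale (convolutions, batch-norm scaling, dense head) is
built from the same digit encoding in vectorised form (shifts, negations,
table selects and adds only); see :mod:`preictal._engine`.  A guarded
:func:`general_multiply` exists purely as instrumentation — the compute path
never calls it, and :func:`mul_ops_count` must read 0 after any inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BitVector",
    "BoothDigits",
    "popcount_shift",
    "pack_pm1",
    "unpack_pm1",
    "xnor_popcount_dot",
    "booth_encode",
    "booth_mac",
    "booth_mul_wide",
    "general_multiply",
    "mul_ops_count",
    "reset_mul_counter",
    "fixed_point_infer",
    "verify_hardware",
]

# Booth group code (b2 b1 b0) -> digit −2·b2 + b1 + b0
_BOOTH_DIGIT_TABLE = (0, 1, 1, 2, -2, -1, -1, 0)

_MUL_COUNTER = 0


def general_multiply(a: int, b: int) -> int:
    """A general-purpose multiply, instrumented.

    The inference compute path must never reach this function; tests assert
    that :func:`mul_ops_count` stays at 0 across full network inferences.
    """
    global _MUL_COUNTER
    _MUL_COUNTER += 1
    return a * b


def mul_ops_count() -> int:
    """Number of general multiplies issued since the last reset."""
    return _MUL_COUNTER


def reset_mul_counter() -> None:
    global _MUL_COUNTER
    _MUL_COUNTER = 0


# ---------------------------------------------------------------------------
# popcount by shift-and-extract
# ---------------------------------------------------------------------------

def popcount_shift(x: int | str) -> int:
    """Popcount of an 8-bit pattern via the 8-cycle shift-and-extract chain.

    ``x`` may be an integer in [0, 255] or an 8-character bit string such as
    ``"11010011"``.  Each cycle shifts the register right by one and adds the
    extracted LSB into the spare bit positions freed on the left; after eight
    cycles the register holds the count (``"11010011"`` → ``0b00000101`` = 5).
    """
    if isinstance(x, str):
        if len(x) != 8 or set(x) - {"0", "1"}:
            raise ValueError(f"expected an 8-bit pattern, got {x!r}")
        reg = int(x, 2)
    else:
        reg = int(x)
        if not 0 <= reg <= 0xFF:
            raise ValueError(f"expected an 8-bit value, got {reg}")
    for cycle in range(1, 9):
        lsb = reg & 1
        reg >>= 1
        # the counter field occupies the top `cycle` bits and shifts along
        # with the data; the extracted bit is added at the field's LSB
        reg += lsb << (8 - cycle)
    return reg


# ---------------------------------------------------------------------------
# XNOR-popcount dot products
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitVector:
    """A packed ±1 vector: −1 encodes to bit 0, +1 to bit 1 (LSB-first)."""

    bits: tuple
    n: int

    def __post_init__(self):
        if self.n < 1 or len(self.bits) != self.n:
            raise ValueError("BitVector length mismatch")
        if set(self.bits) - {0, 1}:
            raise ValueError("BitVector bits must be 0/1")


def pack_pm1(v: Sequence[int]) -> BitVector:
    """Pack a ±1 vector into a :class:`BitVector` (−1→0, +1→1)."""
    bits = []
    for x in v:
        if x == 1:
            bits.append(1)
        elif x == -1:
            bits.append(0)
        else:
            raise ValueError(f"pack_pm1 expects ±1 entries, got {x}")
    return BitVector(tuple(bits), len(bits))


def unpack_pm1(bv: BitVector) -> np.ndarray:
    return np.where(np.asarray(bv.bits, dtype=np.int64) == 1, 1, -1)


def xnor_popcount_dot(u: BitVector, v: BitVector) -> int:
    """Dot product of two ±1 vectors via XNOR + popcount.

    Returns ``2·popcount(XNOR(u, v)) − n``, which equals the integer dot
    product of the underlying ±1 vectors.  The popcount runs through
    :func:`popcount_shift` on zero-padded 8-bit chunks.
    """
    if u.n != v.n:
        raise ValueError(f"length mismatch: {u.n} != {v.n}")
    xnor = [1 - (a ^ b) for a, b in zip(u.bits, v.bits)]
    # pad with zeros to a whole number of bytes; padding adds nothing
    while len(xnor) % 8:
        xnor.append(0)
    pop = 0
    for i in range(0, len(xnor), 8):
        byte = 0
        for j, bit in enumerate(xnor[i : i + 8]):
            byte |= bit << j
        pop += popcount_shift(byte)
    return 2 * pop - u.n


# ---------------------------------------------------------------------------
# radix-4 Booth encoding and MAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoothDigits:
    """Four radix-4 Booth digits for an 8-bit two's-complement multiplier."""

    digits: tuple

    def __post_init__(self):
        if len(self.digits) != 4 or set(self.digits) - {-2, -1, 0, 1, 2}:
            raise ValueError("BoothDigits must be 4 digits in {-2..2}")

    def value(self) -> int:
        return sum(d << (2 * i) for i, d in enumerate(self.digits))


def booth_encode(y: int) -> BoothDigits:
    """Radix-4 Booth encoding of a signed 8-bit multiplier.

    A zero is appended below the LSB (9-bit extension); four overlapping
    3-bit groups are sliced off and mapped through the Booth table to digits
    in {−2,−1,0,1,2} satisfying Σ dᵢ·4ⁱ = y.
    """
    y = int(y)
    if not -128 <= y <= 127:
        raise ValueError(f"multiplier out of signed 8-bit range: {y}")
    # two's complement with sign extension to 9 data bits, then LSB-extend
    y10 = ((y & 0x1FF) << 1) & 0x3FF
    digits = []
    for i in range(4):
        group = (y10 >> (2 * i)) & 0b111
        digits.append(_BOOTH_DIGIT_TABLE[group])
    return BoothDigits(tuple(digits))


def _booth_product(x: int, digit: int) -> int:
    """digit·x using only shift and negation."""
    if digit == 0:
        return 0
    if digit == 1:
        return x
    if digit == 2:
        return x << 1 if x >= 0 else -((-x) << 1)
    if digit == -1:
        return -x
    if digit == -2:
        return -(x << 1) if x >= 0 else (-x) << 1
    raise ValueError(f"invalid Booth digit {digit}")


def booth_mac(x: int, y: int, acc: int = 0, acc_bits: int = 32) -> int:
    """acc + x·y via four chained Booth shift-add units (no multiply).

    ``x`` is the signed 8-bit multiplicand (the stationary kernel value),
    ``y`` the signed 8-bit multiplier.  The four Booth products of ``x`` are
    accumulated into the running partial sum; an accumulator exceeding the
    configured signed width is flagged as an overflow.
    """
    x = int(x)
    if not -128 <= x <= 127:
        raise ValueError(f"multiplicand out of signed 8-bit range: {x}")
    digits = booth_encode(y)
    psum = int(acc)
    for i, d in enumerate(digits.digits):
        psum += _booth_product(x, d) << (2 * i)
    bound = 1 << (acc_bits - 1)
    if not -bound <= psum < bound:
        raise OverflowError(f"accumulator overflow at {acc_bits} bits: {psum}")
    return psum


def booth_mul_wide(s, m: int):
    """Booth shift-add product of a wide integer (array) by an 8-bit multiplier.

    Used for the folded batch-norm scale and the dense head, where the
    stationary 8-bit mantissa multiplies a wide partial sum.  Same digit
    encoding as :func:`booth_mac`; the multiplicand datapath is simply wider.
    Only negation, shifts and adds are applied to ``s``.
    """
    digits = booth_encode(m).digits
    s = np.asarray(s, dtype=np.int64)
    acc = np.zeros_like(s)
    for i, d in enumerate(digits):
        if d == 0:
            continue
        if d == 1:
            p = s
        elif d == -1:
            p = -s
        elif d == 2:
            p = np.left_shift(s, 1)
        else:  # d == -2
            p = -np.left_shift(s, 1)
        acc += np.left_shift(p, 2 * i)
    return acc


# vectorised radix-4 digit extraction: group codes (0..7) for an array of
# signed 8-bit multipliers; products come from an 8-entry lookup of
# shift/negated multiplicands, never from a multiply.

def _booth_group_codes(y: np.ndarray) -> np.ndarray:
    """(4, ...) array of 3-bit Booth group codes for signed 8-bit ``y``."""
    y = np.asarray(y, dtype=np.int64)
    y10 = np.left_shift(np.bitwise_and(y, 0x1FF), 1)
    groups = np.empty((4,) + y.shape, dtype=np.int64)
    for i in range(4):
        groups[i] = np.bitwise_and(np.right_shift(y10, 2 * i), 0b111)
    return groups


def _booth_mul_stationary_x(x: int, y: np.ndarray) -> np.ndarray:
    """x·y for scalar 8-bit multiplicand x and an array of 8-bit multipliers.

    The eight Booth products of the stationary ``x`` are precomputed once
    (shift/negate only) and selected per group code — the software analogue of
    keeping the kernel's Booth products fixed across a whole feature map.
    """
    x = int(x)
    x2 = x << 1 if x >= 0 else -((-x) << 1)
    lut = np.array([0, x, x, x2, -x2, -x, -x, 0], dtype=np.int64)
    groups = _booth_group_codes(y)
    acc = np.zeros(np.asarray(y).shape, dtype=np.int64)
    for i in range(4):
        acc += np.left_shift(np.take(lut, groups[i]), 2 * i)
    return acc


def verify_hardware(rng: np.random.Generator | None = None) -> dict:
    """Run the exhaustive arithmetic oracles; return a pass/fail report.

    * popcount_shift against a table popcount for all 256 byte values;
    * Booth digit structure + reconstruction for all 256 multipliers;
    * booth_mac(x, y, 0) == x·y for all 65,536 signed 8-bit pairs;
    * XNOR-popcount dot identity on random ±1 vector pairs.
    """
    rng = rng or np.random.default_rng(0)
    report = {}

    report["popcount_exhaustive"] = all(
        popcount_shift(b) == bin(b).count("1") for b in range(256)
    )

    ok = True
    for y in range(-128, 128):
        d = booth_encode(y)
        ok &= d.value() == y and len(d.digits) == 4
    report["booth_encode_exhaustive"] = ok

    ok = True
    for x in range(-128, 128):
        for y in range(-128, 128):
            if booth_mac(x, y, 0) != x * y:
                ok = False
                break
        if not ok:
            break
    report["booth_mac_exhaustive"] = ok

    ok = True
    for _ in range(200):
        n = int(rng.choice([8, 64, 128]))
        u = rng.choice([-1, 1], size=n)
        v = rng.choice([-1, 1], size=n)
        if xnor_popcount_dot(pack_pm1(u), pack_pm1(v)) != int(u @ v):
            ok = False
            break
    report["xnor_dot_random"] = ok
    report["all_passed"] = all(report.values())
    return report


def fixed_point_infer(model, window, collect_mul_count: bool = False):
    """Multiplier-free fixed-point inference; see :mod:`preictal._engine`."""
    from preictal._engine import fixed_point_infer as _impl

    return _impl(model, window, collect_mul_count=collect_mul_count)
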