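"""Block-wise universal codes: Elias gamma, Elias delta, Fibonacci.

These self-delimiting variable-length codes serve as compression and speed
baselines for the fixed-width block codecs.  Values are laid down in an
LSB-first bitstream (bit 0 of word 0 is the first bit); within one code the
bit written first occupies the lowest position.

A universal code cannot represent 0, but offset differences are frequently
zero, so block encoders store each difference ``d`` as ``code(d + 1)`` and
decoders subtract 1 — the *shifted* convention.  Blocks hold 64 adjacent
differences (``x[i+1] - x[i]``); decoding within a block is serial, so the
lane-cyclic schemes of the bitpacked codecs would buy nothing here.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np

from .exceptions import CorruptCodeError, NonMonotonicError, ShiftEncodingError

GAMMA = "gamma"
DELTA = "delta"
FIBONACCI = "fibonacci"
UNIVERSAL_CODECS = (GAMMA, DELTA, FIBONACCI)

# Fibonacci numbers F(2), F(3), ... covering the full 33-bit shifted range.
_FIB: list[int] = [1, 2]
while _FIB[-1] < 1 << 34:
    _FIB.append(_FIB[-1] + _FIB[-2])
_FIB_ARR = np.array(_FIB, dtype=np.uint64)


class Bits(NamedTuple):
    """A code as an integer whose bit ``t`` is the ``t``-th bit written."""

    value: int
    length: int

    @property
    def bitstring(self) -> str:
        """Bits in stream order, first-written bit leftmost."""
        return "".join(str((self.value >> t) & 1) for t in range(self.length))


class Bitstream:
    """Append-only LSB-first bit sequence backed by 32-bit words."""

    def __init__(self) -> None:
        self._words: list[int] = []
        self._cur = 0
        self._curbits = 0
        self.nbits = 0

    def append(self, bits: Bits) -> None:
        self._cur |= bits.value << self._curbits
        self._curbits += bits.length
        self.nbits += bits.length
        while self._curbits >= 32:
            self._words.append(self._cur & 0xFFFFFFFF)
            self._cur >>= 32
            self._curbits -= 32

    def to_words(self) -> np.ndarray:
        words = list(self._words)
        if self._curbits:
            words.append(self._cur & 0xFFFFFFFF)
        return np.array(words, dtype=np.uint32)


class BitReader:
    """Positional reader over an LSB-first word array."""

    def __init__(self, words: np.ndarray, bitpos: int = 0) -> None:
        self._words = words
        self._limit = len(words) * 32
        self.bitpos = bitpos

    def read_bit(self) -> int:
        p = self.bitpos
        if p >= self._limit:
            raise CorruptCodeError("bitstream exhausted mid-code")
        self.bitpos = p + 1
        return (int(self._words[p >> 5]) >> (p & 31)) & 1

    def read_bits(self, n: int) -> int:
        if n == 0:
            return 0
        p = self.bitpos
        if p + n > self._limit:
            raise CorruptCodeError("bitstream exhausted mid-code")
        self.bitpos = p + n
        out = 0
        got = 0
        while got < n:
            take = min(n - got, 32 - (p & 31))
            chunk = (int(self._words[p >> 5]) >> (p & 31)) & ((1 << take) - 1)
            out |= chunk << got
            got += take
            p += take
        return out


# ---------------------------------------------------------------------------
# Scalar codecs
# ---------------------------------------------------------------------------


def _require_positive(v: int) -> None:
    if v < 1:
        raise ShiftEncodingError("universal codes encode v >= 1; use the shifted block encoder for 0")


def gamma_encode(v: int) -> Bits:
    """Elias gamma: ``c - 1`` zero bits, then the ``c`` bits of ``v`` (2c-1 bits total)."""
    _require_positive(v)
    c = v.bit_length()
    # marker 1 doubles as the most significant bit of v; the remaining c-1
    # value bits follow least-significant-first
    value = (1 << (c - 1)) | ((v & ((1 << (c - 1)) - 1)) << c)
    return Bits(value, 2 * c - 1)


def gamma_decode(reader: BitReader) -> int:
    z = 0
    while reader.read_bit() == 0:
        z += 1
        if z > 33:
            raise CorruptCodeError("gamma zero-run exceeds 33 bits")
    c = z + 1
    return (1 << (c - 1)) | reader.read_bits(c - 1)


def delta_encode(v: int) -> Bits:
    """Elias delta: gamma-code the bit count ``c``, then the ``c - 1`` bits after the MSB."""
    _require_positive(v)
    c = v.bit_length()
    g = gamma_encode(c)
    value = g.value | ((v & ((1 << (c - 1)) - 1)) << g.length)
    return Bits(value, g.length + c - 1)


def delta_decode(reader: BitReader) -> int:
    c = gamma_decode(reader)
    if c > 34:
        raise CorruptCodeError("delta bit count out of range")
    return (1 << (c - 1)) | reader.read_bits(c - 1)


def fibonacci_encode(v: int) -> Bits:
    """Zeckendorf representation, lowest Fibonacci number first, '11'-terminated."""
    _require_positive(v)
    # greedy from the largest Fibonacci number <= v gives the Zeckendorf form
    hi = 0
    while hi + 1 < len(_FIB) and _FIB[hi + 1] <= v:
        hi += 1
    value = 0
    rem = v
    for i in range(hi, -1, -1):
        if _FIB[i] <= rem:
            rem -= _FIB[i]
            value |= 1 << i
    value |= 1 << (hi + 1)  # terminator: forms the only '11' pair
    return Bits(value, hi + 2)


def fibonacci_decode(reader: BitReader) -> int:
    v = 0
    prev = 0
    i = 0
    while True:
        if i >= len(_FIB) + 1:
            raise CorruptCodeError("Fibonacci code exceeds the 33-bit range")
        b = reader.read_bit()
        if b and prev:
            return v
        if b:
            v += _FIB[i]
        prev = b
        i += 1


_ENCODERS = {GAMMA: gamma_encode, DELTA: delta_encode, FIBONACCI: fibonacci_encode}
_DECODERS = {GAMMA: gamma_decode, DELTA: delta_decode, FIBONACCI: fibonacci_decode}


# ---------------------------------------------------------------------------
# Block interface
# ---------------------------------------------------------------------------


def encode_block_shifted(diffs: Sequence[int], codec: str) -> Bitstream:
    """Encode one block of adjacent differences, storing each ``d`` as ``code(d + 1)``."""
    encoder = _ENCODERS[codec]
    bs = Bitstream()
    for d in diffs:
        d = int(d)
        if d < 0:
            raise NonMonotonicError("negative difference")
        bs.append(encoder(d + 1))
    return bs


def decode_block_at(words: np.ndarray, bit_offset: int, x0: int, r: int, codec: str,
                    block_size: int = 64) -> int:
    """Serially decode ``r`` shifted codes from a block start and return ``x_r``."""
    if not 1 <= r <= block_size:
        raise IndexError(f"block position {r} out of range 1..{block_size}")
    decoder = _DECODERS[codec]
    reader = BitReader(words, bit_offset)
    total = x0
    for _ in range(r):
        total += decoder(reader) - 1
    return total


def decode_block_pair_at(words: np.ndarray, bit_offset: int, x0: int, r: int, codec: str,
                         block_size: int = 64) -> tuple[int, int]:
    """One-pass serial decode of ``(x_r, x_{r+1})``: continue one code past ``x_r``."""
    if not 1 <= r <= block_size - 1:
        raise IndexError(f"block position {r} out of range 1..{block_size - 1}")
    decoder = _DECODERS[codec]
    reader = BitReader(words, bit_offset)
    total = x0
    for _ in range(r):
        total += decoder(reader) - 1
    first = total
    return first, total + decoder(reader) - 1


# ---------------------------------------------------------------------------
# Vectorized encoders (used when compressing whole arrays)
# ---------------------------------------------------------------------------


def _bit_length(v: np.ndarray) -> np.ndarray:
    # exact for v < 2**53: frexp's exponent of an integer m > 0 is bit_length(m)
    return np.frexp(v.astype(np.float64))[1].astype(np.int64)


def _gamma_codes(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = _bit_length(v)
    one = np.uint64(1)
    cm1 = (c - 1).astype(np.uint64)
    low = v & ((one << cm1) - one)
    codes = (one << cm1) | (low << c.astype(np.uint64))
    return codes, 2 * c - 1


def _delta_codes(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = _bit_length(v)
    gcodes, glens = _gamma_codes(c.astype(np.uint64))
    one = np.uint64(1)
    cm1 = (c - 1).astype(np.uint64)
    codes = gcodes | ((v & ((one << cm1) - one)) << glens.astype(np.uint64))
    return codes, glens + c - 1


def _fibonacci_codes(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rem = v.astype(np.uint64).copy()
    codes = np.zeros_like(rem)
    hi = np.searchsorted(_FIB_ARR, v, side="right").astype(np.int64) - 1
    for i in range(len(_FIB) - 1, -1, -1):
        take = rem >= _FIB_ARR[i]
        codes |= take.astype(np.uint64) << np.uint64(i)
        rem -= np.where(take, _FIB_ARR[i], np.uint64(0))
    codes |= np.uint64(1) << (hi + 1).astype(np.uint64)
    return codes, hi + 2


_VECTOR_ENCODERS = {GAMMA: _gamma_codes, DELTA: _delta_codes, FIBONACCI: _fibonacci_codes}


def encode_values(values: np.ndarray, codec: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized codes and bit lengths for positive values < 2**31.

    Codes longer than 64 bits cannot be held in a uint64 lane, so values at
    or above 2**31 fall back to the scalar encoders.
    """
    values = np.asarray(values, dtype=np.uint64)
    if values.size and int(values.max()) >= 1 << 31:
        pairs = [_ENCODERS[codec](int(v)) for v in values]
        codes = np.array([p.value for p in pairs], dtype=object)
        lens = np.array([p.length for p in pairs], dtype=np.int64)
        return codes, lens
    return _VECTOR_ENCODERS[codec](values)


def pack_varlen(codes: np.ndarray, lens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate variable-length codes into an LSB-first word array.

    Returns (words, starts) where ``starts[i]`` is the bit offset of code i
    and ``starts[-1]`` the total bit count.
    """
    n = len(codes)
    starts = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lens, out=starts[1:])
    total_bits = int(starts[-1])
    words = np.zeros((total_bits + 31) // 32, dtype=np.uint32)
    if n == 0:
        return words, starts
    if codes.dtype == object:  # scalar fallback path (codes may exceed 64 bits)
        for code, s, ln in zip(codes, starts[:-1], lens):
            code = int(code) << (int(s) & 31)
            wi = int(s) >> 5
            while code:
                words[wi] |= code & 0xFFFFFFFF
                code >>= 32
                wi += 1
        return words, starts
    s = starts[:-1]
    wi = (s >> 5).astype(np.int64)
    sh = (s & 31).astype(np.uint64)
    lo = codes & np.uint64(0xFFFFFFFF)
    hi = codes >> np.uint64(32)
    mask = np.uint64(0xFFFFFFFF)
    inv = np.where(sh > 0, np.uint64(32) - sh, np.uint64(0))
    c0 = (lo << sh) & mask
    c1 = np.where(sh > 0, lo >> inv, np.uint64(0)) | ((hi << sh) & mask)
    c2 = np.where(sh > 0, hi >> inv, np.uint64(0))
    out = np.zeros(len(words) + 2, dtype=np.uint64)  # slack for the tail words
    np.bitwise_or.at(out, wi, c0)
    np.bitwise_or.at(out, wi + 1, c1)
    np.bitwise_or.at(out, wi + 2, c2)
    words |= out[: len(words)].astype(np.uint32)
    return words, starts
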