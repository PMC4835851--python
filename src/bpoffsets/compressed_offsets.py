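"""Random-access compressed offset vectors.

A :class:`CompressedOffsetVector` replaces a monotone nondecreasing 32-bit
offset array by a bitstream of per-block compressed differences plus a
metainformation array holding, for every block, a pointer into the bitstream
and the prefix sum at the block's first element.  Lookups of one value, or of
the two adjacent values delimiting a k-mer's positions list, touch only one
or two blocks.

Supported schemes:

====================  =====================================================
``bp64v``             vertical layout, unidirectional differences, block 64
``bp64c``             columnar layout, bidirectional differences, block 64
``bp32c``             columnar layout, bidirectional differences, block 32
``gamma``/``delta``/``fibonacci``
                      universal codes, 64 adjacent differences per block
====================  =====================================================

For the bitpacked schemes the pointer is in 128-bit vector units and the
block's bit width is implicit in the difference between successive pointers;
for the universal schemes the pointer is a bit offset.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import blockcodec as bc
from . import universal_codes as uc
from .blockcodec import (BP32_COLUMNAR, BP64_COLUMNAR, BP64_VERTICAL,
                         BlockScheme, DecodeStats, PackedBlock)
from .exceptions import ContainerFormatError, NonMonotonicError

BITPACKED_SCHEMES = {
    "bp64v": BP64_VERTICAL,
    "bp64c": BP64_COLUMNAR,
    "bp32c": BP32_COLUMNAR,
}
ALL_SCHEMES = tuple(BITPACKED_SCHEMES) + uc.UNIVERSAL_CODECS

_MAGIC = b"BPOF"
_VERSION = 1
_SCHEME_IDS = {name: i for i, name in enumerate(ALL_SCHEMES)}
_SCHEME_NAMES = {i: name for name, i in _SCHEME_IDS.items()}
_HEADER = struct.Struct("<4sHBBIqQQ")  # magic, version, scheme, pad, B, k, n, n_meta; words follow


@dataclass
class CompressedOffsetVector:
    """Bitstream + metainformation for one compressed offset array."""

    scheme: str
    n: int  # logical length (4**k + 1 for a k-mer table)
    words: np.ndarray  # uint32 bitstream
    pointers: np.ndarray  # int64, one per block + sentinel
    prefix_sums: np.ndarray  # uint32 prefix sum at each block start + sentinel
    k: Optional[int] = None  # oligomer length, when built from a hash table

    @property
    def block_size(self) -> int:
        return BITPACKED_SCHEMES[self.scheme].block_size if self.is_bitpacked else 64

    @property
    def is_bitpacked(self) -> bool:
        return self.scheme in BITPACKED_SCHEMES

    @property
    def n_blocks(self) -> int:
        return len(self.pointers) - 1

    def widths(self) -> np.ndarray:
        """Per-block bit widths, recovered implicitly from pointer differences."""
        if not self.is_bitpacked:
            raise ValueError("widths are defined only for bitpacked schemes")
        # one 128-bit vector holds 128 / width ... width = vectors * 128 / B
        return (np.diff(self.pointers) * 128 // self.block_size).astype(np.int64)


def _block_layout(n: int, block_size: int) -> int:
    """Number of blocks covering the n - 1 differences of an n-value array."""
    return max(0, -(-(n - 1) // block_size))


def _padded_values(offsets: np.ndarray, block_size: int) -> np.ndarray:
    """int64 copy padded to a whole number of blocks by repeating the last offset."""
    n = len(offsets)
    nb = _block_layout(n, block_size)
    X = np.empty(nb * block_size + 1, dtype=np.int64)
    X[:n] = offsets
    X[n:] = int(offsets[-1])
    return X


def _block_diffs(X: np.ndarray, scheme_name: str) -> np.ndarray:
    """(nb, B) difference matrix for the padded value array ``X``."""
    if scheme_name in BITPACKED_SCHEMES:
        scheme = BITPACKED_SCHEMES[scheme_name]
        B = scheme.block_size
    else:
        scheme = None
        B = 64
    nb = (len(X) - 1) // B
    V = np.empty((nb, B + 1), dtype=np.int64)
    V[:, :B] = X[:-1].reshape(nb, B)
    V[:, B] = X[B::B]
    if scheme is None:
        return V[:, 1:] - V[:, :-1]
    if scheme.direction == bc.UNIDIRECTIONAL:
        D = np.empty((nb, B), dtype=np.int64)
        D[:, :4] = V[:, 1:5] - V[:, :1]
        D[:, 4:] = V[:, 5 : B + 1] - V[:, 1 : B - 3]
        return D
    h = B // 2
    D = np.empty((nb, B), dtype=np.int64)
    D[:, :4] = V[:, 1:5] - V[:, :1]
    D[:, 4:h] = V[:, 5 : h + 1] - V[:, 1 : h - 3]
    D[:, h : h + 4] = V[:, B:] - V[:, B - 1 : B - 5 : -1]
    j = np.arange(4, h)
    D[:, h + 4 :] = V[:, B + 3 - j] - V[:, B - 1 - j]
    return D


def compress(offsets, scheme: str, k: Optional[int] = None) -> CompressedOffsetVector:
    """Compress a monotone nondecreasing 32-bit offset array under ``scheme``.

    The final partial block is padded by repeating the last offset; padded
    values are never exposed by lookups.  The metainformation array carries
    one sentinel entry past the last block so the ending prefix sum of every
    block, including the last, is available for bidirectional decoding.
    """
    if scheme not in ALL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose one of {ALL_SCHEMES}")
    offsets = np.asarray(offsets)
    if offsets.ndim != 1 or len(offsets) == 0:
        raise ValueError("offsets must be a nonempty 1-D array")
    off64 = offsets.astype(np.int64)
    if np.any(np.diff(off64) < 0):
        raise NonMonotonicError("negative difference: offsets are not monotone nondecreasing")
    if int(off64[0]) < 0 or int(off64[-1]) >= 1 << 32:
        raise NonMonotonicError("offsets must lie in the unsigned 32-bit range")
    n = len(off64)
    blk = BITPACKED_SCHEMES.get(scheme)
    B = blk.block_size if blk is not None else 64
    X = _padded_values(off64, B)
    nb = (len(X) - 1) // B
    prefix_sums = X[::B].astype(np.uint32)  # nb + 1 entries
    if nb == 0:
        return CompressedOffsetVector(scheme, n, np.empty(0, np.uint32),
                                      np.zeros(1, np.int64), prefix_sums, k)
    D = _block_diffs(X, scheme)
    if blk is not None:
        maxd = D.max(axis=1)
        bits = np.zeros(nb, dtype=np.int64)
        nz = maxd > 0
        bits[nz] = np.frexp(maxd[nz].astype(np.float64))[1]
        step = blk.width_step
        widths = -(-bits // step) * step
        words, word_starts = bc.pack_blocks(D, widths, blk)
        pointers = word_starts // 4  # 128-bit vector units
    else:
        codes, lens = uc.encode_values((D + 1).reshape(-1), scheme)
        words, starts = uc.pack_varlen(codes, lens)
        pointers = starts[::B].copy()  # bit offsets of each block + total
    return CompressedOffsetVector(scheme, n, words, pointers, prefix_sums, k)


def decompress(v: CompressedOffsetVector) -> np.ndarray:
    """Expand the full offset array (the exact inverse of :func:`compress`)."""
    n, B = v.n, v.block_size
    nb = v.n_blocks
    if nb == 0:
        return v.prefix_sums[:1].astype(np.uint32).copy()
    x0 = v.prefix_sums[:-1].astype(np.int64)
    if v.is_bitpacked:
        scheme = BITPACKED_SCHEMES[v.scheme]
        D = bc.unpack_blocks(v.words, v.pointers * 4, v.widths(), scheme)
        X = np.empty(nb * B + 1, dtype=np.int64)
        X[0] = x0[0]
        if scheme.direction == bc.UNIDIRECTIONAL:
            C = D.reshape(nb, B // 4, 4).cumsum(axis=1)
            X[1:] = (x0[:, None, None] + C).reshape(-1)
        else:
            h = B // 2
            xB = v.prefix_sums[1:].astype(np.int64)
            C1 = D[:, :h].reshape(nb, h // 4, 4).cumsum(axis=1)
            blockvals = np.empty((nb, B), dtype=np.int64)  # x at positions 1..B per block
            blockvals[:, :h] = (x0[:, None, None] + C1).reshape(nb, h)
            Y = D[:, h:].reshape(nb, h // 4, 4).cumsum(axis=1).reshape(nb, h)
            back = xB[:, None] - Y  # x[B - s] for s = 1..h
            blockvals[:, h - 1 : B - 1] = back[:, ::-1][:, : h]
            blockvals[:, B - 1] = xB
            X[1:] = blockvals.reshape(-1)
        return X[:n].astype(np.uint32)
    out = np.empty(nb * B + 1, dtype=np.int64)
    out[0] = x0[0]
    dec = uc._DECODERS[v.scheme]
    reader = uc.BitReader(v.words, 0)
    pos = 1
    for b in range(nb):
        total = int(x0[b])
        for _ in range(B):
            total += dec(reader) - 1
            out[pos] = total
            pos += 1
    return out[:n].astype(np.uint32)


# ---------------------------------------------------------------------------
# Lookups
# ---------------------------------------------------------------------------


def _block_view(v: CompressedOffsetVector, b: int) -> PackedBlock:
    p0, p1 = int(v.pointers[b]) * 4, int(v.pointers[b + 1]) * 4
    width = (p1 - p0) * 32 // v.block_size
    return PackedBlock(words=v.words[p0:p1], width=width, block_size=v.block_size)


def _decode_in_block(v: CompressedOffsetVector, b: int, r: int,
                     stats: Optional[DecodeStats], cache: Optional[dict]) -> int:
    x0 = int(v.prefix_sums[b])
    if v.is_bitpacked:
        scheme = BITPACKED_SCHEMES[v.scheme]
        packed = _block_view(v, b)
        if scheme.layout == bc.VERTICAL:
            return bc.decode_vertical_at(packed, x0, r, stats, _cache=cache)
        xB = int(v.prefix_sums[b + 1])
        return bc.decode_columnar_at(packed, (x0, xB), r, scheme.direction, stats, _cache=cache)
    return uc.decode_block_at(v.words, int(v.pointers[b]), x0, r, v.scheme, v.block_size)


def lookup(v: CompressedOffsetVector, i: int, stats: Optional[DecodeStats] = None) -> int:
    """Random-access read of ``offsets[i]``.

    Block-boundary indices come straight from the stored prefix sums without
    touching the bitstream.
    """
    if not 0 <= i < v.n:
        raise IndexError(f"index {i} out of range 0..{v.n - 1}")
    b, r = divmod(i, v.block_size)
    if r == 0:
        if stats is not None:
            stats.reset()
        return int(v.prefix_sums[b])
    return _decode_in_block(v, b, r, stats, None)


def lookup_pair_twopass(v: CompressedOffsetVector, i: int,
                        stats: Optional[DecodeStats] = None) -> tuple[int, int]:
    """``(offsets[i], offsets[i+1])`` via two independent decode calls."""
    if not 0 <= i < v.n - 1:
        raise IndexError(f"pair index {i} out of range 0..{v.n - 2}")
    if stats is None:
        return lookup(v, i), lookup(v, i + 1)
    stats.reset()
    s1, s2 = DecodeStats(), DecodeStats()
    a = lookup(v, i, s1)
    b = lookup(v, i + 1, s2)
    stats.group_steps = s1.group_steps + s2.group_steps
    stats.vector_loads = s1.vector_loads + s2.vector_loads
    stats.terms_summed = s1.terms_summed + s2.terms_summed
    return a, b


def lookup_pair_onepass(v: CompressedOffsetVector, i: int,
                        stats: Optional[DecodeStats] = None) -> tuple[int, int]:
    """``(offsets[i], offsets[i+1])`` in one merged pass.

    Adjacent in-block positions live in neighboring columns of the columnar
    layout (column 3 neighboring column 0), which are adjacent stripes, so
    the two decodes share already-loaded vectors; the universal codecs simply
    continue the serial scan by one more code.
    """
    if not 0 <= i < v.n - 1:
        raise IndexError(f"pair index {i} out of range 0..{v.n - 2}")
    if stats is not None:
        stats.reset()
    B = v.block_size
    b, r = divmod(i, B)
    if r == B - 1:  # the second value is the next block's stored prefix sum
        first = _decode_in_block(v, b, r, stats, None) if r else int(v.prefix_sums[b])
        return first, int(v.prefix_sums[b + 1])
    if r == 0:
        return int(v.prefix_sums[b]), _decode_in_block(v, b, 1, stats, None)
    if not v.is_bitpacked:
        return uc.decode_block_pair_at(v.words, int(v.pointers[b]),
                                       int(v.prefix_sums[b]), r, v.scheme, B)
    cache: dict = {}
    s1 = DecodeStats()
    s2 = DecodeStats()
    a = _decode_in_block(v, b, r, s1, cache)
    c = _decode_in_block(v, b, r + 1, s2, cache)
    if stats is not None:
        stats.group_steps = s1.group_steps + s2.group_steps
        stats.vector_loads = s1.vector_loads + s2.vector_loads  # cache-shared: misses only
        stats.terms_summed = s1.terms_summed + s2.terms_summed
    return a, c


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def serialize(v: CompressedOffsetVector, path) -> None:
    """Write the container: 'BPOF' header, meta arrays, then the bitstream."""
    header = _HEADER.pack(_MAGIC, _VERSION, _SCHEME_IDS[v.scheme], 0, v.block_size,
                          -1 if v.k is None else v.k, v.n, len(v.pointers))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(v.pointers.astype("<i8").tobytes())
        fh.write(v.prefix_sums.astype("<u4").tobytes())
        fh.write(np.asarray(v.words).astype("<u4").tobytes())


def deserialize(path) -> CompressedOffsetVector:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size or raw[:4] != _MAGIC:
        raise ContainerFormatError("unrecognized file: bad magic")
    magic, version, scheme_id, _, B, k, n, n_meta = _HEADER.unpack_from(raw)
    if version != _VERSION:
        raise ContainerFormatError(f"unrecognized container version {version}")
    if scheme_id not in _SCHEME_NAMES:
        raise ContainerFormatError(f"unknown scheme id {scheme_id}")
    scheme = _SCHEME_NAMES[scheme_id]
    pos = _HEADER.size
    need = n_meta * 8 + n_meta * 4
    if len(raw) < pos + need:
        raise ContainerFormatError("corrupt container: truncated metainformation")
    pointers = np.frombuffer(raw, dtype="<i8", count=n_meta, offset=pos).astype(np.int64)
    pos += n_meta * 8
    prefix_sums = np.frombuffer(raw, dtype="<u4", count=n_meta, offset=pos).astype(np.uint32)
    pos += n_meta * 4
    n_words = (len(raw) - pos) // 4
    v = CompressedOffsetVector(scheme, n,
                               np.frombuffer(raw, dtype="<u4", count=n_words, offset=pos).copy(),
                               pointers, prefix_sums, None if k < 0 else k)
    expected = int(pointers[-1]) * (4 if v.is_bitpacked else 0)
    if v.is_bitpacked and n_words < expected:
        raise ContainerFormatError("corrupt container: truncated bitstream")
    if not v.is_bitpacked and n_words * 32 < int(pointers[-1]):
        raise ContainerFormatError("corrupt container: truncated bitstream")
    return v


def storage_size_bytes(fmt: Union[str, CompressedOffsetVector],
                       k: Optional[int] = None, n: Optional[int] = None) -> int:
    """In-memory size accounting.

    ``storage_size_bytes("uncompressed", k=15)`` is the classic 4-bytes-per-
    entry offset array (4 GiB for 15-mers); a compressed vector is counted as
    4 bytes per bitstream word plus 8 bytes (pointer + prefix sum) per
    metainformation entry.
    """
    if isinstance(fmt, CompressedOffsetVector):
        return 4 * len(fmt.words) + 8 * len(fmt.pointers)
    if fmt == "uncompressed":
        if k is not None:
            return 4 * 4 ** k
        if n is not None:
            return 4 * n
        raise ValueError("give k or n for the uncompressed size")
    raise ValueError("pass a CompressedOffsetVector or the string 'uncompressed'")


def inspect_dump(v: CompressedOffsetVector, limit: Optional[int] = None) -> str:
    """Plain-text per-block dump: index, width (or bit length), pointer, prefix sum."""
    lines = [f"scheme={v.scheme} n={v.n} block_size={v.block_size} "
             f"blocks={v.n_blocks} words={len(v.words)} k={v.k}"]
    widths = v.widths() if v.is_bitpacked else np.diff(v.pointers)
    unit = "width" if v.is_bitpacked else "bits"
    lines.append(f"block\t{unit}\tpointer\tprefix_sum")
    nb = v.n_blocks if limit is None else min(limit, v.n_blocks)
    for b in range(nb):
        lines.append(f"{b}\t{int(widths[b])}\t{int(v.pointers[b])}\t{int(v.prefix_sums[b])}")
    if nb < v.n_blocks:
        lines.append(f"... ({v.n_blocks - nb} more blocks)")
    lines.append(f"sentinel\t-\t{int(v.pointers[-1])}\t{int(v.prefix_sums[-1])}")
    return "\n".join(lines)
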