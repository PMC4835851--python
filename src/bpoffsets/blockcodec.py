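"""Block codecs for differential bitpacking of monotone integer arrays.

A block holds ``B`` consecutive differences of a monotone nondecreasing
sequence, stored with a single uniform bit width chosen per block.  Within a
128-bit vector of four 32-bit words, each word position is a *lane*; the
difference schemes keep four running sums, one per lane, so the stored
differences are lane-cyclic (``x[i+4] - x[i]``) rather than adjacent.

Two packing layouts are provided:

* **vertical** — differences striped across lanes in index order, decoded
  serially front-to-back (the classic BP128 arrangement at block size 64);
* **columnar** — the differences of one *column* (the lane-cyclic chain that
  feeds a single target position) packed contiguously, so random access to
  one value touches only its own column.

The columnar layout is paired with a **bidirectional** difference scheme:
the first half-block is encoded forward from the block's beginning prefix
sum, the second half backward from the ending prefix sum (which is the next
block's beginning prefix sum and therefore already stored).  Every block
position is then within two group-decode steps of a stored prefix sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache, partial
from typing import Optional, Sequence

import numpy as np

from .exceptions import NonMonotonicError, WidthOverflowError

VERTICAL = "vertical"
COLUMNAR = "columnar"
UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"

_WORD_MASK = 0xFFFFFFFF


@dataclass(frozen=True)
class BlockScheme:
    """Layout + difference direction + block size of one bitpacked codec."""

    layout: str
    direction: str
    block_size: int

    def __post_init__(self) -> None:
        if self.layout not in (VERTICAL, COLUMNAR):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.direction not in (UNIDIRECTIONAL, BIDIRECTIONAL):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.block_size not in (32, 64):
            raise ValueError("block_size must be 32 or 64")
        if self.layout == VERTICAL and self.direction != UNIDIRECTIONAL:
            raise ValueError("the vertical layout is unidirectional")

    @property
    def width_step(self) -> int:
        """Granularity of allowed bit widths (2 for block 64, 4 for block 32).

        Widths are restricted so that a block always fills a whole number of
        128-bit vectors: block_size * width must be a multiple of 128.
        """
        return 128 // self.block_size

    @property
    def allowed_widths(self) -> tuple[int, ...]:
        return tuple(range(0, 33, self.width_step))


# The three shipped bitpacked configurations.
BP64_VERTICAL = BlockScheme(VERTICAL, UNIDIRECTIONAL, 64)
BP64_COLUMNAR = BlockScheme(COLUMNAR, BIDIRECTIONAL, 64)
BP32_COLUMNAR = BlockScheme(COLUMNAR, BIDIRECTIONAL, 32)


@dataclass
class DiffBlock:
    """Differences of one block plus its two bounding prefix sums."""

    diffs: np.ndarray  # length B, nonnegative int64
    x0: int  # prefix sum at the block's first element
    x_end: int  # prefix sum at the block's last element (= next block's x0)
    direction: str = UNIDIRECTIONAL


@dataclass
class PackedBlock:
    """Bit-packed differences of one block: 32-bit words at a uniform width."""

    words: np.ndarray  # uint32, grouped in vectors of four
    width: int
    block_size: int


@dataclass
class DecodeStats:
    """Operation counters for one decode call.

    group_steps
        shift/mask/add cycles over groups of four lane entries (the unit the
        step-count claims are stated in).
    vector_loads
        distinct four-word vectors actually read from the block.
    terms_summed
        scalar terms added after the final parallel addition (columnar only).
    """

    group_steps: int = 0
    vector_loads: int = 0
    terms_summed: int = 0

    def reset(self) -> None:
        self.group_steps = 0
        self.vector_loads = 0
        self.terms_summed = 0


@dataclass(frozen=True)
class ColumnAddress:
    """Where a block position lives in the columnar layout."""

    r: int
    delta: int  # distance to the nearest stored prefix sum
    column: Optional[int]  # delta mod 4; None when r sits on the far prefix sum
    quarter: int  # 1..4
    row: Optional[int]  # floor(delta / 4) within the column


def locate_column(r: int, block_size: int = 64, direction: str = BIDIRECTIONAL) -> ColumnAddress:
    """Map block position ``r`` (1-based) to its column/row/quarter address.

    For the bidirectional scheme the distance to the nearest prefix sum is
    ``delta = (B/2 - 1) - |r - B/2|`` (for B = 64: ``31 - |r - 32|``); the
    unidirectional scheme measures from the block start, ``delta = r - 1``.
    """
    B = block_size
    if not 1 <= r <= B:
        raise IndexError(f"block position {r} out of range 1..{B}")
    quarter = (r - 1) // (B // 4) + 1
    if direction == BIDIRECTIONAL:
        delta = (B // 2 - 1) - abs(r - B // 2)
    elif direction == UNIDIRECTIONAL:
        delta = r - 1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if delta < 0:  # r == B under the bidirectional scheme: value is x_B itself
        return ColumnAddress(r=r, delta=delta, column=None, quarter=quarter, row=None)
    return ColumnAddress(r=r, delta=delta, column=delta % 4, quarter=quarter, row=delta // 4)


# ---------------------------------------------------------------------------
# Difference transforms
# ---------------------------------------------------------------------------


def _check_block(x: Sequence[int], block_size: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.shape != (block_size + 1,):
        raise ValueError(f"expected {block_size + 1} values, got {x.shape}")
    if np.any(np.diff(x) < 0):
        raise NonMonotonicError("negative difference: input is not monotone nondecreasing")
    return x


def diffs_unidirectional(x: Sequence[int], block_size: int = 64) -> DiffBlock:
    """Lane-cyclic forward differences of ``block_size + 1`` monotone values.

    ``d[i] = x[i+1] - x[i-3]`` for ``i >= 4``; the first four differences are
    taken relative to the block prefix sum ``x[0]``.
    """
    x = _check_block(x, block_size)
    B = block_size
    d = np.empty(B, dtype=np.int64)
    d[:4] = x[1:5] - x[0]
    d[4:] = x[5 : B + 1] - x[1 : B - 3]
    return DiffBlock(diffs=d, x0=int(x[0]), x_end=int(x[B]), direction=UNIDIRECTIONAL)


def diffs_bidirectional(x: Sequence[int], block_size: int = 64) -> DiffBlock:
    """Bidirectional lane-cyclic differences.

    The first half-block matches :func:`diffs_unidirectional` relative to
    ``x[0]``; the second half encodes the mirrored chain toward ``x[B]``, so a
    second-half value is recovered by subtracting a short cumulative sum from
    the ending prefix sum.  ``x[B/2]`` reconstructs identically from either end.
    """
    x = _check_block(x, block_size)
    B = block_size
    h = B // 2
    d = np.empty(B, dtype=np.int64)
    d[:4] = x[1:5] - x[0]
    d[4:h] = x[5 : h + 1] - x[1 : h - 3]
    # second half, mirrored: with y[s] = x[B] - x[B - s], d[h + j] is the
    # unidirectional difference of y, i.e. y[j+1] - y[j-3] (y[<=0] = 0)
    j = np.arange(4, h)
    d[h : h + 4] = x[B] - x[B - 1 : B - 5 : -1]
    d[h + 4 :] = x[B + 3 - j] - x[B - 1 - j]
    return DiffBlock(diffs=d, x0=int(x[0]), x_end=int(x[B]), direction=BIDIRECTIONAL)


def undiff(block: DiffBlock, block_size: Optional[int] = None) -> np.ndarray:
    """Invert the difference transform, returning the ``B + 1`` original values."""
    d = np.asarray(block.diffs, dtype=np.int64)
    B = block_size if block_size is not None else len(d)
    if len(d) != B:
        raise ValueError("difference count does not match block size")
    x = np.empty(B + 1, dtype=np.int64)
    x[0] = block.x0
    if block.direction == UNIDIRECTIONAL:
        c = d.reshape(B // 4, 4).cumsum(axis=0)
        x[1:] = (block.x0 + c).reshape(B)
        return x
    h = B // 2
    c = d[:h].reshape(h // 4, 4).cumsum(axis=0)
    x[1 : h + 1] = (block.x0 + c).reshape(h)
    y = d[h:].reshape(h // 4, 4).cumsum(axis=0).reshape(h)  # y[s] for s = 1..h
    x_back = block.x_end - y
    if int(x_back[h - 1]) != int(x[h]):
        raise NonMonotonicError("half-block prefix sums disagree between directions")
    x[B] = block.x_end
    x[h:B][::-1] = x_back
    return x


# ---------------------------------------------------------------------------
# Width selection and storage arithmetic
# ---------------------------------------------------------------------------


def select_width(diffs, scheme: BlockScheme) -> int:
    """Smallest allowed bit width that fits the largest difference in the block.

    Width 0 flags the all-zero block; width 32 always suffices for 32-bit
    differences.  Block 64 rounds up to even widths, block 32 to multiples of
    four, so a block always fills whole 128-bit vectors.
    """
    if isinstance(diffs, DiffBlock):
        diffs = diffs.diffs
    m = int(np.max(diffs)) if len(diffs) else 0
    if m < 0:
        raise NonMonotonicError("negative difference")
    bits = m.bit_length()
    step = scheme.width_step
    return -(-bits // step) * step  # round up to the allowed granularity


def storage_size_vectors(block_size: int, width: int) -> float:
    """128-bit vectors needed to store one block (fractional for disallowed widths)."""
    if not 0 <= width <= 32:
        raise ValueError("width out of range 0..32")
    return block_size * width / 128


# ---------------------------------------------------------------------------
# Lane orders: which difference index sits at position j of lane l
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _lane_order(layout: str, direction: str, block_size: int) -> np.ndarray:
    """(4, B/4) table: entry [l, j] is the diff index at slot j of lane l.

    Slot j of lane l occupies lane bits ``[j*width, (j+1)*width)``; lane l's
    bits live in words ``4*v + l``.

    * vertical: slots follow index order, ``idx = 4j + l``.
    * columnar unidirectional: columns 0..3 in order, each column's rows
      striped in groups of four across lanes.
    * columnar bidirectional: first-half columns 0..3, then second-half
      columns 3..0, so that the neighboring column of any column (successor
      for the first half, predecessor for the mirrored second half) is the
      adjacent stripe — the property one-pass pair retrieval relies on.
    """
    B = block_size
    order = np.empty((4, B // 4), dtype=np.int64)
    if layout == VERTICAL:
        for l in range(4):
            order[l] = 4 * np.arange(B // 4) + l
        return order
    if direction == UNIDIRECTIONAL:
        g_per_col = B // 16
        for l in range(4):
            j = 0
            for c in range(4):
                for g in range(g_per_col):
                    order[l, j] = c + 4 * (4 * g + l)
                    j += 1
        return order
    h = B // 2
    g_per_col = h // 16 or 1  # groups of four rows per half-column (2 for B=64, 1 for B=32)
    for l in range(4):
        j = 0
        for c in range(4):  # first half, columns in order
            for g in range(g_per_col):
                order[l, j] = c + 4 * (4 * g + l)
                j += 1
        for c in range(3, -1, -1):  # second half, columns reversed
            for g in range(g_per_col):
                order[l, j] = h + c + 4 * (4 * g + l)
                j += 1
    return order


# ---------------------------------------------------------------------------
# Packing / unpacking
# ---------------------------------------------------------------------------


def pack(diffs, width: int, scheme: BlockScheme) -> PackedBlock:
    """Pack one block of differences at a uniform bit width.

    Bit order within a lane is least-significant-first; a value straddling a
    32-bit word boundary puts its low bits in the earlier vector.
    """
    if isinstance(diffs, DiffBlock):
        diffs = diffs.diffs
    d = np.asarray(diffs, dtype=np.int64)
    B = scheme.block_size
    if d.shape != (B,):
        raise ValueError(f"expected {B} differences")
    if width not in scheme.allowed_widths:
        raise ValueError(f"width {width} not allowed for block size {B}")
    if np.any(d < 0):
        raise NonMonotonicError("negative difference")
    if width < 32 and np.any(d >= (1 << width)):
        raise WidthOverflowError(f"difference does not fit in {width} bits")
    n_words = B * width // 32
    words = np.zeros(n_words, dtype=np.uint32)
    if width == 0:
        return PackedBlock(words=words, width=0, block_size=B)
    order = _lane_order(scheme.layout, scheme.direction, B)
    for l in range(4):
        acc = 0
        for j, idx in enumerate(order[l]):
            acc |= int(d[idx]) << (j * width)
        for v in range(n_words // 4):
            words[4 * v + l] = (acc >> (32 * v)) & _WORD_MASK
    return PackedBlock(words=words, width=width, block_size=B)


def unpack(packed: PackedBlock, scheme: BlockScheme) -> np.ndarray:
    """Invert :func:`pack`, returning the block's differences in index order."""
    B = scheme.block_size
    if packed.block_size != B:
        raise ValueError("block size mismatch")
    w = packed.width
    d = np.zeros(B, dtype=np.int64)
    if w == 0:
        return d
    order = _lane_order(scheme.layout, scheme.direction, B)
    mask = (1 << w) - 1
    for l in range(4):
        acc = 0
        for v in range(len(packed.words) // 4):
            acc |= int(packed.words[4 * v + l]) << (32 * v)
        for j, idx in enumerate(order[l]):
            d[idx] = (acc >> (j * w)) & mask
    return d


# Vectorized multi-block packing used by the container codec. --------------


def pack_blocks(D: np.ndarray, widths: np.ndarray, scheme: BlockScheme) -> tuple[np.ndarray, np.ndarray]:
    """Pack many blocks at once.

    Parameters
    ----------
    D : (nb, B) nonnegative differences
    widths : (nb,) selected width per block (allowed values only)

    Returns
    -------
    words : concatenated uint32 bitstream of all blocks, in block order
    word_starts : (nb + 1,) word offset of each block in ``words``
    """
    nb, B = D.shape
    counts = widths.astype(np.int64) * B // 32
    word_starts = np.zeros(nb + 1, dtype=np.int64)
    np.cumsum(counts, out=word_starts[1:])
    words = np.zeros(int(word_starts[-1]), dtype=np.uint32)
    order = _lane_order(scheme.layout, scheme.direction, B).T.reshape(-1)  # slot-major: (j, l)
    for w in np.unique(widths):
        w = int(w)
        if w == 0:
            continue
        sel = np.flatnonzero(widths == w)
        vals = D[sel][:, order].astype(np.uint64).reshape(len(sel), B // 4, 4)
        out = np.zeros((len(sel), w * B // 128, 4), dtype=np.uint64)
        for j in range(B // 4):
            off = j * w
            vi, sh = off >> 5, off & 31
            out[:, vi, :] |= (vals[:, j, :] << np.uint64(sh)) & np.uint64(_WORD_MASK)
            if sh + w > 32:
                out[:, vi + 1, :] |= vals[:, j, :] >> np.uint64(32 - sh)
        flat = out.reshape(len(sel), -1).astype(np.uint32)
        starts = word_starts[sel]
        idx = starts[:, None] + np.arange(flat.shape[1])[None, :]
        words[idx.reshape(-1)] = flat.reshape(-1)
    return words, word_starts


def unpack_blocks(words: np.ndarray, word_starts: np.ndarray, widths: np.ndarray, scheme: BlockScheme) -> np.ndarray:
    """Invert :func:`pack_blocks`; returns the (nb, B) difference matrix."""
    nb = len(widths)
    B = scheme.block_size
    D = np.zeros((nb, B), dtype=np.int64)
    order = _lane_order(scheme.layout, scheme.direction, B).T.reshape(-1)
    inv = np.empty_like(order)
    inv[order] = np.arange(B)
    for w in np.unique(widths):
        w = int(w)
        if w == 0:
            continue
        sel = np.flatnonzero(widths == w)
        n_words = w * B // 32
        starts = word_starts[sel]
        idx = starts[:, None] + np.arange(n_words)[None, :]
        blk = words[idx.reshape(-1)].reshape(len(sel), n_words // 4, 4).astype(np.uint64)
        vals = np.empty((len(sel), B // 4, 4), dtype=np.uint64)
        mask = np.uint64((1 << w) - 1)
        for j in range(B // 4):
            off = j * w
            vi, sh = off >> 5, off & 31
            v = blk[:, vi, :] >> np.uint64(sh)
            if sh + w > 32:
                v |= blk[:, vi + 1, :] << np.uint64(32 - sh)
            vals[:, j, :] = v & mask
        D[sel[:, None], order[None, :]] = vals.reshape(len(sel), B).astype(np.int64)
    return D


# ---------------------------------------------------------------------------
# Random-access decoding
# ---------------------------------------------------------------------------


def _load_vector(words: np.ndarray, v: int, cache: dict, stats: DecodeStats) -> tuple[int, int, int, int]:
    vec = cache.get(v)
    if vec is None:
        base = 4 * v
        vec = (int(words[base]), int(words[base + 1]), int(words[base + 2]), int(words[base + 3]))
        cache[v] = vec
        stats.vector_loads += 1
    return vec


def _read_group(words: np.ndarray, width: int, lane_bit: int, cache: dict, stats: DecodeStats) -> list[int]:
    """Extract the four lane values whose bits start at ``lane_bit`` in each lane."""
    v1, sh = lane_bit >> 5, lane_bit & 31
    mask = (1 << width) - 1
    w1 = _load_vector(words, v1, cache, stats)
    if sh + width <= 32:
        return [(w1[l] >> sh) & mask for l in range(4)]
    w2 = _load_vector(words, v1 + 1, cache, stats)
    return [((w1[l] >> sh) | (w2[l] << (32 - sh))) & mask for l in range(4)]


def decode_vertical_at(
    packed: PackedBlock,
    x0: int,
    r: int,
    stats: Optional[DecodeStats] = None,
    _cache: Optional[dict] = None,
) -> int:
    """Serially decode the vertical layout up to block position ``r`` (1-based).

    Performs ``ceil(r / 4)`` shift/mask/add cycles, maintaining four running
    lane sums, and returns the exact cumulative value ``x_r``.
    """
    B = packed.block_size
    if not 1 <= r <= B:
        raise IndexError(f"block position {r} out of range 1..{B}")
    if stats is None:
        stats = DecodeStats()
    else:
        stats.reset()
    cache = _cache if _cache is not None else {}
    G = -(-r // 4)
    stats.group_steps += G
    if packed.width == 0:
        return x0
    sums = [0, 0, 0, 0]
    for t in range(G):
        vals = _read_group(packed.words, packed.width, t * packed.width, cache, stats)
        for l in range(4):
            sums[l] += vals[l]
    return x0 + sums[(r - 1) % 4]


def _columnar_groups_needed(quarter: int, direction: str, groups_per_column: int) -> int:
    if direction == BIDIRECTIONAL:
        g = quarter if quarter <= 2 else 5 - quarter  # 1/2/2/1 pattern
    else:
        g = quarter  # 1/2/3/4 pattern
    return min(g, groups_per_column)


def decode_columnar_at(
    packed: PackedBlock,
    meta: tuple[int, int],
    r: int,
    direction: str = BIDIRECTIONAL,
    stats: Optional[DecodeStats] = None,
    _cache: Optional[dict] = None,
) -> int:
    """Random-access decode of ``x_r`` from a columnar block.

    ``meta`` is the pair (beginning prefix sum, ending prefix sum).  The
    decode loads only the column addressed by :func:`locate_column`, chains
    parallel additions over its groups, and finishes with a scalar summation
    of at most four terms.  Width 0 short-circuits to the prefix sum.
    """
    x0, x_end = meta
    B = packed.block_size
    if not 1 <= r <= B:
        raise IndexError(f"block position {r} out of range 1..{B}")
    if stats is None:
        stats = DecodeStats()
    else:
        stats.reset()
    if packed.width == 0:
        return x0
    addr = locate_column(r, B, direction)
    if addr.column is None:  # bidirectional r == B: the stored ending prefix sum
        return x_end
    w = packed.width
    if direction == BIDIRECTIONAL:
        h = B // 2
        groups_per_column = (h // 4) // 4 or 1
        second = r > h
        seg = (4 + (3 - addr.column)) if second else addr.column
    else:
        groups_per_column = (B // 4) // 4 or 1
        second = False
        seg = addr.column
    G = _columnar_groups_needed(addr.quarter, direction, groups_per_column)
    cache = _cache if _cache is not None else {}
    base = seg * groups_per_column * w
    cums: list[list[int]] = []
    for g in range(G):
        vals = _read_group(packed.words, w, base + g * w, cache, stats)
        stats.group_steps += 1
        if cums:
            prev = cums[-1]
            vals = [prev[l] + vals[l] for l in range(4)]  # parallel addition
        cums.append(vals)
    g, m = divmod(addr.row, 4)
    terms = cums[g][: m + 1]
    if g >= 1:
        terms = terms + cums[g - 1][m + 1 :]
    stats.terms_summed += len(terms)
    s = sum(terms)
    return x_end - s if second else x0 + s


# ---------------------------------------------------------------------------
# Jump-table dispatch
# ---------------------------------------------------------------------------


def _dispatch_decode(packed: PackedBlock, meta: tuple[int, int], r: int, *, width: int,
                     column: int, quarter: int, direction: str, block_size: int,
                     stats: Optional[DecodeStats] = None) -> int:
    addr = locate_column(r, block_size, direction)
    if packed.width != width or addr.column != column or addr.quarter != quarter:
        raise ValueError("jump-table entry invoked for the wrong (width, column, quarter)")
    return decode_columnar_at(packed, meta, r, direction, stats)


@lru_cache(maxsize=None)
def jump_table(block_size: int = 64, direction: str = BIDIRECTIONAL):
    """Indexed dispatch for columnar decoding, keyed by (width, column, quarter).

    Nonzero allowed widths x 4 columns x 4 quarters; for block size 64 that
    is 16 x 4 x 4 = 256 entries.  Width 0 is handled outside the table.
    """
    scheme = BlockScheme(COLUMNAR, direction, block_size)
    return {
        (w, c, q): partial(_dispatch_decode, width=w, column=c, quarter=q,
                           direction=direction, block_size=block_size)
        for w in scheme.allowed_widths if w > 0
        for c in range(4)
        for q in range(1, 5)
    }


@lru_cache(maxsize=None)
def primitive_procedures(block_size: int = 64, direction: str = BIDIRECTIONAL):
    """The primitive Q2/Q3 decode variants.

    Q1 values fall out en route to Q2 and Q4 en route to Q3, so only the Q2
    and Q3 procedures are distinct: nonzero widths x 4 columns x 2 quarters
    (128 for block size 64).
    """
    table = jump_table(block_size, direction)
    return {key: proc for key, proc in table.items() if key[2] in (2, 3)}
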