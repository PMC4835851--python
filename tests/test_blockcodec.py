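"""Block codec unit and property tests: difference schemes, packing, decoding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bpoffsets import blockcodec as bc
from bpoffsets.exceptions import NonMonotonicError, WidthOverflowError

UNI_COLUMNAR_64 = bc.BlockScheme(bc.COLUMNAR, bc.UNIDIRECTIONAL, 64)
ALL_BLOCK_SCHEMES = [bc.BP64_VERTICAL, bc.BP64_COLUMNAR, bc.BP32_COLUMNAR, UNI_COLUMNAR_64]


def monotone_blocks(block_size=64, max_step=1000):
    return st.lists(st.integers(0, max_step), min_size=block_size, max_size=block_size).map(
        lambda steps: np.cumsum(np.concatenate([[50], steps]))
    )


# -- width selection --------------------------------------------------------


@pytest.mark.parametrize(
    "maxdiff,block_size,expected",
    [
        (0, 64, 0),  # all-zero block: the width-0 special case
        (63, 64, 6),
        (7, 64, 4),  # 3 bits rounds up: same storage as width 4
        (7, 32, 4),
        (63, 32, 8),  # 6 bits rounds to the next multiple of 4
        ((1 << 32) - 1, 64, 32),
    ],
)
def test_select_width_rounds_to_allowed_granularity(maxdiff, block_size, expected):
    scheme = bc.BP64_COLUMNAR if block_size == 64 else bc.BP32_COLUMNAR
    diffs = np.zeros(block_size, dtype=np.int64)
    diffs[3] = maxdiff
    assert bc.select_width(diffs, scheme) == expected


def test_width_zero_iff_all_zero():
    scheme = bc.BP64_VERTICAL
    assert bc.select_width(np.zeros(64, np.int64), scheme) == 0
    d = np.zeros(64, np.int64)
    d[0] = 1
    assert bc.select_width(d, scheme) == 2


@pytest.mark.parametrize(
    "block_size,width,vectors",
    [(128, 3, 3), (64, 4, 2), (64, 6, 3), (64, 0, 0), (32, 4, 1)],
)
def test_storage_size_vectors(block_size, width, vectors):
    assert bc.storage_size_vectors(block_size, width) == vectors


# -- difference schemes -----------------------------------------------------


@given(monotone_blocks())
def test_unidirectional_round_trip(x):
    db = bc.diffs_unidirectional(x)
    assert np.all(db.diffs >= 0)
    assert np.array_equal(bc.undiff(db), x)


@given(monotone_blocks())
def test_bidirectional_round_trip_and_midpoint_agreement(x):
    db = bc.diffs_bidirectional(x)
    assert np.all(db.diffs >= 0)
    assert np.array_equal(bc.undiff(db), x)
    # x_32 computed from the front equals x_32 computed from the back
    front = db.x0 + sum(int(db.diffs[3 + 4 * t]) for t in range(8))
    back = db.x_end - sum(int(db.diffs[32 + 3 + 4 * t]) for t in range(8))
    assert front == back == x[32]


@pytest.mark.parametrize("transform", [bc.diffs_unidirectional, bc.diffs_bidirectional])
def test_constant_block_gives_all_zero_diffs(transform):
    x = np.full(65, 42)
    assert np.all(transform(x).diffs == 0)


def test_non_monotone_input_rejected():
    x = np.arange(65)
    x[30] = 0
    with pytest.raises(NonMonotonicError):
        bc.diffs_unidirectional(x)


@pytest.mark.parametrize("block_size", [32, 64])
def test_block32_round_trips(block_size, rng):
    x = np.cumsum(np.concatenate([[9], rng.integers(0, 99, block_size)]))
    for fn in (bc.diffs_unidirectional, bc.diffs_bidirectional):
        assert np.array_equal(bc.undiff(fn(x, block_size), block_size), x)


# -- packing ----------------------------------------------------------------


@pytest.mark.parametrize("scheme", ALL_BLOCK_SCHEMES, ids=str)
def test_pack_round_trip_all_widths(scheme, rng):
    for w in scheme.allowed_widths:
        hi = 1 << w if w else 1
        d = rng.integers(0, hi, scheme.block_size).astype(np.int64)
        if w:
            d[0] = hi - 1  # force the full width to be exercised
        p = bc.pack(d, w, scheme)
        assert len(p.words) == scheme.block_size * w // 32  # no padding
        assert np.array_equal(bc.unpack(p, scheme), d)


def test_pack_width_zero_is_empty():
    p = bc.pack(np.zeros(64, np.int64), 0, bc.BP64_VERTICAL)
    assert len(p.words) == 0
    assert np.all(bc.unpack(p, bc.BP64_VERTICAL) == 0)


def test_pack_rejects_overflow_and_odd_widths():
    d = np.zeros(64, np.int64)
    d[5] = 64
    with pytest.raises(WidthOverflowError):
        bc.pack(d, 6, bc.BP64_COLUMNAR)
    with pytest.raises(ValueError):
        bc.pack(np.zeros(64, np.int64), 3, bc.BP64_COLUMNAR)
    with pytest.raises(ValueError):
        bc.pack(np.zeros(32, np.int64), 6, bc.BP32_COLUMNAR)


def test_columnar_bidirectional_bit_positions_match_worked_example():
    """Width 6: first-half column 2, group 0 sits at lane bits 24-29 (one
    24-bit right shift exposes it); group 1 straddles the word boundary and
    needs a 30-bit right shift of vector 0 plus a 2-bit left shift of vector 1."""
    d = np.zeros(64, dtype=np.int64)
    d[2], d[6], d[10], d[14] = 0b101011, 1, 2, 3  # column 2 rows 0-3 -> lanes 0-3
    d[18] = 0b110101  # column 2 row 4 -> lane 0, group 1
    p = bc.pack(d, 6, bc.BP64_COLUMNAR)
    for lane, val in enumerate([0b101011, 1, 2, 3]):
        assert (int(p.words[lane]) >> 24) & 0x3F == val
    lane0_v0, lane0_v1 = int(p.words[0]), int(p.words[4])
    assert ((lane0_v0 >> 30) | (lane0_v1 << 2)) & 0x3F == 0b110101


def test_pack_blocks_matches_single_block_pack(rng):
    for scheme in ALL_BLOCK_SCHEMES:
        B = scheme.block_size
        D = rng.integers(0, 70, (9, B)).astype(np.int64)
        D[0] = 0  # a width-0 block in the batch
        widths = np.array([bc.select_width(d, scheme) for d in D])
        words, starts = bc.pack_blocks(D, widths, scheme)
        for b in range(9):
            single = bc.pack(D[b], int(widths[b]), scheme)
            assert np.array_equal(words[starts[b] : starts[b + 1]], single.words)
        assert np.array_equal(bc.unpack_blocks(words, starts, widths, scheme), D)


# -- addressing -------------------------------------------------------------


@pytest.mark.parametrize(
    "r,direction,delta,column,quarter,row",
    [
        (23, bc.BIDIRECTIONAL, 22, 2, 2, 5),
        (1, bc.BIDIRECTIONAL, 0, 0, 1, 0),
        (43, bc.BIDIRECTIONAL, 20, 0, 3, 5),
        (43, bc.UNIDIRECTIONAL, 42, 2, 3, 10),
        (64, bc.UNIDIRECTIONAL, 63, 3, 4, 15),
    ],
)
def test_locate_column(r, direction, delta, column, quarter, row):
    addr = bc.locate_column(r, 64, direction)
    assert (addr.delta, addr.column, addr.quarter, addr.row) == (delta, column, quarter, row)


def test_locate_column_distance_formula_and_range():
    for r in range(1, 65):
        addr = bc.locate_column(r, 64, bc.BIDIRECTIONAL)
        assert addr.delta == 31 - abs(r - 32)
    with pytest.raises(IndexError):
        bc.locate_column(0, 64, bc.BIDIRECTIONAL)
    with pytest.raises(IndexError):
        bc.locate_column(65, 64, bc.BIDIRECTIONAL)


def test_adjacent_positions_use_neighboring_columns():
    """Column 3 neighbors column 0: the cycle one-pass pair retrieval uses."""
    for r in range(1, 32):
        c1 = bc.locate_column(r, 64, bc.BIDIRECTIONAL).column
        c2 = bc.locate_column(r + 1, 64, bc.BIDIRECTIONAL).column
        assert c2 == (c1 + 1) % 4


# -- decoding ---------------------------------------------------------------


def _packed(x, scheme):
    fn = bc.diffs_bidirectional if scheme.direction == bc.BIDIRECTIONAL else bc.diffs_unidirectional
    db = fn(x, scheme.block_size)
    return bc.pack(db, bc.select_width(db, scheme), scheme), db


@pytest.mark.parametrize("scheme", ALL_BLOCK_SCHEMES, ids=str)
def test_decode_at_matches_prefix_sum_oracle_exhaustively(scheme, rng):
    B = scheme.block_size
    for trial in range(4):
        steps = rng.integers(0, [1, 9, 500, 80000][trial], B)
        x = np.cumsum(np.concatenate([[rng.integers(0, 10**6)], steps]))
        packed, db = _packed(x, scheme)
        for r in range(1, B + 1):
            if scheme.layout == bc.VERTICAL:
                got = bc.decode_vertical_at(packed, db.x0, r)
            else:
                got = bc.decode_columnar_at(packed, (db.x0, db.x_end), r, scheme.direction)
            assert got == x[r], (scheme, r)


def test_vertical_steps_are_ceil_r_over_4(monotone_block):
    packed, db = _packed(monotone_block, bc.BP64_VERTICAL)
    stats = bc.DecodeStats()
    for r in range(1, 65):
        bc.decode_vertical_at(packed, db.x0, r, stats)
        assert stats.group_steps == -(-r // 4)
    bc.decode_vertical_at(packed, db.x0, 43, stats)
    assert stats.group_steps == 11


def test_columnar_step_patterns(monotone_block):
    """Unidirectional columnar needs 1/2/3/4 group steps for Q1-Q4;
    the bidirectional scheme needs only 1/2/2/1."""
    pu, dbu = _packed(monotone_block, UNI_COLUMNAR_64)
    pb, dbb = _packed(monotone_block, bc.BP64_COLUMNAR)
    stats = bc.DecodeStats()
    for r in range(1, 64):
        q = (r - 1) // 16 + 1
        bc.decode_columnar_at(pu, (dbu.x0, dbu.x_end), r, bc.UNIDIRECTIONAL, stats)
        assert stats.group_steps == q
        bc.decode_columnar_at(pb, (dbb.x0, dbb.x_end), r, bc.BIDIRECTIONAL, stats)
        assert stats.group_steps == {1: 1, 2: 2, 3: 2, 4: 1}[q]
        assert stats.group_steps <= 2


def test_reaching_x43_costs_11_vertical_3_unidirectional_2_bidirectional(monotone_block):
    stats = bc.DecodeStats()
    pv, dbv = _packed(monotone_block, bc.BP64_VERTICAL)
    bc.decode_vertical_at(pv, dbv.x0, 43, stats)
    assert stats.group_steps == 11
    pu, dbu = _packed(monotone_block, UNI_COLUMNAR_64)
    bc.decode_columnar_at(pu, (dbu.x0, dbu.x_end), 43, bc.UNIDIRECTIONAL, stats)
    assert stats.group_steps == 3
    pb, dbb = _packed(monotone_block, bc.BP64_COLUMNAR)
    bc.decode_columnar_at(pb, (dbb.x0, dbb.x_end), 43, bc.BIDIRECTIONAL, stats)
    assert stats.group_steps == 2


def test_at_most_four_terms_summed_and_x23_uses_exactly_four(monotone_block):
    packed, db = _packed(monotone_block, bc.BP64_COLUMNAR)
    stats = bc.DecodeStats()
    for r in range(1, 64):
        bc.decode_columnar_at(packed, (db.x0, db.x_end), r, bc.BIDIRECTIONAL, stats)
        assert 1 <= stats.terms_summed <= 4
    bc.decode_columnar_at(packed, (db.x0, db.x_end), 23, bc.BIDIRECTIONAL, stats)
    assert stats.terms_summed == 4


def test_width_zero_short_circuits_columnar(monotone_block):
    packed = bc.pack(np.zeros(64, np.int64), 0, bc.BP64_COLUMNAR)
    stats = bc.DecodeStats()
    assert bc.decode_columnar_at(packed, (7, 7), 30, bc.BIDIRECTIONAL, stats) == 7
    assert stats.group_steps == 0 and stats.vector_loads == 0


def test_decode_rejects_out_of_range_positions(monotone_block):
    packed, db = _packed(monotone_block, bc.BP64_COLUMNAR)
    for bad in (0, 65):
        with pytest.raises(IndexError):
            bc.decode_columnar_at(packed, (db.x0, db.x_end), bad)
        with pytest.raises(IndexError):
            bc.decode_vertical_at(_packed(monotone_block, bc.BP64_VERTICAL)[0], db.x0, bad)


# -- jump-table dispatch ----------------------------------------------------


def test_jump_table_has_256_entries_and_128_primitives():
    table = bc.jump_table(64)
    assert len(table) == 256  # 16 even widths x 4 columns x 4 quarters
    assert len({k[0] for k in table}) == 16
    prim = bc.primitive_procedures(64)
    assert len(prim) == 128  # only Q2/Q3 are primitive
    assert {k[2] for k in prim} == {2, 3}


def test_jump_table_dispatch_agrees_with_direct_decode(monotone_block):
    packed, db = _packed(monotone_block, bc.BP64_COLUMNAR)
    table = bc.jump_table(64)
    for r in range(1, 64):
        addr = bc.locate_column(r, 64, bc.BIDIRECTIONAL)
        proc = table[(packed.width, addr.column, addr.quarter)]
        assert proc(packed, (db.x0, db.x_end), r) == monotone_block[r]
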