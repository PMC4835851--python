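"""Lookup hash tables for genomic k-mers.

A lookup hash table maps every possible k-mer (4**k of them, over {A,C,G,T})
to the list of its genomic start positions.  It is stored as two arrays: an
*offset array* of length 4**k + 1 whose entry ``m`` points at the start of
k-mer ``m``'s list inside a concatenated *positions array*; the pair
``(offsets[m], offsets[m+1])`` delimits the list.  The offset array is
monotone nondecreasing — the property the compressed containers exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

from .exceptions import KTooLargeError, UnencodableKmerError

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}

# 2-bit base codes by ASCII value; -1 marks ambiguity codes (N, IUPAC, ...)
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODES.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c


@dataclass
class GenomeSequence:
    """A named DNA sequence, 0-based coordinates."""

    name: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class HashTable:
    """Offset array + positions array for all k-mers of a genome."""

    k: int
    sampling: int
    offsets: np.ndarray  # uint32, length 4**k + 1, monotone nondecreasing
    positions: np.ndarray  # uint32, genomic start positions grouped by k-mer code


def encode_kmer(kmer: str) -> int:
    """Base-4 code of a k-mer: A=0, C=1, G=2, T=3, leftmost base most significant."""
    code = 0
    for ch in kmer:
        c = _LUT[ord(ch)] if ord(ch) < 256 else -1
        if c < 0:
            raise UnencodableKmerError(f"unencodable k-mer: base {ch!r} is not A/C/G/T")
        code = (code << 2) | int(c)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= code < 4 ** k:
        raise IndexError(f"code {code} out of range for k={k}")
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def read_fasta(path, separator: str = "N") -> GenomeSequence:
    """Read a (multi-record) FASTA file into one global coordinate space.

    Records are concatenated with a non-ACGT separator so that no k-mer spans
    records; positions are global over the concatenation.  Bases are treated
    case-insensitively.
    """
    parts = []
    names = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts.append(str(rec.seq).upper())
        names.append(rec.id)
    if not parts:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(name="|".join(names), bases=separator.join(parts))


def build_hash_table(genome: GenomeSequence, k: int, sampling: int = 1,
                     max_k: int = 15) -> HashTable:
    """Count-then-prefix-sum construction of the lookup table.

    Stores position ``p`` for every ``p`` with ``p % sampling == 0``,
    ``p + k <= len(genome)`` and the k-mer at ``p`` entirely in {A,C,G,T};
    k-mers containing any other character are skipped, not masked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sampling < 1:
        raise ValueError("sampling must be >= 1")
    if k > max_k:
        raise KTooLargeError(f"k={k}: a 4**{k} + 1 offset array cannot be allocated")
    n_entries = 4 ** k + 1
    seq = np.frombuffer(genome.bases.upper().encode("ascii", "replace"), dtype=np.uint8)
    base_codes = _LUT[seq].astype(np.int64)
    n = len(seq)
    if n < k:
        return HashTable(k, sampling, np.zeros(n_entries, np.uint32), np.zeros(0, np.uint32))
    # windows touching an invalid base are found via a cumulative bad count
    bad = np.concatenate([[0], np.cumsum(base_codes < 0)])
    p = np.arange(0, n - k + 1, sampling, dtype=np.int64)
    p = p[bad[p + k] - bad[p] == 0]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(base_codes, k)
    codes = windows[p] @ powers
    counts = np.bincount(codes, minlength=n_entries - 1)
    offsets = np.zeros(n_entries, dtype=np.uint32)
    np.cumsum(counts, out=offsets[1:])
    order = np.argsort(codes, kind="stable")  # stable: positions stay ascending per code
    return HashTable(k, sampling, offsets, p[order].astype(np.uint32))


def lookup_positions(table: HashTable, code: int) -> np.ndarray:
    """Positions of the k-mer with the given code (empty when absent)."""
    if not 0 <= code < 4 ** table.k:
        raise IndexError(f"code {code} out of range for k={table.k}")
    return table.positions[int(table.offsets[code]) : int(table.offsets[code + 1])]


def lookup_kmer(table: HashTable, kmer: str) -> np.ndarray:
    if len(kmer) != table.k:
        raise ValueError(f"expected a {table.k}-mer, got {len(kmer)} bases")
    return lookup_positions(table, encode_kmer(kmer))


def dump_arrays(table: HashTable, offsets_path, positions_path) -> None:
    """Raw binary dump: little-endian unsigned 32-bit words, no header."""
    table.offsets.astype("<u4").tofile(offsets_path)
    table.positions.astype("<u4").tofile(positions_path)


def load_offsets(path) -> np.ndarray:
    """Read a raw little-endian uint32 offset array (no header)."""
    return np.fromfile(path, dtype="<u4")
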