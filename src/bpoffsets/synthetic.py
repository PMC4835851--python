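"""Synthetic genomes, synthetic offset arrays, and the benchmark protocol.

The offset generator emulates the statistics of k-mer hash-table offset
arrays: monotone nondecreasing 32-bit values whose successive differences
are mostly zero or small (most k-mers are rare or absent) with an occasional
large value where a repetitive k-mer carries a long positions list.  The
genome generator optionally injects tandem repeats to reproduce that skew
from the sequence side.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import compressed_offsets as co
from .exceptions import ChecksumMismatchError, DynamicRangeError
from .kmer_hash import GenomeSequence

_U64 = (1 << 64) - 1


@dataclass
class RepeatSpec:
    """Tandem/dispersed repeats to inject into a synthetic genome."""

    unit_length: int = 13
    copies: int = 40
    loci: int = 5


@dataclass
class OffsetModel:
    """Difference-distribution model for synthetic offset arrays.

    zero_fraction
        share of zero differences (absent or unsampled k-mers).
    tail
        Zipf exponent (> 1) of the nonzero differences; smaller is heavier,
        i.e. more strongly repetitive k-mers.
    max_diff
        clip for single differences, keeping the cumulative sum in 32 bits.
    """

    n: int
    zero_fraction: float = 0.85
    tail: float = 1.4
    max_diff: int = 1 << 16
    seed: int = 0


def random_genome(length: int, gc: float = 0.42, n_rate: float = 0.0,
                  repeat_spec: Optional[RepeatSpec] = None, seed: int = 0) -> GenomeSequence:
    """Reproducible random genome with the given GC content and N rate."""
    if not 0.0 <= gc <= 1.0 or not 0.0 <= n_rate <= 1.0:
        raise ValueError("gc and n_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    if repeat_spec is not None and length > repeat_spec.unit_length:
        unit = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=repeat_spec.unit_length)
        tract = np.tile(unit, repeat_spec.copies)
        for _ in range(repeat_spec.loci):
            start = int(rng.integers(0, max(1, length - len(tract))))
            stop = min(length, start + len(tract))
            bases[start:stop] = tract[: stop - start]
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        bases[mask] = ord("N")
    return GenomeSequence(name=f"synthetic_{length}_{seed}", bases=bases.tobytes().decode("ascii"))


def random_offsets(model: OffsetModel) -> np.ndarray:
    """Monotone nondecreasing uint32 array drawn from the difference model."""
    if model.n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= model.zero_fraction <= 1.0:
        raise ValueError("zero_fraction must lie in [0, 1]")
    if model.tail <= 1.0:
        raise ValueError("tail must be > 1 (Zipf exponent)")
    rng = np.random.default_rng(model.seed)
    m = model.n - 1
    diffs = np.zeros(m, dtype=np.int64)
    nz = rng.random(m) >= model.zero_fraction
    diffs[nz] = np.minimum(rng.zipf(model.tail, size=int(nz.sum())), model.max_diff)
    offsets = np.zeros(model.n, dtype=np.int64)
    np.cumsum(diffs, out=offsets[1:])
    if offsets[-1] >= 1 << 32:
        raise DynamicRangeError("dynamic range: cumulative offsets exceed 32 bits")
    return offsets.astype(np.uint32)


# ---------------------------------------------------------------------------
# Benchmark protocol
# ---------------------------------------------------------------------------


def _query_pairs(vector, queries) -> tuple[int, int]:
    """Run the pair-retrieval query stream; returns (checksum, elapsed ns)."""
    checksum = 0
    if isinstance(vector, np.ndarray):
        t0 = time.perf_counter_ns()
        for i in queries:
            checksum += int(vector[i]) + int(vector[i + 1])
        t1 = time.perf_counter_ns()
    else:
        pair = co.lookup_pair_onepass
        t0 = time.perf_counter_ns()
        for i in queries:
            a, b = pair(vector, i)
            checksum += a + b
        t1 = time.perf_counter_ns()
    return checksum & _U64, t1 - t0


def run_benchmark(vectors: Mapping[str, Union[co.CompressedOffsetVector, np.ndarray]],
                  n_queries: int = 10_000_000, trials: int = 9, seed: int = 0) -> pd.DataFrame:
    """Median pair-retrieval timings plus exact space accounting.

    Each trial draws fresh uniform random pair queries over indices
    ``0 .. n - 2`` (the last index has no successor) and visits the schemes
    in a freshly shuffled order; the per-query loop overhead is measured on a
    dummy stream and subtracted.  A 64-bit additive checksum over the
    returned offset pairs must agree across all schemes in every trial.

    Timing numbers are hardware-dependent and are reported, never asserted;
    space numbers are deterministic functions of data and scheme.
    """
    names = list(vectors)
    if not names:
        raise ValueError("no vectors to benchmark")
    first = next(iter(vectors.values()))
    n = len(first) if isinstance(first, np.ndarray) else first.n
    rng = np.random.default_rng(seed)
    times: dict[str, list[float]] = {name: [] for name in names}
    checksums: dict[str, int] = {}
    for _trial in range(trials):
        queries = [int(q) for q in rng.integers(0, n - 1, size=n_queries)]
        # loop overhead: same iteration pattern with a no-op body
        t0 = time.perf_counter_ns()
        dummy = 0
        for i in queries:
            dummy += i
        overhead = time.perf_counter_ns() - t0
        trial_checksums = {}
        for name in rng.permutation(names):
            checksum, elapsed = _query_pairs(vectors[name], queries)
            trial_checksums[name] = checksum
            times[name].append(max(0.0, (elapsed - overhead) / n_queries))
        if len(set(trial_checksums.values())) != 1:
            raise ChecksumMismatchError(f"inconsistent codec results: {trial_checksums}")
        checksums.update(trial_checksums)
    rows = []
    for name in names:
        vec = vectors[name]
        nbytes = 4 * len(vec) if isinstance(vec, np.ndarray) else co.storage_size_bytes(vec)
        rows.append({
            "scheme": name,
            "bytes": nbytes,
            "ns_per_query_median": float(np.median(times[name])),
            "trials": trials,
            "n_queries": n_queries,
            "checksum": checksums[name],
        })
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Pretty text table of a benchmark report."""
    return report.to_string(index=False,
                            formatters={"ns_per_query_median": "{:.1f}".format})
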