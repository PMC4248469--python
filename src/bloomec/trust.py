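"""Passes 1 and 2: k-mer subsampling and the per-position trust test.

Pass 1 walks every read and keeps each valid k-mer window with
probability alpha, adding survivors (canonicalized) to Bloom filter A.
The survival draw is a counter-based PRNG keyed by (seed, read ordinal,
window offset), so the sample is reproducible and independent of read
order or thread count.

Pass 2 classifies each read position as trusted or untrusted: a
position overlapped by x in-read k-mers is trusted when at least y_x of
them are found in A (see :mod:`bloomec.model`) and its base quality
exceeds the fifth-percentile cutoff.  Every valid k-mer spanning k
consecutive trusted positions is *solid* and goes into Bloom filter B.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from . import _kernels
from .bloom import BloomFilter, FilterStats
from .kmers import AMBIG_CODE, seq_to_codes
from .model import ThresholdTable

DEFAULT_PHRED_OFFSET = 33
#: Sentinel cutoff meaning "no quality gating" (FASTA input).
NO_QUALITY_CUTOFF = -1


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence, optional Phred quality string."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")


@dataclass(frozen=True)
class QualityThresholds:
    """Fifth-percentile quality cutoffs estimated from the input.

    t1 is the fifth percentile of last-position qualities, t2 of
    first-position qualities; a base with quality <= min(t1, t2-1) is
    untrusted regardless of its k-mer support.  ``enabled`` is False for
    quality-less input, which disables the gate entirely.
    """

    t1: int
    t2: int
    cutoff: int
    sample_size: int
    enabled: bool = True

    @classmethod
    def disabled(cls) -> "QualityThresholds":
        return cls(t1=0, t2=0, cutoff=NO_QUALITY_CUTOFF, sample_size=0,
                   enabled=False)


@dataclass
class TrustVector:
    """Per-position outcome of the pass-2 test for one read."""

    trusted: np.ndarray  # bool per position
    hits: np.ndarray     # overlapping k-mers found in A
    x: np.ndarray        # overlapping k-mer count


# ---------------------------------------------------------------------------
# Batch encoding


def encode_batch(reads: Sequence[ReadRecord],
                 phred_offset: int = DEFAULT_PHRED_OFFSET,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Encode reads into padded code/quality matrices for the kernels.

    Returns (codes2d, lens, quals2d, has_qual).  Padding cells hold the
    ambiguity code and quality 0; kernels only read the first lens[r]
    cells of each row.  has_qual is True when every read carries a
    quality string.
    """
    n = len(reads)
    lens = np.fromiter((len(r.seq) for r in reads), dtype=np.int64, count=n)
    lmax = int(lens.max()) if n else 1
    codes2d = np.full((n, max(lmax, 1)), AMBIG_CODE, dtype=np.int8)
    quals2d = np.zeros((n, max(lmax, 1)), dtype=np.uint8)
    has_qual = n > 0 and all(r.qual is not None for r in reads)
    for i, r in enumerate(reads):
        codes2d[i, : lens[i]] = seq_to_codes(r.seq)
        if has_qual:
            q = np.frombuffer(r.qual.encode("ascii"), dtype=np.uint8)
            quals2d[i, : lens[i]] = q - phred_offset
    return codes2d, lens, quals2d, has_qual


def iter_batches(reads: Iterable[ReadRecord],
                 batch_size: int = 20000) -> Iterator[list[ReadRecord]]:
    batch: list[ReadRecord] = []
    for r in reads:
        batch.append(r)
        if len(batch) >= batch_size:
            yield batch
            batch = []
    if batch:
        yield batch


# ---------------------------------------------------------------------------
# Pass 1


def sample_kmers(reads: Iterable[ReadRecord], k: int, alpha: float, seed: int,
                 filter_a: BloomFilter, *, ordinal0: int = 0,
                 batch_size: int = 20000) -> FilterStats:
    """Bernoulli(alpha)-subsample all valid k-mer windows into filter A.

    A distinct k-mer occurring N times in the data is missed entirely
    with probability (1-alpha)^N, which is how low-multiplicity
    (error-derived) k-mers are preferentially excluded.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    ordinal = ordinal0
    for batch in iter_batches(reads, batch_size):
        codes2d, lens, _, _ = encode_batch(batch)
        filter_a.inserts += int(_kernels.pass1_chunk(
            codes2d, lens, k, alpha, seed, ordinal, *filter_a._bloom_args()))
        ordinal += len(batch)
    return filter_a.stats()


# ---------------------------------------------------------------------------
# Quality thresholds


def _fifth_percentile(values: np.ndarray) -> int:
    """Smallest q with #(values <= q) >= ceil(0.05 * n)."""
    rank = ceil(0.05 * len(values)) - 1
    return int(np.partition(values, rank)[rank])


def quality_thresholds(reads: Iterable[ReadRecord],
                       max_reads: int = 1_000_000,
                       phred_offset: int = DEFAULT_PHRED_OFFSET,
                       ) -> QualityThresholds:
    """Estimate t1/t2 from the first ``max_reads`` reads.

    Raises on an empty stream; returns a disabled gate when the input
    carries no quality strings (FASTA).
    """
    first: list[int] = []
    last: list[int] = []
    n = 0
    for r in reads:
        if n >= max_reads:
            break
        n += 1
        if r.qual is None or not r.qual:
            continue
        first.append(ord(r.qual[0]) - phred_offset)
        last.append(ord(r.qual[-1]) - phred_offset)
    if n == 0:
        raise ValueError("empty read stream")
    if not first:
        return QualityThresholds.disabled()
    t1 = _fifth_percentile(np.asarray(last, dtype=np.int64))
    t2 = _fifth_percentile(np.asarray(first, dtype=np.int64))
    return QualityThresholds(t1=t1, t2=t2, cutoff=min(t1, t2 - 1),
                             sample_size=len(first))


# ---------------------------------------------------------------------------
# Pass 2


def trust_positions(read: ReadRecord, filter_a: BloomFilter,
                    thresholds: ThresholdTable,
                    qthresh: QualityThresholds,
                    phred_offset: int = DEFAULT_PHRED_OFFSET) -> TrustVector:
    """Classify every position of one read as trusted/untrusted.

    Invalid (ambiguous-base) windows count toward a position's coverage
    x but can never be found in A.  Reads shorter than k have every
    position untrusted.
    """
    L = len(read.seq)
    codes = seq_to_codes(read.seq)
    has_qual = qthresh.enabled and read.qual is not None
    if has_qual:
        quals = (np.frombuffer(read.qual.encode("ascii"), dtype=np.uint8)
                 - phred_offset).astype(np.uint8)
    else:
        quals = np.zeros(max(L, 1), dtype=np.uint8)
    trusted = np.empty(max(L, 1), dtype=np.bool_)
    hits = np.empty(max(L, 1), dtype=np.int32)
    xs = np.empty(max(L, 1), dtype=np.int32)
    _kernels.trust_read(codes, L, quals, has_qual, qthresh.cutoff,
                        thresholds.k, thresholds.y,
                        *filter_a._bloom_args(), trusted, hits, xs)
    return TrustVector(trusted=trusted[:L], hits=hits[:L], x=xs[:L])


def collect_solid(read: ReadRecord, trust: TrustVector,
                  filter_b: BloomFilter, k: int) -> int:
    """Add every valid k-mer spanning k consecutive trusted positions to B.

    Returns the number of windows whose k-mer was not already in B.
    """
    codes = seq_to_codes(read.seq)
    return int(_kernels.collect_solid_read(codes, len(read.seq), k,
                                           trust.trusted.astype(np.bool_),
                                           *filter_b._bloom_args()))


def build_solid_filter(reads: Iterable[ReadRecord], filter_a: BloomFilter,
                       filter_b: BloomFilter, thresholds: ThresholdTable,
                       qthresh: QualityThresholds,
                       phred_offset: int = DEFAULT_PHRED_OFFSET,
                       batch_size: int = 20000) -> int:
    """Run pass 2 over a read stream; returns solid k-mers newly added to B."""
    added = 0
    for batch in iter_batches(reads, batch_size):
        codes2d, lens, quals2d, has_qual = encode_batch(batch, phred_offset)
        has_qual = has_qual and qthresh.enabled
        added += int(_kernels.pass2_chunk(
            codes2d, lens, quals2d, has_qual, qthresh.cutoff,
            thresholds.k, thresholds.y,
            *filter_a._bloom_args(), *filter_b._bloom_args()))
    return added
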