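"""Pattern-blocked Bloom filter over canonical k-mers.

The filter is an array of ``m`` bits divided into blocks of
``block_bits`` bits (a power of two, default 512 — one cache line).  One
hash selects the block for a key; ``h`` further hash values, derived by
double hashing from two seeded 64-bit mixes of the key, select bit
offsets inside that block.  Confining all of a key's bits to one block
trades a slightly higher false-positive rate for far better cache
locality on large filters.

An :class:`ExactKmerSet` with the same query interface (backed by a
sorted code array, zero false positives) is provided for use as a
reference membership structure in small-scale analyses.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import BinaryIO, Iterable, Union

import numpy as np

from . import _kernels
from .kmers import CanonicalKmer, canonicalize

_MAGIC = b"BLEC-BF1"

_EMPTY_U64 = np.empty(0, dtype=np.uint64)


@dataclass(frozen=True)
class FilterStats:
    """Occupancy snapshot of a Bloom filter."""

    occupancy: float
    inserts: int
    est_fp: float


def expected_fp_rate(n: int, m: int, h: int) -> float:
    """Classical Bloom false-positive rate (1 - e^{-hn/m})^h.

    ``n`` is the number of distinct keys inserted.  A blocked filter
    runs slightly above this because keys are confined to blocks whose
    loads fluctuate around the mean.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    return float((1.0 - np.exp(-h * n / m)) ** h)


class BloomFilter:
    """m-bit pattern-blocked Bloom filter with h hash functions."""

    def __init__(self, m: int, h: int, block_bits: int = 512, seed: int = 0):
        if block_bits < 64 or block_bits > 4096 or block_bits & (block_bits - 1):
            raise ValueError("block_bits must be a power of two in [64, 4096]")
        if m < block_bits or m % block_bits:
            raise ValueError("m must be a positive multiple of block_bits")
        if h < 1:
            raise ValueError("h must be >= 1")
        self.m = int(m)
        self.h = int(h)
        self.block_bits = int(block_bits)
        self.seed = int(seed)
        self.bits = np.zeros(m // 64, dtype=np.uint64)
        self.inserts = 0
        base = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
        mix = _kernels._mix
        self._seeds = tuple(
            np.uint64(mix(base ^ np.uint64((0x5851F42D4C957F2D * (j + 1))
                                           & (2**64 - 1))))
            for j in range(3))

    # -- kernel plumbing ---------------------------------------------------

    @property
    def nblocks(self) -> int:
        return self.m // self.block_bits

    def _bloom_args(self):
        s0, s1, s2 = self._seeds
        return (self.bits, np.uint64(self.nblocks), np.uint64(self.block_bits),
                self.h, s0, s1, s2)

    def _member_args(self):
        bits, nblocks, block_bits, h, s0, s1, s2 = self._bloom_args()
        return (_kernels.MODE_BLOOM, bits, _EMPTY_U64, nblocks, block_bits,
                h, s0, s1, s2)

    # -- scalar API --------------------------------------------------------

    @staticmethod
    def _code_of(kmer: Union[CanonicalKmer, str, int, np.uint64]) -> np.uint64:
        if isinstance(kmer, CanonicalKmer):
            return np.uint64(kmer.code)
        if isinstance(kmer, str):
            return np.uint64(canonicalize(kmer).code)
        return np.uint64(kmer)

    def add(self, kmer: Union[CanonicalKmer, str, int]) -> None:
        self.add_codes(np.asarray([self._code_of(kmer)], dtype=np.uint64))

    def contains(self, kmer: Union[CanonicalKmer, str, int]) -> bool:
        return bool(self.contains_codes(
            np.asarray([self._code_of(kmer)], dtype=np.uint64))[0])

    def __contains__(self, kmer) -> bool:
        return self.contains(kmer)

    # -- bulk API ----------------------------------------------------------

    def add_codes(self, codes: np.ndarray) -> int:
        """Insert canonical 2-bit codes; returns count of not-yet-present keys."""
        fresh = _kernels.bloom_add_codes(*self._bloom_args(), codes)
        self.inserts += len(codes)
        return int(fresh)

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        out = np.empty(len(codes), dtype=np.bool_)
        _kernels.bloom_test_codes(*self._bloom_args(), codes, out)
        return out

    # -- analytics ---------------------------------------------------------

    def set_bit_count(self) -> int:
        return int(_kernels.popcount_words(self.bits))

    def occupancy(self) -> float:
        return self.set_bit_count() / self.m

    def estimate_fp(self) -> float:
        """Occupancy-based false-positive estimate: occupancy ** h.

        A query is a false positive when all h probed bits happen to be
        set; with occupancy rho that has probability ~ rho^h.
        """
        return self.occupancy() ** self.h

    def stats(self) -> FilterStats:
        return FilterStats(self.occupancy(), self.inserts, self.estimate_fp())

    # -- persistence -------------------------------------------------------

    def dump(self, fh: BinaryIO) -> None:
        """Little-endian binary dump: magic, m, h, block_bits, seed, bits."""
        fh.write(_MAGIC)
        fh.write(struct.pack("<QQQq", self.m, self.h, self.block_bits, self.seed))
        fh.write(self.bits.astype("<u8").tobytes())

    @classmethod
    def load(cls, fh: BinaryIO) -> "BloomFilter":
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError("not a bloomec Bloom filter dump")
        m, h, block_bits, seed = struct.unpack("<QQQq", fh.read(32))
        obj = cls(m, h, block_bits, seed)
        raw = fh.read(m // 8)
        if len(raw) != m // 8:
            raise ValueError("truncated Bloom filter dump")
        obj.bits = np.frombuffer(raw, dtype="<u8").astype(np.uint64)
        return obj


class ExactKmerSet:
    """Exact membership set over canonical k-mer codes.

    Query-compatible with :class:`BloomFilter` (including the kernel
    plumbing) but backed by a sorted array, so it never yields false
    positives.  Useful as a ground-truth stand-in for filter B.
    """

    def __init__(self, codes: Iterable[int] = ()):
        arr = np.asarray(sorted(set(int(c) for c in codes)), dtype=np.uint64)
        self.keys = arr

    @classmethod
    def from_kmers(cls, kmers: Iterable[Union[str, CanonicalKmer]]) -> "ExactKmerSet":
        return cls(BloomFilter._code_of(k) for k in kmers)

    def _member_args(self):
        one = np.uint64(1)
        z = np.uint64(0)
        return (_kernels.MODE_EXACT, _EMPTY_U64, self.keys, one,
                np.uint64(64), 1, z, z, z)

    def contains(self, kmer) -> bool:
        code = BloomFilter._code_of(kmer)
        i = int(np.searchsorted(self.keys, code))
        return i < len(self.keys) and self.keys[i] == code

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.keys, codes)
        idx = np.minimum(idx, max(len(self.keys) - 1, 0))
        if len(self.keys) == 0:
            return np.zeros(len(codes), dtype=bool)
        return self.keys[idx] == codes

    def __contains__(self, kmer) -> bool:
        return self.contains(kmer)

    def __len__(self) -> int:
        return len(self.keys)
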