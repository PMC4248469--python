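"""Synthetic genome and short-read simulator with ground-truth tracking.

The simulator emulates a typical Illumina-style protocol: fixed-length
single-end reads drawn uniformly from a random (optionally diploid)
genome, with a per-base substitution error probability that rises
linearly from e/2 at the 5' end to 3e/2 at the 3' end, so the mean
per-base error rate is exactly e while errors concentrate toward the 3'
terminus as in real data.  Phred qualities are derived from the true
per-position error probabilities (q = round(-10 log10 p), clamped to
[2, 40]), so the quality gate of pass 2 sees realistic values.

Every injected substitution is recorded in a :class:`TruthLedger`,
which is what makes TP/FP/FN accounting of a corrector exact.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterator, Optional, TextIO, Union

import numpy as np

from .kmers import canonical_codes, codes_to_seq, seq_to_codes
from .trust import ReadRecord

QUAL_MIN, QUAL_MAX = 2, 40


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``ramp`` defaults to (e/2, 3e/2); any explicit ramp must average to
    ``mean_error`` and be nondecreasing toward the 3' end.
    """

    genome_len: int
    coverage: float
    read_len: int = 101
    mean_error: float = 0.01
    ramp: Optional[tuple[float, float]] = None
    diploid: bool = False
    het_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ramp is None:
            self.ramp = (self.mean_error / 2.0, 1.5 * self.mean_error)
        r5, r3 = self.ramp
        if not (0.0 <= r5 <= r3):
            raise ValueError("ramp must satisfy 0 <= r5 <= r3")
        if abs((r5 + r3) / 2.0 - self.mean_error) > 1e-12:
            raise ValueError("ramp must average to mean_error")

    def n_reads(self) -> int:
        return int(round(self.coverage * self.genome_len / self.read_len))

    def error_profile(self) -> np.ndarray:
        """Per-position substitution probability, 5' to 3'."""
        r5, r3 = self.ramp
        if self.read_len == 1:
            return np.asarray([self.mean_error])
        return r5 + (r3 - r5) * np.arange(self.read_len) / (self.read_len - 1)

    def quality_string(self, phred_offset: int = 33) -> str:
        p = self.error_profile()
        with np.errstate(divide="ignore"):
            q = np.where(p > 0, np.rint(-10.0 * np.log10(np.maximum(p, 1e-30))),
                         QUAL_MAX)
        q = np.clip(q, QUAL_MIN, QUAL_MAX).astype(np.uint8)
        return (q + phred_offset).tobytes().decode("ascii")


@dataclass
class Genome:
    """A simulated haploid or diploid reference."""

    seq: str
    hap2: Optional[str] = None
    het_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def diploid(self) -> bool:
        return self.hap2 is not None

    def __len__(self) -> int:
        return len(self.seq)

    def write_fasta(self, fh: TextIO, name: str = "sim") -> None:
        for label, seq in [(name, self.seq)] + (
                [(name + "_hap2", self.hap2)] if self.diploid else []):
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


@dataclass
class TruthLedger:
    """Flat record of every injected error, aligned to read coordinates."""

    n_reads: int
    read_idx: np.ndarray   # int64, sorted
    pos: np.ndarray        # int32, position within read
    true_base: np.ndarray  # int8 code of the error-free base
    obs_base: np.ndarray   # int8 code actually emitted
    haplotype: np.ndarray  # int8 per read (0/1; 0 for haploid)

    @property
    def n_errors(self) -> int:
        return len(self.pos)

    def errors_by_read(self) -> Iterator[tuple[int, np.ndarray, np.ndarray,
                                               np.ndarray]]:
        """Yield (read_index, positions, true_codes, observed_codes) groups."""
        bounds = np.searchsorted(self.read_idx,
                                 np.arange(self.n_reads + 1))
        for r in range(self.n_reads):
            lo, hi = bounds[r], bounds[r + 1]
            yield r, self.pos[lo:hi], self.true_base[lo:hi], self.obs_base[lo:hi]

    def write_tsv(self, path: str) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("read_idx\tpos\ttrue\tobserved\n")
            bases = "ACGTN"
            for i in range(self.n_errors):
                fh.write(f"{self.read_idx[i]}\t{self.pos[i]}\t"
                         f"{bases[self.true_base[i]]}\t"
                         f"{bases[self.obs_base[i]]}\n")

    @classmethod
    def read_tsv(cls, path: str, n_reads: int) -> "TruthLedger":
        opener = gzip.open if str(path).endswith(".gz") else open
        rows = []
        code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
        with opener(path, "rt") as fh:
            next(fh)
            for line in fh:
                r, p, t, o = line.rstrip("\n").split("\t")
                rows.append((int(r), int(p), code[t], code[o]))
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64) if rows else np.empty((0, 4),
                                                                     np.int64)
        return cls(n_reads=n_reads,
                   read_idx=arr[:, 0].astype(np.int64),
                   pos=arr[:, 1].astype(np.int32),
                   true_base=arr[:, 2].astype(np.int8),
                   obs_base=arr[:, 3].astype(np.int8),
                   haplotype=np.zeros(n_reads, dtype=np.int8))


def make_genome(length: int, seed: int, diploid: bool = False,
                het_rate: float = 0.001) -> Genome:
    """I.i.d. uniform ACGT genome; diploid mode adds heterozygous SNPs.

    In diploid mode the second haplotype is a copy with a Bernoulli
    (het_rate) subset of positions substituted to a uniformly chosen
    different base.
    """
    if length < 1:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.int8)
    seq = codes_to_seq(codes)
    if not diploid:
        return Genome(seq=seq)
    het = np.flatnonzero(rng.random(length) < het_rate)
    codes2 = codes.copy()
    codes2[het] = (codes2[het] + rng.integers(1, 4, size=len(het))) % 4
    return Genome(seq=seq, hap2=codes_to_seq(codes2), het_positions=het)


def simulate_reads(genome: Genome, config: SimConfig,
                   ) -> tuple[list[ReadRecord], TruthLedger]:
    """Draw reads uniformly from the genome and inject ramped errors.

    Read count is round(coverage * genome_len / read_len); start
    positions and strands are uniform; in diploid mode each read's
    haplotype is drawn uniformly.  Reproducible: identical (genome,
    config) pairs give identical output.
    """
    L = config.read_len
    glen = len(genome)
    if glen < L:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_reads()
    profile = config.error_profile()
    qual = config.quality_string()
    gcodes = [seq_to_codes(genome.seq)]
    if genome.diploid:
        gcodes.append(seq_to_codes(genome.hap2))

    reads: list[ReadRecord] = []
    led_read: list[np.ndarray] = []
    led_pos: list[np.ndarray] = []
    led_true: list[np.ndarray] = []
    led_obs: list[np.ndarray] = []
    haplotype = np.zeros(n, dtype=np.int8)

    chunk = 100_000
    for c0 in range(0, n, chunk):
        c1 = min(n, c0 + chunk)
        m = c1 - c0
        starts = rng.integers(0, glen - L + 1, size=m)
        strands = rng.integers(0, 2, size=m)
        if genome.diploid:
            haps = rng.integers(0, 2, size=m).astype(np.int8)
        else:
            haps = np.zeros(m, dtype=np.int8)
        haplotype[c0:c1] = haps
        # gather true read codes (2D), then reverse-complement minus-strand rows
        idx = starts[:, None] + np.arange(L)[None, :]
        mat = np.empty((m, L), dtype=np.int8)
        for hap in np.unique(haps):
            rows = haps == hap
            mat[rows] = gcodes[hap][idx[rows]]
        minus = strands == 1
        mat[minus] = 3 - mat[minus][:, ::-1]
        true_mat = mat.copy()
        # inject substitution errors along the ramp
        err = rng.random((m, L)) < profile[None, :]
        shift = rng.integers(1, 4, size=(m, L), dtype=np.int8)
        mat[err] = (mat[err] + shift[err]) % 4
        rr, pp = np.nonzero(err)
        led_read.append(rr.astype(np.int64) + c0)
        led_pos.append(pp.astype(np.int32))
        led_true.append(true_mat[rr, pp])
        led_obs.append(mat[rr, pp])
        for i in range(m):
            reads.append(ReadRecord(id=f"r{c0 + i}",
                                    seq=codes_to_seq(mat[i]), qual=qual))

    ledger = TruthLedger(
        n_reads=n,
        read_idx=np.concatenate(led_read) if led_read else np.empty(0, np.int64),
        pos=np.concatenate(led_pos) if led_pos else np.empty(0, np.int32),
        true_base=np.concatenate(led_true) if led_true else np.empty(0, np.int8),
        obs_base=np.concatenate(led_obs) if led_obs else np.empty(0, np.int8),
        haplotype=haplotype)
    return reads, ledger


@dataclass
class KmerCensus:
    """Exact canonical k-mer census of a genome (evaluation oracle)."""

    codes: np.ndarray   # sorted distinct canonical codes
    counts: np.ndarray  # multiplicities, aligned with codes

    @property
    def distinct(self) -> int:
        return len(self.codes)


def kmer_census(genome: Union[str, Genome], k: int) -> KmerCensus:
    """Exact census of distinct canonical k-mers and their multiplicities.

    For a diploid genome both haplotypes contribute occurrences.
    """
    seqs = [genome] if isinstance(genome, str) else (
        [genome.seq, genome.hap2] if genome.diploid else [genome.seq])
    all_codes = []
    for s in seqs:
        canon, valid = canonical_codes(seq_to_codes(s), k)
        all_codes.append(canon[valid])
    codes, counts = np.unique(np.concatenate(all_codes), return_counts=True)
    return KmerCensus(codes=codes, counts=counts)
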