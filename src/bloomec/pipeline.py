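"""Three-pass correction engine over re-iterable read sources.

The corrector streams the input three times (subsample -> trust/solid
-> correct), so it takes a *provider*: a zero-argument callable
returning a fresh iterator of :class:`~bloomec.trust.ReadRecord`.  A
list of reads works directly.  Peak memory is dominated by the two
Bloom filters; reads are processed in bounded batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .bloom import BloomFilter
from .correct import BudgetPolicy, CorrectionResult, correct_dataset
from .model import ThresholdTable, alpha_from_coverage, p_star, thresholds
from .trust import (DEFAULT_PHRED_OFFSET, QualityThresholds, ReadRecord,
                    build_solid_filter, quality_thresholds, sample_kmers)

ReadProvider = Union[Sequence[ReadRecord], Callable[[], Iterable[ReadRecord]]]

DEFAULT_BITS_PER_G = 32
DEFAULT_HASHES = 3
DEFAULT_BLOCK_BITS = 512


@dataclass
class RunReport:
    """Machine-readable account of one correction run."""

    k: int
    G: int
    alpha: float
    beta: float
    quantile: float
    y: list[int]
    qual_cutoff: Optional[int]
    occupancy_a: float
    occupancy_b: float
    solid_added: int
    n_reads: int = 0
    n_edits: int = 0
    n_ambiguous: int = 0
    n_unanchored: int = 0

    def to_dict(self) -> dict:
        return {key: getattr(self, key) for key in self.__dataclass_fields__}


def _as_provider(reads: ReadProvider) -> Callable[[], Iterator[ReadRecord]]:
    if callable(reads):
        return lambda: iter(reads())
    return lambda: iter(reads)


def build_filters(reads: ReadProvider, *, k: int, G: int,
                  alpha: Optional[float] = None,
                  coverage: Optional[float] = None,
                  seed: int = 0,
                  bits_per_g: float = DEFAULT_BITS_PER_G,
                  h: int = DEFAULT_HASHES,
                  block_bits: int = DEFAULT_BLOCK_BITS,
                  quantile: float = 0.995,
                  phred_offset: int = DEFAULT_PHRED_OFFSET,
                  ) -> tuple[BloomFilter, BloomFilter, ThresholdTable,
                             QualityThresholds, RunReport]:
    """Run passes 1 and 2; returns (A, B, thresholds, qthresh, report).

    Exactly one of ``alpha``/``coverage`` must be given; coverage is
    translated to alpha = min(1, 7/C).  Both filters are sized at
    ``bits_per_g`` bits per genomic k-mer.
    """
    if (alpha is None) == (coverage is None):
        raise ValueError("give exactly one of alpha or coverage")
    if alpha is None:
        alpha = alpha_from_coverage(coverage)
    provider = _as_provider(reads)

    m = int(np.ceil(bits_per_g * G / block_bits)) * block_bits
    filter_a = BloomFilter(m, h, block_bits, seed=seed * 2 + 1)
    filter_b = BloomFilter(m, h, block_bits, seed=seed * 2 + 2)

    qthresh = quality_thresholds(provider(), phred_offset=phred_offset)
    sample_kmers(provider(), k, alpha, seed, filter_a)
    beta = filter_a.estimate_fp()
    table = thresholds(k, p_star(alpha, beta), quantile)
    solid = build_solid_filter(provider(), filter_a, filter_b, table, qthresh,
                               phred_offset=phred_offset)
    report = RunReport(
        k=k, G=G, alpha=alpha, beta=beta, quantile=quantile,
        y=[int(v) for v in table.y[1:]],
        qual_cutoff=qthresh.cutoff if qthresh.enabled else None,
        occupancy_a=filter_a.occupancy(),
        occupancy_b=filter_b.occupancy(),
        solid_added=solid)
    return filter_a, filter_b, table, qthresh, report


def run_pipeline(reads: ReadProvider, *, k: int, G: int,
                 alpha: Optional[float] = None,
                 coverage: Optional[float] = None,
                 seed: int = 0,
                 maxcor: float = 4.0,
                 workers: int = 1,
                 bits_per_g: float = DEFAULT_BITS_PER_G,
                 h: int = DEFAULT_HASHES,
                 block_bits: int = DEFAULT_BLOCK_BITS,
                 quantile: float = 0.995,
                 phred_offset: int = DEFAULT_PHRED_OFFSET,
                 ) -> tuple[list[CorrectionResult], RunReport]:
    """Full three-pass correction; returns all results plus the report."""
    _a, filter_b, _t, qthresh, report = build_filters(
        reads, k=k, G=G, alpha=alpha, coverage=coverage, seed=seed,
        bits_per_g=bits_per_g, h=h, block_bits=block_bits,
        quantile=quantile, phred_offset=phred_offset)
    policy = BudgetPolicy(limit=maxcor)
    provider = _as_provider(reads)
    results = []
    for res in correct_dataset(provider(), filter_b, k, qthresh, policy,
                               workers=workers, phred_offset=phred_offset):
        results.append(res)
        report.n_edits += len(res.edits)
        report.n_ambiguous += len(res.ambiguous_positions)
        if not res.anchored:
            report.n_unanchored += 1
    report.n_reads = len(results)
    return results, report
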