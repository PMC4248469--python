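"""Pass 3: greedy substitution-based correction against the solid set.

Each read is anchored at its longest run of consecutive k-mers found in
Bloom filter B.  Walking right from the anchor, the first window absent
from B implicates its last base; each of the four nucleotides is scored
by the length of the stretch of consecutive member windows it creates
(capped at k, continued virtually past the read end when the error sits
near the 3' terminus), and the unique strict winner is substituted.
Ties leave the position uncorrected ("ambiguous").  The left side of
the anchor is handled by running the identical walk on the reverse
complement, which is exact because membership is canonical.

A per-window correction budget caps the total weight of edits inside
any k consecutive positions (N bases weigh 0, low-quality bases 0.5,
others 1); an edit that would exceed it stops extension on that side.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from . import _kernels
from .bloom import BloomFilter, ExactKmerSet
from .kmers import codes_to_seq, seq_to_codes
from .trust import (DEFAULT_PHRED_OFFSET, QualityThresholds, ReadRecord,
                    encode_batch, iter_batches)

Membership = Union[BloomFilter, ExactKmerSet]

_BASES = "ACGTN"


@dataclass(frozen=True)
class BudgetPolicy:
    """Cap on weighted corrections inside any window of k positions."""

    limit: float = 4.0
    weight_n: float = 0.0
    weight_lowq: float = 0.5
    weight_normal: float = 1.0


@dataclass
class CorrectionResult:
    """Outcome of correcting one read.

    ``seq`` always has the input length; ``edits`` lists applied
    substitutions as (position, from_base, to_base).  ``anchored`` is
    False when no window of the read was found in B (read returned
    untouched); ``budget_stop`` marks a correction blocked by the
    per-window budget.
    """

    id: str
    seq: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    ambiguous_positions: list[int] = field(default_factory=list)
    budget_stop: bool = False
    anchored: bool = True


def find_anchor(read: Union[ReadRecord, str], filter_b: Membership,
                k: int) -> Optional[tuple[int, int]]:
    """Leftmost maximal run of consecutive windows present in B.

    Returns 0-based window offsets (b, e), or None when no window of
    the read is in B.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    codes = seq_to_codes(seq)
    b, e = _kernels.longest_member_run(codes, len(seq), k,
                                       *filter_b._member_args())
    return None if b < 0 else (int(b), int(e))


def score_substitution(read: Union[ReadRecord, str], pos: int, base: str,
                       filter_b: Membership, k: int,
                       direction: str = "right") -> int:
    """Stretch length created by substituting ``base`` at ``pos``.

    ``direction='right'`` scores the window ending at pos (the failing
    window of the rightward walk); ``'left'`` mirrors through the
    reverse complement.  The count is capped at k and may include
    virtual windows beyond the read end.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    L = len(seq)
    codes = seq_to_codes(seq).copy()
    if direction == "left":
        codes = np.where(codes <= 3, 3 - codes, codes)[::-1].astype(np.int8).copy()
        pos = L - 1 - pos
        base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base.upper()]
    elif direction != "right":
        raise ValueError("direction must be 'right' or 'left'")
    codes[pos] = "ACGT".index(base.upper())
    i = pos - k + 1
    if i < 0 or i > L - k:
        raise ValueError("substitution position has no in-read failing window")
    return int(_kernels.stretch_length(codes, L, i, k,
                                       *filter_b._member_args()))


def correct_read(read: ReadRecord, filter_b: Membership, k: int,
                 qthresh: Optional[QualityThresholds] = None,
                 policy: BudgetPolicy = BudgetPolicy(),
                 phred_offset: int = DEFAULT_PHRED_OFFSET) -> CorrectionResult:
    """Greedy correction of a single read (see module docstring)."""
    L = len(read.seq)
    if L < k:
        return CorrectionResult(id=read.id, seq=read.seq, anchored=False)
    qthresh = qthresh or QualityThresholds.disabled()
    codes = seq_to_codes(read.seq).copy()
    has_qual = qthresh.enabled and read.qual is not None
    if has_qual:
        quals = (np.frombuffer(read.qual.encode("ascii"), dtype=np.uint8)
                 - phred_offset).astype(np.uint8)
    else:
        quals = np.zeros(L, dtype=np.uint8)
    cap = 2 * L + 2
    epos = np.empty(cap, dtype=np.int32)
    efrom = np.empty(cap, dtype=np.int8)
    eto = np.empty(cap, dtype=np.int8)
    eflag = np.empty(cap, dtype=np.int8)
    n, anchored, budget_stop = _kernels.correct_read_kernel(
        codes, L, quals, has_qual, qthresh.cutoff, k, policy.limit,
        *filter_b._member_args(), epos, efrom, eto, eflag)
    res = CorrectionResult(id=read.id, seq=codes_to_seq(codes),
                           anchored=bool(anchored),
                           budget_stop=bool(budget_stop))
    for t in range(n):
        p = int(epos[t])
        if eflag[t] == _kernels.FLAG_APPLIED:
            res.edits.append((p, _BASES[efrom[t]], _BASES[eto[t]]))
        elif eflag[t] == _kernels.FLAG_AMBIGUOUS:
            res.ambiguous_positions.append(p)
    res.edits.sort()
    res.ambiguous_positions.sort()
    return res


def _correct_batch(batch: Sequence[ReadRecord], filter_b: Membership, k: int,
                   qthresh: QualityThresholds, policy: BudgetPolicy,
                   phred_offset: int) -> list[CorrectionResult]:
    codes2d, lens, quals2d, has_qual = encode_batch(batch, phred_offset)
    has_qual = has_qual and qthresh.enabled
    n = len(batch)
    cap = max(256, 8 * n)
    anchored = np.zeros(n, dtype=np.bool_)
    budget = np.zeros(n, dtype=np.bool_)
    member_args = filter_b._member_args()
    records: list[tuple[np.ndarray, ...]] = []
    start = 0
    while start < n:
        out_read = np.empty(cap, dtype=np.int32)
        out_pos = np.empty(cap, dtype=np.int32)
        out_from = np.empty(cap, dtype=np.int8)
        out_to = np.empty(cap, dtype=np.int8)
        out_flag = np.empty(cap, dtype=np.int8)
        done, nrec = _kernels.pass3_chunk(
            codes2d[start:], lens[start:], quals2d[start:], has_qual,
            qthresh.cutoff, k, policy.limit, *member_args,
            out_read, out_pos, out_from, out_to, out_flag,
            anchored[start:], budget[start:])
        records.append((out_read[:nrec] + start, out_pos[:nrec],
                        out_from[:nrec], out_to[:nrec], out_flag[:nrec]))
        if done == 0:  # one pathological read outgrew the buffer
            cap *= 4
            continue
        start += done
    results = [CorrectionResult(id=r.id, seq="", anchored=bool(anchored[i]),
                                budget_stop=bool(budget[i]))
               for i, r in enumerate(batch)]
    for out_read, out_pos, out_from, out_to, out_flag in records:
        for t in range(len(out_read)):
            r = int(out_read[t])
            p = int(out_pos[t])
            if out_flag[t] == _kernels.FLAG_APPLIED:
                results[r].edits.append((p, _BASES[out_from[t]],
                                         _BASES[out_to[t]]))
            elif out_flag[t] == _kernels.FLAG_AMBIGUOUS:
                results[r].ambiguous_positions.append(p)
    for i, r in enumerate(batch):
        results[i].seq = codes_to_seq(codes2d[i, : lens[i]])
        results[i].edits.sort()
        results[i].ambiguous_positions.sort()
    return results


def correct_dataset(reads: Iterable[ReadRecord], filter_b: Membership, k: int,
                    qthresh: Optional[QualityThresholds] = None,
                    policy: BudgetPolicy = BudgetPolicy(),
                    workers: int = 1,
                    phred_offset: int = DEFAULT_PHRED_OFFSET,
                    batch_size: int = 20000) -> Iterator[CorrectionResult]:
    """Correct a read stream; output order and content match the input.

    B is only queried, never modified, so batches are independent: with
    ``workers > 1`` they are corrected on a thread pool (the kernels
    release the GIL) and re-emitted in input order, byte-identical to a
    single-worker run.
    """
    qthresh = qthresh or QualityThresholds.disabled()
    if workers <= 1:
        for batch in iter_batches(reads, batch_size):
            yield from _correct_batch(batch, filter_b, k, qthresh, policy,
                                      phred_offset)
        return
    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = []
        for batch in iter_batches(reads, batch_size):
            futures.append(pool.submit(_correct_batch, batch, filter_b, k,
                                       qthresh, policy, phred_offset))
            # keep a bounded window of in-flight batches
            while len(futures) > 2 * workers:
                yield from futures.pop(0).result()
        for fut in futures:
            yield from fut.result()
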