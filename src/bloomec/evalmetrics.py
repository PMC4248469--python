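"""Per-nucleotide scoring of corrected reads against the truth ledger.

Every nucleotide of every read is in scope.  A true positive is an
injected error restored to the correct base; a false positive is a
substitution at an error-free position; a false negative is an injected
error that was missed *or* replaced with a wrong base (a wrong
substitution at an error position counts once, as FN, never as FP).

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F         = 2 * recall * precision / (recall + precision)
    gain      = (TP - FP) / (TP + FN)

Gain is the net fraction of errors removed after penalizing spurious
edits; gain <= recall, with equality iff FP = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .correct import CorrectionResult
from .simdata import TruthLedger

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class EvalSummary:
    TP: int
    FP: int
    FN: int

    @property
    def recall(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.TP + self.FP
        return self.TP / d if d else 0.0

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0

    @property
    def gain(self) -> float:
        d = self.TP + self.FN
        return (self.TP - self.FP) / d if d else 0.0


def classify(corrected: Iterable[CorrectionResult],
             ledger: TruthLedger) -> EvalSummary:
    """Score a corrected read stream against the injected-error ledger.

    Streams must align 1:1 in order with the ledger's read indices
    (ids ``r<i>`` as emitted by the simulator).
    """
    tp = fp = fn = 0
    groups = ledger.errors_by_read()
    for res, (ridx, pos, true_b, _obs) in zip(corrected, groups, strict=True):
        if res.id != f"r{ridx}":
            raise ValueError(
                f"read id mismatch: corrected {res.id!r} vs ledger r{ridx}")
        err = {int(p): int(t) for p, t in zip(pos, true_b)}
        hit = set()
        for p, _from, to in res.edits:
            if p in err:
                hit.add(p)
                if _CODE[to] == err[p]:
                    tp += 1
                else:
                    fn += 1
            else:
                fp += 1
        fn += len(err) - len(hit)
    return EvalSummary(TP=tp, FP=fp, FN=fn)


def summarize_table(summaries: Sequence[EvalSummary],
                    labels: Sequence[str], fh: TextIO) -> None:
    """Write one TSV row per run: label and the four rates as percentages."""
    fh.write("label\trecall\tprecision\tf_score\tgain\n")
    for label, s in zip(labels, summaries, strict=True):
        fh.write(f"{label}\t{100 * s.recall:.2f}\t{100 * s.precision:.2f}\t"
                 f"{100 * s.f_score:.2f}\t{100 * s.gain:.2f}\n")
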