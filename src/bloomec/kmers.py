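"""k-mer encoding, canonicalization and enumeration.

Nucleotides are encoded as 2-bit integers (A=0, C=1, G=2, T=3) so that a
k-mer with k <= 31 fits a single unsigned 64-bit word with the leftmost
base most significant.  Membership data structures always store the
*canonical* form of a k-mer: the lexicographically smaller of the k-mer
and its reverse complement under A < C < G < T, which makes every set
query strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

MAX_K = 31

#: Integer codes for the four unambiguous nucleotides.
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"

# Any byte outside ACGT/acgt maps to the sentinel code 4 ("ambiguous").
AMBIG_CODE = 4
_CODE_LUT = np.full(256, AMBIG_CODE, dtype=np.int8)
for _b, _c in _BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class MalformedSequenceError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC set."""


def _check_k(k: int) -> None:
    if not (1 <= k <= MAX_K):
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


@dataclass(frozen=True)
class CanonicalKmer:
    """A strand-normalized k-mer word.

    Invariant: ``word`` is lexicographically <= its reverse complement
    and contains only A/C/G/T.
    """

    word: str

    @property
    def k(self) -> int:
        return len(self.word)

    def __post_init__(self) -> None:
        _check_k(len(self.word))
        if any(b not in _BASE_TO_CODE for b in self.word):
            raise MalformedSequenceError(f"non-ACGT base in k-mer {self.word!r}")
        if reverse_complement(self.word) < self.word:
            raise ValueError(f"{self.word!r} is not canonical")

    @property
    def code(self) -> int:
        return encode2bit(self.word)


@dataclass(frozen=True)
class KmerWindow:
    """A k-length window of a read: raw substring plus its offset.

    ``valid`` is False when the window contains any non-ACGT character;
    invalid windows are never sampled or queried but still count toward
    per-position coverage in the trust test.
    """

    read_offset: int
    word: str
    valid: bool


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; 'N' maps to 'N'. Involution."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise MalformedSequenceError(
            f"non-IUPAC character {exc.args[0]!r} in sequence"
        ) from None


def canonicalize(word: str) -> CanonicalKmer:
    """Return min(word, reverse_complement(word)) as a :class:`CanonicalKmer`."""
    word = word.upper()
    if any(b not in _BASE_TO_CODE for b in word):
        raise MalformedSequenceError(f"cannot canonicalize ambiguous k-mer {word!r}")
    rc = reverse_complement(word)
    return CanonicalKmer(word if word <= rc else rc)


def encode2bit(word: str) -> int:
    """Pack an ACGT word (k <= 31) into an integer, leftmost base most significant."""
    _check_k(len(word))
    code = 0
    for b in word.upper():
        try:
            code = (code << 2) | _BASE_TO_CODE[b]
        except KeyError:
            raise MalformedSequenceError(f"cannot encode base {b!r}") from None
    return code


def decode2bit(code: int, k: int) -> str:
    """Inverse of :func:`encode2bit`."""
    _check_k(k)
    if not (0 <= code < 4**k):
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_CODE_TO_BASE[(code >> shift) & 3])
    return "".join(out)


def iter_kmers(seq: str, k: int) -> Iterator[KmerWindow]:
    """Yield every k-length window of ``seq`` in order.

    Reads shorter than k yield nothing.  Windows containing non-ACGT
    characters are yielded with ``valid=False``.
    """
    _check_k(k)
    seq = seq.upper()
    codes = seq_to_codes(seq)
    n_bad = np.cumsum(codes == AMBIG_CODE)
    for i in range(len(seq) - k + 1):
        bad = n_bad[i + k - 1] - (n_bad[i - 1] if i else 0)
        yield KmerWindow(read_offset=i, word=seq[i : i + k], valid=bad == 0)


# ---------------------------------------------------------------------------
# Vectorized helpers shared by the bulk passes, the simulator and the census.


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence to int8 codes (A=0..T=3, anything else 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode int8 codes back to an ACGTN string."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 64-bit codes of all k-windows of an encoded sequence.

    Returns ``(canon, valid)`` where ``canon[i]`` is the canonical 2-bit
    packing of the window at offset ``i`` and ``valid[i]`` is False when
    the window contains an ambiguous base (its code is then undefined).
    """
    _check_k(k)
    n = codes.shape[0] - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    safe = np.where(codes == AMBIG_CODE, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | safe[t : t + n]
    for t in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | (np.uint64(3) - safe[t : t + n])
    canon = np.minimum(fwd, rev)
    bad = (codes == AMBIG_CODE).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(bad)))
    valid = (csum[k:] - csum[:-k]) == 0
    return canon, valid
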