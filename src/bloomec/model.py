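"""Closed-form machinery behind the counting-free trust test.

The corrector never counts k-mers.  Instead it keeps a Bernoulli(alpha)
subsample of all sequenced k-mer occurrences in Bloom filter A and asks,
for each read position, how many of the (up to k) overlapping k-mers are
present in A.  Under the model, a k-mer derived from a sequencing error
has low multiplicity — at most f(alpha) = max(2, 0.2/alpha) occurrences
— so its probability of landing in A is

    P(alpha) = 1 - (1 - alpha)^f(alpha),

and, folding in A's false-positive rate beta,

    P*(alpha) = P(alpha) + beta - beta * P(alpha).

For a position overlapped by x k-mers that is genuinely erroneous, the
number found in A is Binom(x, P*(alpha)); the trust threshold y_x is the
smallest count such an erroneous position exceeds with probability at
most 1 - quantile (default 0.005).  Because f(alpha) ~ 0.2/alpha for
small alpha, P(alpha) — and with it the whole threshold table — is
nearly invariant when alpha is scaled inversely with coverage, which is
what keeps accuracy and filter occupancy flat across sequencing depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log, log1p
from typing import TextIO

import numpy as np

DEFAULT_QUANTILE = 0.995


@dataclass
class ModelParams:
    """User-facing model parameters for one run."""

    alpha: float
    k: int
    G: int
    coverage: float | None = None
    beta: float = 0.0
    quantile: float = DEFAULT_QUANTILE

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must be in [0, 1)")
        if not (0.5 < self.quantile < 1.0):
            raise ValueError("quantile must be in (0.5, 1)")


@dataclass
class ThresholdTable:
    """Minimal passing k-mer counts y_x for x = 1..k overlapping k-mers."""

    y: np.ndarray  # shape (k+1,); y[0] unused

    @property
    def k(self) -> int:
        return len(self.y) - 1

    def __getitem__(self, x: int) -> int:
        if not (1 <= x <= self.k):
            raise IndexError(f"x must be in [1, {self.k}]")
        return int(self.y[x])

    def dump_tsv(self, fh: TextIO) -> None:
        fh.write("x\ty_x\n")
        for x in range(1, self.k + 1):
            fh.write(f"{x}\t{int(self.y[x])}\n")


@dataclass
class SeqModelDiag:
    """Poisson rates of the sequencing/subsampling model (diagnostics only)."""

    K: float
    epsilon: float
    lambda_correct: float
    lambda_correct_full: float


def alpha_from_coverage(C: float) -> float:
    """Subsampling fraction scaled inversely with coverage: min(1, 7/C).

    Calibrated so that alpha = 0.1 at 70-fold coverage; the product
    alpha*K (expected subsample size) is then constant in C.
    """
    if C <= 0:
        raise ValueError("coverage must be positive")
    return min(1.0, 7.0 / C)


def f_alpha(alpha: float) -> float:
    """Assumed maximal multiplicity of a weak k-mer: max(2, 0.2/alpha)."""
    _check_alpha(alpha)
    return max(2.0, 0.2 / alpha)


def p_alpha(alpha: float) -> float:
    """Probability a weak k-mer survives into A: 1 - (1-alpha)^f(alpha)."""
    _check_alpha(alpha)
    if alpha == 1.0:
        return 1.0
    return -float(np.expm1(f_alpha(alpha) * log1p(-alpha)))


def p_star(alpha: float, beta: float) -> float:
    """P(alpha) adjusted for A's false-positive rate: P + beta - beta*P."""
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must be in [0, 1)")
    p = p_alpha(alpha)
    return p + beta - beta * p


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")


def _binom_cdf_exact(x: int, p: float) -> np.ndarray:
    """CDF of Binom(x, p) at 0..x by log-space pmf summation.

    x <= 31 here, so exact term-by-term summation is cheap and avoids
    any normal/Poisson approximation of the tail.
    """
    if p <= 0.0:
        out = np.ones(x + 1)
        return out
    if p >= 1.0:
        out = np.zeros(x + 1)
        out[x] = 1.0
        return out
    lp, lq = log(p), log1p(-p)
    lc = lgamma(x + 1)
    pmf = np.empty(x + 1)
    for i in range(x + 1):
        pmf[i] = exp(lc - lgamma(i + 1) - lgamma(x - i + 1) + i * lp + (x - i) * lq)
    return np.minimum(np.cumsum(pmf), 1.0)


def thresholds(k: int, p_star_val: float,
               quantile: float = DEFAULT_QUANTILE) -> ThresholdTable:
    """Trust thresholds y_x for x = 1..k.

    y_x is the minimum integer such that P(Binom(x, p*) <= y_x - 1) >=
    quantile: the smallest count an erroneous position is very unlikely
    to reach.  y_x can exceed x (then no position with x overlapping
    k-mers can ever be trusted — the over-sampled regime).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= p_star_val <= 1.0):
        raise ValueError("p_star must be in [0, 1]")
    y = np.zeros(k + 1, dtype=np.int64)
    for x in range(1, k + 1):
        cdf = _binom_cdf_exact(x, p_star_val)
        # smallest q with CDF(q) >= quantile, allowing for float round-off
        q = int(np.searchsorted(cdf, quantile - 1e-12))
        y[x] = q + 1
    return ThresholdTable(y=y)


def poisson_diagnostics(alpha: float, K: float, epsilon: float,
                        G: int) -> SeqModelDiag:
    """Poisson rates for correct k-mer multiplicities, full and subsampled.

    A correct k-mer appears Pois(K(1-eps)/G) times among the sequenced
    k-mers and Pois(alpha*K*(1-eps)/G) times in the pass-1 subsample.
    Used to validate the read simulator, not by the corrector itself.
    """
    if min(alpha, K, 1.0 - epsilon) < 0 or epsilon < 0 or G <= 0:
        raise ValueError("invalid sequencing-model parameters")
    full = K * (1.0 - epsilon) / G
    return SeqModelDiag(K=K, epsilon=epsilon,
                        lambda_correct=alpha * full,
                        lambda_correct_full=full)
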