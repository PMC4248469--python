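# Methods

## Model and procedure

`bloomec` treats sequencing as uniform sampling of k-mers from a
genome of G distinct k-mers.  A correct k-mer appears ~Pois(K(1−ε)/G)
times among the K sequenced k-mers (ε = fraction of k-mers altered by
an error), i.e. proportionally to coverage, while an error-derived
k-mer is nearly unique.  Instead of measuring multiplicities by
counting, the method exploits this gap through Bernoulli(α)
subsampling: a k-mer occurring N times is captured by the subsample
with probability 1 − (1−α)^N, which stays near 1 for abundant k-mers
and near Nα for rare ones.

**Pass 1** stores the subsample in a Bloom filter A.  The survival
draw for the window at offset j of read r is a counter-based hash of
(seed, r, j), so the sample — and everything downstream — is
independent of read order and thread count.

**Pass 2** assumes weak (error-derived) k-mers have multiplicity at
most f(α) = max(2, 0.2/α), giving the capture probability
P(α) = 1 − (1−α)^f(α) and, with A's false-positive rate β folded in,
P\*(α) = P + β − βP.  For a read position overlapped by x in-read
k-mers (1 ≤ x ≤ k), the number of overlapping k-mers found in A at an
*erroneous* position is Binom(x, P\*); the trust threshold y_x is the
smallest count whose exceedance probability is below 0.005
(quantile 0.995, configurable).  The binomial CDF is summed exactly in
log space — no normal approximation — since x ≤ 31.  A position is
trusted when its hit count reaches y_x and its base quality exceeds
the quality cutoff (below).  Windows of k consecutive trusted
positions are *solid*; their k-mers are check-then-inserted into Bloom
filter B.  Because f(α) ≈ 0.2/α for small α, P(α) — hence the
threshold table, the content of both filters, and the accuracy — is
nearly invariant when α is scaled as 7/C with coverage C.

**Pass 3** corrects each read greedily against B: anchor at the
leftmost longest run of member windows; walk right; at the first
non-member window presume its last base wrong; score all four
nucleotides by the number of consecutive member windows created
(capped at k); apply the unique strict maximizer; on a tie record the
position as ambiguous and resume k windows later.  The left side of
the anchor is handled by running the identical walk on the reverse
complement, which is exact because membership is canonical
(min(k-mer, reverse complement) under A<C<G<T).  When fewer than k
in-read windows remain past the presumed error, counting continues
virtually beyond the read end: a virtual window counts only while
exactly one nucleotide extends the current (k−1)-suffix to a member of
B.  This resolves most ties at read termini without ever editing
beyond the read.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | user-set (≤ 31) | k-mer length; 23 works well at ~1% error |
| G | user-set | genome-size proxy used only for filter sizing |
| α | min(1, 7/C) | pass-1 subsampling fraction |
| quantile | 0.995 | binomial tail mass defining y_x |
| maxcor | 4.0 | correction budget per k-window of a read |
| bits_per_g | 32 | filter bits per genomic k-mer (each filter) |
| h | 3 | hash functions per filter |
| block_bits | 512 | Bloom filter block size (one cache line) |

**Filter sizing.**  Each filter gets m = 32·G bits with h = 3.  At
typical loads (A holds roughly 2G distinct k-mers at 1% error) this
keeps A's occupancy near 18% and β = occupancy³ below 1%.  β this
small matters twice: the threshold table stays at the values the
subsampling model alone would give (at α = 0.35 an inflated β raises
y₂₃ from 20 to 21, which silently blocks a few percent of genomic
k-mers from ever becoming solid and breaks the depth-invariance of
filter B), and B's own false positives would otherwise create spurious
stretch ties during greedy correction, measurably depressing recall.
Eight bytes per genome position for both filters together is still an
order of magnitude below what counting tables would need.

**Quality cutoff.**  The fifth percentile t₁ of last-position
qualities and t₂ of first-position qualities are taken over the first
10⁶ reads (smallest q with #(values ≤ q) ≥ ⌈0.05n⌉); bases with
quality ≤ min(t₁, t₂−1) are untrusted regardless of k-mer support.
Quality-less (FASTA) input disables the gate.  Edit weights for the
pass-3 budget are 0 for N bases, 0.5 for bases at or below the cutoff,
1 otherwise.

## Bloom filters

Pattern-blocked layout: one hash selects a 512-bit block, and h bit
positions inside the block are derived by double hashing from two
further seeded 64-bit mixes (SplitMix64 finalizer) of the 2-bit k-mer
code.  Blocking confines each key's probes to one cache line at the
cost of running slightly above the classical (1 − e^{−hn/m})^h rate —
about +9% at the loads used here, because block loads fluctuate around
the mean.  The occupancy-based estimate β = occupancy^h is used
wherever the false-positive rate is needed.  An `ExactKmerSet` (sorted
code array, zero false positives) implements the same query interface
for reference analyses and oracle tests.

## Simulator

The generator emulates a standard single-end Illumina protocol:
i.i.d. uniform ACGT genome; reads of fixed length (default 101 bp)
with uniform start and strand; per-base substitution probability
rising linearly from e/2 at the 5′ end to 3e/2 at the 3′ end, so the
mean error rate is exactly e while errors concentrate at the 3′
terminus; Phred qualities q = round(−10·log₁₀ p) clamped to [2, 40],
consistent with the true error probabilities; optional diploid mode
(second haplotype with heterozygous SNPs at rate 0.001 by default,
reads drawn equally from both).  Every injected substitution is
recorded in a truth ledger, making per-nucleotide TP/FP/FN accounting
exact: a restored error is a TP, an edit at an error-free position an
FP, and a missed or wrongly substituted error an FN (counted once).

What the simulator does *not* model: indels, sequence-context error
bias, stochastic quality values (qualities are a deterministic
function of position — one consequence is that the fifth-percentile
gate becomes all-or-nothing per position), PCR/GC coverage bias, and
paired-end fragment geometry.  Passing results on these data therefore
demonstrate the method's statistical machinery, not robustness to
every artifact of real instruments.

## Numerical and design choices

* Thresholds: y_x = 1 + the smallest q with CDF_Binom(x,P\*)(q) ≥
  quantile, with a 10⁻¹² slack absorbing float round-off in the pmf
  summation; y_x may exceed x, in which case positions with x
  overlapping k-mers are never trusted (the over-subsampled regime).
* Anchor ties take the leftmost longest run; candidate substitutions
  are all four nucleotides (the original base can never win strictly,
  since its window is absent from B by construction).
* A correction is applied only on a unique strict maximum with a
  nonzero stretch; "all four score zero" counts as a tie and is
  reported ambiguous.
* After a successful edit the walk resumes at the next window and
  re-tests membership on the edited sequence; after a tie it skips k
  windows, mirroring the resume rule for ambiguous positions.
* Budget enforcement is causal: each candidate edit is tested against
  the weighted sum of already-applied edits in every k-window covering
  it; a blocked edit stops extension on that side but earlier edits
  stand.
* Reads shorter than k pass through untouched and unanchored; windows
  containing any non-ACGT character are invalid — they count toward a
  position's coverage x but can never hit a filter.
* Pass 3 may run on a thread pool (B is read-only and the kernels
  release the GIL); output is re-emitted in input order and is
  byte-identical for any worker count.  Passes 1–2 are
  single-threaded; B insertion is check-then-insert.

## Problem sizes

The test suite and the acceptance script run the method end-to-end at
desk scale: 1-Mbp genomes at 35× (~347k reads) for accuracy and
solid-set completeness, 0.5 Mbp across 20–140× for occupancy
constancy, and 0.3 Mbp diploid at 70× for heterozygous-k-mer
retention.  These sizes give tens of thousands of injected errors and
hundreds of thousands of distinct k-mers per run, enough to resolve
the reported percentages to well under one point.

## Known limitations

* Substitutions only; indels shift every downstream window and are
  neither detected nor repaired.
* k is capped at 31 (one 64-bit word per k-mer).
* G, k and α must be supplied by the user; nothing is estimated from
  the reads.
* At large α (low coverage) the thresholds sharpen toward y_x > x and
  solid-set completeness degrades — the method's own over-sampling
  regime; α between roughly 0.05 and 0.2 is the comfortable range.
* The blocked filter's false-positive rate is slightly above the
  classical formula; the +9% figure is specific to 512-bit blocks at
  the default loads.
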