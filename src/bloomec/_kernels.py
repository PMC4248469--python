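"""Numba-compiled kernels for the three correction passes.

Everything here operates on 2-bit nucleotide codes (A=0..T=3, ambiguous=4)
and on raw Bloom-filter bit arrays, so the hot loops run at native speed.
The public modules (:mod:`bloomec.bloom`, :mod:`bloomec.trust`,
:mod:`bloomec.correct`) are thin object wrappers over these functions;
there is exactly one implementation of each algorithmic step.

Set membership is generic over two backends:

* ``mode=0`` — a pattern-blocked Bloom filter (bits, nblocks, block_bits,
  h, three hash seeds);
* ``mode=1`` — an exact sorted array of 64-bit canonical codes, queried
  by binary search (used for zero-false-positive reference sets).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)

MODE_BLOOM = 0
MODE_EXACT = 1

# Edit-record flags emitted by the correction kernel.
FLAG_APPLIED = 0
FLAG_AMBIGUOUS = 1
FLAG_BUDGET = 2


@njit(cache=False, inline="always")
def _mix(x):
    """SplitMix64 finalizer: a well-mixed 64-bit hash of a 64-bit word."""
    z = x + U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=False, inline="always")
def _u01(seed, ordinal, offset):
    """Counter-based uniform(0,1) keyed by (seed, read ordinal, window offset)."""
    z = _mix(_mix(U64(seed) ^ (U64(ordinal) * _GOLDEN)) ^ (U64(offset) + U64(1)))
    return (z >> U64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# Blocked Bloom filter primitives


@njit(cache=False, inline="always")
def _bloom_test(bits, nblocks, block_bits, h, s0, s1, s2, code):
    base = (_mix(code ^ s0) % nblocks) * block_bits
    h1 = _mix(code ^ s1)
    h2 = _mix(code ^ s2) | U64(1)
    mask = block_bits - U64(1)
    for j in range(h):
        bit = base + ((h1 + U64(j) * h2) & mask)
        if bits[bit >> U64(6)] & (U64(1) << (bit & U64(63))) == U64(0):
            return False
    return True


@njit(cache=False, inline="always")
def _bloom_set(bits, nblocks, block_bits, h, s0, s1, s2, code):
    """Set the h bits for ``code``; returns True when any bit was newly set."""
    base = (_mix(code ^ s0) % nblocks) * block_bits
    h1 = _mix(code ^ s1)
    h2 = _mix(code ^ s2) | U64(1)
    mask = block_bits - U64(1)
    new = False
    for j in range(h):
        bit = base + ((h1 + U64(j) * h2) & mask)
        word = bit >> U64(6)
        sel = U64(1) << (bit & U64(63))
        if bits[word] & sel == U64(0):
            bits[word] |= sel
            new = True
    return new


@njit(cache=False, inline="always")
def _sorted_test(keys, code):
    lo = 0
    hi = keys.shape[0]
    while lo < hi:
        mid = (lo + hi) >> 1
        if keys[mid] < code:
            lo = mid + 1
        else:
            hi = mid
    return lo < keys.shape[0] and keys[lo] == code


@njit(cache=False, inline="always")
def _member_test(mode, bits, keys, nblocks, block_bits, h, s0, s1, s2, code):
    if mode == MODE_EXACT:
        return _sorted_test(keys, code)
    return _bloom_test(bits, nblocks, block_bits, h, s0, s1, s2, code)


@njit(cache=False)
def bloom_add_codes(bits, nblocks, block_bits, h, s0, s1, s2, codes):
    """Insert an array of codes; returns the number that set at least one new bit."""
    fresh = 0
    for i in range(codes.shape[0]):
        if _bloom_set(bits, nblocks, block_bits, h, s0, s1, s2, codes[i]):
            fresh += 1
    return fresh


@njit(cache=False, nogil=True)
def bloom_test_codes(bits, nblocks, block_bits, h, s0, s1, s2, codes, out):
    for i in range(codes.shape[0]):
        out[i] = _bloom_test(bits, nblocks, block_bits, h, s0, s1, s2, codes[i])


@njit(cache=False)
def popcount_words(bits):
    total = 0
    for i in range(bits.shape[0]):
        w = bits[i]
        while w != U64(0):
            w &= w - U64(1)
            total += 1
    return total


# ---------------------------------------------------------------------------
# Canonical k-mer scanning


@njit(cache=False, inline="always")
def _canon_at(codes, i, k):
    """Canonical code of the window at offset i; returns (code, valid)."""
    fwd = U64(0)
    rev = U64(0)
    valid = True
    for t in range(k):
        c = codes[i + t]
        if c > 3:
            valid = False
            c = 0
        cc = U64(c)
        fwd = (fwd << U64(2)) | cc
        rev = (rev >> U64(2)) | ((U64(3) - cc) << U64(2 * (k - 1)))
    if rev < fwd:
        fwd = rev
    return fwd, valid


@njit(cache=False, inline="always")
def _fill_canon(codes, L, k, canon, valid):
    """Rolling canonical codes for all windows of codes[:L] in O(L)."""
    mask = (U64(1) << U64(2 * k)) - U64(1)
    shift = U64(2 * (k - 1))
    fwd = U64(0)
    rev = U64(0)
    bad = 0
    for t in range(L):
        c = codes[t]
        if c > 3:
            bad += 1
            c = 0
        cc = U64(c)
        fwd = ((fwd << U64(2)) | cc) & mask
        rev = (rev >> U64(2)) | ((U64(3) - cc) << shift)
        if t >= k and codes[t - k] > 3:
            bad -= 1
        if t >= k - 1:
            j = t - k + 1
            valid[j] = bad == 0
            canon[j] = fwd if fwd <= rev else rev


# ---------------------------------------------------------------------------
# Pass 1: subsampled k-mer insertion into Bloom filter A


@njit(cache=False)
def pass1_chunk(codes2d, lens, k, alpha, seed, ordinal0,
                bits, nblocks, block_bits, h, s0, s1, s2):
    """Bernoulli(alpha)-subsample every valid window into the filter.

    The survival draw is keyed by (seed, read ordinal, window offset), so
    the outcome is independent of processing order.  Returns the number
    of occurrences added (survivors).
    """
    nmax = codes2d.shape[1] - k + 1
    canon = np.empty(max(nmax, 1), dtype=np.uint64)
    valid = np.empty(max(nmax, 1), dtype=np.bool_)
    added = 0
    for r in range(codes2d.shape[0]):
        L = lens[r]
        if L < k:
            continue
        row = codes2d[r]
        _fill_canon(row, L, k, canon, valid)
        ordinal = ordinal0 + r
        for j in range(L - k + 1):
            if not valid[j]:
                continue
            if _u01(seed, ordinal, j) < alpha:
                _bloom_set(bits, nblocks, block_bits, h, s0, s1, s2, canon[j])
                added += 1
    return added


# ---------------------------------------------------------------------------
# Pass 2: per-position trust test and solid k-mer collection


@njit(cache=False)
def trust_read(codes, L, quals, has_qual, cutoff, k, y,
               bitsA, nblocksA, block_bitsA, hA, a0, a1, a2,
               trusted, hits, xs):
    """Mark each position of one read trusted/untrusted.

    ``y`` is the threshold table indexed by x (1..k).  ``trusted``,
    ``hits`` and ``xs`` are output arrays of length >= L.  Positions of
    reads shorter than k are all untrusted (xs = 0).
    """
    for pos in range(L):
        trusted[pos] = False
        hits[pos] = 0
        xs[pos] = 0
    if L < k:
        return
    nwin = L - k + 1
    canon = np.empty(nwin, dtype=np.uint64)
    valid = np.empty(nwin, dtype=np.bool_)
    _fill_canon(codes, L, k, canon, valid)
    # prefix sums of window membership in A
    pre = np.empty(nwin + 1, dtype=np.int32)
    pre[0] = 0
    for j in range(nwin):
        inA = valid[j] and _bloom_test(
            bitsA, nblocksA, block_bitsA, hA, a0, a1, a2, canon[j])
        pre[j + 1] = pre[j] + (1 if inA else 0)
    for pos in range(L):
        lo = pos - k + 1
        if lo < 0:
            lo = 0
        hi = pos if pos < nwin - 1 else nwin - 1
        x = hi - lo + 1
        nh = pre[hi + 1] - pre[lo]
        xs[pos] = x
        hits[pos] = nh
        ok = nh >= y[x]
        if ok and has_qual and quals[pos] <= cutoff:
            ok = False
        trusted[pos] = ok


@njit(cache=False)
def collect_solid_read(codes, L, k, trusted,
                       bitsB, nblocksB, block_bitsB, hB, b0, b1, b2):
    """Add every valid window whose k positions are all trusted to B.

    Insertion is check-then-set; returns the number of windows whose
    k-mer was not already present.
    """
    if L < k:
        return 0
    nwin = L - k + 1
    canon = np.empty(nwin, dtype=np.uint64)
    valid = np.empty(nwin, dtype=np.bool_)
    _fill_canon(codes, L, k, canon, valid)
    added = 0
    pre = np.empty(L + 1, dtype=np.int32)
    pre[0] = 0
    for pos in range(L):
        pre[pos + 1] = pre[pos] + (1 if trusted[pos] else 0)
    for j in range(nwin):
        if not valid[j]:
            continue
        if pre[j + k] - pre[j] == k:
            if not _bloom_test(bitsB, nblocksB, block_bitsB, hB, b0, b1, b2,
                               canon[j]):
                _bloom_set(bitsB, nblocksB, block_bitsB, hB, b0, b1, b2,
                           canon[j])
                added += 1
    return added


@njit(cache=False)
def pass2_chunk(codes2d, lens, quals2d, has_qual, cutoff, k, y,
                bitsA, nblocksA, block_bitsA, hA, a0, a1, a2,
                bitsB, nblocksB, block_bitsB, hB, b0, b1, b2):
    """Trust-test every read of a chunk and collect solid k-mers into B."""
    Lmax = codes2d.shape[1]
    trusted = np.empty(Lmax, dtype=np.bool_)
    hits = np.empty(Lmax, dtype=np.int32)
    xs = np.empty(Lmax, dtype=np.int32)
    added = 0
    for r in range(codes2d.shape[0]):
        L = lens[r]
        row = codes2d[r]
        q = quals2d[r]
        trust_read(row, L, q, has_qual, cutoff, k, y,
                   bitsA, nblocksA, block_bitsA, hA, a0, a1, a2,
                   trusted, hits, xs)
        added += collect_solid_read(row, L, k, trusted,
                                    bitsB, nblocksB, block_bitsB, hB, b0, b1, b2)
    return added


# ---------------------------------------------------------------------------
# Pass 3: greedy substitution correction


@njit(cache=False, nogil=True)
def longest_member_run(codes, L, k,
                       mode, bits, keys, nblocks, block_bits, h, s0, s1, s2):
    """Leftmost longest run of consecutive windows present in the set.

    Returns (b, e) window offsets, or (-1, -1) when no window is present.
    """
    if L < k:
        return -1, -1
    nwin = L - k + 1
    best_b = -1
    best_len = 0
    run_b = -1
    run_len = 0
    for j in range(nwin):
        code, ok = _canon_at(codes, j, k)
        inb = ok and _member_test(mode, bits, keys, nblocks, block_bits, h,
                                  s0, s1, s2, code)
        if inb:
            if run_len == 0:
                run_b = j
            run_len += 1
            if run_len > best_len:
                best_len = run_len
                best_b = run_b
        else:
            run_len = 0
    if best_b < 0:
        return -1, -1
    return best_b, best_b + best_len - 1


@njit(cache=False, nogil=True)
def stretch_length(codes, L, i, k,
                   mode, bits, keys, nblocks, block_bits, h, s0, s1, s2):
    """Consecutive windows in the set starting at window i, capped at k.

    When the read runs out of windows before k are counted, counting
    continues virtually beyond the 3' end: a virtual window counts only
    if exactly one nucleotide extends the current (k-1)-suffix to a
    member k-mer; any tie or miss stops the count.
    """
    cnt = 0
    j = i
    while j <= L - k and cnt < k:
        code, ok = _canon_at(codes, j, k)
        if not (ok and _member_test(mode, bits, keys, nblocks, block_bits, h,
                                    s0, s1, s2, code)):
            return cnt
        cnt += 1
        j += 1
    if cnt == 0 or cnt >= k:
        return cnt
    # virtual extension: suffix = last k-1 bases of the read
    buf = np.empty(k, dtype=np.int8)
    for t in range(k - 1):
        buf[t] = codes[L - k + 1 + t]
    while cnt < k:
        nmatch = 0
        winner = -1
        for c in range(4):
            buf[k - 1] = c
            code, ok = _canon_at(buf, 0, k)
            if ok and _member_test(mode, bits, keys, nblocks, block_bits, h,
                                   s0, s1, s2, code):
                nmatch += 1
                winner = c
        if nmatch != 1:
            break
        cnt += 1
        for t in range(k - 2):
            buf[t] = buf[t + 1]
        buf[k - 2] = winner
    return cnt


@njit(cache=False, nogil=True, inline="always")
def _edit_weight(orig_code, qual, has_qual, cutoff):
    if orig_code > 3:
        return 0.0
    if has_qual and qual <= cutoff:
        return 0.5
    return 1.0


@njit(cache=False, nogil=True, inline="always")
def _budget_allows(weights, L, k, p, w, limit):
    """True when adding weight w at position p keeps every k-window <= limit."""
    lo = p - k + 1
    if lo < 0:
        lo = 0
    hi = p
    if hi > L - k:
        hi = L - k
    if hi < lo:  # read shorter than k: single pseudo-window
        lo = 0
        hi = 0
    for s in range(lo, hi + 1):
        tot = w
        e = s + k
        if e > L:
            e = L
        for t in range(s, e):
            tot += weights[t]
        if tot > limit + 1e-9:
            return False
    return True


@njit(cache=False, nogil=True)
def _walk_right(codes, L, quals, has_qual, cutoff, k, limit, weights, start_i,
                mode, bits, keys, nblocks, block_bits, h, s0, s1, s2,
                epos, efrom, eto, eflag, n0):
    """Greedy rightward repair from window ``start_i``; mutates ``codes``.

    Appends edit records starting at index n0; returns (n_records,
    budget_stopped).  Flags: 0 applied, 1 ambiguous, 2 budget-blocked.
    """
    n = n0
    i = start_i
    budget_stop = False
    while i <= L - k:
        code, ok = _canon_at(codes, i, k)
        if ok and _member_test(mode, bits, keys, nblocks, block_bits, h,
                               s0, s1, s2, code):
            i += 1
            continue
        p = i + k - 1
        orig = codes[p]
        best_len = -1
        best_c = -1
        ties = 0
        for c in range(4):
            codes[p] = c
            s = stretch_length(codes, L, i, k, mode, bits, keys, nblocks,
                               block_bits, h, s0, s1, s2)
            if s > best_len:
                best_len = s
                best_c = c
                ties = 1
            elif s == best_len:
                ties += 1
        codes[p] = orig
        if best_len > 0 and ties == 1:
            w = _edit_weight(orig, quals[p], has_qual, cutoff)
            if _budget_allows(weights, L, k, p, w, limit):
                codes[p] = np.int8(best_c)
                weights[p] += w
                epos[n] = p
                efrom[n] = orig
                eto[n] = best_c
                eflag[n] = FLAG_APPLIED
                n += 1
                i += 1
            else:
                epos[n] = p
                efrom[n] = orig
                eto[n] = best_c
                eflag[n] = FLAG_BUDGET
                n += 1
                budget_stop = True
                break
        else:
            # tie between candidates (possibly all at stretch 0): ambiguous
            epos[n] = p
            efrom[n] = orig
            eto[n] = orig
            eflag[n] = FLAG_AMBIGUOUS
            n += 1
            i = i + k
    return n, budget_stop


@njit(cache=False, nogil=True)
def correct_read_kernel(codes, L, quals, has_qual, cutoff, k, limit,
                        mode, bits, keys, nblocks, block_bits, h, s0, s1, s2,
                        epos, efrom, eto, eflag):
    """Full greedy correction of one read; mutates ``codes`` in place.

    Returns (n_records, anchored, budget_stop).  Record arrays must have
    capacity >= 2*L + 2.
    """
    if L < k:
        return 0, False, False
    b, e = longest_member_run(codes, L, k, mode, bits, keys, nblocks,
                              block_bits, h, s0, s1, s2)
    if b < 0:
        return 0, False, False
    weights = np.zeros(L, dtype=np.float64)
    n, stop_r = _walk_right(codes, L, quals, has_qual, cutoff, k, limit,
                            weights, e + 1,
                            mode, bits, keys, nblocks, block_bits, h,
                            s0, s1, s2, epos, efrom, eto, eflag, 0)
    # Leftward half: run the same walk on the reverse complement, whose
    # window (L-k-b) mirrors the anchor's left edge.  Canonicalized
    # membership is strand-symmetric, so the mirrored walk is exact.
    rc = np.empty(L, dtype=np.int8)
    rq = np.empty(L, dtype=np.uint8)
    rw = np.empty(L, dtype=np.float64)
    for t in range(L):
        c = codes[L - 1 - t]
        rc[t] = 3 - c if c <= 3 else c
        rq[t] = quals[L - 1 - t]
        rw[t] = weights[L - 1 - t]
    n1 = n
    n, stop_l = _walk_right(rc, L, rq, has_qual, cutoff, k, limit, rw,
                            (L - k - b) + 1,
                            mode, bits, keys, nblocks, block_bits, h,
                            s0, s1, s2, epos, efrom, eto, eflag, n1)
    # map the leftward records back to forward coordinates
    for t in range(n1, n):
        p = L - 1 - epos[t]
        epos[t] = p
        f = efrom[t]
        g = eto[t]
        efrom[t] = 3 - f if f <= 3 else f
        eto[t] = 3 - g if g <= 3 else g
        if eflag[t] == FLAG_APPLIED:
            codes[p] = eto[t]
    return n, True, stop_r or stop_l


@njit(cache=False, nogil=True)
def pass3_chunk(codes2d, lens, quals2d, has_qual, cutoff, k, limit,
                mode, bits, keys, nblocks, block_bits, h, s0, s1, s2,
                out_read, out_pos, out_from, out_to, out_flag,
                anchored, budget):
    """Correct a chunk of reads in place.

    Edit records are appended to the flat ``out_*`` arrays with the read
    index in ``out_read``.  Returns (reads_done, n_records); the driver
    stops early if the next read might overflow the record capacity, and
    the Python wrapper resumes with a larger buffer.
    """
    cap = out_read.shape[0]
    Lmax = codes2d.shape[1]
    epos = np.empty(2 * Lmax + 2, dtype=np.int32)
    efrom = np.empty(2 * Lmax + 2, dtype=np.int8)
    eto = np.empty(2 * Lmax + 2, dtype=np.int8)
    eflag = np.empty(2 * Lmax + 2, dtype=np.int8)
    n = 0
    r = 0
    nreads = codes2d.shape[0]
    while r < nreads:
        L = lens[r]
        if n + 2 * L + 2 > cap:
            break
        cnt, anch, stop = correct_read_kernel(
            codes2d[r], L, quals2d[r], has_qual, cutoff, k, limit,
            mode, bits, keys, nblocks, block_bits, h, s0, s1, s2,
            epos, efrom, eto, eflag)
        anchored[r] = anch
        budget[r] = stop
        for t in range(cnt):
            out_read[n] = r
            out_pos[n] = epos[t]
            out_from[n] = efrom[t]
            out_to[n] = eto[t]
            out_flag[n] = eflag[t]
            n += 1
        r += 1
    return r, n
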