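"""Brute-force reference implementations used as test oracles.

Everything here works on plain Python strings and sets — no bit
packing, no Bloom filters — and follows the greedy third-pass rules
directly: anchor at the leftmost longest run of member windows, walk
right scoring all four substitutions by consecutive-member stretch
(capped at k, with unique-extension counting past the read end), walk
left on the reverse complement, enforce the per-window edit budget.
"""

_RC = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def rc(seq):
    return seq.translate(_RC)[::-1]


def canon(word):
    r = rc(word)
    return word if word <= r else r


def member(bset, word):
    return "N" not in word and canon(word) in bset


def windows_member(seq, k, bset):
    return [member(bset, seq[i:i + k]) for i in range(len(seq) - k + 1)]


def leftmost_longest_run(flags):
    best_b, best_len, run_b, run_len = -1, 0, -1, 0
    for j, f in enumerate(flags):
        if f:
            if run_len == 0:
                run_b = j
            run_len += 1
            if run_len > best_len:
                best_b, best_len = run_b, run_len
        else:
            run_len = 0
    return (None if best_b < 0 else (best_b, best_b + best_len - 1))


def stretch(seq, i, k, bset):
    L = len(seq)
    cnt, j = 0, i
    while j <= L - k and cnt < k:
        if not member(bset, seq[j:j + k]):
            return cnt
        cnt += 1
        j += 1
    if cnt == 0 or cnt >= k:
        return cnt
    suffix = seq[L - k + 1:]
    while cnt < k:
        cands = [c for c in BASES if member(bset, suffix + c)]
        if len(cands) != 1:
            break
        cnt += 1
        suffix = (suffix + cands[0])[1:]
    return cnt


def _budget_ok(weights, p, k, w, limit):
    L = len(weights)
    lo, hi = max(0, p - k + 1), min(p, L - k)
    for s in range(lo, hi + 1):
        if sum(weights[s:s + k]) + w > limit + 1e-9:
            return False
    return True


def _walk_right(chars, quals, cutoff, k, limit, weights, start_i, bset,
                edits, ambig):
    L = len(chars)
    i = start_i
    while i <= L - k:
        if member(bset, "".join(chars[i:i + k])):
            i += 1
            continue
        p = i + k - 1
        orig = chars[p]
        scores = {}
        for c in BASES:
            chars[p] = c
            scores[c] = stretch("".join(chars), i, k, bset)
        chars[p] = orig
        best = max(scores.values())
        winners = [c for c in BASES if scores[c] == best]
        if best > 0 and len(winners) == 1:
            w = (0.0 if orig == "N" else
                 0.5 if quals is not None and quals[p] <= cutoff else 1.0)
            if _budget_ok(weights, p, k, w, limit):
                chars[p] = winners[0]
                weights[p] += w
                edits.append((p, orig, winners[0]))
                i += 1
            else:
                return True
        else:
            ambig.append(p)
            i += k
    return False


def oracle_correct(seq, k, bset, quals=None, cutoff=-1, limit=4.0):
    """Reference greedy correction; returns a dict of outcome fields."""
    L = len(seq)
    out = dict(seq=seq, edits=[], ambiguous=[], anchored=True,
               budget_stop=False)
    if L < k:
        out["anchored"] = False
        return out
    anchor = leftmost_longest_run(windows_member(seq, k, bset))
    if anchor is None:
        out["anchored"] = False
        return out
    b, e = anchor
    chars = list(seq)
    weights = [0.0] * L
    edits, ambig = [], []
    stop_r = _walk_right(chars, quals, cutoff, k, limit, weights, e + 1,
                         bset, edits, ambig)
    # mirrored leftward walk on the reverse complement
    rchars = list(rc("".join(chars)))
    rquals = None if quals is None else list(reversed(quals))
    rweights = list(reversed(weights))
    redits, rambig = [], []
    stop_l = _walk_right(rchars, rquals, cutoff, k, limit, rweights,
                         (L - k - b) + 1, bset, redits, rambig)
    for p, f, t in redits:
        q = L - 1 - p
        chars[q] = rc(t)
        edits.append((q, rc(f), rc(t)))
    ambig += [L - 1 - p for p in rambig]
    out.update(seq="".join(chars), edits=sorted(edits),
               ambiguous=sorted(ambig), budget_stop=stop_r or stop_l)
    return out
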