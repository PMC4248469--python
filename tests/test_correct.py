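import numpy as np

from bloomec.bloom import BloomFilter, ExactKmerSet
from bloomec.correct import (BudgetPolicy, correct_dataset, correct_read,
                             find_anchor, score_substitution)
from bloomec.kmers import canonical_codes, reverse_complement, seq_to_codes
from bloomec.trust import QualityThresholds, ReadRecord
from conftest import genome_kmer_set, random_seq
from _reference import canon, oracle_correct

K = 9


def mutate(seq, pos, rng=None, base=None):
    old = seq[pos]
    if base is None:
        base = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(0, 3))) % 4]
    return seq[:pos] + base + seq[pos + 1:]


# ---------------------------------------------------------------------------
# Anchor


def test_anchor_spans_whole_read_when_all_windows_solid(toy_genome):
    bset = genome_kmer_set(toy_genome, K)
    read = toy_genome[50:110]
    assert find_anchor(read, bset, K) == (0, len(read) - K)


def test_anchor_none_when_no_window_solid(rng):
    bset = ExactKmerSet([])
    assert find_anchor(random_seq(rng, 60), bset, K) is None


def test_anchor_takes_leftmost_longest_run(toy_genome):
    read = toy_genome[100:160]
    wins = [read[i:i + K] for i in range(len(read) - K + 1)]
    keep = list(range(0, 3)) + list(range(10, 15)) + list(range(30, 35))
    bset = ExactKmerSet.from_kmers([wins[i] for i in keep])
    assert find_anchor(read, bset, K) == (10, 14)  # first of the two 5-runs


# ---------------------------------------------------------------------------
# Substitution scoring


def test_true_base_scores_longest_stretch(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    read = toy_genome[40:100]
    pos = 30
    bad = mutate(read, pos, rng)
    true_base = read[pos]
    scores = {c: score_substitution(bad, pos, c, bset, K) for c in "ACGT"}
    assert scores[true_base] == K  # capped at k
    assert all(s < scores[true_base]
               for c, s in scores.items() if c != true_base)


def test_nonmember_substitution_scores_zero(toy_genome, rng):
    bset = ExactKmerSet([])
    read = toy_genome[40:100]
    assert score_substitution(read, 30, "A", bset, K) == 0


def test_virtual_extension_resolves_last_position(toy_genome, rng):
    """An error at the very last base is scored using windows that
    extend beyond the read end, avoiding a forced tie."""
    bset = genome_kmer_set(toy_genome, K)
    read = toy_genome[40:100]
    pos = len(read) - 1
    bad = mutate(read, pos, rng)
    scores = {c: score_substitution(bad, pos, c, bset, K) for c in "ACGT"}
    best = max(scores.values())
    assert best > 1  # in-read evidence alone is a single window
    assert [c for c in "ACGT" if scores[c] == best] == [read[pos]]


def test_leftward_scoring_mirrors_rightward(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    read = toy_genome[40:100]
    pos = 4  # within the first k-1 bases: only leftward windows exist
    bad = mutate(read, pos, rng)
    scores = {c: score_substitution(bad, pos, c, bset, K, direction="left")
              for c in "ACGT"}
    best = max(scores.values())
    assert [c for c in "ACGT" if scores[c] == best] == [read[pos]]


# ---------------------------------------------------------------------------
# Single-read correction


def test_error_free_read_unchanged(toy_genome):
    bset = genome_kmer_set(toy_genome, K)
    read = ReadRecord("r0", toy_genome[20:90])
    res = correct_read(read, bset, K)
    assert res.seq == read.seq
    assert res.edits == [] and res.anchored and not res.budget_stop


def test_single_mid_read_error_restored(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    true = toy_genome[20:90]
    for pos in [0, 5, 20, 35, 60, 68, 69]:
        bad = mutate(true, pos, rng)
        res = correct_read(ReadRecord("r0", bad), bset, K)
        assert res.seq == true, f"error at {pos} not restored"
        assert res.edits == [(pos, bad[pos], true[pos])]


def test_engineered_repeat_is_ambiguous(toy_genome):
    """When two substitutions both yield full stretches the position is
    left uncorrected and reported ambiguous."""
    true = toy_genome[20:80]
    pos = 30
    alt = mutate(true, pos, base="ACGT"[("ACGT".index(true[pos]) + 1) % 4])
    bset = ExactKmerSet.from_kmers(
        [true[i:i + K] for i in range(len(true) - K + 1)]
        + [alt[i:i + K] for i in range(len(alt) - K + 1)])
    observed = mutate(true, pos, base="ACGT"[("ACGT".index(true[pos]) + 2) % 4])
    res = correct_read(ReadRecord("r0", observed), bset, K)
    assert res.seq == observed
    assert res.edits == []
    assert pos in res.ambiguous_positions


def test_short_read_passes_through():
    res = correct_read(ReadRecord("r0", "ACGT"), ExactKmerSet([]), K)
    assert res.seq == "ACGT" and not res.anchored


def test_unanchored_read_unchanged(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    junk = random_seq(rng, 60)
    res = correct_read(ReadRecord("r0", junk), bset, K)
    if not res.anchored:  # random 60-mer shares no 9-mer with the genome
        assert res.seq == junk


def test_budget_limits_edits_in_window(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    true = toy_genome[20:90]
    bad = mutate(mutate(true, 40, rng), 44, rng)  # two errors in one k-window
    res = correct_read(ReadRecord("r0", bad), bset, K,
                       policy=BudgetPolicy(limit=1.0))
    assert len(res.edits) <= 1
    assert res.budget_stop
    full = correct_read(ReadRecord("r0", bad), bset, K)
    assert full.seq == true  # default budget of 4 repairs both


def test_length_preserved_and_edits_consistent(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    for _ in range(50):
        start = int(rng.integers(0, 340))
        true = toy_genome[start:start + 60]
        bad = true
        for pos in rng.choice(60, size=int(rng.integers(0, 4)), replace=False):
            bad = mutate(bad, int(pos), rng)
        res = correct_read(ReadRecord("r0", bad), bset, K)
        assert len(res.seq) == len(bad)
        diff = [i for i in range(60) if res.seq[i] != bad[i]]
        assert diff == [p for p, _, _ in res.edits]
        for p, b_from, b_to in res.edits:
            assert bad[p] == b_from and res.seq[p] == b_to


def test_budget_invariant_post_hoc(toy_genome, rng):
    """Sum of applied edit weights inside every k-window <= limit."""
    bset = genome_kmer_set(toy_genome, K)
    limit = 2.0
    for _ in range(30):
        start = int(rng.integers(0, 330))
        bad = toy_genome[start:start + 70]
        for pos in rng.choice(70, size=5, replace=False):
            bad = mutate(bad, int(pos), rng)
        res = correct_read(ReadRecord("r0", bad), bset, K,
                           policy=BudgetPolicy(limit=limit))
        w = np.zeros(70)
        for p, _, _ in res.edits:
            w[p] += 1.0
        for s in range(70 - K + 1):
            assert w[s:s + K].sum() <= limit + 1e-9


def test_correcting_twice_is_idempotent(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    for _ in range(20):
        start = int(rng.integers(0, 330))
        bad = toy_genome[start:start + 60]
        for pos in rng.choice(60, size=2, replace=False):
            bad = mutate(bad, int(pos), rng)
        once = correct_read(ReadRecord("r0", bad), bset, K)
        twice = correct_read(ReadRecord("r0", once.seq), bset, K)
        assert twice.seq == once.seq
        assert twice.edits == []


# ---------------------------------------------------------------------------
# Oracle equivalence (string-level brute force vs kernel)


def test_correct_read_matches_reference_oracle(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    str_set = {canon(toy_genome[i:i + K])
               for i in range(len(toy_genome) - K + 1)}
    for _ in range(150):
        start = int(rng.integers(0, 340))
        length = int(rng.integers(K + 2, 61))
        bad = toy_genome[start:start + length]
        for pos in rng.choice(length, size=int(rng.integers(0, 3)),
                              replace=False):
            bad = mutate(bad, int(pos), rng)
        res = correct_read(ReadRecord("r0", bad), bset, K)
        ref = oracle_correct(bad, K, str_set)
        assert res.seq == ref["seq"]
        assert res.edits == ref["edits"]
        assert res.ambiguous_positions == ref["ambiguous"]
        assert res.anchored == ref["anchored"]
        assert res.budget_stop == ref["budget_stop"]


def test_reads_with_n_match_reference(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    str_set = {canon(toy_genome[i:i + K])
               for i in range(len(toy_genome) - K + 1)}
    for _ in range(50):
        start = int(rng.integers(0, 340))
        bad = toy_genome[start:start + 50]
        p = int(rng.integers(0, 50))
        bad = bad[:p] + "N" + bad[p + 1:]
        res = correct_read(ReadRecord("r0", bad), bset, K)
        ref = oracle_correct(bad, K, str_set)
        assert res.seq == ref["seq"]
        assert res.edits == ref["edits"]


def test_low_quality_edits_weigh_half(toy_genome, rng):
    """Edits at low-quality bases consume 0.5 budget, so twice as many
    fit in a window."""
    bset = genome_kmer_set(toy_genome, K)
    true = toy_genome[20:90]
    bad = mutate(mutate(true, 40, rng), 44, rng)
    qual = "I" * 70
    qt = QualityThresholds(t1=40, t2=41, cutoff=40, sample_size=1)  # all low
    res = correct_read(ReadRecord("r0", bad, qual), bset, K, qthresh=qt,
                       policy=BudgetPolicy(limit=1.0))
    assert res.seq == true  # 0.5 + 0.5 fits the budget of 1
    assert not res.budget_stop


# ---------------------------------------------------------------------------
# Dataset-level correction


def _simulated_reads(toy_genome, rng, n=300):
    reads, truths = [], []
    for i in range(n):
        start = int(rng.integers(0, 330))
        true = toy_genome[start:start + 60]
        bad = true
        for pos in rng.choice(60, size=int(rng.integers(0, 3)), replace=False):
            bad = mutate(bad, int(pos), rng)
        reads.append(ReadRecord(f"r{i}", bad, "I" * 60))
        truths.append(true)
    return reads, truths


def test_dataset_matches_per_read_path(toy_genome, rng):
    """The batched kernel path and the single-read API agree exactly,
    also when B is a real Bloom filter with false positives."""
    canonc, valid = canonical_codes(seq_to_codes(toy_genome), K)
    bf = BloomFilter(1 << 14, 3, 512, seed=3)
    bf.add_codes(canonc[valid])
    reads, _ = _simulated_reads(toy_genome, rng)
    batch = list(correct_dataset(reads, bf, K, batch_size=64))
    for r, res in zip(reads, batch):
        single = correct_read(r, bf, K)
        assert res.seq == single.seq
        assert res.edits == single.edits
        assert res.ambiguous_positions == single.ambiguous_positions
        assert (res.anchored, res.budget_stop) == (single.anchored,
                                                   single.budget_stop)


def test_worker_count_does_not_change_output(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    reads, _ = _simulated_reads(toy_genome, rng, n=500)
    one = list(correct_dataset(reads, bset, K, workers=1, batch_size=37))
    four = list(correct_dataset(reads, bset, K, workers=4, batch_size=37))
    assert [(r.id, r.seq, tuple(r.edits)) for r in one] == \
           [(r.id, r.seq, tuple(r.edits)) for r in four]


def test_empty_input_and_count_preservation(toy_genome, rng):
    bset = genome_kmer_set(toy_genome, K)
    assert list(correct_dataset([], bset, K)) == []
    reads, _ = _simulated_reads(toy_genome, rng, n=57)
    out = list(correct_dataset(reads, bset, K, batch_size=10))
    assert [r.id for r in out] == [r.id for r in reads]
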