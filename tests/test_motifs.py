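import itertools

import numpy as np
import pytest

from astromarkers.motifs import (
    PWM,
    empirical_pvalues,
    exact_tail_probability,
    read_pwm_jaspar,
    reverse_complement,
    scan,
    score_distribution,
    shuffle_sequence,
    write_pwm_jaspar,
)


@pytest.fixture
def toy_pwm():
    # strong 5-mer, consensus ACGTA
    counts = np.array(
        [[8, 0, 0, 0, 8], [0, 8, 0, 0, 0], [0, 0, 8, 0, 0], [0, 0, 0, 8, 0]], float
    )
    return PWM("toy", counts)


def random_pwm(rng, length, strength=10):
    counts = rng.integers(0, strength, (4, length)).astype(float)
    counts[rng.integers(0, 4, length), np.arange(length)] += strength
    return PWM(f"rand{length}", counts)


def test_jaspar_roundtrip_and_normalization(tmp_path, toy_pwm):
    eight = PWM("m8", np.abs(np.random.default_rng(0).normal(4, 2, (4, 8))))
    path = tmp_path / "m.jaspar"
    write_pwm_jaspar([toy_pwm, eight], path)
    back = read_pwm_jaspar(path)
    assert [p.id for p in back] == ["toy", "m8"]
    assert back[1].length == 8
    assert np.allclose(back[1].probabilities.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(back[1].counts, eight.counts, atol=1e-6)


def test_zero_column_with_pseudocount_becomes_uniform():
    pwm = PWM("z", np.array([[0, 4], [0, 0], [0, 0], [0, 4]], float), pseudocount=0.25)
    assert np.allclose(pwm.probabilities[:, 0], 0.25)


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        PWM("bad", np.array([[1, 2], [3, 4]], float))  # not 4 rows
    with pytest.raises(ValueError):
        PWM("neg", -np.ones((4, 3)))


def test_consensus_scores_maximal_at_offset_zero(toy_pwm):
    scores = scan(toy_pwm.consensus, toy_pwm)
    assert scores.shape == (2, 1)
    assert scores[0, 0] == pytest.approx(toy_pwm.max_score)


def test_palindromic_pwm_scores_equal_on_both_strands():
    # consensus ACGT = its own reverse complement, symmetric counts
    counts = np.array([[9, 1, 1, 1], [1, 9, 1, 1], [1, 1, 9, 1], [1, 1, 1, 9]], float)
    pwm = PWM("pal", counts)
    seq = "TTACGTAA"
    scores = scan(seq, pwm)
    assert np.allclose(scores[0], scores[1])


def test_scan_matches_hand_computed_log_odds(toy_pwm):
    seq = "ACGTACGT"  # 4 positions x 2 strands for a 5-mer
    scores = scan(seq, toy_pwm)
    lo = toy_pwm.log_odds
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(4):
        fwd = sum(lo[idx[seq[i + j]], j] for j in range(5))
        rc = reverse_complement(seq[i : i + 5])
        rev = sum(lo[idx[rc[j]], j] for j in range(5))
        assert scores[0, i] == pytest.approx(fwd)
        assert scores[1, i] == pytest.approx(rev)


def test_scan_matches_biopython_pssm(toy_pwm):
    Bio_motifs = pytest.importorskip("Bio.motifs")
    from Bio.Seq import Seq

    m = Bio_motifs.Motif(
        alignment=None,
        counts={b: list(toy_pwm.counts[i]) for i, b in enumerate("ACGT")},
    )
    pssm = m.counts.normalize(pseudocounts=0.25).log_odds()
    seq = "ACGTACGTTTGACA"
    ours = scan(seq, toy_pwm)[0]
    theirs = pssm.calculate(Seq(seq))
    assert np.allclose(ours, np.asarray(theirs), atol=1e-5)


def test_n_bases_contribute_zero(toy_pwm):
    all_n = "N" * 5
    assert scan(all_n, toy_pwm)[0, 0] == pytest.approx(0.0)


def test_score_distribution_is_exact_for_l4():
    rng = np.random.default_rng(1)
    pwm = random_pwm(rng, 4)
    scores, probs = score_distribution(pwm)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    # brute-force enumeration of all 4^4 windows under the uniform background
    lo = pwm.log_odds
    brute = {}
    for word in itertools.product(range(4), repeat=4):
        s = round(sum(lo[b, j] for j, b in enumerate(word)), 9)
        brute[s] = brute.get(s, 0.0) + 0.25**4
    # expand both distributions to the 256 equally likely words and compare
    expanded = np.repeat(scores, np.round(probs * 4**4).astype(int))
    brute_words = np.sort(
        [s for s, p in brute.items() for _ in range(round(p * 4**4))]
    )
    assert expanded.size == 256
    assert np.allclose(expanded, brute_words, atol=1e-6)
    # exact tail at the median score agrees with the brute-force tail
    thresh = float(np.median(scores))
    brute_tail = sum(p for s, p in brute.items() if s >= thresh - 1e-6)
    assert exact_tail_probability(thresh, pwm)[0] == pytest.approx(brute_tail, abs=1e-9)


def test_exact_enum_rejects_long_motifs():
    pwm = PWM("long", np.ones((4, 13)))
    with pytest.raises(ValueError):
        score_distribution(pwm)


def test_max_score_pvalue_hits_add_one_floor(toy_pwm):
    seq = "T" * 20 + toy_pwm.consensus + "T" * 20
    scores = scan(seq, toy_pwm)
    n_pos = scores.shape[1]
    p = empirical_pvalues(toy_pwm.max_score, seq, toy_pwm, "shuffle_mono", 100, seed=0)
    n_null = 100 * 2 * n_pos
    assert p[0] >= 1.0 / (1 + n_null)
    assert 0 < p[0] <= 1


def test_pvalue_monotone_in_score(toy_pwm, rng):
    seq = "".join(rng.choice(list("ACGT"), 60))
    scores = np.sort(scan(seq, toy_pwm).ravel())
    p = empirical_pvalues(scores, seq, toy_pwm, "shuffle_mono", 200, seed=1)
    assert (np.diff(p) <= 1e-12).all()  # higher score never gets larger p


def test_shuffles_are_seeded_and_composition_preserving(rng):
    seq = "".join(rng.choice(list("ACGT"), 80))
    for mode in ("shuffle_mono", "shuffle_di"):
        a = shuffle_sequence(seq, mode, np.random.default_rng(5))
        b = shuffle_sequence(seq, mode, np.random.default_rng(5))
        assert a == b
        assert sorted(a) == sorted(seq)
    di = shuffle_sequence(seq, "shuffle_di", np.random.default_rng(6))
    count = lambda s: {p: sum(1 for q in zip(s, s[1:]) if q == p)
                       for p in set(zip(s, s[1:]))}
    assert count(di) == count(seq)


def test_strand_symmetry_of_scan(rng):
    pwm = random_pwm(rng, 6)
    seq = "".join(rng.choice(list("ACGT"), 50))
    fwd = scan(seq, pwm)
    rev = scan(reverse_complement(seq), pwm)
    # scanning the reverse complement swaps strands and mirrors offsets
    assert np.allclose(fwd[0], rev[1][::-1])
    assert np.allclose(fwd[1], rev[0][::-1])
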