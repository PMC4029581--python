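import itertools

import numpy as np
import pytest

from astromarkers.datasets import load_fixture
from astromarkers.genesets import GeneSet
from astromarkers.markers import (
    FoldChangeCriterion,
    StringentPolicy,
    heatmap_matrix,
    interrogate_gene_set,
    pairwise_fold_filter,
    stringent_marker_filter,
)
from astromarkers.preprocess import clean_matrix
from astromarkers.simulate import StudyDesign, generate_aux_datasets, generate_expression_study

from conftest import ASTRO, NSC, make_matrix, random_clean_matrix

UP5 = FoldChangeCriterion(ASTRO, NSC, 5.0, "up")


def brute_force_pass_set(m, group_a, group_b, fold, direction, inclusive=True):
    """Independent nested-loop re-check of the all-pairs criterion."""
    a_cols = [s for s, g in m.groups.items() if g == group_a]
    b_cols = [s for s, g in m.groups.items() if g == group_b]
    passed = set()
    for gene in m.gene_ids:
        ok = True
        for a, b in itertools.product(a_cols, b_cols):
            ia, ib = m.values.at[gene, a], m.values.at[gene, b]
            ratio = ia / ib if direction == "up" else ib / ia
            if not (ratio >= fold if inclusive else ratio > fold):
                ok = False
        if ok:
            passed.add(gene)
    return passed


def test_gfap_fold_and_ordering():
    m = clean_matrix(load_fixture("stringent_markers"))
    results = pairwise_fold_filter(m, UP5)
    by_gene = {r.gene: r for r in results}
    assert by_gene["GFAP"].min_pairwise_fold == pytest.approx(1456 / 8)
    folds = [r.min_pairwise_fold for r in results]
    assert folds == sorted(folds, reverse=True)


def test_flat_gene_fails_any_threshold_above_one():
    m = make_matrix({"FLAT": [7, 7, 7, 7]})
    assert pairwise_fold_filter(m, FoldChangeCriterion(ASTRO, NSC, 1.01)) == []
    strict1 = FoldChangeCriterion(ASTRO, NSC, 1.0, boundary="strict")
    assert pairwise_fold_filter(m, strict1) == []


def test_filter_matches_bruteforce_oracle(rng):
    m = random_clean_matrix(rng, n_genes=200)
    for fold, direction in [(5.0, "up"), (2.0, "up"), (2.0, "down")]:
        crit = FoldChangeCriterion(ASTRO, NSC, fold, direction)
        got = {r.gene for r in pairwise_fold_filter(m, crit)}
        assert got == brute_force_pass_set(m, ASTRO, NSC, fold, direction)


def test_boundary_modes_differ_exactly_at_threshold():
    m = make_matrix({"EDGE": [100, 100, 50, 50], "OVER": [101, 101, 50, 50]})
    inclusive = {r.gene for r in pairwise_fold_filter(
        m, FoldChangeCriterion(ASTRO, NSC, 2.0, boundary="inclusive"))}
    strict = {r.gene for r in pairwise_fold_filter(
        m, FoldChangeCriterion(ASTRO, NSC, 2.0, boundary="strict"))}
    assert inclusive == {"EDGE", "OVER"}
    assert strict == {"OVER"}


def test_monotonicity_and_group_swap_symmetry(rng):
    for _ in range(20):
        m = random_clean_matrix(rng, n_genes=30)
        thresholds = [1.5, 2.0, 5.0, 8.0]
        passes = [
            {r.gene for r in pairwise_fold_filter(m, FoldChangeCriterion(ASTRO, NSC, t))}
            for t in thresholds
        ]
        for small, large in zip(passes, passes[1:]):
            assert large <= small
        down = {r.gene for r in pairwise_fold_filter(
            m, FoldChangeCriterion(ASTRO, NSC, 3.0, "down"))}
        up_swapped = {r.gene for r in pairwise_fold_filter(
            m, FoldChangeCriterion(NSC, ASTRO, 3.0, "up"))}
        assert down == up_swapped


def test_overlapping_groups_rejected():
    m = make_matrix({"A": [60, 60, 60, 60]})
    with pytest.raises(ValueError):
        pairwise_fold_filter(m, FoldChangeCriterion(ASTRO, ASTRO, 2.0))


def test_uncleaned_matrix_rejected():
    m = make_matrix({"A": [0, 60, 60, 60]})
    with pytest.raises(ValueError, match="cleaned"):
        pairwise_fold_filter(m, UP5)


def test_stringent_filter_recovers_planted_subset():
    design = StudyDesign(n_genes=120, n_planted_markers=10, planted_fold=8,
                         noise_cv=0.0, seed=7)
    m, truth = generate_expression_study(design)
    candidates = pairwise_fold_filter(clean_matrix(m), UP5)
    assert {r.gene for r in candidates} == truth
    da, extra_nsc, neurons, strue = generate_aux_datasets(truth, design, stringent_true=6)
    kept = stringent_marker_filter(candidates, [da], [extra_nsc], neurons)
    assert {r.gene for r in kept} == strue
    assert all(r.stage == "stringent_pass" for r in kept)
    # stringent pass set is a subset of the pairwise pass set
    assert {r.gene for r in kept} <= {r.gene for r in candidates}


def test_stringent_excludes_candidate_below_floor_in_one_astro_sample():
    cand_matrix = make_matrix({"X": [400, 400, 1, 1]})
    cands = pairwise_fold_filter(cand_matrix, UP5)
    da = make_matrix({"X": [200, 30, 200, 200]},
                     samples=["d1", "d2", "d3", "d4"],
                     groups={f"d{i}": "derived" for i in range(1, 5)})
    low = make_matrix({"X": [1, 1, 1, 1]},
                      samples=["n1", "n2", "n3", "n4"],
                      groups={f"n{i}": "other" for i in range(1, 5)})
    assert stringent_marker_filter(cands, [da], [low], low) == []
    assert stringent_marker_filter([], [da], [low], low) == []


def test_stringent_missing_gene_policy():
    cands = pairwise_fold_filter(make_matrix({"X": [400, 400, 1, 1]}), UP5)
    empty = make_matrix({"OTHER": [200, 200, 200, 200]},
                        samples=["d1", "d2", "d3", "d4"],
                        groups={f"d{i}": "derived" for i in range(1, 5)})
    low = make_matrix({"X": [1, 1, 1, 1]},
                      samples=["n1", "n2", "n3", "n4"],
                      groups={f"n{i}": "o" for i in range(1, 5)})
    assert stringent_marker_filter(cands, [empty], [low], low) == []
    kept = stringent_marker_filter(
        cands, [empty], [low], low, StringentPolicy(missing_policy="ignore"))
    assert [r.gene for r in kept] == ["X"]


def test_gene_set_interrogation_reproduces_tf_counts():
    up_m = clean_matrix(load_fixture("tf_up"))
    summary = interrogate_gene_set(
        up_m, GeneSet("tf", tuple(up_m.gene_ids)), ASTRO, NSC, fold=2.0)
    assert summary.up_in_a == 46
    down_m = clean_matrix(load_fixture("tf_down"))
    summary_down = interrogate_gene_set(
        down_m, GeneSet("tf", tuple(down_m.gene_ids)), ASTRO, NSC, fold=2.0)
    assert summary_down.down_in_a == 51


def test_gene_set_disjoint_from_matrix_counts_zero():
    m = make_matrix({"A": [60, 60, 60, 60]})
    s = interrogate_gene_set(m, GeneSet("none", ("X", "Y")), ASTRO, NSC)
    assert (s.expressed_a, s.expressed_b, s.up_in_a, s.down_in_a) == (0, 0, 0, 0)
    assert not s.table["in_matrix"].any()


def test_heatmap_matrix_transforms_and_ordering():
    m = clean_matrix(load_fixture("stringent_markers"))
    summary = interrogate_gene_set(m, GeneSet("mk", tuple(m.gene_ids)), ASTRO, NSC)
    hm = heatmap_matrix(summary.table, m.sample_ids)
    assert hm.shape == (24, 4)
    assert "GFAP" in hm.index[:5]  # among the largest log2 spreads
    assert np.allclose(hm.loc["GFAP"], np.log2([3280, 1456, 8, 1]))
    z = heatmap_matrix(summary.table, m.sample_ids, row_scale="zscore")
    assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)
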