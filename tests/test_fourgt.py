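import numpy as np
import pytest

import cenhap as ch
from cenhap.fourgt import (
    FilterConfig,
    four_gamete,
    fourgt_dco,
    fourgt_dco_pass,
    fourgt_dco_reference,
    pair_fails,
)
from cenhap.ld_stats import gamete_table
from oracles import four_gamete_explicit


def perfect_tree_matrix(make_matrix):
    """Nested clades, no recombination: no pair shows four gametes."""
    alleles = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 1, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
        ]
    )
    return make_matrix(alleles)


def test_four_gamete_examples(make_matrix):
    m = make_matrix(np.array([[0, 0], [1, 0], [0, 1], [1, 1]]))
    assert four_gamete(m, 0, 1)
    col = np.array([0, 1, 0, 1])
    m = make_matrix(np.stack([col, col], axis=1))
    assert not four_gamete(m, 0, 1)
    m = make_matrix(np.array([[0, 0], [0, 1], [1, 1], [1, 1]]))
    assert not four_gamete(m, 0, 1)  # 00, 01, 11 only


def test_four_gamete_matches_explicit_enumeration(make_matrix):
    rng = np.random.default_rng(3)
    for _ in range(200):
        a = rng.integers(0, 2, size=8)
        b = rng.integers(0, 2, size=8)
        m = make_matrix(np.stack([a, b], axis=1))
        assert four_gamete(m, 0, 1) == four_gamete_explicit(a, b)


def test_pair_fails_perfect_tree(make_matrix):
    m = perfect_tree_matrix(make_matrix)
    assert not pair_fails(m, 1, 0, 2)


def error_island_matrix(make_matrix):
    """Focal = subclade of the flank clade with one haplotype flipped;
    flanks in complete LD with each other."""
    left = np.array([1, 1, 1, 0, 0, 0])
    right = left.copy()
    focal = np.array([1, 1, 0, 0, 0, 0])  # nested within the flank clade
    focal[4] = 1  # the apparent single-site conversion
    return make_matrix(np.stack([left, focal, right], axis=1))


def test_pair_fails_on_single_haplotype_island(make_matrix):
    m = error_island_matrix(make_matrix)
    assert four_gamete(m, 1, 0) and four_gamete(m, 1, 2)
    assert not four_gamete(m, 0, 2)
    assert pair_fails(m, 1, 0, 2)


def test_pair_fails_requires_consistent_flanks(make_matrix):
    # flanks exhibiting four gametes between themselves veto the pair
    alleles = np.array(
        [[0, 0, 0], [0, 1, 1], [1, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 0]]
    )
    m = make_matrix(alleles)
    assert four_gamete(m, 0, 2)
    assert not pair_fails(m, 1, 0, 2)


def single_error_fixture():
    """50-SNP perfect-tree region with one flipped allele at site 25.

    The flipped haplotype is the first one whose flip turns site 25 into
    a four-gamete island against its immediate neighbours (a flip can
    also land where it stays tree-consistent and invisible).
    """
    params = ch.paper_like_params(seed=21, n_haplotypes=40)
    rng = np.random.default_rng(21)
    drop = ch.drop_mutations(ch.simulate_genealogy(params, rng), n_sites=50, rng=rng)
    m = drop.matrix
    for s in range(20, 40):
        for h in range(m.n_haplotypes):
            alleles = m.alleles.copy()
            alleles[h, s] = 1 - alleles[h, s]
            m2 = ch.HaplotypeMatrix(
                list(m.hap_ids), list(m.sites), alleles, m.region
            ).with_recomputed_mac()
            if pair_fails(m2, s, s - 1, s + 1):
                return m2, s
    raise AssertionError("no detectable flip found")


def test_single_error_removed_exactly():
    """Exactly the error-bearing SNP is removed at tolerance 0."""
    m, s = single_error_fixture()
    result = fourgt_dco(m, FilterConfig(tolerance=0))
    assert [idx for idx, _, _ in result.removed] == [s]
    assert result.removed[0][1] == 1  # caught in the first pass
    ref = fourgt_dco_reference(m, FilterConfig(tolerance=0))
    assert ref.removed == result.removed


def test_tolerance_above_failing_count_keeps_site():
    m, _ = single_error_fixture()
    baseline = fourgt_dco(m, FilterConfig(windows=(10,), tolerance=0))
    n_failing = baseline.removed[0][2]
    result = fourgt_dco(m, FilterConfig(windows=(10,), tolerance=n_failing))
    assert result.removed == []


def test_no_removals_without_four_gamete_pairs(clean_sim, make_matrix):
    _, drop = clean_sim
    result = fourgt_dco(drop.matrix)
    assert result.removed == []
    # all-identical columns can never fail either
    col = np.array([0, 1, 1, 0, 1])
    m = make_matrix(np.stack([col] * 12, axis=1))
    assert fourgt_dco(m).removed == []


def test_pass_threads_surviving_set(make_matrix):
    m, s = single_error_fixture()
    surv = list(range(m.n_sites))
    out = fourgt_dco_pass(m, surv, 10, 0)
    assert s not in out and len(out) == m.n_sites - 1


def test_production_equals_reference_on_random_matrices(make_matrix):
    rng = np.random.default_rng(17)
    for _ in range(15):
        alleles = (rng.random((30, 60)) < rng.uniform(0.1, 0.5)).astype(np.int8)
        m = make_matrix(alleles)
        config = FilterConfig(tolerance=int(rng.integers(0, 4)))
        prod = fourgt_dco(m, config)
        ref = fourgt_dco_reference(m, config)
        assert prod.surviving == ref.surviving
        assert prod.removed == ref.removed


def test_removal_does_not_change_other_gamete_tables(make_matrix):
    """Filtering only re-windows; pairwise tables are untouched."""
    rng = np.random.default_rng(9)
    alleles = (rng.random((20, 30)) < 0.4).astype(np.int8)
    m = make_matrix(alleles)
    result = fourgt_dco(m)
    kept = m.take_sites(result.surviving)
    for a in range(min(5, kept.n_sites)):
        for b in range(a + 1, min(8, kept.n_sites)):
            assert gamete_table(kept, a, b) == gamete_table(
                m, result.surviving[a], result.surviving[b]
            )
    assert set(result.surviving).isdisjoint(i for i, _, _ in result.removed)
    assert len(result.surviving) + len(result.removed) == m.n_sites


def test_tolerance_zero_removes_at_least_as_much_as_three():
    """First-pass removals at tolerance 0 >= at tolerance 3 on one input."""
    params = ch.paper_like_params(seed=31, n_haplotypes=80)
    rng = np.random.default_rng(31)
    drop = ch.drop_mutations(ch.simulate_genealogy(params, rng), n_sites=300, rng=rng)
    noisy, _ = ch.inject_errors(drop.matrix, 0.003, rng)
    surv = list(range(noisy.n_sites))
    log0, log3 = [], []
    fourgt_dco_pass(noisy, surv, 10, 0, "and", log0)
    fourgt_dco_pass(noisy, surv, 10, 3, "and", log3)
    assert len(log0) >= len(log3) > 0


def test_flank_rule_variants_are_nested(make_matrix):
    m = error_island_matrix(make_matrix)
    assert pair_fails(m, 1, 0, 2, "and")
    assert pair_fails(m, 1, 0, 2, "or")
    assert not pair_fails(m, 1, 0, 2, "xor")
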