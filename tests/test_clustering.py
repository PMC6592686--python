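import numpy as np
import pytest

import cenhap as ch
from cenhap.clustering import (
    DistanceMatrix,
    cut_tree,
    find_recombinants,
    hamming_matrix,
    match_diploid,
    upgma,
    upgma_reference,
)
from oracles import hamming_pairs


def test_hamming_examples(make_matrix):
    m = make_matrix(np.array([[0, 1, 0, 1], [0, 1, 0, 1], [0, 0, 1, 1], [1, 0, 1, 0]]))
    d = hamming_matrix(m)
    assert d.d[0, 1] == 0
    assert d.d[0, 2] == 2  # 0101 vs 0011
    assert d.d[0, 3] == 4  # complementary
    rng = np.random.default_rng(0)
    alleles = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
    np.testing.assert_array_equal(
        hamming_matrix(make_matrix(alleles)).d, hamming_pairs(alleles)
    )


def test_hamming_empty_subset_rejected(make_matrix):
    m = make_matrix(np.zeros((3, 4)))
    with pytest.raises(ValueError):
        hamming_matrix(m, [])


def test_upgma_hand_example():
    """d(A,B)=2, d(A,C)=d(B,C)=8: merge (A,B) at height 1, then C at 4."""
    d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
    tree = upgma(d)
    np.testing.assert_allclose(tree.heights, [1.0, 4.0])
    part = cut_tree(tree, height=2.0)
    groups = {frozenset(part.members(g)) for g in part.labels}
    assert groups == {frozenset({"A", "B"}), frozenset({"C"})}


def test_upgma_ultrametric_and_matches_reference():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = 20
        pts = rng.random((n, 6))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dist = DistanceMatrix([f"h{i}" for i in range(n)], d)
        tree = upgma(dist)
        # ultrametric: merge heights non-decreasing, all leaves at root height
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()
        np.testing.assert_allclose(
            tree.cophenetic(), upgma_reference(dist), atol=1e-9
        )


def test_cut_tree_extremes(make_matrix):
    rng = np.random.default_rng(2)
    m = make_matrix(rng.integers(0, 2, size=(8, 30)))
    tree = upgma(hamming_matrix(m))
    assert len(cut_tree(tree, height=tree.root_height + 1).labels) == 1
    assert len(cut_tree(tree, height=-0.5).labels) == 8
    with pytest.raises(ValueError):
        cut_tree(tree, k=9)
    with pytest.raises(ValueError):
        cut_tree(tree, height=1.0, k=2)


def test_partition_invariant_to_input_order(make_matrix):
    rng = np.random.default_rng(6)
    alleles = rng.integers(0, 2, size=(12, 50))
    ids = [f"h{i}" for i in range(12)]
    m1 = make_matrix(alleles, hap_ids=ids)
    perm = rng.permutation(12)
    m2 = make_matrix(alleles[perm], hap_ids=[ids[i] for i in perm])
    p1 = cut_tree(upgma(hamming_matrix(m1)), k=3)
    p2 = cut_tree(upgma(hamming_matrix(m2)), k=3)
    assert p1.assignment == p2.assignment


def test_deep_split_recovered_exactly():
    """Cutting at the deepest node recovers true lineage membership."""
    params = ch.paper_like_params(seed=41, n_haplotypes=80, introgression_fraction=0.1)
    rng = np.random.default_rng(41)
    gen = ch.simulate_genealogy(params, rng)
    drop = ch.drop_mutations(gen, n_sites=300, rng=rng)
    part = cut_tree(upgma(hamming_matrix(drop.matrix)), k=2)
    intro = set(gen.introgressed)
    assert 0 < len(intro) < 80
    groups = {g: set(part.members(g)) for g in part.labels}
    assert any(mem == intro for mem in groups.values())


def test_nested_recut_refines_named_group(make_matrix):
    rng = np.random.default_rng(8)
    alleles = rng.integers(0, 2, size=(12, 60))
    m = make_matrix(alleles)
    tree = upgma(hamming_matrix(m))
    base = cut_tree(tree, k=2)
    refined = cut_tree(tree, k=2, refine={1: {"k": 2}})
    assert len(refined.labels) == 3
    # the untouched group keeps its membership intact
    other = set(base.members(2))
    assert any(set(refined.members(g)) == other for g in refined.labels)


def splice_fixture():
    params = ch.paper_like_params(seed=51, n_haplotypes=60, introgression_fraction=0.2)
    rng = np.random.default_rng(51)
    gen = ch.simulate_genealogy(params, rng)
    drop = ch.drop_mutations(gen, n_sites=400, rng=rng)
    return gen, drop.matrix


def test_find_recombinants_zero_crossover():
    _, m = splice_fixture()
    left = np.arange(0, 200)
    right = np.arange(200, 400)
    assert find_recombinants(m, left, right, k=2) == []
    with pytest.raises(ValueError):
        find_recombinants(m, np.arange(0, 210), np.arange(200, 400), k=2)


def test_find_recombinants_flags_spliced_haplotypes():
    gen, m = splice_fixture()
    intro = set(gen.introgressed)
    modern = [h for h in m.hap_ids if h not in intro]
    idx = {h: i for i, h in enumerate(m.hap_ids)}
    # splice a minority of each lineage so majority pairings stay intact
    spliced = sorted(intro)[:3] + modern[:9]
    donors = modern[9:12] + sorted(intro)[3:12]
    out = m
    for h, donor in zip(spliced, donors):
        out = ch.splice_flank(out, idx[h], idx[donor], "right", 200)
    flagged = find_recombinants(out, np.arange(0, 200), np.arange(200, 400), k=2)
    assert set(flagged) == set(spliced)
    assert len(flagged) > 10  # the filtering rule engages


def test_match_diploid_self_match_and_classes(make_matrix):
    rng = np.random.default_rng(10)
    alleles = rng.integers(0, 2, size=(10, 50))
    ids = [f"s{i // 2}_{i % 2}" for i in range(10)]
    m = make_matrix(alleles, hap_ids=ids)
    part = cut_tree(upgma(hamming_matrix(m)), k=2)
    positions = [s.pos for s in m.sites]
    dosage = dict(zip(positions, (alleles[2] + alleles[3]).tolist()))
    report = match_diploid(dosage, m, part)
    assert report.best_sample == "s1"
    best = report.per_candidate.set_index("sample").loc["s1"]
    assert best["total_mismatch_alleles"] == 0
    assert report.best_cenhap_genotype == tuple(
        sorted((part.assignment["s1_0"], part.assignment["s1_1"]))
    )
    # class counts partition the compared sites for every candidate
    pc = report.per_candidate
    assert (pc["two_allele"] + pc["one_allele"] + pc["match"] == 50).all()


def test_match_diploid_two_allele_mismatch(make_matrix):
    m = make_matrix(np.array([[1, 1], [1, 1]]), hap_ids=["s0_0", "s0_1"])
    report = match_diploid({100: 0, 200: 2}, m)
    assert report.best_counts == (1, 0, 1)
    with pytest.raises(ValueError):
        match_diploid({}, m)
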