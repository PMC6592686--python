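import numpy as np
import pytest
from scipy import stats

import cenhap as ch
from cenhap.fourgt import four_gamete
from cenhap.simulate import (
    SimParams,
    simulate_split_genealogy,
)
from oracles import four_gamete_explicit


def run_sim(seed, **kw):
    params = ch.paper_like_params(seed=seed, **kw)
    rng = np.random.default_rng(seed)
    gen = ch.simulate_genealogy(params, rng)
    drop = ch.drop_mutations(gen, n_sites=kw.pop("n_sites", 150), rng=rng)
    return params, gen, drop


def test_identical_seeds_bit_identical():
    _, g1, d1 = run_sim(77, n_haplotypes=40)
    _, g2, d2 = run_sim(77, n_haplotypes=40)
    assert g1.newick() == g2.newick()
    assert d1.matrix == d2.matrix
    assert g1.introgressed == g2.introgressed


def test_params_validation():
    with pytest.raises(ValueError):
        SimParams(introgression_fraction=1.5)
    with pytest.raises(ValueError):
        SimParams(genotyping_error_rate=-0.1)
    with pytest.raises(ValueError):
        ch.simulate_genealogy(SimParams(n_haplotypes=1))


def test_no_four_gamete_pairs_in_clean_central_block(clean_sim):
    """Infinite sites + no recombination: the four-gamete test never fires."""
    _, drop = clean_sim
    m = drop.matrix
    rng = np.random.default_rng(0)
    for _ in range(400):
        i, j = rng.choice(m.n_sites, size=2, replace=False)
        assert not four_gamete(m, int(i), int(j))


def test_introgressed_tip_count_is_binomial_like():
    counts = []
    for seed in range(25):
        params = ch.paper_like_params(seed=seed, n_haplotypes=200)
        gen = ch.simulate_genealogy(params)
        counts.append(len(gen.introgressed))
    mean = np.mean(counts)
    # Binomial(200, 0.05): mean 10, sd ~3.1; the 25-replicate mean is tight
    assert abs(mean - 10) < 2.5
    assert ch.simulate_genealogy(
        ch.paper_like_params(seed=1, introgression_fraction=0.0)
    ).introgressed == []


def test_pairwise_tmrca_matches_coalescent_expectation():
    """E[pairwise TMRCA] = 2N generations for a neutral sample of two."""
    ne = 400.0
    times = []
    rng = np.random.default_rng(123)
    for _ in range(300):
        params = SimParams(
            n_haplotypes=2, diploid_ne=ne, introgression_fraction=0.0,
            archaic_split_time=5e6, calibration_age=50e6,
        )
        gen = ch.simulate_genealogy(params, rng)
        times.append(gen.mrca(["hap_0", "hap_1"]).time)
    expected = 2 * ne
    assert np.mean(times) == pytest.approx(expected, rel=0.15)


def test_site_count_proportional_to_branch_length():
    """Poisson site counts scale linearly with the mutation rate."""
    params = ch.paper_like_params(seed=9, n_haplotypes=30)
    rng = np.random.default_rng(9)
    gen = ch.simulate_genealogy(params, rng)
    n1 = ch.drop_mutations(gen, mutation_rate=2e-6, rng=np.random.default_rng(1))
    n2 = ch.drop_mutations(gen, mutation_rate=4e-6, rng=np.random.default_rng(1))
    assert n2.matrix.n_sites == pytest.approx(2 * n1.matrix.n_sites, rel=0.25)


def test_inject_errors_edge_rates(clean_sim):
    _, drop = clean_sim
    m = drop.matrix
    same, flips = ch.inject_errors(m, 0.0, np.random.default_rng(0))
    assert np.array_equal(same.alleles, m.alleles) and len(flips) == 0
    comp, flips = ch.inject_errors(m, 1.0, np.random.default_rng(0))
    assert np.array_equal(comp.alleles, 1 - m.alleles)
    assert len(flips) == m.alleles.size


def test_inject_errors_binomial_count(clean_sim):
    _, drop = clean_sim
    m = drop.matrix
    rate = 0.01
    _, flips = ch.inject_errors(m, rate, np.random.default_rng(5))
    n = m.alleles.size
    lo, hi = stats.binom.ppf([0.001, 0.999], n, rate)
    assert lo <= len(flips) <= hi


def test_inject_conversions_tracts(clean_sim):
    _, drop = clean_sim
    m = drop.matrix
    same, tracts = ch.inject_conversions(m, 0.0, 3, np.random.default_rng(0))
    assert np.array_equal(same.alleles, m.alleles) and tracts == []
    conv, tracts = ch.inject_conversions(m, 0.02, 3, np.random.default_rng(2))
    assert tracts
    expected = m.alleles.copy()
    for h, s, e, donor in tracts:
        assert 0 <= s < e <= m.n_sites and e - s <= 3 and donor != h
        expected[h, s:e] = m.alleles[donor, s:e]
    np.testing.assert_array_equal(conv.alleles, expected)


def test_flank_recombination_confined_to_flanks(clean_sim):
    _, drop = clean_sim
    m = drop.matrix
    central = (80, 120)
    same, events = ch.add_flank_recombination(m, central, 0.0, np.random.default_rng(0))
    assert np.array_equal(same.alleles, m.alleles) and events == []
    out, events = ch.add_flank_recombination(m, central, 0.5, np.random.default_rng(3))
    assert events
    changed = np.flatnonzero((out.alleles != m.alleles).any(axis=0))
    assert all(j < central[0] or j > central[1] for j in changed)


def test_simulate_codons_zero_rate_and_omega(clean_sim):
    gen, _ = clean_sim
    alns = ch.simulate_codons(gen, 1, 50, 0.0, rng=np.random.default_rng(0))
    seqs = list(alns[0].sequences.values())
    assert all(s == seqs[0] for s in seqs)
    alns = ch.simulate_codons(
        gen, 1, 120, 3e-7, omega=0.0, rng=np.random.default_rng(1)
    )
    a = alns[0]
    est = ch.ng86_pair(a.sequences["hap_0"], a.sequences["outgroup"])
    assert est.nonsyn_diffs == 0 and est.syn_diffs > 0


def test_outgroup_divergence_scales_with_depth():
    ds = []
    for cal in (3e6, 6e6):
        rng = np.random.default_rng(9)
        gen = simulate_split_genealogy([5e5], 2, ne=300, calibration_age=cal, rng=rng)
        alns = ch.simulate_codons(gen, 3, 300, 3e-7, rng=np.random.default_rng(4))
        vals = [
            ch.ng86_pair(a.sequences["g0_hap0"], a.sequences["outgroup"]).dS
            for a in alns
        ]
        ds.append(np.mean(vals))
    assert ds[1] / ds[0] == pytest.approx(2.0, rel=0.3)


def test_archaic_annotation_consistency(clean_sim):
    gen, drop = clean_sim
    annot = ch.emit_archaic_annotation(drop)
    assert list(annot["pos"]) == [s.pos for s in drop.matrix.sites]
    # sites mutated on branches above NEA are archaic-derived
    derived = annot["nea_allele"] != annot["outgroup_allele"]
    np.testing.assert_array_equal(derived.to_numpy(), drop.nea_derived)


def test_array_counts_expectations():
    rng = np.random.default_rng(11)
    genos = {f"s{i}": {"chrA": ("x", "x")} for i in range(300)}
    counts, truth = ch.simulate_array_counts(
        genos, {("chrA", "x"): 50.0}, coverage=4.0, rng=rng
    )
    assert (truth["true_size"] == 100.0).all()
    assert counts["cen_count"].mean() == pytest.approx(4.0 * 100.0, rel=0.05)
    zero, _ = ch.simulate_array_counts(
        {"s": {"chrA": ("x",)}}, {("chrA", "x"): 50.0}, coverage=0.0,
        rng=np.random.default_rng(0),
    )
    assert (zero["cen_count"] == 0).all()


def test_four_gamete_vec_agrees_with_enumeration(clean_sim):
    _, drop = clean_sim
    m = drop.matrix
    rng = np.random.default_rng(1)
    noisy, _ = ch.inject_errors(m, 0.05, rng)
    for _ in range(100):
        i, j = rng.choice(m.n_sites, size=2, replace=False)
        assert four_gamete(noisy, int(i), int(j)) == four_gamete_explicit(
            noisy.alleles[:, i], noisy.alleles[:, j]
        )
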