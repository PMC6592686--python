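import itertools

import numpy as np
import pandas as pd
import pytest

from cenhap.clustering import CenhapPartition
from cenhap.divergence import (
    CodonAlignment,
    bootstrap_ci,
    count_replacements,
    group_diversity,
    ng86_pair,
    ng86_sites,
    read_codon_fasta,
    tmrca_by_ratio,
    tmrca_tree,
    write_codon_fasta,
)
from oracles import SENSE_CODONS, ng_diffs_enumeration, ng_sites_enumeration


def test_ng86_sites_known_codons():
    s, n = ng86_sites("TTT")
    assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)
    s, n = ng86_sites("TGG")  # Trp: no synonymous single change
    assert s == 0.0 and n == 3.0
    with pytest.raises(ValueError):
        ng86_sites("TAA")


def test_ng86_sites_match_enumeration_for_all_codons():
    for codon in SENSE_CODONS:
        s, n = ng86_sites(codon)
        se, ne = ng_sites_enumeration(codon)
        assert s == pytest.approx(se, abs=1e-12)
        assert s + n == pytest.approx(3.0)


def test_ng86_pair_basics():
    est = ng86_pair("TTTACG", "TTTACG")
    assert est.syn_diffs == est.nonsyn_diffs == 0 and est.dS == est.dN == 0
    est = ng86_pair("TTT", "TTA")  # Phe -> Leu, nonsynonymous
    assert est.nonsyn_diffs == 1 and est.syn_diffs == 0
    a, b = "TTTACGGGA", "TTAACGGGC"
    ea, eb = ng86_pair(a, b), ng86_pair(b, a)
    assert ea.syn_diffs == eb.syn_diffs and ea.nonsyn_diffs == eb.nonsyn_diffs
    with pytest.raises(ValueError):
        ng86_pair("TTT", "TTTAAA")


def test_ng86_pair_matches_pathway_oracle_on_all_two_diff_pairs():
    """Complete enumeration over one- and two-difference codon pairs."""
    for a, b in itertools.product(SENSE_CODONS, SENSE_CODONS):
        ndiff = sum(x != y for x, y in zip(a, b))
        if ndiff == 0 or ndiff > 2:
            continue
        est = ng86_pair(a, b)
        sd, nd = ng_diffs_enumeration(a, b)
        assert est.syn_diffs == pytest.approx(sd, abs=1e-12), (a, b)
        assert est.nonsyn_diffs == pytest.approx(nd, abs=1e-12), (a, b)
        assert est.syn_diffs + est.nonsyn_diffs == pytest.approx(ndiff)


def test_jukes_cantor_correction_behaviour():
    est = ng86_pair("TTT" * 30, "TTC" * 30)  # all synonymous third positions
    assert est.pS > 0 and est.dS > est.pS
    assert est.dN == 0


def test_group_diversity_definition():
    aln = CodonAlignment(
        "g",
        {
            "a": "TTTACG",
            "b": "TTCACG",
            "c": "TTTACT",
            "outgroup": "TTTACG",
        },
    )
    pis, pin = group_diversity(aln, ["a", "b", "c"])
    pairs = [("a", "b"), ("a", "c"), ("b", "c")]
    exp = np.mean([ng86_pair(aln.sequences[x], aln.sequences[y]).pS for x, y in pairs])
    assert pis == pytest.approx(exp)
    assert group_diversity(aln, ["a", "a"])[0] == 0.0
    with pytest.raises(ValueError):
        group_diversity(aln, ["a"])


def test_codon_alignment_validation():
    with pytest.raises(ValueError, match="stop"):
        CodonAlignment("g", {"a": "TAATTT", "outgroup": "TTTTTT"})
    with pytest.raises(ValueError, match="unequal"):
        CodonAlignment("g", {"a": "TTT", "outgroup": "TTTTTT"})
    with pytest.raises(ValueError, match="outgroup"):
        CodonAlignment("g", {"a": "TTT", "b": "TTT"})


def test_codon_fasta_round_trip(tmp_path):
    aln = CodonAlignment("g0", {"a": "TTTACG", "pan_outgroup": "TTCACG"},
                         outgroup_id="pan_outgroup")
    path = tmp_path / "g0.fa"
    write_codon_fasta(aln, path)
    again = read_codon_fasta(path, gene_id="g0")
    assert again.sequences == aln.sequences
    assert again.outgroup_id == "pan_outgroup"


def test_bootstrap_ci_properties():
    assert bootstrap_ci([0.5] * 6, B=500, seed=0) == (0.5, 0.5)
    rng = np.random.default_rng(1)
    values = rng.normal(1.0, 0.2, size=40)
    lo, hi = bootstrap_ci(values, B=4000, seed=2)
    assert lo < values.mean() < hi
    # symmetric data: BC interval close to the plain percentile interval
    boots = values[rng.integers(0, 40, size=(10000, 40))].mean(axis=1)
    plo, phi = np.quantile(boots, [0.025, 0.975])
    assert lo == pytest.approx(plo, abs=0.02)
    assert hi == pytest.approx(phi, abs=0.02)
    with pytest.raises(ValueError):
        bootstrap_ci([1.0], B=500)


def _ds_frame(vals, labels):
    return pd.DataFrame(vals, index=labels, columns=labels, dtype=float)


def test_tmrca_tree_linearity_and_identical_groups():
    labels = ["1", "2", "outgroup"]
    gene = _ds_frame(
        [[0.0, 0.0, 0.10], [0.0, 0.0, 0.10], [0.10, 0.10, 0.0]], labels
    )
    per_gene = {"gA": gene, "gB": gene * 1.2}
    tt = tmrca_tree(per_gene, calibration_age=6.5e6)
    inner = tt.nodes[tt.nodes["members"] == frozenset({"1", "2"})]
    assert inner["tmrca"].iloc[0] == pytest.approx(0.0)
    tt2 = tmrca_tree(per_gene, calibration_age=13e6)
    assert np.allclose(tt2.nodes["tmrca"], 2 * tt.nodes["tmrca"])


def test_tmrca_tree_excludes_zero_divergence_gene():
    labels = ["1", "2", "outgroup"]
    good = _ds_frame([[0, 0.02, 0.1], [0.02, 0, 0.1], [0.1, 0.1, 0]], labels)
    bad = good * 0.0
    with pytest.warns(UserWarning, match="zero outgroup"):
        tt = tmrca_tree({"g": good, "z": bad})
    assert len(tt.nodes) == 2
    node = tt.nodes[tt.nodes["members"] == frozenset({"1", "2"})]
    # height 0.01 against outgroup height 0.05 -> 6.5 MY * 0.2
    assert node["tmrca"].iloc[0] == pytest.approx(1.3e6)


@pytest.mark.parametrize(
    "ratio,anchor,expected",
    [(2.0, 575e3, 1.15e6), (1.0, 4.2e5, 4.2e5), (0.5, 6.5e6, 3.25e6)],
)
def test_tmrca_by_ratio(ratio, anchor, expected):
    assert tmrca_by_ratio(ratio, anchor) == pytest.approx(expected)
    with pytest.raises(ValueError):
        tmrca_by_ratio(0.0, 575e3)


def test_count_replacements_engineered_substitutions():
    base = "TTTACGGGA"
    seqs = {f"a{i}": base for i in range(3)}
    # group b carries one fixed nonsynonymous and one synonymous change
    seqs.update({f"b{i}": "CTTACGGGG" for i in range(3)})  # TTT->CTT (F->L), GGA->GGG (syn)
    seqs["outgroup"] = base
    aln = CodonAlignment("g0", seqs)
    part = CenhapPartition({**{f"a{i}": 1 for i in range(3)}, **{f"b{i}": 2 for i in range(3)}})
    table = count_replacements([aln], part, [1, 2])
    by_group = table.set_index("group")["replacements"]
    assert by_group[2] == 1  # only the amino-acid change counts
    assert by_group[1] == 1  # symmetric comparison: group 1 differs from b-consensus
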