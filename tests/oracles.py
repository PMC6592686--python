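"""Independent brute-force oracles used only by the test suite.

Deliberately written as direct restatements of the definitions, without
sharing code with the package implementation.
"""

import itertools

import numpy as np

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def chi2_closed_form(n00, n01, n10, n11):
    H = n00 + n01 + n10 + n11
    r1, r2 = n00 + n01, n10 + n11
    c1, c2 = n00 + n10, n01 + n11
    return H * (n00 * n11 - n01 * n10) ** 2 / (r1 * r2 * c1 * c2)


def ng_sites_enumeration(codon):
    """Fraction of synonymous one-step mutants, summed over positions."""
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                s += 1.0 / 3.0
    return s, 3.0 - s


def ng_diffs_enumeration(a, b):
    """Average syn/nonsyn steps over orderings, skipping stop pathways."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
            if GENETIC_CODE[nxt] == "*" or GENETIC_CODE[cur] != GENETIC_CODE[nxt]:
                non += 1
            else:
                syn += 1
            cur = nxt
        paths.append((ok, syn, non))
    kept = [(s, n) for ok, s, n in paths if ok] or [(s, n) for _, s, n in paths]
    return (
        sum(s for s, _ in kept) / len(kept),
        sum(n for _, n in kept) / len(kept),
    )


def four_gamete_explicit(col_a, col_b):
    gametes = {(int(x), int(y)) for x, y in zip(col_a, col_b)}
    return gametes == {(0, 0), (0, 1), (1, 0), (1, 1)}


def hamming_pairs(alleles):
    H = alleles.shape[0]
    d = np.zeros((H, H))
    for i in range(H):
        for j in range(i + 1, H):
            d[i, j] = d[j, i] = int((alleles[i] != alleles[j]).sum())
    return d
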