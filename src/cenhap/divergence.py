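"""Coding divergence, diversity and calibrated TMRCAs.

Synonymous/nonsynonymous site and difference counts follow the
pathway-counting estimator of Nei & Gojobori (method I): per codon
position the synonymous fraction is the share of the three possible
single-base changes that preserve the amino acid (changes to stop codons
count as nonsynonymous); codons differing at k positions are resolved by
averaging syn/nonsyn steps over the k! orderings of single steps,
excluding pathways through stop codons.  Proportions pS = Sd/S and
pN = Nd/N are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p), to give
dS and dN; diversity (pi_s, pi_n) is the average pairwise uncorrected
proportion, i.e. expected heterozygosity.

TMRCAs of cenhap groups are read off UPGMA node heights on mean
synonymous divergence, scaled so the human/outgroup node sits at the
calibration age (default 6.5 MY); the cross-gene spread gives +-2 SD
error bands.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .clustering import CenhapPartition, DistanceMatrix, UltrametricTree, upgma

__all__ = [
    "CodonAlignment",
    "NGEstimate",
    "TmrcaTree",
    "ng86_sites",
    "ng86_pair",
    "group_diversity",
    "group_divergence",
    "bootstrap_ci",
    "tmrca_tree",
    "tmrca_by_ratio",
    "count_replacements",
    "read_codon_fasta",
    "write_codon_fasta",
]

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """In-frame CDS alignment: haplotype sequences plus one outgroup.

    All sequences equal length, divisible by 3, alphabet ACGT, no
    in-frame stop codons (violations are rejected with the gene id — the
    validator never edits).
    """

    gene_id: str
    sequences: dict[str, str]
    outgroup_id: str = "outgroup"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")
        for name, seq in self.sequences.items():
            if set(seq) - set(_BASES):
                raise ValueError(f"{self.gene_id}/{name}: non-ACGT characters")
            for i in range(0, length, 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError(
                        f"{self.gene_id}/{name}: in-frame stop at codon {i // 3}"
                    )
        if self.outgroup_id not in self.sequences:
            raise ValueError(f"{self.gene_id}: missing outgroup {self.outgroup_id!r}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def ingroup_ids(self) -> list[str]:
        return [k for k in self.sequences if k != self.outgroup_id]


@dataclass
class NGEstimate:
    """NG86 site/difference counts and (corrected) divergences."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False

    @property
    def pS(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else 0.0

    @property
    def pN(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites else 0.0

    @property
    def dS(self) -> float:
        return _jc(self.pS)

    @property
    def dN(self) -> float:
        return _jc(self.pN)


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) for one codon, s+n=3."""
    codon = codon.upper()
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    if codon not in _CODE:
        raise ValueError(f"invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            # stop-codon changes count as nonsynonymous
            if mutant not in _STOPS and _CODE[mutant] == _CODE[codon]:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_diffs(a: str, b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) step counts over single-step pathways a -> b.

    Pathways through stop codons are excluded; if every pathway is
    blocked, all pathways are used (rare, only possible for multi-step
    pairs hemmed in by stops).
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    tallies = []
    for order in itertools.permutations(positions):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if nxt in _STOPS or _CODE.get(cur) != _CODE.get(nxt):
                nonsyn += 1
            else:
                syn += 1
            cur = nxt
        tallies.append((blocked, syn, nonsyn))
    open_paths = [(s, n) for blocked, s, n in tallies if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in tallies]
    syn = sum(s for s, _ in open_paths) / len(open_paths)
    nonsyn = sum(n for _, n in open_paths) / len(open_paths)
    return syn, nonsyn


def ng86_pair(seq_a: str, seq_b: str) -> NGEstimate:
    """NG86 method-I estimate between two in-frame sequences.

    Site counts are averaged over the two sequences; multi-difference
    codons are resolved by pathway averaging.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequence length mismatch")
    if len(seq_a) % 3:
        raise ValueError("length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _codon_diffs(ca, cb)
        Sd += ds
        Nd += dn
    est = NGEstimate(S, N, Sd, Nd)
    if est.pS >= 0.75 or est.pN >= 0.75:
        est.saturated = True
    return est


def group_diversity(alignment: CodonAlignment, members: list[str]) -> tuple[float, float]:
    """Average pairwise (pi_s, pi_n): uncorrected expected heterozygosity."""
    if len(members) < 2:
        raise ValueError("need at least 2 members for diversity")
    ps, pn = [], []
    for a, b in itertools.combinations(members, 2):
        est = ng86_pair(alignment.sequences[a], alignment.sequences[b])
        ps.append(est.pS)
        pn.append(est.pN)
    return float(np.mean(ps)), float(np.mean(pn))


def group_divergence(
    alignment: CodonAlignment, group_a: list[str], group_b: list[str],
    corrected: bool = True,
) -> tuple[float, float]:
    """Mean pairwise (dS, dN) between two haplotype groups."""
    ds, dn = [], []
    for a in group_a:
        for b in group_b:
            est = ng86_pair(alignment.sequences[a], alignment.sequences[b])
            ds.append(est.dS if corrected else est.pS)
            dn.append(est.dN if corrected else est.pN)
    return float(np.mean(ds)), float(np.mean(dn))


def bootstrap_ci(
    per_gene_values,
    B: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected (BC) bootstrap CI for the cross-gene mean.

    Resamples genes with replacement; the bias-correction factor z0 is
    the normal quantile of the fraction of bootstrap means below the
    observed mean.  Degenerate (all-equal) inputs give a point interval.
    """
    from scipy.stats import norm

    values = np.asarray(list(per_gene_values), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 genes")
    if B < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    if np.ptp(values) == 0:
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    obs = values.mean()
    idx = rng.integers(0, len(values), size=(B, len(values)))
    boots = values[idx].mean(axis=1)
    frac = np.clip((boots < obs).mean(), 1.0 / B, 1.0 - 1.0 / B)
    z0 = norm.ppf(frac)
    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    lo_q = norm.cdf(2 * z0 + z_lo)
    hi_q = norm.cdf(2 * z0 + z_hi)
    return float(np.quantile(boots, lo_q)), float(np.quantile(boots, hi_q))


@dataclass
class TmrcaTree:
    """Calibrated UPGMA tree over cenhap groups.

    ``nodes`` rows: node_id, members (frozenset of group labels), the
    combined TMRCA in years, its across-gene SD, and the +-2 SD band.
    """

    tree: UltrametricTree
    nodes: pd.DataFrame
    calibration_age: float

    def newick(self) -> str:
        return self.tree.newick()


def _node_clades(tree: UltrametricTree) -> list[tuple[int, frozenset, frozenset]]:
    """For each internal merge: (merge index, clade A labels, clade B labels)."""
    n = len(tree.hap_ids)
    members: dict[int, frozenset] = {i: frozenset([tree.hap_ids[i]]) for i in range(n)}
    out = []
    for m, (a, b, _, _) in enumerate(tree.linkage):
        ca, cb = members[int(a)], members[int(b)]
        members[n + m] = ca | cb
        out.append((m, ca, cb))
    return out


def tmrca_tree(
    per_gene_ds: dict[str, pd.DataFrame],
    calibration_age: float = 6.5e6,
    outgroup_label: str = "outgroup",
) -> TmrcaTree:
    """Calibrated TMRCAs of cenhap groups from per-gene dS matrices.

    ``per_gene_ds`` maps gene id -> symmetric DataFrame of group-mean dS
    including the outgroup row/column.  The combined tree is the UPGMA
    of the cross-gene mean matrix; per gene, each node's TMRCA is
    ``calibration_age x node_height_g / outgroup_height_g`` where the
    heights are mean between-clade dS / 2 evaluated on that gene, and
    the outgroup height is the gene's mean group-to-outgroup dS / 2.
    Genes with zero group/outgroup divergence are excluded with a
    warning.  Reported ages are across-gene means with +-2 SD bands.
    """
    import warnings

    genes = list(per_gene_ds)
    labels = [l for l in per_gene_ds[genes[0]].index if l != outgroup_label]
    order = labels + [outgroup_label]

    usable = []
    for g in genes:
        mat = per_gene_ds[g].loc[order, order]
        out_div = mat.loc[labels, outgroup_label].mean()
        if out_div <= 0:
            warnings.warn(f"gene {g}: zero outgroup divergence, excluded")
            continue
        usable.append(g)
    if not usable:
        raise ValueError("no gene with positive outgroup divergence")

    mean_mat = sum(per_gene_ds[g].loc[order, order] for g in usable) / len(usable)
    dist = DistanceMatrix(order, mean_mat.to_numpy())
    tree = upgma(dist)

    rows = []
    for m, ca, cb in _node_clades(tree):
        ages = []
        for g in usable:
            mat = per_gene_ds[g].loc[order, order]
            between = mat.loc[sorted(ca), sorted(cb)].to_numpy().mean()
            out_h = mat.loc[labels, outgroup_label].mean() / 2.0
            ages.append(calibration_age * (between / 2.0) / out_h)
        ages = np.asarray(ages)
        mean_age = float(ages.mean())
        sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
        rows.append(
            {
                "node": m,
                "members": ca | cb,
                "tmrca": mean_age,
                "sd": sd,
                "lo": mean_age - 2 * sd,
                "hi": mean_age + 2 * sd,
            }
        )
    return TmrcaTree(tree, pd.DataFrame(rows), calibration_age)


def tmrca_by_ratio(divergence_ratio: float, anchor_tmrca: float) -> float:
    """Scale an anchor TMRCA by a divergence ratio (linear clock).

    E.g. a cenhap twice as diverged as one anchored at 575 KY dates to
    1.15 MY.
    """
    if divergence_ratio <= 0 or anchor_tmrca <= 0:
        raise ValueError("ratio and anchor must be positive")
    return divergence_ratio * anchor_tmrca


def count_replacements(
    alignments: list[CodonAlignment],
    partition: CenhapPartition,
    lineage_groups: list[int],
    freq_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-gene amino-acid replacements fixed on specified cenhap lineages.

    For each gene and group, a codon column counts as a replacement when
    a codon at frequency >= ``freq_threshold`` within the group encodes a
    different amino acid than the consensus codon of all other groups'
    members.
    """
    rows = []
    for aln in alignments:
        in_aln = set(aln.ingroup_ids())
        for group in lineage_groups:
            members = [h for h in partition.members(group) if h in in_aln]
            others = [
                h
                for h, g in partition.assignment.items()
                if g != group and h in in_aln
            ]
            count = 0
            if members and others:
                for ci in range(aln.n_codons):
                    in_codons = pd.Series(
                        [aln.sequences[h][3 * ci : 3 * ci + 3] for h in members]
                    )
                    top = in_codons.value_counts()
                    if top.iloc[0] / len(members) < freq_threshold:
                        continue
                    grp_codon = top.index[0]
                    out_codons = pd.Series(
                        [aln.sequences[h][3 * ci : 3 * ci + 3] for h in others]
                    )
                    other_codon = out_codons.value_counts().index[0]
                    if _CODE[grp_codon] != _CODE[other_codon]:
                        count += 1
            rows.append({"gene": aln.gene_id, "group": group, "replacements": count})
    return pd.DataFrame(rows)


def read_codon_fasta(path, gene_id: str | None = None,
                     outgroup_suffix: str = "outgroup") -> CodonAlignment:
    """Load a per-gene multi-FASTA; the outgroup record is identified by
    its id equalling or ending with ``outgroup_suffix``."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty alignment")
    sequences = {r.id: str(r.seq).upper() for r in records}
    outgroup = next(
        (r.id for r in records if r.id == outgroup_suffix or r.id.endswith(outgroup_suffix)),
        None,
    )
    if outgroup is None:
        raise ValueError(f"{path}: no outgroup record (*{outgroup_suffix})")
    return CodonAlignment(
        gene_id=gene_id or str(path), sequences=sequences, outgroup_id=outgroup
    )


def write_codon_fasta(alignment: CodonAlignment, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in alignment.sequences.items()
    ]
    seqio_write(records, str(path), "fasta")
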