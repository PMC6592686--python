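"""Cenhap definition: hamming + UPGMA + tree cuts.

Haplotypes are clustered over a central SNP subset flanking the assembly
gap using average-linkage (UPGMA) agglomeration on raw hamming mismatch
counts; cutting the ultrametric dendrogram at one or more heights yields
the cenhap groups.  Node heights are half the average inter-cluster
mismatch count at the merge, so heights are in units of
mismatches-per-pair / 2 — the convention the TMRCA scaling consumes.

Also here: detection of apparent recombinants between cenhaps (left/right
flank cluster-membership disagreement — an operationalization, flagged
as such in output metadata) and matching of an unphased diploid genotype
vector to its closest phased individual (the HuRef procedure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genotype_io import HaplotypeMatrix

__all__ = [
    "DistanceMatrix",
    "UltrametricTree",
    "CenhapPartition",
    "DiploidMatchReport",
    "hamming_matrix",
    "upgma",
    "upgma_reference",
    "cophenetic_from_merges",
    "cut_tree",
    "find_recombinants",
    "match_diploid",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise mismatch counts between haplotypes."""

    hap_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.hap_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have zero diagonal")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.hap_ids), k=1)
        return self.d[iu]


@dataclass
class UltrametricTree:
    """UPGMA result: a scipy linkage matrix plus the distance matrix.

    ``linkage`` rows are (child_a, child_b, merge_distance, count) in
    scipy convention; node *heights* are merge_distance / 2.
    """

    hap_ids: list[str]
    linkage: np.ndarray
    distances: DistanceMatrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2] / 2.0)

    def leaf_order(self) -> list[str]:
        return [self.hap_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(hierarchy.cophenet(self.linkage))

    def newick(self) -> str:
        n = len(self.hap_ids)

        def fmt(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.hap_ids[node]}:{parent_h:.6g}"
            a, b, dist, _ = self.linkage[node - n]
            h = dist / 2.0
            return (
                f"({fmt(int(a), h)},{fmt(int(b), h)}):{parent_h - h:.6g}"
            )

        root = 2 * n - 2
        a, b, dist, _ = self.linkage[-1]
        h = dist / 2.0
        return f"({fmt(int(a), h)},{fmt(int(b), h)});" if root >= n else f"({self.hap_ids[0]});"


@dataclass
class CenhapPartition:
    """Haplotype -> cenhap group assignment from one or more cuts.

    Group labels are integers 1..G assigned in decreasing group-size
    order (ties broken by the lexicographically smallest member id), so
    the labeling is invariant to haplotype input order.
    """

    assignment: dict[str, int]
    cut_spec: dict = field(default_factory=dict)

    @property
    def group_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for g in self.assignment.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, group: int) -> list[str]:
        return [h for h, g in self.assignment.items() if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hap_id": list(self.assignment), "group": list(self.assignment.values())}
        )


def hamming_matrix(matrix: HaplotypeMatrix, site_subset=None) -> DistanceMatrix:
    """Raw pairwise allele-mismatch counts over the clustering subset."""
    subset = (
        np.arange(matrix.n_sites) if site_subset is None else np.asarray(site_subset)
    )
    if len(subset) == 0:
        raise ValueError("empty clustering site subset")
    X = matrix.alleles[:, subset].astype(np.int64)
    ones = X @ X.T
    tot = X.sum(axis=1)
    # mismatches = sites where exactly one of the pair carries the alt allele
    d = tot[:, None] + tot[None, :] - 2 * ones
    np.fill_diagonal(d, 0)
    return DistanceMatrix(list(matrix.hap_ids), d.astype(float))


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of the distance matrix."""
    if len(dist.hap_ids) < 2:
        raise ValueError("need at least 2 haplotypes to cluster")
    Z = hierarchy.linkage(dist.condensed(), method="average")
    return UltrametricTree(list(dist.hap_ids), Z, dist)


def upgma_reference(dist: DistanceMatrix) -> np.ndarray:
    """Naive O(n^3) UPGMA; returns the cophenetic distance matrix.

    Ties are broken by the lexicographically smallest cluster-index pair.
    Kept as an independent cross-check of the production path.
    """
    n = len(dist.hap_ids)
    d = {(i, j): dist.d[i, j] for i in range(n) for j in range(i + 1, n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(members) > 1:
        ids = sorted(members)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                key = (min(a, b), max(a, b))
                cand = (d[key], a, b)
                if best is None or cand < best:
                    best = cand
        dmin, a, b = best
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = dmin
        sa, sb = len(members[a]), len(members[b])
        merged = members[a] + members[b]
        for c in ids:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            d[(min(next_id, c), max(next_id, c))] = (
                sa * d[ka] + sb * d[kb]
            ) / (sa + sb)
        members.pop(a)
        members.pop(b)
        members[next_id] = merged
        next_id += 1
    return coph


def cophenetic_from_merges(tree: UltrametricTree) -> np.ndarray:
    return tree.cophenetic()


def _canonical_partition(hap_ids: list[str], raw_labels: np.ndarray,
                         cut_spec: dict) -> CenhapPartition:
    groups: dict[int, list[str]] = {}
    for h, lab in zip(hap_ids, raw_labels):
        groups.setdefault(int(lab), []).append(h)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
    assignment = {h: gi + 1 for gi, mem in enumerate(ordered) for h in mem}
    # preserve input haplotype order in the mapping
    assignment = {h: assignment[h] for h in hap_ids}
    return CenhapPartition(assignment=assignment, cut_spec=cut_spec)


def cut_tree(
    tree: UltrametricTree,
    height: float | None = None,
    k: int | None = None,
    refine: dict[int, dict] | None = None,
) -> CenhapPartition:
    """Cut the dendrogram into cenhap groups.

    Exactly one of ``height`` (in node-height units, i.e. mismatches/2)
    or ``k`` (number of groups) must be given.  ``refine`` maps a group
    label from the primary cut to a nested cut spec
    (``{"height": h}`` or ``{"k": k}``) applied to that group's members
    only; refined subgroups get labels ``parent.sub`` encoded as new
    integer labels appended after the primary ones.
    """
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    n = len(tree.hap_ids)
    if k is not None:
        if k > n:
            raise ValueError("k exceeds the number of haplotypes")
        raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
        spec = {"k": k}
    else:
        raw = hierarchy.fcluster(tree.linkage, t=2 * height, criterion="distance")
        spec = {"height": height}
    part = _canonical_partition(tree.hap_ids, raw, spec)

    if refine:
        spec = dict(part.cut_spec, refine=refine)
        assignment = dict(part.assignment)
        next_label = max(assignment.values())
        idx = {h: i for i, h in enumerate(tree.hap_ids)}
        for group, sub_spec in refine.items():
            mem = part.members(group)
            if len(mem) < 2:
                continue
            sel = [idx[h] for h in mem]
            sub_d = DistanceMatrix(mem, tree.distances.d[np.ix_(sel, sel)])
            sub_part = cut_tree(upgma(sub_d), **sub_spec)
            for h, sub_lab in sub_part.assignment.items():
                assignment[h] = next_label + sub_lab
            next_label = max(assignment.values())
        part = _canonical_partition(
            tree.hap_ids, np.array([assignment[h] for h in tree.hap_ids]), spec
        )
    return part


def find_recombinants(
    matrix: HaplotypeMatrix,
    left_sites,
    right_sites,
    k: int = 2,
) -> list[str]:
    """Apparent inter-cenhap recombinants by flank-cluster disagreement.

    The left and right flanks are clustered separately into ``k`` groups;
    each left group is paired with the right group the majority of its
    members fall in, and a haplotype whose own right group disagrees with
    its left group's majority pairing is flagged.  Downstream divergence
    and TMRCA analyses drop the flagged haplotypes when more than 10 are
    observed.
    """
    left_sites = np.asarray(left_sites)
    right_sites = np.asarray(right_sites)
    if np.intersect1d(left_sites, right_sites).size:
        raise ValueError("flank site subsets must be disjoint")
    lp = cut_tree(upgma(hamming_matrix(matrix, left_sites)), k=k)
    rp = cut_tree(upgma(hamming_matrix(matrix, right_sites)), k=k)
    pairs = pd.DataFrame(
        {
            "hap": matrix.hap_ids,
            "left": [lp.assignment[h] for h in matrix.hap_ids],
            "right": [rp.assignment[h] for h in matrix.hap_ids],
        }
    )
    majority = (
        pairs.groupby("left")["right"].agg(lambda s: s.value_counts().idxmax())
    )
    expected = pairs["left"].map(majority)
    return pairs.loc[pairs["right"] != expected, "hap"].tolist()


@dataclass
class DiploidMatchReport:
    """Mismatch profile of an unphased diploid against phased individuals.

    For each candidate individual, every compared site is classified as a
    two-allele mismatch (0/0 vs 1/1), a one-allele mismatch (hom vs het)
    or a match; the three counts sum to the number of compared sites.
    """

    per_candidate: pd.DataFrame  # sample, two_allele, one_allele, match, total_mismatch_alleles
    best_sample: str
    best_cenhap_genotype: tuple[int, int] | None

    @property
    def best_counts(self) -> tuple[int, int, int]:
        row = self.per_candidate.set_index("sample").loc[self.best_sample]
        return int(row["two_allele"]), int(row["one_allele"]), int(row["match"])


def match_diploid(
    diploid_genotypes: dict[int, int] | pd.Series,
    matrix: HaplotypeMatrix,
    partition: CenhapPartition | None = None,
) -> DiploidMatchReport:
    """Match unphased diploid alt-allele dosages to phased individuals.

    ``diploid_genotypes`` maps position -> alt-allele count (0, 1, 2) at
    sites present in the matrix.  Candidates are the diploid individuals
    formed by consecutive ``<sample>_0`` / ``<sample>_1`` haplotype
    pairs; the best candidate minimizes the total number of mismatching
    alleles, and its cenhap genotype is read from ``partition``.
    """
    if isinstance(diploid_genotypes, pd.Series):
        diploid_genotypes = diploid_genotypes.to_dict()
    if not diploid_genotypes:
        raise ValueError("empty diploid site set")
    pos_to_col = {s.pos: j for j, s in enumerate(matrix.sites)}
    cols = []
    dosages = []
    for pos, g in diploid_genotypes.items():
        if pos not in pos_to_col:
            raise ValueError(f"diploid site {pos} absent from the matrix")
        if g not in (0, 1, 2):
            raise ValueError(f"dosage at {pos} must be 0, 1 or 2")
        cols.append(pos_to_col[pos])
        dosages.append(g)
    cols = np.asarray(cols)
    dosages = np.asarray(dosages)

    if len(matrix.hap_ids) % 2:
        raise ValueError("haplotypes cannot be paired into diploids")
    samples = [matrix.hap_ids[i][:-2] for i in range(0, len(matrix.hap_ids), 2)]
    X = matrix.alleles[:, cols]
    cand = X[0::2] + X[1::2]  # per-sample dosage
    diff = np.abs(cand - dosages[None, :])
    report = pd.DataFrame(
        {
            "sample": samples,
            "two_allele": (diff == 2).sum(axis=1),
            "one_allele": (diff == 1).sum(axis=1),
            "match": (diff == 0).sum(axis=1),
            "total_mismatch_alleles": diff.sum(axis=1),
        }
    )
    best_i = int(report["total_mismatch_alleles"].idxmin())
    best = report.loc[best_i, "sample"]
    genotype = None
    if partition is not None:
        g0 = partition.assignment.get(f"{best}_0")
        g1 = partition.assignment.get(f"{best}_1")
        if g0 is not None and g1 is not None:
            genotype = tuple(sorted((g0, g1)))
    return DiploidMatchReport(report, best, genotype)
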