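"""Archaic affinity of cenhaps by outgroup-polarized allele sharing.

Each usable site is polarized by the outgroup (chimpanzee) allele:
"derived" means different from the outgroup.  A haplotype allele is then
classified against each archaic source (Neanderthal, Denisovan) as
DM (archaic derived, haplotype matches), DN (archaic derived, haplotype
ancestral), AM (archaic ancestral, haplotype matches) or AN (archaic
ancestral, haplotype derived).  An introgressed cenhap shows a high
DM/(DM+DN) — it carries most of the alleles derived on the archaic
lineage — and a low count of AN private derived alleles.

Sites are usable only when the outgroup and archaic alleles are defined,
single-base, and the outgroup allele matches REF or ALT (otherwise the
site cannot be polarized).  Archaic states come from a homozygous allele
table; heterozygous or missing archaic calls are unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import CenhapPartition
from .genotype_io import HaplotypeMatrix

__all__ = [
    "ArchaicAnnotation",
    "ArchaicCounts",
    "classify_site",
    "count_archaic",
    "summarize_by_cenhap",
    "read_annotation_tsv",
]

CLASSES = ("DM", "DN", "AM", "AN")
_VALID = {"A", "C", "G", "T"}


@dataclass
class ArchaicAnnotation:
    """Per-site outgroup and archaic alleles, keyed by (chrom, pos).

    ``table`` columns: chrom, pos, outgroup_allele and one
    ``<source>_allele`` column per archaic source (e.g. nea_allele,
    den_allele).
    """

    table: pd.DataFrame

    @property
    def sources(self) -> list[str]:
        return [c[:-7] for c in self.table.columns if c.endswith("_allele")
                and c != "outgroup_allele"]


def read_annotation_tsv(path) -> ArchaicAnnotation:
    return ArchaicAnnotation(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def classify_site(hap_allele: str, archaic_allele: str, outgroup_allele: str) -> str:
    """Classify one haplotype allele against one archaic source.

    Returns "DM", "DN", "AM", "AN" or "unusable".
    """
    alleles = (hap_allele, archaic_allele, outgroup_allele)
    if any(a is None or not isinstance(a, str) or a.upper() not in _VALID
           for a in alleles):
        return "unusable"
    hap, arc, out = (a.upper() for a in alleles)
    archaic_derived = arc != out
    hap_derived = hap != out
    if archaic_derived:
        return "DM" if hap == arc else "DN"
    return "AM" if not hap_derived else "AN"


@dataclass
class ArchaicCounts:
    """Per-haplotype DM/DN/AM/AN tallies for each archaic source.

    ``counts[source]`` is a DataFrame indexed by hap_id with columns
    DM, DN, AM, AN; each row sums to ``usable_sites[source]``.
    """

    counts: dict[str, pd.DataFrame]
    usable_sites: dict[str, int]


def count_archaic(
    matrix: HaplotypeMatrix,
    annot: ArchaicAnnotation,
    region_limit: tuple[int, int] | None = None,
) -> ArchaicCounts:
    """Tally site classes per haplotype over usable annotated sites.

    ``region_limit`` restricts to positions in [start, end] (1-based
    inclusive) — the region with reliable archaic alignment.
    """
    key = annot.table.set_index(["chrom", "pos"])
    counts: dict[str, pd.DataFrame] = {}
    usable: dict[str, int] = {}
    H = matrix.n_haplotypes
    for source in annot.sources:
        col = f"{source}_allele"
        tall = np.zeros((H, 4), dtype=np.int64)
        n_usable = 0
        for j, site in enumerate(matrix.sites):
            if region_limit is not None and not (
                region_limit[0] <= site.pos <= region_limit[1]
            ):
                continue
            try:
                row = key.loc[(site.chrom, site.pos)]
            except KeyError:
                continue
            out_allele = row["outgroup_allele"]
            arc_allele = row[col]
            if (
                not isinstance(out_allele, str)
                or out_allele.upper() not in _VALID
                or out_allele.upper() not in (site.ref_allele, site.alt_allele)
            ):
                continue
            if not isinstance(arc_allele, str) or arc_allele.upper() not in _VALID:
                continue
            n_usable += 1
            out_b, arc_b = out_allele.upper(), arc_allele.upper()
            hap_is_alt = matrix.alleles[:, j] == 1
            hap_base_alt = site.alt_allele == arc_b
            hap_base_ref = site.ref_allele == arc_b
            matches_archaic = np.where(hap_is_alt, hap_base_alt, hap_base_ref)
            if arc_b != out_b:  # archaic carries the derived state
                tall[:, 0] += matches_archaic  # DM
                tall[:, 1] += ~matches_archaic  # DN
            else:
                matches_out = ~hap_is_alt if out_b == site.ref_allele else hap_is_alt
                tall[:, 2] += matches_out  # AM
                tall[:, 3] += ~matches_out  # AN
        if n_usable == 0:
            raise ValueError(f"no usable sites for archaic source {source!r}")
        counts[source] = pd.DataFrame(tall, index=matrix.hap_ids, columns=CLASSES)
        usable[source] = n_usable
    return ArchaicCounts(counts, usable)


def summarize_by_cenhap(
    counts: ArchaicCounts,
    partition: CenhapPartition,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Group means, 95% CIs and introgression ratios per cenhap x source.

    CIs are normal approximations on the group mean (mean +- 1.96 SE);
    groups of size < 2 carry NaN CIs.  Ratios are computed from group
    means: ratio_dmdn = DM / (DM + DN), ratio_dman = DM / (DM + AN).
    ``exclude`` optionally drops haplotypes (e.g. apparent recombinants)
    before summarizing.  log2(count + 1) display columns are included.
    """
    exclude = set(exclude or ())
    rows = []
    for source, df in counts.counts.items():
        for group in partition.labels:
            members = [h for h in partition.members(group)
                       if h in df.index and h not in exclude]
            if not members:
                continue
            sub = df.loc[members]
            means = sub.mean()
            n = len(members)
            if n >= 2:
                se = sub.std(ddof=1) / np.sqrt(n)
                lo, hi = means - 1.96 * se, means + 1.96 * se
            else:
                lo = hi = pd.Series(np.nan, index=means.index)
            dm, dn, an = means["DM"], means["DN"], means["AN"]
            row = {"source": source, "cenhap": group, "n": n}
            for c in CLASSES:
                row[f"{c}_mean"] = means[c]
                row[f"{c}_lo"] = lo[c]
                row[f"{c}_hi"] = hi[c]
                row[f"{c}_log2"] = np.log2(means[c] + 1.0)
            row["ratio_dmdn"] = dm / (dm + dn) if dm + dn > 0 else np.nan
            row["ratio_dman"] = dm / (dm + an) if dm + an > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
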