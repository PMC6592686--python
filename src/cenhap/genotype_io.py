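"""Phased-genotype I/O and the haplotype matrix.

The substrate of every downstream analysis is a matrix of phased 0/1
alleles over biallelic SNPs in a centromere-proximal region (CPR).
Haplotypes are rows, sites are columns.  All user-facing coordinates are
1-based inclusive (VCF convention); interval arithmetic internally is
0-based half-open.

Males on chrX are hemizygous and contribute a single haplotype; diploid
samples contribute two.  Inputs are expected to be fully phased and
imputed — missing or unphased genotypes are an error, not silently
repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

logger = logging.getLogger("cenhap")

__all__ = [
    "Site",
    "HaplotypeMatrix",
    "MaskSet",
    "read_vcf_region",
    "write_vcf",
    "central_subset",
]


@dataclass(frozen=True)
class Site:
    """One biallelic SNP.

    ``mac`` is the minor-allele count over the haplotypes that were
    included when the matrix was built, so ``mac <= H // 2`` always.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    mac: int

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"site {self.chrom}:{self.pos} is not a SNP")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.chrom}:{self.pos} has identical alleles")
        if self.mac < 0:
            raise ValueError("mac must be >= 0")


@dataclass
class HaplotypeMatrix:
    """H phased haplotypes x S biallelic sites, entries in {0, 1}.

    ``region`` is (chrom, start, end), 0-based half-open.
    """

    hap_ids: list[str]
    sites: list[Site]
    alleles: np.ndarray
    region: tuple[str, int, int]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        H, S = self.alleles.shape if self.alleles.size else (len(self.hap_ids), 0)
        if self.alleles.size == 0:
            self.alleles = self.alleles.reshape(len(self.hap_ids), len(self.sites))
        if self.alleles.shape != (len(self.hap_ids), len(self.sites)):
            raise ValueError("alleles shape does not match hap_ids x sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 with no missing entries")
        pos = self.positions
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def macs(self) -> np.ndarray:
        """Recompute minor-allele counts column-wise."""
        ones = self.alleles.sum(axis=0)
        return np.minimum(ones, self.n_haplotypes - ones).astype(np.int64)

    def take_sites(self, indices) -> "HaplotypeMatrix":
        """Matrix restricted to the given site indices (order preserved)."""
        indices = np.asarray(indices, dtype=np.int64)
        sites = [self.sites[i] for i in indices]
        return HaplotypeMatrix(
            hap_ids=list(self.hap_ids),
            sites=sites,
            alleles=self.alleles[:, indices],
            region=self.region,
        )

    def with_recomputed_mac(self) -> "HaplotypeMatrix":
        macs = self.macs()
        sites = [replace(s, mac=int(m)) for s, m in zip(self.sites, macs)]
        return HaplotypeMatrix(self.hap_ids, sites, self.alleles, self.region)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.hap_ids == other.hap_ids
            and self.sites == other.sites
            and np.array_equal(self.alleles, other.alleles)
        )

    def site_table(self):
        """Site metadata as a pandas DataFrame (chrom, pos, ref, alt, mac)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref_allele for s in self.sites],
                "alt": [s.alt_allele for s in self.sites],
                "mac": [s.mac for s in self.sites],
            }
        )


@dataclass
class MaskSet:
    """Hard-mask intervals, (chrom, start, end) 0-based half-open.

    Intervals are merged per chromosome on construction so membership
    queries see a non-overlapping set.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted({c for c, _, _ in self.intervals}):
            ivs = sorted((s, e) for c, s, e in self.intervals if c == chrom)
            for s, e in ivs:
                if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
                    c0, s0, e0 = merged[-1]
                    merged[-1] = (c0, s0, max(e0, e))
                else:
                    merged.append((chrom, s, e))
        self.intervals = merged

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start), int(end)))
        return cls(intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside a mask."""
        p0 = pos - 1
        return any(c == chrom and s <= p0 < e for c, s, e in self.intervals)


def _parse_region(region: str | tuple[str, int, int]) -> tuple[str, int, int]:
    """Accept 'chr:start-end' (1-based inclusive) or an internal tuple."""
    if isinstance(region, tuple):
        return region
    chrom, _, span = region.partition(":")
    start, _, end = span.partition("-")
    s, e = int(start.replace(",", "")), int(end.replace(",", ""))
    if e < s:
        raise ValueError(f"malformed region {region!r}")
    return (chrom, s - 1, e)


def read_vcf_region(
    path,
    region: str | tuple[str, int, int],
    min_mac: int = 0,
    masks: MaskSet | None = None,
    ploidy_mode: str = "diploid",
) -> HaplotypeMatrix:
    """Load phased biallelic SNPs from a VCF into a haplotype matrix.

    Parameters
    ----------
    region
        ``"chrom:start-end"`` (1-based inclusive) or an internal
        (chrom, start, end) half-open tuple.
    min_mac
        Minimum minor-allele count; sites below it are dropped after the
        matrix is built.
    ploidy_mode
        ``"diploid"`` (every sample contributes two phased haplotypes),
        ``"haploid-male-X"`` (every sample one haplotype), or ``"mixed"``
        (per-call: haploid records one, diploid two — all samples must be
        consistent across sites).

    Unphased diploid calls and missing alleles raise ``ValueError`` naming
    the offending site.  Multi-allelic and non-SNP records are skipped and
    counted in a log message.
    """
    if ploidy_mode not in ("diploid", "haploid-male-X", "mixed"):
        raise ValueError(f"unknown ploidy_mode {ploidy_mode!r}")
    chrom, start, end = _parse_region(region)
    masks = masks or MaskSet()

    columns: list[np.ndarray] = []
    sites: list[Site] = []
    hap_ids: list[str] | None = None
    n_skipped = 0

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.chrom != chrom:
                continue
            pos0 = rec.pos - 1
            if not (start <= pos0 < end):
                continue
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if masks.contains(rec.chrom, rec.pos):
                continue
            col: list[int] = []
            ids: list[str] = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    raise ValueError(
                        f"missing genotype for {sample} at {rec.chrom}:{rec.pos}"
                    )
                if len(gt) == 1:
                    if ploidy_mode == "diploid":
                        raise ValueError(
                            f"haploid call for {sample} at {rec.chrom}:{rec.pos} "
                            "in diploid mode"
                        )
                    col.append(gt[0])
                    ids.append(sample)
                else:
                    if ploidy_mode == "haploid-male-X":
                        raise ValueError(
                            f"diploid call for {sample} at {rec.chrom}:{rec.pos} "
                            "in haploid mode"
                        )
                    if not call.phased:
                        raise ValueError(
                            f"unphased genotype for {sample} at {rec.chrom}:{rec.pos}"
                        )
                    col.extend(gt)
                    ids.extend([f"{sample}_0", f"{sample}_1"])
            if hap_ids is None:
                hap_ids = ids
            elif ids != hap_ids:
                raise ValueError(
                    f"inconsistent ploidy across sites at {rec.chrom}:{rec.pos}"
                )
            arr = np.asarray(col, dtype=np.int8)
            mac = int(min(arr.sum(), len(arr) - arr.sum()))
            sites.append(Site(rec.chrom, rec.pos, rec.ref, alts[0], mac))
            columns.append(arr)

    if n_skipped:
        logger.info("read_vcf_region: skipped %d non-biallelic-SNP records", n_skipped)

    if hap_ids is None:
        hap_ids = []
    alleles = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(hap_ids), 0), dtype=np.int8)
    )
    matrix = HaplotypeMatrix(hap_ids, sites, alleles, (chrom, start, end))
    if min_mac > 0 and matrix.n_sites:
        keep = np.flatnonzero(matrix.macs() >= min_mac)
        matrix = matrix.take_sites(keep)
    return matrix


def _infer_ploidy(hap_ids: list[str]) -> str:
    paired = (
        len(hap_ids) % 2 == 0
        and all(h.endswith(("_0", "_1")) for h in hap_ids)
        and all(
            hap_ids[i][:-2] == hap_ids[i + 1][:-2]
            and hap_ids[i].endswith("_0")
            and hap_ids[i + 1].endswith("_1")
            for i in range(0, len(hap_ids), 2)
        )
    )
    return "diploid" if paired else "haploid-male-X"


def write_vcf(matrix: HaplotypeMatrix, path, ploidy_mode: str = "infer") -> None:
    """Write a haplotype matrix as an uncompressed VCF 4.2 file.

    Diploid mode pairs consecutive ``<sample>_0`` / ``<sample>_1``
    haplotypes into phased GT fields; haploid mode writes one allele per
    sample.  ``read_vcf_region(write_vcf(m))`` round-trips exactly when
    no MAC filter or mask is applied.
    """
    if ploidy_mode == "infer":
        ploidy_mode = _infer_ploidy(matrix.hap_ids)
    if ploidy_mode == "diploid" and len(matrix.hap_ids) % 2:
        raise ValueError("odd haplotype count cannot be paired into diploids")

    chrom, start, end = matrix.region
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    max_pos = int(matrix.positions.max()) if matrix.n_sites else end
    header.contigs.add(chrom, length=max(end, max_pos) + 1)
    if ploidy_mode == "diploid":
        samples = [matrix.hap_ids[i][:-2] for i in range(0, len(matrix.hap_ids), 2)]
    else:
        samples = list(matrix.hap_ids)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref_allele, site.alt_allele),
            )
            col = matrix.alleles[:, j]
            if ploidy_mode == "diploid":
                for k, sample in enumerate(samples):
                    rec.samples[sample]["GT"] = (int(col[2 * k]), int(col[2 * k + 1]))
                    rec.samples[sample].phased = True
            else:
                for k, sample in enumerate(samples):
                    rec.samples[sample]["GT"] = (int(col[k]),)
            out.write(rec)


def central_subset(
    matrix: HaplotypeMatrix,
    left_interval: tuple[int, int],
    right_interval: tuple[int, int],
    gap: tuple[int, int] | None = None,
) -> np.ndarray:
    """Indices of sites inside either flanking interval (1-based inclusive).

    The two intervals are the central clustering windows immediately left
    and right of the centromeric assembly gap.  If ``gap`` is given the
    intervals must not overlap it.
    """
    (ls, le), (rs, re) = left_interval, right_interval
    if gap is not None:
        gs, ge = gap
        for s, e in (left_interval, right_interval):
            if s <= ge and gs <= e:
                raise ValueError("central interval overlaps the assembly gap")
    pos = matrix.positions
    inside = ((pos >= ls) & (pos <= le)) | ((pos >= rs) & (pos <= re))
    return np.flatnonzero(inside)
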