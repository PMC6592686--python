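"""Alpha-satellite array sizes from centromeric read counts.

Raw per-sample per-chromosome counts of reads mapping to the
chromosome's centromeric (CEN) model — uniquely or multiply but
chromosome-specifically — are turned into array-size estimates in two
stages: (1) division by the sample's mean coverage over chr1 unique
regions, which removes sequencing depth; (2) division by the sample's
sum of stage-1 sizes over all chromosomes, which absorbs library- and
technology-driven sample-to-sample variation.  Sizes are then summarized
as empirical cumulative distributions (ecdf) by cenhap genotype; on chrX
female (two-array) values are halved to be comparable with hemizygous
males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArrayCountTable",
    "GenotypeSizeSummary",
    "normalize_stage1",
    "normalize_stage2",
    "load_count_table",
    "summarize_by_genotype",
]


def normalize_stage1(raw_count: float, chr1_mean_coverage: float) -> float:
    """Depth-normalized size: raw count / chr1 unique-region mean coverage."""
    if chr1_mean_coverage <= 0:
        raise ValueError("chr1 mean coverage must be > 0")
    return raw_count / chr1_mean_coverage


def normalize_stage2(stage1_sizes) -> np.ndarray:
    """Within-sample proportions: each chromosome / sum over chromosomes."""
    sizes = np.asarray(stage1_sizes, dtype=float)
    total = sizes.sum()
    if total <= 0:
        raise ValueError("all-zero sample cannot be stage-2 normalized")
    return sizes / total


@dataclass
class ArrayCountTable:
    """Count table with both normalization stages applied.

    ``table`` columns: sample, chrom, cen_count, chr1_mean_cov, size_s1
    (stage 1), size_s2 (stage 2, summing to 1 within each sample).
    Samples with zero chr1 coverage or an all-zero count vector are
    excluded and listed in ``excluded``.  Stage-1 sizes in the lowest
    decile carry ``small_array_flag`` — small estimates may reflect
    divergence from the CEN reference model rather than a small array.
    """

    table: pd.DataFrame
    excluded: list[str]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ArrayCountTable":
        required = {"sample", "chrom", "cen_count", "chr1_mean_cov"}
        if not required <= set(counts.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if (counts["cen_count"] < 0).any():
            raise ValueError("negative read count")
        excluded = sorted(
            set(counts.loc[counts["chr1_mean_cov"] <= 0, "sample"])
        )
        df = counts[~counts["sample"].isin(excluded)].copy()
        df["size_s1"] = df["cen_count"] / df["chr1_mean_cov"]
        totals = df.groupby("sample")["size_s1"].transform("sum")
        zero = sorted(set(df.loc[totals <= 0, "sample"]))
        excluded += zero
        df = df[~df["sample"].isin(zero)].copy()
        totals = df.groupby("sample")["size_s1"].transform("sum")
        df["size_s2"] = df["size_s1"] / totals
        cutoff = df["size_s1"].quantile(0.1)
        df["small_array_flag"] = df["size_s1"] <= cutoff
        return cls(df.reset_index(drop=True), excluded)


@dataclass
class GenotypeSizeSummary:
    """Per-genotype n, mean and ecdf of array sizes."""

    summary: pd.DataFrame  # genotype, n, mean
    ecdfs: dict[str, pd.DataFrame]  # genotype -> (size, cum_frac)


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"size": v, "cum_frac": np.arange(1, len(v) + 1) / len(v)})


def summarize_by_genotype(
    sizes: pd.DataFrame,
    genotypes: pd.Series | dict,
    sex: pd.Series | dict | None = None,
    chrx: bool = False,
    chrx_female_factor: float = 0.5,
    size_col: str = "size_s1",
) -> GenotypeSizeSummary:
    """Summarize one chromosome's sizes by cenhap genotype class.

    ``sizes`` must hold one row per sample with ``size_col``;
    ``genotypes`` maps sample -> genotype label (e.g. "3_4").  With
    ``chrx=True`` female samples (``sex[sample] == "F"``) are scaled by
    ``chrx_female_factor`` so two-array females plot with one-array
    males.  Genotype classes with no samples are omitted.
    """
    genotypes = pd.Series(genotypes) if isinstance(genotypes, dict) else genotypes
    sex = pd.Series(sex) if isinstance(sex, dict) else sex
    df = sizes.set_index("sample") if "sample" in sizes.columns else sizes
    rows = []
    ecdfs: dict[str, pd.DataFrame] = {}
    for genotype in sorted(genotypes.unique()):
        samples = [s for s in genotypes.index[genotypes == genotype] if s in df.index]
        if not samples:
            continue
        vals = df.loc[samples, size_col].to_numpy(dtype=float)
        if chrx and sex is not None:
            female = np.array([sex.get(s) == "F" for s in samples])
            vals = np.where(female, vals * chrx_female_factor, vals)
        rows.append({"genotype": genotype, "n": len(vals), "mean": float(vals.mean())})
        ecdfs[genotype] = _ecdf(vals)
    return GenotypeSizeSummary(pd.DataFrame(rows), ecdfs)


def load_count_table(path) -> ArrayCountTable:
    """Read a TSV (sample, chrom, cen_count, chr1_mean_cov) and normalize."""
    return ArrayCountTable.from_counts(pd.read_csv(path, sep="\t"))
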