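"""Pairwise linkage disequilibrium by the 2x2 chi-squared test.

For each ordered site pair the haplotypes are cross-tabulated into the
four gametotype counts and tested for independence with the Pearson
chi-squared statistic (1 df, no continuity correction),
chi2 = H (n00 n11 - n01 n10)^2 / (r1 r2 c1 c2).  Pairs with a zero
marginal (a monomorphic site) are flagged undefined rather than tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .genotype_io import HaplotypeMatrix

__all__ = ["GameteTable", "gamete_table", "chi2_independence", "ld_matrix", "NEGLOG10P_CAP"]

# Smallest chi2(1) upper-tail probability representable in float64 maps to
# about 10^-308; -log10(p) is capped there and the cap recorded in output.
NEGLOG10P_CAP = -np.log10(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class GameteTable:
    """Gametotype counts between two biallelic sites: n_ab = #(i=a, j=b)."""

    n00: int
    n01: int
    n10: int
    n11: int

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def marginals(self) -> tuple[int, int, int, int]:
        return (
            self.n00 + self.n01,
            self.n10 + self.n11,
            self.n00 + self.n10,
            self.n01 + self.n11,
        )


def gamete_table(matrix: HaplotypeMatrix, i: int, j: int) -> GameteTable:
    """Cross-tabulate haplotypes by their alleles at sites i and j."""
    if i == j:
        raise ValueError("need two distinct sites")
    a = matrix.alleles[:, i]
    b = matrix.alleles[:, j]
    n11 = int((a & b).sum())
    n10 = int((a & (1 - b)).sum())
    n01 = int(((1 - a) & b).sum())
    n00 = int(((1 - a) & (1 - b)).sum())
    return GameteTable(n00=n00, n01=n01, n10=n10, n11=n11)


def chi2_independence(table: GameteTable) -> tuple[float, float, float]:
    """Pearson chi-squared for independence on a 2x2 gamete table.

    Returns (chi2, p, -log10 p).  Raises ``ValueError`` on a zero
    marginal, where the test is undefined.
    """
    r1, r2, c1, c2 = table.marginals()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-squared undefined: zero marginal")
    H = table.total
    det = table.n00 * table.n11 - table.n01 * table.n10
    chi2 = H * det * det / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(chi2, 1))
    neglog = min(-np.log10(p), NEGLOG10P_CAP) if p > 0 else NEGLOG10P_CAP
    return float(chi2), p, float(neglog)


def ld_matrix(matrix: HaplotypeMatrix, site_subset=None) -> pd.DataFrame:
    """All within-subset pairwise chi-squared LD statistics.

    Returns a long-format DataFrame (i, j, i_pos, j_pos, chi2, p,
    neglog10p, defined) over ordered pairs i < j; undefined pairs (zero
    marginal) carry NaN statistics and ``defined=False``.  The
    -log10(p) cap is stored in ``df.attrs['neglog10p_cap']``.
    """
    subset = (
        np.arange(matrix.n_sites) if site_subset is None else np.asarray(site_subset)
    )
    m = len(subset)
    if m < 2:
        df = pd.DataFrame(
            columns=["i", "j", "i_pos", "j_pos", "chi2", "p", "neglog10p", "defined"]
        )
        df.attrs["neglog10p_cap"] = NEGLOG10P_CAP
        return df

    X = matrix.alleles[:, subset].astype(np.int64)
    H = matrix.n_haplotypes
    ones = X.sum(axis=0)
    n11 = X.T @ X
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = H - n11 - n10 - n01

    r1, r2 = n00 + n01, n10 + n11
    c1, c2 = n00 + n10, n01 + n11
    defined = (np.minimum(np.minimum(r1, r2), np.minimum(c1, c2)) > 0)
    det = n00 * n11 - n01 * n10
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(defined, H * det.astype(float) ** 2 /
                        (r1 * r2 * c1 * c2).astype(float), np.nan)
    iu, ju = np.triu_indices(m, k=1)
    chi2_flat = chi2[iu, ju]
    p = np.full_like(chi2_flat, np.nan)
    ok = ~np.isnan(chi2_flat)
    p[ok] = chi2_dist.sf(chi2_flat[ok], 1)
    with np.errstate(divide="ignore"):
        neglog = np.where(p > 0, -np.log10(p), NEGLOG10P_CAP)
    neglog = np.minimum(neglog, NEGLOG10P_CAP)

    pos = matrix.positions[subset]
    df = pd.DataFrame(
        {
            "i": subset[iu],
            "j": subset[ju],
            "i_pos": pos[iu],
            "j_pos": pos[ju],
            "chi2": chi2_flat,
            "p": p,
            "neglog10p": neglog,
            "defined": defined[iu, ju],
        }
    )
    df.attrs["neglog10p_cap"] = NEGLOG10P_CAP
    return df
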