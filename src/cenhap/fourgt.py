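"""Windowed four-gamete "double crossover" filter (4gt_dco).

In a region with essentially no crossing over, a genotyping error looks
like a gene conversion at a single site: the focal SNP shows all four
gametotypes against nearby SNPs that are themselves mutually consistent
with a single genealogy.  The filter walks the region 5'->3'; a focal
SNP fails a flanking pair (left, right) when it shows all four gametes
with each of the two while the flanks show at most three gametes
between themselves — the signature of an allele island ("double
crossover") rather than a genuine single exchange, which breaks the
four-gamete pattern on one side only.  A focal SNP whose failing-pair count exceeds the
tolerance is removed immediately, so later windows are drawn from the
surviving set.  The schedule repeats with successively larger
half-windows (default +-10, +-20, +-30, +-40 surviving SNPs).

``fourgt_dco`` is the production (vectorized) implementation;
``fourgt_dco_reference`` is a deliberately naive triple-loop version of
the same definition, kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import HaplotypeMatrix

__all__ = [
    "FilterConfig",
    "FilterResult",
    "four_gamete",
    "pair_fails",
    "fourgt_dco_pass",
    "fourgt_dco",
    "fourgt_dco_reference",
]


@dataclass(frozen=True)
class FilterConfig:
    """Window schedule (half-widths in surviving-SNP counts) and tolerance.

    ``tolerance`` is the maximum number of flanking pairs in a window
    allowed to fail before the focal SNP is filtered: removal happens
    when the failing count is strictly greater.
    """

    windows: tuple[int, ...] = (10, 20, 30, 40)
    tolerance: int = 0
    flank_rule: str = "and"  # "and": four gametes with both flanks; "or"/"xor" available

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.windows, self.windows[1:])):
            raise ValueError("windows must be strictly increasing")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.flank_rule not in ("and", "or", "xor"):
            raise ValueError("flank_rule must be 'and', 'or' or 'xor'")


@dataclass
class FilterResult:
    """Outcome of the full window schedule."""

    surviving: list[int]
    removed: list[tuple[int, int, int]]  # (site index, pass number, failing pairs)
    per_pass_removed: list[int] = field(default_factory=list)

    def removal_table(self, matrix: HaplotypeMatrix):
        import pandas as pd

        return pd.DataFrame(
            {
                "pos": [matrix.sites[i].pos for i, _, _ in self.removed],
                "pass": [p for _, p, _ in self.removed],
                "failing_pairs": [c for _, _, c in self.removed],
            }
        )


def four_gamete(matrix: HaplotypeMatrix, i: int, j: int) -> bool:
    """True iff all four gametotypes 00/01/10/11 occur between sites i, j."""
    a = matrix.alleles[:, i].astype(bool)
    b = matrix.alleles[:, j].astype(bool)
    return bool(
        (a & b).any() and (a & ~b).any() and (~a & b).any() and (~a & ~b).any()
    )


def pair_fails(matrix: HaplotypeMatrix, focal: int, left: int, right: int,
               flank_rule: str = "and") -> bool:
    """One flanking-pair test for the focal SNP.

    Positive when the focal SNP exhibits all four gametes with both
    flanks (``flank_rule='and'``, the double-crossover signature;
    ``'or'`` relaxes to at least one flank, ``'xor'`` to exactly one)
    while the flanks show at most three gametes between themselves.
    """
    if not (left < focal < right):
        raise ValueError("need left < focal < right")
    if four_gamete(matrix, left, right):
        return False
    fl = four_gamete(matrix, focal, left)
    fr = four_gamete(matrix, focal, right)
    if flank_rule == "and":
        return fl and fr
    if flank_rule == "xor":
        return fl != fr
    return fl or fr


def _fourg_one_vs_many(f: np.ndarray, block: np.ndarray, H: int) -> np.ndarray:
    """Four-gamete flags between one column and each column of a block."""
    n11 = f @ block
    n10 = f.sum() - n11
    n01 = block.sum(axis=0) - n11
    n00 = H - n11 - n10 - n01
    return (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)


def _fourg_cross(L: np.ndarray, R: np.ndarray, H: int) -> np.ndarray:
    """Four-gamete flags for every (left, right) column pair."""
    n11 = L.T @ R
    n10 = L.sum(axis=0)[:, None] - n11
    n01 = R.sum(axis=0)[None, :] - n11
    n00 = H - n11 - n10 - n01
    return (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)


def fourgt_dco_pass(
    matrix: HaplotypeMatrix,
    surviving: list[int],
    half_window: int,
    tolerance: int,
    flank_rule: str = "and",
    _removed_log: list[tuple[int, int]] | None = None,
) -> list[int]:
    """One 5'->3' sweep at a single half-window width.

    For each focal SNP the flanking candidates are the nearest
    ``half_window`` surviving SNPs on each side (fewer near the edges);
    all left x right combinations are tested.  Removal is immediate, so
    the windows of downstream focal SNPs reflect it.  Focal SNPs with an
    empty side are never removed (the test needs flanks on both sides).
    """
    X = matrix.alleles.astype(np.int64)
    H = matrix.n_haplotypes
    surv = list(surviving)
    k = 0
    while k < len(surv):
        left_idx = surv[max(0, k - half_window) : k]
        right_idx = surv[k + 1 : k + 1 + half_window]
        if not left_idx or not right_idx:
            k += 1
            continue
        f = X[:, surv[k]]
        L = X[:, left_idx]
        R = X[:, right_idx]
        fg_l = _fourg_one_vs_many(f, L, H)  # (a,)
        fg_r = _fourg_one_vs_many(f, R, H)  # (b,)
        fg_lr = _fourg_cross(L, R, H)  # (a, b)
        if flank_rule == "and":
            focal_part = fg_l[:, None] & fg_r[None, :]
        elif flank_rule == "xor":
            focal_part = fg_l[:, None] != fg_r[None, :]
        else:
            focal_part = fg_l[:, None] | fg_r[None, :]
        n_failing = int((focal_part & ~fg_lr).sum())
        if n_failing > tolerance:
            if _removed_log is not None:
                _removed_log.append((surv[k], n_failing))
            del surv[k]
        else:
            k += 1
    return surv


def fourgt_dco(matrix: HaplotypeMatrix, config: FilterConfig = FilterConfig()) -> FilterResult:
    """Full window schedule, threading the surviving set between passes."""
    surviving = list(range(matrix.n_sites))
    removed: list[tuple[int, int, int]] = []
    per_pass: list[int] = []
    for pass_no, w in enumerate(config.windows, start=1):
        log: list[tuple[int, int]] = []
        surviving = fourgt_dco_pass(
            matrix, surviving, w, config.tolerance, config.flank_rule, log
        )
        removed.extend((idx, pass_no, cnt) for idx, cnt in log)
        per_pass.append(len(log))
    return FilterResult(surviving=surviving, removed=removed, per_pass_removed=per_pass)


# ---------------------------------------------------------------------------
# Naive reference implementation (cross-check only; do not optimize).
# ---------------------------------------------------------------------------


def _four_gamete_cached(matrix, i, j, cache):
    key = (i, j) if i < j else (j, i)
    hit = cache.get(key)
    if hit is None:
        hit = four_gamete(matrix, key[0], key[1])
        cache[key] = hit
    return hit


def fourgt_dco_reference(
    matrix: HaplotypeMatrix, config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Plain-loop restatement of the filter definition.

    Walks every focal SNP, every left flank, every right flank with
    explicit loops.  Pairwise gamete tables are memoized, which is safe
    because removing a SNP never changes the gamete table of any other
    pair.
    """
    cache: dict[tuple[int, int], bool] = {}
    surviving = list(range(matrix.n_sites))
    removed: list[tuple[int, int, int]] = []
    per_pass: list[int] = []
    for pass_no, w in enumerate(config.windows, start=1):
        n_removed_this_pass = 0
        k = 0
        while k < len(surviving):
            focal = surviving[k]
            lefts = surviving[max(0, k - w) : k]
            rights = surviving[k + 1 : k + 1 + w]
            n_failing = 0
            for left in lefts:
                for right in rights:
                    if _four_gamete_cached(matrix, left, right, cache):
                        continue
                    fl = _four_gamete_cached(matrix, focal, left, cache)
                    fr = _four_gamete_cached(matrix, focal, right, cache)
                    if config.flank_rule == "and":
                        if fl and fr:
                            n_failing += 1
                    elif config.flank_rule == "xor":
                        if fl != fr:
                            n_failing += 1
                    elif fl or fr:
                        n_failing += 1
            if lefts and rights and n_failing > config.tolerance:
                removed.append((focal, pass_no, n_failing))
                surviving.pop(k)
                n_removed_this_pass += 1
            else:
                k += 1
        per_pass.append(n_removed_this_pass)
    return FilterResult(surviving=surviving, removed=removed, per_pass_removed=per_pass)
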