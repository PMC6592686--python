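"""Synthetic cenhap data with known truth.

Generates every input the pipeline consumes: a genealogy for a
non-recombining centromere-proximal block (structured Kingman coalescent
with an archaic population, optional introgression, and an outgroup tip
at the human/chimpanzee calibration age), infinite-sites haplotypes,
flank-confined crossovers, genotyping errors and gene-conversion tracts,
codon alignments evolved along the same genealogy, archaic/outgroup
allele tables, and per-sample centromeric read-count tables.

The model is deliberately a single non-recombining central locus with
independently spliced flanks — the haplotype structure that suppressed
centromeric crossing over produces — not a full ancestral-recombination
graph.  Time is carried in generations internally; years enter only
through ``generation_time`` at parameter boundaries.

Every stochastic element is driven by a ``numpy.random.Generator`` so
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import HaplotypeMatrix, Site

__all__ = [
    "SimParams",
    "Node",
    "Genealogy",
    "MutationDrop",
    "simulate_genealogy",
    "drop_mutations",
    "add_flank_recombination",
    "splice_flank",
    "inject_errors",
    "inject_conversions",
    "simulate_codons",
    "emit_archaic_annotation",
    "simulate_array_counts",
    "paper_like_params",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimParams:
    """Study conditions for the synthetic cenhap locus.

    Times are in years; ``generation_time`` converts them to coalescent
    generations.  ``diploid_ne`` is the modern diploid population size,
    ``archaic_ne`` the (smaller) archaic one.
    """

    n_haplotypes: int = 200
    diploid_ne: float = 3000.0
    archaic_ne: float = 300.0
    crossover_rate: float = 0.0  # per-haplotype splice probability per flank
    gene_conversion_rate: float = 0.0  # per-site tract-initiation probability
    conversion_tract_length: int = 3
    mutation_rate: float = 1e-7  # per site per generation (codon evolution)
    genotyping_error_rate: float = 0.003
    archaic_split_time: float = 575_000.0
    admixture_time: float = 50_000.0
    introgression_fraction: float = 0.05
    calibration_age: float = 6_500_000.0
    generation_time: float = 29.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "crossover_rate",
            "gene_conversion_rate",
            "mutation_rate",
            "genotyping_error_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.introgression_fraction <= 1.0:
            raise ValueError("introgression_fraction must be in [0, 1]")

    def gens(self, years: float) -> float:
        return years / self.generation_time


def paper_like_params(seed: int | None = None, **overrides) -> SimParams:
    """Preset emulating the structure behind the published figures."""
    return SimParams(seed=seed, **overrides)


@dataclass
class Node:
    """Genealogy node; ``time`` in generations before present."""

    id: int
    time: float
    children: list["Node"] = field(default_factory=list)
    name: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Genealogy:
    """Coalescent tree over modern haplotypes, archaic tips and outgroup."""

    root: Node
    tips: list[Node]  # modern sampled haplotypes, in hap order
    archaic_tips: dict[str, Node]
    outgroup_tip: Node
    introgressed: list[str]  # names of modern tips of archaic origin
    params: SimParams

    def mrca(self, names: list[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(names)

        def visit(node: Node) -> tuple[set, Node | None]:
            if node.is_tip:
                return ({node.name} & want, None)
            found: set = set()
            for child in node.children:
                f, hit = visit(child)
                if hit is not None:
                    return (found, hit)
                found |= f
            if found == want:
                return (found, node)
            return (found, None)

        _, hit = visit(self.root)
        if hit is None:
            raise ValueError("tips not found in the genealogy")
        return hit

    def all_nodes(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def newick(self) -> str:
        def fmt(node: Node, parent_time: float) -> str:
            bl = parent_time - node.time
            if node.is_tip:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            return f"({inner}):{bl:.6g}"

        inner = ",".join(fmt(c, self.root.time) for c in self.root.children)
        return f"({inner});"


def _coalesce_phase(lineages, t, t_end, rate_denom, rng, next_id):
    """Coalesce within one population until t_end (None = until 1 lineage)."""
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / rate_denom
        wait = rng.exponential(1.0 / rate)
        if t_end is not None and t + wait > t_end:
            return lineages, t_end, next_id
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = Node(id=next_id, time=t, children=[lineages[i], lineages[j]])
        next_id += 1
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(parent)
    if t_end is not None:
        return lineages, t_end, next_id
    return lineages, t, next_id


def simulate_genealogy(params: SimParams, rng: np.random.Generator | None = None) -> Genealogy:
    """Structured coalescent for the non-recombining central block.

    Modern lineages coalesce in a population of size ``diploid_ne``;
    introgressed tips (each sampled with probability
    ``introgression_fraction``) join the archaic population at
    ``admixture_time`` and coalesce there together with the two archaic
    sample tips (NEA, DEN) until the populations merge at
    ``archaic_split_time``.  An outgroup tip attaches at
    ``calibration_age``.
    """
    if params.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    n = params.n_haplotypes
    intro_mask = rng.random(n) < params.introgression_fraction
    tips = [Node(id=i, time=0.0, name=f"hap_{i}") for i in range(n)]
    nea = Node(id=n, time=0.0, name="NEA")
    den = Node(id=n + 1, time=0.0, name="DEN")
    outgroup = Node(id=n + 2, time=0.0, name="outgroup")
    next_id = n + 3

    t_adm = params.gens(params.admixture_time)
    t_split = params.gens(params.archaic_split_time)
    t_cal = params.gens(params.calibration_age)
    if not (0 <= t_adm <= t_split < t_cal):
        raise ValueError("need 0 <= admixture_time <= archaic_split_time < calibration_age")

    modern = [tips[i] for i in range(n) if not intro_mask[i]]
    intro = [tips[i] for i in range(n) if intro_mask[i]]

    # Phase 1: present -> admixture time; only non-introgressed moderns coalesce.
    modern, t_m, next_id = _coalesce_phase(
        modern, 0.0, t_adm, 2.0 * params.diploid_ne, rng, next_id
    )
    # Phase 2: admixture -> archaic split; two populations in parallel.
    archaic = intro + [nea, den]
    modern, _, next_id = _coalesce_phase(
        modern, t_adm, t_split, 2.0 * params.diploid_ne, rng, next_id
    )
    archaic, _, next_id = _coalesce_phase(
        archaic, t_adm, t_split, 2.0 * params.archaic_ne, rng, next_id
    )
    # Phase 3: ancestral population until the human+archaic MRCA.
    lineages = modern + archaic
    lineages, t_mrca, next_id = _coalesce_phase(
        lineages, t_split, None, 2.0 * params.diploid_ne, rng, next_id
    )
    mrca = lineages[0]
    if t_mrca >= t_cal:
        raise ValueError(
            "human+archaic MRCA deeper than the calibration age; "
            "increase calibration_age or decrease population sizes"
        )
    root = Node(id=next_id, time=t_cal, children=[mrca, outgroup])

    return Genealogy(
        root=root,
        tips=tips,
        archaic_tips={"NEA": nea, "DEN": den},
        outgroup_tip=outgroup,
        introgressed=[t.name for t, m in zip(tips, intro_mask) if m],
        params=params,
    )


def simulate_split_genealogy(
    split_times: list[float],
    tips_per_group: int,
    ne: float = 500.0,
    generation_time: float = 29.0,
    calibration_age: float = 6.5e6,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Caterpillar genealogy of k lineages with known split times.

    ``split_times`` (years, increasing) gives the time at which group
    i+1 joins the ancestor of groups 0..i, so k = len(split_times) + 1
    groups are produced with tips named ``g<i>_hap<j>``.  A small ``ne``
    keeps realized node depths close to the nominal splits (each split
    adds only ~2 Ne generations of ancestral coalescence).  The outgroup
    attaches at ``calibration_age``.
    """
    if any(b <= a for a, b in zip(split_times, split_times[1:])):
        raise ValueError("split_times must be strictly increasing")
    rng = rng if rng is not None else np.random.default_rng()
    params = SimParams(
        n_haplotypes=tips_per_group * (len(split_times) + 1),
        diploid_ne=ne,
        generation_time=generation_time,
        calibration_age=calibration_age,
        introgression_fraction=0.0,
    )
    k = len(split_times) + 1
    tips: list[Node] = []
    pops: list[list[Node]] = []
    next_id = 0
    for g in range(k):
        group = []
        for j in range(tips_per_group):
            node = Node(id=next_id, time=0.0, name=f"g{g}_hap{j}")
            next_id += 1
            tips.append(node)
            group.append(node)
        pops.append(group)
    outgroup = Node(id=next_id, time=0.0, name="outgroup")
    next_id += 1

    t = 0.0
    boundaries = [s / generation_time for s in split_times]
    for b_i, t_end in enumerate(boundaries):
        new_pops = []
        for pop in pops:
            pop, _, next_id = _coalesce_phase(pop, t, t_end, 2.0 * ne, rng, next_id)
            new_pops.append(pop)
        # group b_i + 1 merges into the ancestral population of 0..b_i
        merged = new_pops[0] + new_pops[1]
        pops = [merged] + new_pops[2:]
        t = t_end
    lineages, t_mrca, next_id = _coalesce_phase(
        pops[0], t, None, 2.0 * ne, rng, next_id
    )
    t_cal = calibration_age / generation_time
    if t_mrca >= t_cal:
        raise ValueError("MRCA deeper than the calibration age")
    root = Node(id=next_id, time=t_cal, children=[lineages[0], outgroup])
    return Genealogy(
        root=root,
        tips=tips,
        archaic_tips={},
        outgroup_tip=outgroup,
        introgressed=[],
        params=params,
    )


@dataclass
class MutationDrop:
    """Infinite-sites haplotypes plus per-site provenance.

    ``nea_derived`` / ``den_derived`` flag sites whose mutation falls on a
    branch ancestral to the corresponding archaic sample tip; the
    outgroup carries the ancestral (reference) allele at every site.
    """

    matrix: HaplotypeMatrix
    genealogy: Genealogy
    site_branch: np.ndarray  # node id of the mutated branch, per site
    nea_derived: np.ndarray
    den_derived: np.ndarray


def _descendant_table(gen: Genealogy):
    """Per-node boolean vector over modern tips, plus NEA/DEN membership."""
    n = len(gen.tips)
    desc: dict[int, np.ndarray] = {}
    has_nea: dict[int, bool] = {}
    has_den: dict[int, bool] = {}
    has_out: dict[int, bool] = {}

    def visit(node: Node):
        vec = np.zeros(n, dtype=bool)
        nea = den = out = False
        if node.is_tip:
            if node.name.startswith("hap_"):
                vec[int(node.name[4:])] = True
            nea = node.name == "NEA"
            den = node.name == "DEN"
            out = node.name == "outgroup"
        else:
            for child in node.children:
                cv, cn, cd, co = visit(child)
                vec |= cv
                nea |= cn
                den |= cd
                out |= co
        desc[node.id] = vec
        has_nea[node.id] = nea
        has_den[node.id] = den
        has_out[node.id] = out
        return vec, nea, den, out

    visit(gen.root)
    return desc, has_nea, has_den, has_out


def drop_mutations(
    gen: Genealogy,
    n_sites: int | None = None,
    mutation_rate: float | None = None,
    region: tuple[str, int, int] = ("chrSim", 0, 10_000_000),
    rng: np.random.Generator | None = None,
) -> MutationDrop:
    """Drop infinite-sites mutations onto the genealogy.

    Each polymorphic site maps to exactly one branch, chosen with
    probability proportional to branch length among branches that are
    polymorphic in the modern sample (1..H-1 modern descendants).  Either
    a fixed ``n_sites`` or a Poisson draw at ``mutation_rate`` per site
    per generation over the eligible branch length can be requested.
    """
    rng = rng if rng is not None else np.random.default_rng(gen.params.seed)
    n = len(gen.tips)
    desc, has_nea, has_den, _ = _descendant_table(gen)

    parent_time: dict[int, float] = {}

    def walk(node: Node):
        for child in node.children:
            parent_time[child.id] = node.time
            walk(child)

    walk(gen.root)

    branch_nodes = []
    lengths = []
    for node in gen.all_nodes():
        if node is gen.root:
            continue
        k = int(desc[node.id].sum())
        if 1 <= k <= n - 1:
            branch_nodes.append(node)
            lengths.append(parent_time[node.id] - node.time)
    lengths = np.asarray(lengths, dtype=float)
    total = lengths.sum()

    if n_sites is None:
        if mutation_rate is None:
            raise ValueError("give n_sites or mutation_rate")
        n_sites = int(rng.poisson(mutation_rate * total))

    chrom, start, end = region
    if n_sites > end - start:
        raise ValueError("region too small for requested site count")
    positions = np.sort(
        rng.choice(np.arange(start + 1, end + 1), size=n_sites, replace=False)
    )
    if total > 0 and n_sites > 0:
        chosen = rng.choice(len(branch_nodes), size=n_sites, p=lengths / total)
    else:
        chosen = np.zeros(0, dtype=int)

    alleles = np.zeros((n, n_sites), dtype=np.int8)
    site_branch = np.zeros(n_sites, dtype=np.int64)
    nea_d = np.zeros(n_sites, dtype=bool)
    den_d = np.zeros(n_sites, dtype=bool)
    sites = []
    for j in range(n_sites):
        node = branch_nodes[chosen[j]]
        alleles[:, j] = desc[node.id]
        site_branch[j] = node.id
        nea_d[j] = has_nea[node.id]
        den_d[j] = has_den[node.id]
        ref, alt = rng.choice(4, size=2, replace=False)
        ones = int(alleles[:, j].sum())
        sites.append(
            Site(chrom, int(positions[j]), _BASES[ref], _BASES[alt], min(ones, n - ones))
        )

    matrix = HaplotypeMatrix(
        hap_ids=[t.name for t in gen.tips],
        sites=sites,
        alleles=alleles,
        region=region,
    )
    return MutationDrop(matrix, gen, site_branch, nea_d, den_d)


def splice_flank(
    matrix: HaplotypeMatrix,
    hap_index: int,
    donor_index: int,
    side: str,
    breakpoint_idx: int,
) -> HaplotypeMatrix:
    """Copy donor alleles outward from a flank breakpoint onto one haplotype.

    ``side='left'`` replaces site columns [0, breakpoint_idx);
    ``side='right'`` replaces [breakpoint_idx, S).  Models a single
    crossover in the indicated flank.
    """
    alleles = matrix.alleles.copy()
    if side == "left":
        alleles[hap_index, :breakpoint_idx] = matrix.alleles[donor_index, :breakpoint_idx]
    elif side == "right":
        alleles[hap_index, breakpoint_idx:] = matrix.alleles[donor_index, breakpoint_idx:]
    else:
        raise ValueError("side must be 'left' or 'right'")
    out = HaplotypeMatrix(list(matrix.hap_ids), list(matrix.sites), alleles, matrix.region)
    return out.with_recomputed_mac()


def add_flank_recombination(
    matrix: HaplotypeMatrix,
    central_block: tuple[int, int],
    rate: float,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeMatrix, list[tuple[int, str, int, int]]]:
    """Splice crossovers into the flanks, leaving the central block intact.

    ``central_block`` is (first_idx, last_idx) of central sites (inclusive,
    site indices).  Each haplotype independently receives a crossover in
    each flank with probability ``rate``; the breakpoint is uniform over
    the flank's site boundaries and the donor is a random other
    haplotype.  Returns the new matrix and the splice events as
    (hap_index, side, breakpoint_idx, donor_index).
    """
    rng = rng if rng is not None else np.random.default_rng()
    c0, c1 = central_block
    events: list[tuple[int, str, int, int]] = []
    out = matrix
    H, S = matrix.alleles.shape
    for h in range(H):
        if c0 > 0 and rng.random() < rate:
            bp = int(rng.integers(1, c0 + 1))  # splice strictly left of the block
            donor = int(rng.choice([x for x in range(H) if x != h]))
            out = splice_flank(out, h, donor, "left", bp)
            events.append((h, "left", bp, donor))
        if c1 < S - 1 and rng.random() < rate:
            bp = int(rng.integers(c1 + 1, S))
            donor = int(rng.choice([x for x in range(H) if x != h]))
            out = splice_flank(out, h, donor, "right", bp)
            events.append((h, "right", bp, donor))
    return out, events


def inject_errors(
    matrix: HaplotypeMatrix, rate: float, rng: np.random.Generator | None = None
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Flip each allele independently with probability ``rate``.

    Emulates imputation/genotyping error, which in a low-exchange region
    masquerades as a single-site double crossover.  Returns the perturbed
    matrix and the (hap_index, site_index) array of every flip.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    flips = rng.random(matrix.alleles.shape) < rate
    alleles = np.where(flips, 1 - matrix.alleles, matrix.alleles).astype(np.int8)
    out = HaplotypeMatrix(list(matrix.hap_ids), list(matrix.sites), alleles, matrix.region)
    return out.with_recomputed_mac(), np.argwhere(flips)


def inject_conversions(
    matrix: HaplotypeMatrix,
    rate: float,
    tract_length: int,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeMatrix, list[tuple[int, int, int, int]]]:
    """Copy short donor tracts between haplotypes (gene conversion).

    ``rate`` is the per-site tract-initiation probability per haplotype;
    each tract copies ``tract_length`` contiguous sites (clipped at the
    matrix edge) from a random donor.  Returns the tracts as
    (hap_index, start_idx, end_idx_exclusive, donor_index).
    """
    if tract_length < 1:
        raise ValueError("tract_length must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    H, S = matrix.alleles.shape
    alleles = matrix.alleles.copy()
    tracts: list[tuple[int, int, int, int]] = []
    for h in range(H):
        starts = np.flatnonzero(rng.random(S) < rate)
        for s in starts:
            e = min(int(s) + tract_length, S)
            donor = int(rng.choice([x for x in range(H) if x != h]))
            alleles[h, s:e] = matrix.alleles[donor, s:e]
            tracts.append((h, int(s), e, donor))
    out = HaplotypeMatrix(list(matrix.hap_ids), list(matrix.sites), alleles, matrix.region)
    return out.with_recomputed_mac(), tracts


def _random_codons(n: int, rng: np.random.Generator, stops: set[str]) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(_BASES[rng.integers(0, 4, size=3)])
        if codon not in stops:
            out.append(codon)
    return out


def simulate_codons(
    gen: Genealogy,
    n_genes: int,
    codons_per_gene: int,
    mutation_rate: float,
    omega: float = 1.0,
    rng: np.random.Generator | None = None,
    tip_names: list[str] | None = None,
):
    """Evolve in-frame CDS along the genealogy, one alignment per gene.

    Point mutations arrive as a Poisson process at ``mutation_rate`` per
    nucleotide site per generation; a proposed change is discarded when
    it creates a stop codon, and nonsynonymous changes are accepted with
    probability ``omega`` (so ``omega=1`` is neutral and dN/dS -> 1).
    The outgroup tip rides the same process, giving a clock-consistent
    calibration point.
    """
    from Bio.Data.CodonTable import standard_dna_table

    from .divergence import CodonAlignment

    rng = rng if rng is not None else np.random.default_rng(gen.params.seed)
    code = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    keep = set(tip_names) if tip_names is not None else None

    alignments = []
    for g in range(n_genes):
        root_seq = _random_codons(codons_per_gene, rng, stops)
        seqs: dict[str, list[str]] = {}

        def evolve(node: Node, seq: list[str], parent_time: float):
            seq = list(seq)
            bl = parent_time - node.time
            n_events = rng.poisson(mutation_rate * bl * 3 * codons_per_gene)
            for _ in range(n_events):
                ci = int(rng.integers(0, codons_per_gene))
                pos = int(rng.integers(0, 3))
                old = seq[ci]
                base = old[pos]
                new_base = _BASES[rng.choice([b for b in range(4) if _BASES[b] != base])]
                new = old[:pos] + new_base + old[pos + 1 :]
                if new in stops:
                    continue
                if code[old] != code[new] and rng.random() >= omega:
                    continue
                seq[ci] = new
            if node.is_tip:
                if keep is None or node.name in keep or node.name == "outgroup":
                    seqs[node.name] = seq
            else:
                for child in node.children:
                    evolve(child, seq, node.time)

        for child in gen.root.children:
            evolve(child, root_seq, gen.root.time)

        alignments.append(
            CodonAlignment(
                gene_id=f"gene_{g}",
                sequences={k: "".join(v) for k, v in seqs.items()},
                outgroup_id="outgroup",
            )
        )
    return alignments


def emit_archaic_annotation(drop: MutationDrop):
    """Archaic/outgroup allele table for the simulated sites.

    The outgroup carries the ancestral (REF) base everywhere; each
    archaic source carries the derived (ALT) base exactly at sites whose
    mutation is ancestral to its sample tip.  Returned as a DataFrame
    with columns chrom, pos, outgroup_allele, nea_allele, den_allele.
    """
    import pandas as pd

    sites = drop.matrix.sites
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "outgroup_allele": [s.ref_allele for s in sites],
            "nea_allele": [
                s.alt_allele if d else s.ref_allele
                for s, d in zip(sites, drop.nea_derived)
            ],
            "den_allele": [
                s.alt_allele if d else s.ref_allele
                for s, d in zip(sites, drop.den_derived)
            ],
        }
    )


def simulate_array_counts(
    sample_genotypes: dict[str, dict[str, tuple]],
    lineage_sizes: dict[tuple[str, str], float],
    coverage: float = 5.0,
    rng: np.random.Generator | None = None,
):
    """Poisson read counts over centromeric arrays with known true sizes.

    ``sample_genotypes`` maps sample -> {chrom: tuple of cenhap labels}
    (two labels for diploid chromosomes, one for hemizygous male chrX);
    ``lineage_sizes`` maps (chrom, label) -> true array size in arbitrary
    units.  Counts are Poisson(coverage x summed size); the chr1 unique
    coverage estimate fluctuates around ``coverage`` with Poisson noise.
    Returns (counts DataFrame, truth DataFrame).
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    truth = []
    depth_sites = 2000  # pseudo-sites over which chr1 coverage is averaged
    for sample, per_chrom in sample_genotypes.items():
        cov = rng.poisson(coverage * depth_sites) / depth_sites
        for chrom, labels in per_chrom.items():
            size = float(sum(lineage_sizes[(chrom, lab)] for lab in labels))
            count = int(rng.poisson(coverage * size))
            rows.append((sample, chrom, count, cov))
            truth.append((sample, chrom, size, "_".join(str(l) for l in sorted(labels))))
    counts = pd.DataFrame(rows, columns=["sample", "chrom", "cen_count", "chr1_mean_cov"])
    truth = pd.DataFrame(truth, columns=["sample", "chrom", "true_size", "genotype"])
    return counts, truth
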