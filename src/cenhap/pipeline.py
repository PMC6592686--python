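"""Config-driven orchestration: extract -> filter -> cluster -> archaic
-> divergence -> arraysize.

The pipeline runs either on a synthetic preset (the generator in
:mod:`cenhap.simulate` produces every input with known truth) or on
user-supplied files (VCF, archaic annotation TSV, per-gene codon FASTA,
read-count TSV).  Each stage writes plain-text artifacts (TSV, VCF,
newick) into the run directory and records them in a JSON manifest with
SHA-256 hashes; a rerun with the same config and seed is byte-identical,
and completed stages are skipped when resuming.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import archaic as archaic_mod
from . import array_size as arr_mod
from . import clustering as clus_mod
from . import divergence as div_mod
from . import fourgt as fourgt_mod
from . import genotype_io as gio
from . import simulate as sim_mod

logger = logging.getLogger("cenhap")

STAGES = ("extract", "filter", "cluster", "archaic", "divergence", "arraysize")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Run settings; see ``validate_config`` for the constraints."""

    seed: int = 0
    simulate: dict | None = None
    vcf: str | None = None
    region: str | None = None
    min_mac: int = 0
    ploidy_mode: str = "haploid-male-X"
    masks: str | None = None
    filter: dict = field(default_factory=lambda: {"windows": [10, 20, 30, 40], "tolerance": 0})
    cluster: dict = field(default_factory=lambda: {"k": 3})
    archaic: dict = field(default_factory=dict)
    divergence: dict = field(default_factory=dict)
    arraysize: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every validation error (empty list means the config is ok)."""
    errors: list[str] = []
    if config.simulate is None and config.vcf is None:
        errors.append("either 'simulate' or 'vcf' must be given")
    if config.vcf is not None and config.region is None:
        errors.append("'region' is required with 'vcf'")
    if config.min_mac < 0:
        errors.append("min_mac must be >= 0")
    tol = config.filter.get("tolerance", 0)
    if tol < 0:
        errors.append("filter.tolerance must be >= 0")
    windows = config.filter.get("windows", [])
    if any(b <= a for a, b in zip(windows, windows[1:])):
        errors.append("filter.windows must be strictly increasing")
    if "k" in config.cluster and config.cluster["k"] < 1:
        errors.append("cluster.k must be >= 1")
    iv = config.cluster.get("central")
    if iv is not None:
        for a, b in (("p_c", "p_end"), ("q_begin", "q_c")):
            if a in iv and b in iv and iv[b] < iv[a]:
                errors.append(f"cluster.central: {b} < {a}")
    if config.vcf is not None and not Path(config.vcf).exists():
        errors.append(f"vcf not found: {config.vcf}")
    if config.masks is not None and not Path(config.masks).exists():
        errors.append(f"masks not found: {config.masks}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class _Run:
    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.manifest_path = outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "config": config.__dict__}

    def done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        return bool(info) and all(
            (self.outdir / f).exists() for f in info["outputs"]
        )

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [str(p.relative_to(self.outdir)) for p in outputs],
            "sha256": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; returns the manifest dictionary.

    Stage failures raise with the stage name; artifacts of completed
    stages stay on disk and are reused when the run is repeated.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    state: dict = {}

    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](run, state)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return run.manifest


def _stage_seed(config: PipelineConfig, offset: int) -> int:
    return (int(config.seed) * 1000 + offset) % (2**31 - 1)


def _sim_inputs(run: _Run, state: dict) -> None:
    """Generate the synthetic dataset once and cache it in ``state``."""
    if "drop" in state:
        return
    cfg = run.config
    sim = dict(cfg.simulate or {})
    n_sites = sim.pop("n_sites", 600)
    error_rate = sim.pop("genotyping_error_rate", None)
    params = sim_mod.paper_like_params(seed=_stage_seed(cfg, 1), **sim)
    if error_rate is not None:
        params.genotyping_error_rate = error_rate
    rng = np.random.default_rng(params.seed)
    gen = sim_mod.simulate_genealogy(params, rng)
    drop = sim_mod.drop_mutations(gen, n_sites=n_sites, rng=rng)
    matrix, flips = sim_mod.inject_errors(
        drop.matrix, params.genotyping_error_rate, rng
    )
    state.update(
        {"params": params, "gen": gen, "drop": drop, "matrix": matrix, "flips": flips}
    )


def _stage_extract(run: _Run, state: dict) -> None:
    cfg = run.config
    if cfg.simulate is not None:
        _sim_inputs(run, state)
        matrix = state["matrix"]
        if cfg.min_mac > 0:
            matrix = matrix.take_sites(np.flatnonzero(matrix.macs() >= cfg.min_mac))
    else:
        masks = gio.MaskSet.from_bed(cfg.masks) if cfg.masks else None
        matrix = gio.read_vcf_region(
            cfg.vcf, cfg.region, cfg.min_mac, masks, cfg.ploidy_mode
        )
    state["matrix"] = matrix
    if run.done("extract"):
        return
    vcf = run.outdir / "extracted.vcf"
    sites = run.outdir / "sites.tsv"
    gio.write_vcf(matrix, vcf)
    _write_tsv(matrix.site_table(), sites)
    run.record("extract", [vcf, sites])


def _stage_filter(run: _Run, state: dict) -> None:
    cfg = run.config
    fconf = fourgt_mod.FilterConfig(
        windows=tuple(cfg.filter.get("windows", (10, 20, 30, 40))),
        tolerance=int(cfg.filter.get("tolerance", 0)),
    )
    prefilter = state["matrix"]
    result = fourgt_mod.fourgt_dco(prefilter, fconf)
    state["matrix"] = prefilter.take_sites(result.surviving)
    state["filter_result"] = result
    if run.done("filter"):
        return
    removal = run.outdir / "removed_sites.tsv"
    vcf = run.outdir / "filtered.vcf"
    _write_tsv(result.removal_table(prefilter), removal)
    gio.write_vcf(state["matrix"], vcf)
    run.record("filter", [removal, vcf])


def _stage_cluster(run: _Run, state: dict) -> None:
    cfg = run.config
    matrix = state["matrix"]
    central = cfg.cluster.get("central")
    if central is not None:
        subset = gio.central_subset(
            matrix,
            (central["p_c"], central["p_end"]),
            (central["q_begin"], central["q_c"]),
        )
    else:
        subset = np.arange(matrix.n_sites)
    tree = clus_mod.upgma(clus_mod.hamming_matrix(matrix, subset))
    if "height" in cfg.cluster:
        part = clus_mod.cut_tree(tree, height=cfg.cluster["height"])
    else:
        part = clus_mod.cut_tree(tree, k=int(cfg.cluster.get("k", 3)))
    state["tree"], state["partition"], state["central_subset"] = tree, part, subset
    if run.done("cluster"):
        return
    part_path = run.outdir / "partition.tsv"
    nwk = run.outdir / "upgma.nwk"
    _write_tsv(part.to_frame(), part_path)
    nwk.write_text(tree.newick() + "\n")
    run.record("cluster", [part_path, nwk])


def _stage_archaic(run: _Run, state: dict) -> None:
    cfg = run.config
    if cfg.simulate is not None:
        annot = archaic_mod.ArchaicAnnotation(
            sim_mod.emit_archaic_annotation(state["drop"])
        )
    else:
        path = cfg.archaic.get("annotation")
        if path is None:
            logger.info("archaic stage skipped: no annotation provided")
            run.record("archaic", [])
            return
        annot = archaic_mod.read_annotation_tsv(path)
    region = cfg.archaic.get("region")
    counts = archaic_mod.count_archaic(
        state["matrix"], annot, tuple(region) if region else None
    )
    summary = archaic_mod.summarize_by_cenhap(counts, state["partition"])
    state["archaic_summary"] = summary
    if run.done("archaic"):
        return
    path = run.outdir / "archaic_summary.tsv"
    _write_tsv(summary, path)
    run.record("archaic", [path])


def _group_members(state: dict, max_per_group: int, rng) -> dict[int, list[str]]:
    part = state["partition"]
    out = {}
    for g in part.labels:
        members = sorted(part.members(g))
        if len(members) > max_per_group:
            members = sorted(rng.choice(members, size=max_per_group, replace=False))
        out[g] = members
    return out


def per_gene_group_ds(alignments, group_members, outgroup_label="outgroup"):
    """Per-gene symmetric group-mean dS matrices including the outgroup."""
    per_gene = {}
    labels = sorted(group_members)
    order = [str(l) for l in labels] + [outgroup_label]
    for aln in alignments:
        mat = pd.DataFrame(0.0, index=order, columns=order)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ds, _ = div_mod.group_divergence(
                    aln, group_members[a], group_members[b]
                )
                mat.loc[str(a), str(b)] = mat.loc[str(b), str(a)] = ds
            ds, _ = div_mod.group_divergence(
                aln, group_members[a], [aln.outgroup_id]
            )
            mat.loc[str(a), outgroup_label] = mat.loc[outgroup_label, str(a)] = ds
        per_gene[aln.gene_id] = mat
    return per_gene


def _stage_divergence(run: _Run, state: dict) -> None:
    cfg = run.config
    dcfg = dict(cfg.divergence)
    calibration = float(dcfg.get("calibration", 6.5e6))
    rng = np.random.default_rng(_stage_seed(cfg, 5))
    if cfg.simulate is not None:
        members = _group_members(state, int(dcfg.get("max_per_group", 6)), rng)
        tip_names = sorted({h for m in members.values() for h in m})
        alignments = sim_mod.simulate_codons(
            state["gen"],
            n_genes=int(dcfg.get("n_genes", 8)),
            codons_per_gene=int(dcfg.get("codons_per_gene", 120)),
            mutation_rate=float(dcfg.get("mutation_rate", 1e-7)),
            rng=rng,
            tip_names=tip_names,
        )
    else:
        genes_dir = dcfg.get("genes_dir")
        if genes_dir is None:
            logger.info("divergence stage skipped: no genes provided")
            run.record("divergence", [])
            return
        alignments = [
            div_mod.read_codon_fasta(p, gene_id=p.stem)
            for p in sorted(Path(genes_dir).glob("*.fa*"))
        ]
        members = _group_members(state, int(dcfg.get("max_per_group", 6)), rng)

    per_gene = per_gene_group_ds(alignments, members)
    ttree = div_mod.tmrca_tree(per_gene, calibration_age=calibration)

    gene_rows = []
    for aln in alignments:
        ingroup = [h for m in members.values() for h in m if h in aln.sequences]
        pis, pin = (
            div_mod.group_diversity(aln, ingroup) if len(ingroup) >= 2 else (0.0, 0.0)
        )
        out_ds = np.mean(
            [per_gene[aln.gene_id].loc[str(g), "outgroup"] for g in members]
        )
        gene_rows.append(
            {"gene": aln.gene_id, "syn_div": out_ds, "syn_pi": pis, "nonsyn_pi": pin}
        )
    genes_df = pd.DataFrame(gene_rows)
    state["tmrca_tree"] = ttree
    state["gene_table"] = genes_df
    if run.done("divergence"):
        return
    gt = run.outdir / "gene_table.tsv"
    nodes = run.outdir / "tmrca_nodes.tsv"
    nwk = run.outdir / "tmrca.nwk"
    _write_tsv(genes_df, gt)
    nodes_df = ttree.nodes.copy()
    nodes_df["members"] = nodes_df["members"].apply(lambda s: ",".join(sorted(s)))
    _write_tsv(nodes_df, nodes)
    nwk.write_text(ttree.newick() + "\n")
    run.record("divergence", [gt, nodes, nwk])


def _stage_arraysize(run: _Run, state: dict) -> None:
    cfg = run.config
    acfg = dict(cfg.arraysize)
    rng = np.random.default_rng(_stage_seed(cfg, 6))
    part = state["partition"]
    if cfg.simulate is not None:
        # hemizygous haploid samples: one haplotype, one array
        sizes = acfg.get("lineage_sizes")
        if sizes is None:
            sizes = {str(g): 80.0 + 20.0 * i for i, g in enumerate(part.labels)}
        lineage_sizes = {("chrSim", str(g)): float(s) for g, s in sizes.items()}
        genotypes = {
            h: {"chrSim": (str(part.assignment[h]),)} for h in part.assignment
        }
        counts, truth = sim_mod.simulate_array_counts(
            genotypes, lineage_sizes, coverage=float(acfg.get("coverage", 5.0)), rng=rng
        )
        genotype_labels = truth.set_index("sample")["genotype"]
    else:
        path = acfg.get("counts")
        if path is None:
            logger.info("arraysize stage skipped: no counts provided")
            run.record("arraysize", [])
            return
        counts = pd.read_csv(path, sep="\t")
        genotype_labels = pd.read_csv(
            acfg["genotypes"], sep="\t", index_col="sample"
        )["genotype"]
    table = arr_mod.ArrayCountTable.from_counts(counts)
    chrom = acfg.get("chrom", table.table["chrom"].iloc[0])
    sizes = table.table[table.table["chrom"] == chrom]
    summary = arr_mod.summarize_by_genotype(sizes, genotype_labels)
    state["array_summary"] = summary
    if run.done("arraysize"):
        return
    norm = run.outdir / "array_sizes.tsv"
    summ = run.outdir / "array_summary.tsv"
    _write_tsv(table.table, norm)
    _write_tsv(summary.summary, summ)
    run.record("arraysize", [norm, summ])


_STAGE_FUNCS = {
    "extract": _stage_extract,
    "filter": _stage_filter,
    "cluster": _stage_cluster,
    "archaic": _stage_archaic,
    "divergence": _stage_divergence,
    "arraysize": _stage_arraysize,
}
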