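"""End-to-end comparative pipeline: simulate → orthologs → DE → scan → network.

Each stage reads its inputs from and writes its outputs to a working
directory, so stages are individually re-runnable from persisted
intermediates.  ``run_pipeline`` chains them and writes a machine-readable
``summary.json`` (concordance percentages, density class counts, core regulon
sizes, fragmentation reports) whose bytes are a pure function of config and
seed.  Any stage failure aborts with the stage name and input paths in the
error message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io as cio
from .cis import (
    DENSITY_WINDOW,
    MotifDef,
    density_table,
    positional_enrichment,
    scan_motifs,
)
from .expression import (
    de_table,
    estimate_dispersion,
    nb_kmeans,
    normalize,
    ortholog_concordance,
)
from .network import (
    assemble_regulon,
    coexpression_edges,
    core_regulon,
    export_graph,
    fc_profiles,
    fragmentation,
    select_network_genes,
)
from .orthologs import resolve_many_to_one
from .phenotype import phenotype_table
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Pipeline settings; ``synth`` holds generator overrides."""

    seed: int = 7
    outdir: str = "coldregulon_out"
    synth: dict = field(default_factory=dict)
    lfc_threshold: float = 2.0
    p_threshold: float = 0.01
    k: int = 8
    run_clustering: bool = True
    r_min: float = 0.8
    r_core: float = 0.9
    hub_id: str | None = None
    density_motif_name: str = "BRRE"
    density_motif_iupac: str = "CGTGYG"
    density_window: tuple[int, int] = DENSITY_WINDOW

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.density_window = tuple(cfg.density_window)  # type: ignore[assignment]
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["density_window"] = list(self.density_window)
        return d

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def synth_config(self) -> SynthConfig:
        synth = dict(self.synth)
        synth.setdefault("seed", self.seed)
        for key in ("timepoints_hr", "lib_size_range", "focus_window", "plant_window",
                    "baseline_range", "regulon_baseline_range"):
            if key in synth:
                synth[key] = tuple(synth[key])
        return SynthConfig(**synth)


def _stage(name: str):
    def deco(fn):
        def wrapped(cfg: PipelineConfig, workdir: Path, *a, **kw):
            try:
                return fn(cfg, workdir, *a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed in {workdir}: {exc}") from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, workdir: Path) -> None:
    """Generate the synthetic dataset and persist all raw inputs + truth."""
    cm_a, cm_b, pairs, promoters, truth = generate_dataset(cfg.synth_config())
    cio.write_counts(cm_a, workdir / "counts_A.tsv")
    cio.write_counts(cm_b, workdir / "counts_B.tsv")
    cio.write_pairs(pairs, workdir / "ortholog_candidates.tsv")
    cio.write_promoters(promoters, workdir / "promoters_A.fasta")
    truth_json = {
        "hub_id": truth.hub_id,
        "regulon_members": sorted(truth.regulon_members),
        "fragmented_blocks": [sorted(b) for b in truth.fragmented_blocks],
        "de_genes": {k: sorted(v) for k, v in truth.de_genes_by_genotype.items()},
        "up_genes": {k: sorted(v) for k, v in truth.up_genes_by_genotype.items()},
        "cluster_labels": truth.cluster_labels,
        "ortholog_of": truth.ortholog_of,
        "planted_motifs": {
            f"{g}|{m}": pos for (g, m), pos in truth.planted_motif_positions.items()
        },
    }
    (workdir / "truth.json").write_text(json.dumps(truth_json, sort_keys=True, indent=1))


@_stage("orthologs")
def stage_orthologs(cfg: PipelineConfig, workdir: Path) -> None:
    """Resolve many-to-one candidate pairs into a one-to-one ortholog map."""
    candidates = cio.read_pairs(workdir / "ortholog_candidates.tsv")
    cio.write_pairs(resolve_many_to_one(candidates), workdir / "ortholog_pairs.tsv")


@_stage("de")
def stage_de(cfg: PipelineConfig, workdir: Path) -> None:
    """Normalize, estimate dispersion, and test DE per genotype."""
    for genotype in ("A", "B"):
        cm = cio.read_counts(workdir / f"counts_{genotype}.tsv")
        norm, factors = normalize(cm.counts)
        alpha = estimate_dispersion(norm, cm.samples)
        de = de_table(
            norm,
            cm.samples,
            genotype,
            alpha,
            lfc_threshold=cfg.lfc_threshold,
            p_threshold=cfg.p_threshold,
        )
        de.index.name = "gene_id"
        de.to_csv(workdir / f"de_{genotype}.tsv", sep="\t")
        factors.to_csv(workdir / f"size_factors_{genotype}.tsv", sep="\t")
        norm.index.name = "gene_id"
        norm.to_csv(workdir / f"normalized_{genotype}.tsv", sep="\t", float_format="%.6g")


@_stage("cluster")
def stage_cluster(cfg: PipelineConfig, workdir: Path) -> dict:
    """NB model-based K-means on genotype-A per-timepoint mean profiles."""
    cm = cio.read_counts(workdir / "counts_A.tsv")
    norm, _ = normalize(cm.counts)
    alpha = estimate_dispersion(norm, cm.samples)
    timepoints = sorted(cm.samples["timepoint_hr"].unique())
    profiles = pd.DataFrame(
        {t: norm[cm.samples.index[cm.samples["timepoint_hr"] == t]].mean(axis=1) for t in timepoints}
    )
    result = nb_kmeans(profiles, k=cfg.k, alpha=alpha, seed=cfg.seed)
    out = result.labels.to_frame()
    out.index.name = "gene_id"
    out.to_csv(workdir / "clusters_A.tsv", sep="\t")
    return {"k": cfg.k, "n_iterations": result.n_iterations}


@_stage("scan")
def stage_scan(cfg: PipelineConfig, workdir: Path) -> None:
    """Scan promoters, score positional enrichment, classify motif density."""
    promoters = cio.read_promoters(workdir / "promoters_A.fasta")
    motif = MotifDef(cfg.density_motif_name, cfg.density_motif_iupac, "hub")
    hits = scan_motifs(promoters, [motif])
    cio.write_hits(hits, workdir / "motif_hits_A.tsv")
    de_a = pd.read_csv(workdir / "de_A.tsv", sep="\t", index_col="gene_id")
    genes = [p.gene_id for p in promoters]
    upregulated = set(de_a.index[de_a["response_class"] == "up"]) & set(genes)
    scores = positional_enrichment(hits, upregulated, set(genes), p_threshold=cfg.p_threshold)
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(
        workdir / "motif_scores_A.tsv", sep="\t", index=False
    )
    dens = density_table(hits, cfg.density_motif_name, genes, window=cfg.density_window)
    dens.to_csv(workdir / "motif_density_A.tsv", sep="\t", index=False)


@_stage("network")
def stage_network(cfg: PipelineConfig, workdir: Path) -> dict:
    """Assemble hub regulons for both genotypes and quantify fragmentation."""
    de = {
        gt: pd.read_csv(workdir / f"de_{gt}.tsv", sep="\t", index_col="gene_id")
        for gt in ("A", "B")
    }
    dens = pd.read_csv(workdir / "motif_density_A.tsv", sep="\t", index_col="gene_id")
    pairs = cio.read_pairs(workdir / "ortholog_pairs.tsv")
    a_to_b = {p.locus_a: p.locus_b for p in pairs}

    selected = select_network_genes(
        dens["density_class"].to_dict(), de["A"]["response_class"].to_dict()
    )
    hub = cfg.hub_id
    if hub is None:
        truth_path = workdir / "truth.json"
        if truth_path.exists():
            hub = json.loads(truth_path.read_text())["hub_id"]
        elif selected:  # densest upregulated gene as the presumptive hub
            hub = dens.loc[sorted(selected)]["count"].idxmax()
    if hub is None or (hub not in selected and hub not in de["A"].index):
        raise ValueError("no hub gene available; set hub_id in the config")

    nodes_a = sorted(selected | {hub})
    prof_a = fc_profiles(de["A"])
    edges_a = coexpression_edges(prof_a, nodes_a, cfg.r_min)
    net_a = assemble_regulon(edges_a, nodes_a, hub)
    frag_a = fragmentation(edges_a, nodes_a, hub)
    core_a = core_regulon(net_a, cfg.r_core)

    nodes_b = sorted({a_to_b[g] for g in nodes_a if g in a_to_b})
    hub_b = a_to_b.get(hub)
    prof_b = fc_profiles(de["B"])
    edges_b = coexpression_edges(prof_b, nodes_b, cfg.r_min)
    if hub_b is None:
        raise ValueError(f"hub {hub} has no ortholog in genotype B")
    net_b = assemble_regulon(edges_b, nodes_b, hub_b)
    frag_b = fragmentation(edges_b, nodes_b, hub_b)
    core_b = core_regulon(net_b, cfg.r_core)

    report = {}
    for gt, net, frag, core in (("A", net_a, frag_a, core_a), ("B", net_b, frag_b, core_b)):
        export_graph(
            net,
            str(workdir / f"network_{gt}.graphml"),
            str(workdir / f"network_{gt}_edges.tsv"),
            node_attrs={"response_class": de[gt]["response_class"].to_dict()},
        )
        report[gt] = {
            "hub": net.hub_id,
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_components": frag.n_components,
            "largest_component_fraction": round(frag.largest_component_fraction, 6),
            "hub_degree": frag.hub_degree,
            "hub_coupled_fraction": round(frag.hub_coupled_fraction, 6),
            "intact": frag.intact,
            "core_size": len(core),
        }
    rows = [dict(genotype=gt, **vals) for gt, vals in report.items()]
    pd.DataFrame(rows).to_csv(workdir / "network_report.tsv", sep="\t", index=False)
    return report


@_stage("phenotype")
def stage_phenotype(cfg: PipelineConfig, workdir: Path) -> None:
    """Summarize ELI/SES from leakage (and optional recovery) tables."""
    leak_path = workdir / "leakage.tsv"
    if not leak_path.exists():
        logger.info("no leakage.tsv in %s; phenotype stage skipped", workdir)
        return
    leakage = pd.read_csv(leak_path, sep="\t")
    rec_path = workdir / "recovery.tsv"
    recovery = pd.read_csv(rec_path, sep="\t") if rec_path.exists() else None
    phenotype_table(leakage, recovery).to_csv(workdir / "phenotype.tsv", sep="\t", index=False)


STAGES = {
    "simulate": stage_simulate,
    "orthologs": stage_orthologs,
    "de": stage_de,
    "cluster": stage_cluster,
    "scan": stage_scan,
    "network": stage_network,
    "phenotype": stage_phenotype,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write a deterministic ``summary.json``."""
    workdir = Path(config.outdir)
    workdir.mkdir(parents=True, exist_ok=True)

    stage_simulate(config, workdir)
    stage_orthologs(config, workdir)
    stage_de(config, workdir)
    cluster_info = stage_cluster(config, workdir) if config.run_clustering else None
    stage_scan(config, workdir)
    network_report = stage_network(config, workdir)
    stage_phenotype(config, workdir)

    de = {
        gt: pd.read_csv(workdir / f"de_{gt}.tsv", sep="\t", index_col="gene_id")
        for gt in ("A", "B")
    }
    pairs = cio.read_pairs(workdir / "ortholog_pairs.tsv")
    conc = ortholog_concordance(
        de["A"]["response_class"].to_dict(), de["B"]["response_class"].to_dict(), pairs
    )
    dens = pd.read_csv(workdir / "motif_density_A.tsv", sep="\t")
    dens_counts = dens["density_class"].value_counts().to_dict()
    scores = pd.read_csv(workdir / "motif_scores_A.tsv", sep="\t")

    summary = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_genes": int(len(de["A"])),
        "n_ortholog_pairs": len(pairs),
        "de_counts": {
            gt: de[gt]["response_class"].value_counts().reindex(
                ["up", "down", "unchanged"], fill_value=0
            ).astype(int).to_dict()
            for gt in ("A", "B")
        },
        "concordance": {
            "pct_a_up_also_b": round(conc.pct_a_up_also_b, 3),
            "pct_b_up_also_a": round(conc.pct_b_up_also_a, 3),
            "n_pairs": conc.n_pairs,
            "n_excluded": conc.n_excluded,
        },
        "clusters": cluster_info,
        "enrichment": {
            "n_high_score_motifs": int(scores.groupby("motif")["high_score"].any().sum())
        },
        "density_class_counts": {
            cls: int(dens_counts.get(cls, 0)) for cls in ("low", "high", "very_high")
        },
        "network": network_report,
    }
    (workdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1) + "\n")
    return summary
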