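"""Canned validation experiments on planted-truth synthetic data.

Each function builds its own synthetic inputs with a caller-supplied seed,
runs the relevant pipeline stages, and returns the measured quantity:
statistical calibration (type-I error of the NB LRT, false-positive rate of
the ELI injury flag), planted-structure recovery (cluster shapes, DE
concordance, regulon membership), and the intact-vs-fragmented network
contrast.  The problem sizes are the package's standard validation
conditions and are documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cis import MotifDef, density_table, scan_motifs
from .expression import (
    de_table,
    de_test,
    estimate_dispersion,
    nb_kmeans,
    normalize,
    ortholog_concordance,
)
from .network import (
    assemble_regulon,
    coexpression_edges,
    fc_profiles,
    fragmentation,
    select_network_genes,
)
from .phenotype import LeakageRecord, compute_eli
from .synth import CLUSTER_SHAPES, SynthConfig, generate_dataset, simulate_counts

__all__ = [
    "null_type1_rate",
    "eli_false_positive_rate",
    "kmeans_recovery_ari",
    "concordance_recovery",
    "regulon_recovery",
    "intact_vs_fragmented",
]

_TWO_GROUP_SAMPLES = pd.DataFrame(
    [("A", t, r) for t in (0, 24) for r in (1, 2, 3)],
    index=[f"A_{t}h_r{r}" for t in (0, 24) for r in (1, 2, 3)],
    columns=["genotype", "timepoint_hr", "replicate"],
)


def null_type1_rate(
    seed: int,
    n_genes: int = 2000,
    alpha: float = 0.1,
    p_threshold: float = 0.01,
) -> float:
    """Fraction of null genes (no effect, 3 vs 3 replicates) called at p<0.01.

    Dispersion is re-estimated from the data exactly as the pipeline does, so
    the rate reflects the full plug-in procedure, not the known truth.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(20), np.log(500), n_genes))
    r = 1.0 / alpha
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, 6)).astype(float)
    norm = pd.DataFrame(counts, columns=_TWO_GROUP_SAMPLES.index)
    a_hat = estimate_dispersion(norm, _TWO_GROUP_SAMPLES)
    res = de_test(norm, _TWO_GROUP_SAMPLES, "A", 24, a_hat)
    return float((res["p"] < p_threshold).mean())


def eli_false_positive_rate(
    seed: int,
    n_sim: int = 1000,
    n_rep: int = 6,
    mean: float = 0.3,
    sd: float = 0.05,
) -> float:
    """Injury-flag rate when stress and control leakage share the same mean."""
    rng = np.random.default_rng(seed)
    flags = 0
    for _ in range(n_sim):
        control = np.clip(rng.normal(mean, sd, n_rep), 0.0, 1.0)
        stress = np.clip(rng.normal(mean, sd, n_rep), 0.0, 1.0)
        records = [
            LeakageRecord("acc", "control", i, float(v)) for i, v in enumerate(control)
        ] + [LeakageRecord("acc", "stress", i, float(v)) for i, v in enumerate(stress)]
        flags += compute_eli(records).eli_significant
    return flags / n_sim


def kmeans_recovery_ari(
    seed: int,
    genes_per_cluster: int = 50,
    alpha: float = 0.1,
    log2fc: float = 3.0,
) -> float:
    """ARI of NB K-means labels vs the 8 planted temporal shapes."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for sid, shape in CLUSTER_SHAPES.items():
        for _ in range(genes_per_cluster):
            mu0 = float(np.exp(rng.uniform(np.log(50), np.log(500))))
            means = mu0 * 2.0 ** (log2fc * np.concatenate([[0.0], shape]))
            counts = simulate_counts(means, alpha, np.ones(15), rng)
            rows.append(counts.reshape(5, 3).mean(axis=1))
            labels.append(sid)
    profiles = pd.DataFrame(rows)
    result = nb_kmeans(profiles, k=8, alpha=alpha, seed=seed)
    return float(adjusted_rand_score(labels, result.labels))


def concordance_recovery(seed: int, n_genes: int = 2000) -> tuple[float, float]:
    """(estimated, planted) percent of A-upregulated genes also up in B.

    The generator plants a 50% DE overlap between genotypes; the estimate
    runs the full normalize → dispersion → LRT → classify → concordance path
    over the true ortholog pairs.
    """
    cfg = SynthConfig(
        n_genes=n_genes, de_fraction=0.5, de_overlap=0.5, regulon_size=40, seed=seed
    )
    cm_a, cm_b, pairs, _, truth = generate_dataset(cfg, with_promoters=False)
    classes = {}
    for gt, cm in (("A", cm_a), ("B", cm_b)):
        norm, _ = normalize(cm.counts)
        a_hat = estimate_dispersion(norm, cm.samples)
        classes[gt] = de_table(norm, cm.samples, gt, a_hat)["response_class"].to_dict()
    one_to_one = [p for p in pairs if not p.locus_a.startswith("GA_par")]
    conc = ortholog_concordance(classes["A"], classes["B"], one_to_one)
    up_a = truth.up_genes_by_genotype["A"]
    up_b = truth.up_genes_by_genotype["B"]
    planted = 100.0 * sum(truth.ortholog_of[g] in up_b for g in up_a) / len(up_a)
    return conc.pct_a_up_also_b, planted


def _network_nodes(config: SynthConfig, seed: int):
    """generate → DE → scan → density+DE selection for both genotypes."""
    cfg = SynthConfig(**{**config.__dict__, "seed": seed})
    cm_a, cm_b, pairs, promoters, truth = generate_dataset(cfg)
    de = {}
    for gt, cm in (("A", cm_a), ("B", cm_b)):
        norm, _ = normalize(cm.counts)
        a_hat = estimate_dispersion(norm, cm.samples)
        de[gt] = de_table(norm, cm.samples, gt, a_hat)
    motif_iupac = next(iter(cfg.motif_densities))
    hits = scan_motifs(promoters, [MotifDef("hubmotif", motif_iupac)])
    dens = density_table(hits, "hubmotif", [p.gene_id for p in promoters])
    selected = select_network_genes(
        dens.set_index("gene_id")["density_class"].to_dict(),
        de["A"]["response_class"].to_dict(),
    )
    return de, selected, truth


def regulon_recovery(
    seed: int,
    n_noise_genes: int = 400,
    regulon_size: int = 40,
    regulon_corr: float = 0.95,
    r_min: float = 0.8,
) -> tuple[float, float]:
    """(precision, recall) of recovered regulon membership vs planted truth.

    Recovery = the hub plus all hub-coupled (tier ≤ 3) nodes of the network
    assembled over density+DE-selected genes at ``r_min``.
    """
    n = n_noise_genes + regulon_size
    cfg = SynthConfig(
        n_genes=n,
        de_fraction=regulon_size / n,
        regulon_size=regulon_size,
        regulon_corr=regulon_corr,
        seed=seed,
    )
    de, selected, truth = _network_nodes(cfg, seed)
    nodes = sorted(selected | {truth.hub_id})
    edges = coexpression_edges(fc_profiles(de["A"]), nodes, r_min)
    net = assemble_regulon(edges, nodes, truth.hub_id)
    recovered = {g for g, tier in net.tiers.items() if tier != "unlinked"}
    tp = len(recovered & truth.regulon_members)
    precision = tp / len(recovered) if recovered else 0.0
    recall = tp / len(truth.regulon_members)
    return precision, recall


def intact_vs_fragmented(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 200,
    r_min: float = 0.8,
) -> dict:
    """Repeat the end-to-end planted intact-vs-fragmented contrast.

    Each run regenerates a dataset (new seed), selects network genes by
    density and upregulation, builds co-expression graphs for both genotypes
    from estimated fold-change profiles, and records the component counts.
    Success = genotype A yields one component and genotype B at least three.
    """
    base = SynthConfig(n_genes=n_genes, de_fraction=0.4, regulon_size=40, fragment_into=3)
    root = np.random.default_rng(seed)
    successes = 0
    comp_a, comp_b = [], []
    for _ in range(n_runs):
        run_seed = int(root.integers(2**31))
        de, selected, truth = _network_nodes(base, run_seed)
        nodes_a = sorted(selected | {truth.hub_id})
        nodes_b = sorted(truth.ortholog_of[g] for g in nodes_a)
        frag_a = fragmentation(
            coexpression_edges(fc_profiles(de["A"]), nodes_a, r_min), nodes_a, truth.hub_id
        )
        frag_b = fragmentation(
            coexpression_edges(fc_profiles(de["B"]), nodes_b, r_min),
            nodes_b,
            truth.ortholog_of[truth.hub_id],
        )
        comp_a.append(frag_a.n_components)
        comp_b.append(frag_b.n_components)
        successes += frag_a.n_components == 1 and frag_b.n_components >= 3
    return {
        "success_rate": successes / n_runs,
        "n_runs": n_runs,
        "median_components_a": float(np.median(comp_a)),
        "median_components_b": float(np.median(comp_b)),
    }
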