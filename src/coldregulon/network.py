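"""Hub-centered co-expression regulons and their fragmentation metrics.

Genes selected for dense hub-binding motifs (BRRE) and cold upregulation are
joined by edges where the Pearson correlation of their 4-point log2
fold-change profiles reaches ``r_min``.  Breadth-first tiers from the hub
(primary/secondary/tertiary; deeper collapsed to tertiary) describe the
regulon's organization; connected-component statistics quantify whether the
regulon is intact around the hub or fragmented into hub-uncoupled pieces —
the qualitative contrast between the two species' networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedEdge",
    "RegulonNetwork",
    "FragmentationReport",
    "fc_profiles",
    "coexpression_edges",
    "select_network_genes",
    "assemble_regulon",
    "core_regulon",
    "fragmentation",
    "export_graph",
]

TIER_NAMES = {0: "hub", 1: "primary", 2: "secondary", 3: "tertiary"}


@dataclass(frozen=True)
class WeightedEdge:
    """Undirected co-expression edge, stored once in canonical id order."""

    gene_u: str
    gene_v: str
    weight: float

    def __post_init__(self) -> None:
        if self.gene_u == self.gene_v:
            raise ValueError("self-edges are not allowed")
        u, v = self.gene_u, self.gene_v
        if u > v:
            object.__setattr__(self, "gene_u", v)
            object.__setattr__(self, "gene_v", u)


@dataclass
class RegulonNetwork:
    graph: nx.Graph
    hub_id: str
    tiers: dict[str, str]  # node -> hub/primary/secondary/tertiary/unlinked


@dataclass
class FragmentationReport:
    n_components: int
    largest_component_fraction: float
    hub_degree: int
    hub_coupled_fraction: float
    intact: bool


def fc_profiles(de: pd.DataFrame, n_timepoints: int = 4) -> pd.DataFrame:
    """Per-gene log2 fold-change vectors (t1..tT) from a DE table.

    Column order is fixed by the timepoint index regardless of input layout;
    genes with any missing fold change are excluded with a log message.
    """
    cols = [f"log2fc_{i}" for i in range(1, n_timepoints + 1)]
    missing = [c for c in cols if c not in de.columns]
    if missing:
        raise ValueError(f"DE table lacks fold-change columns: {missing}")
    prof = de[cols].astype(float)
    bad = prof.isna().any(axis=1)
    if bad.any():
        logger.info("excluding %d genes with missing fold changes", int(bad.sum()))
    return prof[~bad]


def coexpression_edges(
    profiles: pd.DataFrame,
    genes: Iterable[str],
    r_min: float,
) -> list[WeightedEdge]:
    """All-pairs Pearson edges at ``r ≥ r_min`` within a gene set.

    Constant profiles have undefined correlation and contribute no edges
    (logged).  Requires ≥3 profile dimensions and ``r_min`` in (0, 1).
    """
    if not 0.0 < r_min < 1.0:
        raise ValueError("r_min must be in (0, 1)")
    if profiles.shape[1] < 3:
        raise ValueError("profiles need at least 3 dimensions for correlation edges")
    genes = sorted(set(genes) & set(profiles.index))
    if len(genes) < 2:
        return []
    x = profiles.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant profiles excluded from correlation", int(constant.sum()))
    keep = np.flatnonzero(~constant)
    if len(keep) < 2:
        return []
    r = np.corrcoef(x[keep])
    edges = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            if r[a, b] >= r_min:
                edges.append(WeightedEdge(genes[keep[a]], genes[keep[b]], float(r[a, b])))
    return edges


def select_network_genes(
    density_classes: Mapping[str, str],
    response_classes: Mapping[str, str],
) -> set[str]:
    """Genes that are both motif-dense (high/very_high) and cold-upregulated."""
    selected = {
        g
        for g, dc in density_classes.items()
        if dc in ("high", "very_high") and response_classes.get(g) == "up"
    }
    if not selected:
        logger.warning("no gene passed the density + upregulation selection")
    return selected


def _build_graph(edges: Iterable[WeightedEdge], nodes: Iterable[str]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for e in edges:
        if e.gene_u in g and e.gene_v in g:
            g.add_edge(e.gene_u, e.gene_v, weight=e.weight)
    return g


def assemble_regulon(
    edges: Iterable[WeightedEdge],
    nodes: Iterable[str],
    hub_id: str,
    tier_cap: int = 3,
) -> RegulonNetwork:
    """BFS tiers from the hub; unreachable nodes stay, labeled ``unlinked``.

    Depths 1..3 map to primary/secondary/tertiary; anything deeper collapses
    to tertiary (the fragmented remainder is exactly the ``unlinked`` set).
    """
    g = _build_graph(edges, nodes)
    if hub_id not in g:
        raise ValueError(f"hub {hub_id!r} is not in the node set")
    depths = nx.single_source_shortest_path_length(g, hub_id)
    tiers = {}
    for node in g.nodes:
        if node not in depths:
            tiers[node] = "unlinked"
        else:
            tiers[node] = TIER_NAMES[min(depths[node], tier_cap)]
    return RegulonNetwork(g, hub_id, tiers)


def core_regulon(network: RegulonNetwork, r_core: float) -> set[str]:
    """Hub plus direct neighbors whose edge weight reaches ``r_core``."""
    g, hub = network.graph, network.hub_id
    core = {hub}
    for nbr in g.neighbors(hub):
        if g.edges[hub, nbr]["weight"] >= r_core:
            core.add(nbr)
    return core


def fragmentation(
    edges: Iterable[WeightedEdge],
    nodes: Iterable[str],
    hub_id: str,
) -> FragmentationReport:
    """Connected-component summary of the induced co-expression graph."""
    g = _build_graph(edges, nodes)
    if g.number_of_nodes() == 0:
        raise ValueError("node set is empty")
    components = list(nx.connected_components(g))
    hub_comp = next((c for c in components if hub_id in c), set())
    n = g.number_of_nodes()
    return FragmentationReport(
        n_components=len(components),
        largest_component_fraction=max(len(c) for c in components) / n,
        hub_degree=g.degree(hub_id) if hub_id in g else 0,
        hub_coupled_fraction=len(hub_comp) / n,
        intact=len(components) == 1,
    )


def export_graph(
    network: RegulonNetwork,
    graphml_path: str,
    edgelist_path: str | None = None,
    node_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write GraphML (+ optional edge-list TSV) with tier and weight attributes.

    Edge ``length`` is exported as ``1 − r`` so layout tools place strongly
    co-expressed genes close together.
    """
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["tier"] = network.tiers[node]
        if node_attrs:
            for attr, mapping in node_attrs.items():
                if node in mapping:
                    g.nodes[node][attr] = mapping[node]
    for u, v, data in g.edges(data=True):
        data["length"] = 1.0 - data["weight"]
    try:
        nx.write_graphml(g, graphml_path)
        if edgelist_path is not None:
            rows = [
                dict(gene_u=u, gene_v=v, weight=d["weight"], length=d["length"])
                for u, v, d in sorted(g.edges(data=True))
            ]
            pd.DataFrame(rows, columns=["gene_u", "gene_v", "weight", "length"]).to_csv(
                edgelist_path, sep="\t", index=False
            )
    except OSError as exc:
        raise OSError(f"failed writing graph files to {graphml_path}: {exc}") from exc
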