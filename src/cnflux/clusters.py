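"""Cluster-level analyses: carbon/nitrogen categorization, Fisher enrichment,
and the cluster-metabolite connectivity graph.

Coregulated gene clusters (produced upstream by biclustering) are linked to
metabolism through the model's GPRs: each cluster inherits the substrate and
product sets of its genes' reactions (currency metabolites removed), and two
clusters are connected when their sets are nearly identical — the
connectivity of a pair is the number of shared metabolites over the total in
both clusters (read as the Jaccard index), with an edge strictly above the
0.9 threshold.  Enrichment of a term in a cluster against the gene universe
uses the exact hypergeometric tails, over- ("enriched") and under-
("purified") representation, without any term-hierarchy propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import MetabolicModel, map_genes_to_reactions, reaction_sides

__all__ = [
    "ClusterSet",
    "CategoryMap",
    "EnrichmentRecord",
    "ConnectivityGraph",
    "build_category_map",
    "enrich",
    "flag_cn_clusters",
    "cluster_metabolite_sets",
    "connectivity_graph",
    "graph_topology",
]

#: subsystems whose genes count as nitrogen metabolism
NITROGEN_SUBSYSTEMS = frozenset(
    {"amino acid metabolism", "nitrogen metabolism", "nucleotide metabolism",
     "urea cycle"}
)
#: subsystems whose genes count as carbon metabolism
CARBON_SUBSYSTEMS = frozenset(
    {"aldehyde degradation", "ascorbate metabolism", "butanoate metabolism",
     "calvin-benson cycle", "carbon fixation", "galactose metabolism",
     "nucleotide sugar metabolism", "oxidative phosphorylation",
     "photosynthesis", "pentose interconversions", "pentose phosphate pathway",
     "pyruvate metabolism"}
)
#: the TCA cycle bridges both macro-categories
BOTH_SUBSYSTEMS = frozenset({"tricarboxylic acid cycle"})

#: default subsystem -> display group assignment (the nine figure groups)
DEFAULT_DISPLAY_GROUPS = {
    "amino acid metabolism": "amino acid",
    "nitrogen metabolism": "amino acid",
    "urea cycle": "amino acid",
    "nucleotide metabolism": "nucleotide",
    "nucleotide sugar metabolism": "carbon",
    "aldehyde degradation": "carbon",
    "ascorbate metabolism": "carbon",
    "butanoate metabolism": "carbon",
    "calvin-benson cycle": "carbon",
    "carbon fixation": "carbon",
    "galactose metabolism": "carbon",
    "glycolysis/gluconeogenesis": "carbon",
    "pentose interconversions": "carbon",
    "pentose phosphate pathway": "carbon",
    "pyruvate metabolism": "carbon",
    "tricarboxylic acid cycle": "energy",
    "oxidative phosphorylation": "energy",
    "photosynthesis": "energy",
    "cofactor metabolism": "cofactor",
    "glycan metabolism": "glycan",
    "lipid metabolism": "lipid",
    "pigment metabolism": "pigments",
    "chlorophyll biosynthesis": "pigments",
    "carotenoid biosynthesis": "pigments",
    "transport": "transport",
}


@dataclass
class ClusterSet:
    """Cluster id -> member gene ids (optionally member conditions)."""

    clusters: dict[str, set[str]]
    conditions: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, genes in self.clusters.items():
            if not genes:
                raise ValueError(f"cluster {cid} has no member genes")

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.clusters)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.clusters.values():
            out |= genes
        return out


@dataclass
class CategoryMap:
    """Subsystem -> {carbon, nitrogen} macro-categories and display group."""

    macro: dict[str, frozenset[str]]
    display: dict[str, str]

    def macro_categories(self, subsystem: str) -> frozenset[str]:
        return self.macro.get(subsystem.strip().lower(), frozenset())

    def display_group(self, subsystem: str) -> str:
        return self.display.get(subsystem.strip().lower(), "unmapped")


@dataclass
class EnrichmentRecord:
    cluster_id: str
    term: str
    direction: str  # enriched | purified
    p_value: float
    q_value: float | None
    k: int  # in-cluster genes carrying the term
    n: int  # cluster size
    K: int  # universe genes carrying the term
    N: int  # universe size


@dataclass
class ConnectivityGraph:
    graph: nx.Graph
    side: str  # substrates | products
    threshold: float

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_category_map(
    subsystems: set[str] | None = None,
    display_lookup: dict[str, str] | None = None,
) -> CategoryMap:
    """Category map from the fixed carbon/nitrogen subsystem lists.

    Matching is case-insensitive.  ``display_lookup`` entries override or
    extend the default subsystem -> group assignment.
    """
    macro: dict[str, frozenset[str]] = {}
    for s in NITROGEN_SUBSYSTEMS:
        macro[s] = frozenset({"nitrogen"})
    for s in CARBON_SUBSYSTEMS:
        macro[s] = frozenset({"carbon"})
    for s in BOTH_SUBSYSTEMS:
        macro[s] = frozenset({"carbon", "nitrogen"})
    display = dict(DEFAULT_DISPLAY_GROUPS)
    if display_lookup:
        display.update({k.strip().lower(): v for k, v in display_lookup.items()})
    if subsystems is not None:
        known = {s.strip().lower() for s in subsystems}
        macro = {s: v for s, v in macro.items() if s in known}
        display = {s: v for s, v in display.items() if s in known}
    return CategoryMap(macro=macro, display=display)


def enrich(
    clusters: ClusterSet,
    gene_terms: dict[str, set[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Exact hypergeometric over/under-representation per (cluster, term).

    The universe defaults to the union of all cluster genes.  For each pair
    the smaller one-sided tail decides the direction (enriched or purified)
    and provides the p-value; BH-FDR is applied across all pairs.  No term
    hierarchy is modeled and no parent propagation occurs.
    """
    if universe is None:
        universe = clusters.all_genes
    offenders = sorted(clusters.all_genes - universe)
    if offenders:
        raise ValueError(f"cluster genes outside the universe: {offenders[:10]}")
    N = len(universe)
    carriers: dict[str, set[str]] = {}
    for g in universe:
        for t in gene_terms.get(g, ()):
            carriers.setdefault(t, set()).add(g)

    records: list[EnrichmentRecord] = []
    for cid in clusters.cluster_ids:
        members = clusters.clusters[cid] & universe
        n = len(members)
        for term in sorted(carriers):
            K = len(carriers[term])
            k = len(members & carriers[term])
            p_over = float(hypergeom.sf(k - 1, N, K, n))
            p_under = float(hypergeom.cdf(k, N, K, n))
            if p_over <= p_under:
                direction, p = "enriched", p_over
            else:
                direction, p = "purified", p_under
            records.append(
                EnrichmentRecord(cid, term, direction, min(p, 1.0), None, k, n, K, N)
            )
    from .shifttest import bh_adjust

    q = bh_adjust([r.p_value for r in records])
    for r, qv in zip(records, q):
        r.q_value = float(qv)
    return records


def flag_cn_clusters(
    records: list[EnrichmentRecord],
    cmap: CategoryMap,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Per-cluster carbon/nitrogen flags from significant enrichment records.

    A cluster is flagged "carbon" (resp. "nitrogen") if any record with
    q < alpha carries a term mapping to that macro-category; both
    over-represented and under-represented ("purified") terms count.
    """
    flags: dict[str, set[str]] = {}
    for r in records:
        flags.setdefault(r.cluster_id, set())
        if r.q_value is not None and r.q_value < alpha:
            flags[r.cluster_id] |= cmap.macro_categories(r.term)
    return flags


def cluster_metabolite_sets(
    clusters: ClusterSet,
    model: MetabolicModel,
    side: str = "products",
    drop_currency: bool = True,
) -> dict[str, set[str]]:
    """Substrate or product metabolite set of each cluster.

    The union, over the cluster's genes, of the metabolites on the requested
    side of every reaction the gene participates in (reversible reactions
    contribute to both sides).  Genes without reactions contribute nothing.
    """
    if side not in ("substrates", "products"):
        raise ValueError("side must be 'substrates' or 'products'")
    gene_map = map_genes_to_reactions(model, clusters.all_genes)
    out: dict[str, set[str]] = {}
    for cid in clusters.cluster_ids:
        mets: set[str] = set()
        for g in clusters.clusters[cid]:
            for rid in gene_map.get(g, ()):
                subs, prods = reaction_sides(model, rid, drop_currency=drop_currency)
                mets |= subs if side == "substrates" else prods
        out[cid] = mets
    return out


def connectivity_graph(
    sets: dict[str, set[str]],
    threshold: float = 0.9,
    side: str = "products",
    denominator: str = "union",
) -> ConnectivityGraph:
    """Cluster graph with an edge wherever pairwise connectivity > threshold.

    Connectivity is shared metabolites over the total in both clusters; the
    total is the set union by default (the Jaccard index — with a summed
    denominator no score could exceed 0.5 and the 0.9 threshold would be
    unreachable), selectable via ``denominator``.  The inequality is strict
    and clusters with empty sets remain isolated nodes.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if denominator not in ("union", "sum"):
        raise ValueError("denominator must be 'union' or 'sum'")
    g = nx.Graph()
    ids = sorted(sets)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(sets[a] & sets[b])
            denom = (
                len(sets[a] | sets[b]) if denominator == "union"
                else len(sets[a]) + len(sets[b])
            )
            score = inter / denom if denom else 0.0
            if score > threshold:
                g.add_edge(a, b, weight=score)
    return ConnectivityGraph(graph=g, side=side, threshold=threshold)


def graph_topology(
    cg: ConnectivityGraph,
) -> tuple[list[int], dict[str, float]]:
    """Connected-component sizes (descending) and normalized betweenness.

    Betweenness is computed on the unweighted topology: edge presence, not
    score, is what the module-structure statements rest on.
    """
    sizes = sorted((len(c) for c in nx.connected_components(cg.graph)), reverse=True)
    btw = nx.betweenness_centrality(cg.graph, normalized=True, weight=None)
    return sizes, btw


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_clusters_tsv(path) -> ClusterSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"cluster_id", "gene_id"}.issubset(df.columns):
        raise ValueError(f"{path}: cluster table needs cluster_id and gene_id columns")
    clusters: dict[str, set[str]] = {}
    for row in df.itertuples():
        clusters.setdefault(row.cluster_id, set()).add(row.gene_id)
    return ClusterSet(clusters)


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    rows = [
        (cid, g)
        for cid in clusters.cluster_ids
        for g in sorted(clusters.clusters[cid])
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_terms_tsv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "term"}.issubset(df.columns):
        raise ValueError(f"{path}: term table needs gene_id and term columns")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.gene_id, set())
        if isinstance(row.term, str) and row.term:
            out[row.gene_id].add(row.term)
    return out


def write_gene_terms_tsv(gene_terms: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(gene_terms) for t in sorted(gene_terms[g])]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(records: list[EnrichmentRecord], path) -> None:
    pd.DataFrame(
        [
            (r.cluster_id, r.term, r.direction, r.p_value, r.q_value, r.k, r.n, r.K, r.N)
            for r in records
        ],
        columns=["cluster_id", "term", "direction", "p", "q", "k", "n", "K", "N"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_edges_tsv(cg: ConnectivityGraph, path) -> None:
    rows = [
        (a, b, cg.graph.edges[a, b]["weight"], cg.side)
        for a, b in sorted(cg.edges)
    ]
    pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "score", "side"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_graphml(cg: ConnectivityGraph, path) -> None:
    nx.write_graphml(cg.graph, path)
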