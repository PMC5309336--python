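"""Synthetic fixtures: a hand-solvable toy metabolic network, flux-sample
matrices with planted distribution shifts, and cluster/term tables with
planted enrichment and connectivity.

The toy network emulates the features of the diatom model that the carbon/
nitrogen analysis exercises: forced bicarbonate and nitrate uptake, a biomass
objective with a known C:N stoichiometry, a DMSP demand as the only carbon
release route, a nitrate-storage demand, and TAG/chrysolaminarin storage
demands.  Carbon is book-kept in integer units (1 cfix = 1 fixed carbon) so
conservation checks are exact: at any steady state

    c_per_biomass * v_BOF + dmsp_carbons * v_DMSP + ... = carbon uptake.

The chrysolaminarin route deliberately consumes ``chryso_penalty`` extra
carbon per unit so that parsimonious FBA always routes excess carbon through
the TAG demand — a modeling choice that makes the storage-preference
prediction deterministic, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, Metabolite, Reaction
from .sampling import FluxSampleSet

__all__ = [
    "ToyModelParams",
    "PlantedShiftSpec",
    "make_toy_model",
    "make_planted_samples",
    "make_planted_clusters",
]

ALL_DEMANDS = ("DM_dmsp_c", "DM_no3_c", "DM_tag_c", "DM_chryso_c")


@dataclass(frozen=True)
class ToyModelParams:
    c_per_biomass: float = 6.0
    n_per_biomass: float = 1.0
    dmsp_carbons: float = 5.0
    tag_carbons: float = 50.0
    chryso_carbons: float = 6.0
    chryso_penalty: float = 1.0
    include_demands: tuple[str, ...] = ALL_DEMANDS

    def __post_init__(self) -> None:
        for name in (
            "c_per_biomass", "n_per_biomass", "dmsp_carbons",
            "tag_carbons", "chryso_carbons", "chryso_penalty",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.include_demands) - set(ALL_DEMANDS)
        if unknown:
            raise ValueError(f"unknown demand ids: {sorted(unknown)}")


def make_toy_model(p: ToyModelParams = ToyModelParams()) -> MetabolicModel:
    """Two-compartment toy network with HCO3/NO3 uptake and storage demands.

    With all demands open and uptakes forced to ``(U_C, U_N)`` the biomass
    optimum is ``min(U_C / c_per_biomass, U_N / n_per_biomass)`` in closed
    form, which the LP engine must reproduce exactly.
    """
    mets = [
        Metabolite("hco3_e", "bicarbonate", "e"),
        Metabolite("no3_e", "nitrate", "e"),
        Metabolite("hco3_c", "bicarbonate", "c"),
        Metabolite("no3_c", "nitrate", "c"),
        Metabolite("cfix_c", "fixed carbon", "c"),
        Metabolite("orgN_c", "organic nitrogen", "c"),
        Metabolite("dmsp_c", "DMSP", "c"),
        Metabolite("tag_c", "triacylglycerol", "c"),
        Metabolite("chryso_c", "chrysolaminarin", "c"),
    ]
    W = 1000.0
    rxns = [
        Reaction("EX_hco3_e", {"hco3_e": -1.0}, -W, W, "gEXC", "transport",
                 "bicarbonate exchange"),
        Reaction("EX_no3_e", {"no3_e": -1.0}, -W, W, "gEXN", "transport",
                 "nitrate exchange"),
        Reaction("HCO3t", {"hco3_e": -1.0, "hco3_c": 1.0}, 0, W, "gHCO3t",
                 "transport", "bicarbonate transporter"),
        Reaction("NO3t", {"no3_e": -1.0, "no3_c": 1.0}, 0, W, "gNO3t",
                 "transport", "nitrate transporter"),
        Reaction("CFIX", {"hco3_c": -1.0, "cfix_c": 1.0}, 0, W, "gCFIX",
                 "carbon fixation", "carbon fixation"),
        Reaction("NASM", {"no3_c": -1.0, "orgN_c": 1.0}, 0, W, "gNASM",
                 "nitrogen metabolism", "nitrate assimilation"),
        Reaction("BOF", {"cfix_c": -p.c_per_biomass, "orgN_c": -p.n_per_biomass},
                 0, W, "gBOF", "biomass", "biomass objective"),
        Reaction("DMSPS", {"cfix_c": -p.dmsp_carbons, "dmsp_c": 1.0}, 0, W,
                 "gDMSP", "amino acid metabolism", "DMSP synthesis"),
        Reaction("TAGS", {"cfix_c": -p.tag_carbons, "tag_c": 1.0}, 0, W,
                 "gTAG", "lipid metabolism", "TAG synthesis"),
        Reaction("CHRYS", {"cfix_c": -(p.chryso_carbons + p.chryso_penalty),
                           "chryso_c": 1.0}, 0, W, "gCHRYS",
                 "glycan metabolism", "chrysolaminarin synthesis"),
    ]
    demand_defs = {
        "DM_dmsp_c": Reaction("DM_dmsp_c", {"dmsp_c": -1.0}, 0, W, "gDMSP",
                              "amino acid metabolism", "DMSP release demand"),
        "DM_no3_c": Reaction("DM_no3_c", {"no3_c": -1.0}, 0, W, "gNSTO",
                             "nitrogen metabolism", "nitrate storage demand"),
        "DM_tag_c": Reaction("DM_tag_c", {"tag_c": -1.0}, 0, W, "gTAG",
                             "lipid metabolism", "TAG storage demand"),
        "DM_chryso_c": Reaction("DM_chryso_c", {"chryso_c": -1.0}, 0, W,
                                "gCHRYS", "glycan metabolism",
                                "chrysolaminarin storage demand"),
    }
    for did in ALL_DEMANDS:
        if did in p.include_demands:
            rxns.append(demand_defs[did])
    return MetabolicModel(
        id="toy_cn", metabolites=mets, reactions=rxns, objective_id="BOF"
    )


# ---------------------------------------------------------------------------
# planted flux-sample fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedShiftSpec:
    """Low/high-condition sample matrices with a known set of shifted columns.

    Null columns are i.i.d. draws from the base distribution in both
    conditions; shifted columns get the high-condition mean displaced by
    ``shift_sd_units`` standard deviations.  These matrices are fixtures for
    the distribution-shift statistic and are intentionally NOT mass-balanced;
    sampler feasibility is covered separately.
    """

    n_null_reactions: int = 50
    n_shifted_reactions: int = 10
    n_samples: int = 1000
    shift_sd_units: float = 2.0
    base_distribution: str = "normal"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null_reactions < 0 or self.n_shifted_reactions < 0:
            raise ValueError("reaction counts must be >= 0")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.base_distribution not in ("normal", "lognormal"):
            raise ValueError("base_distribution must be normal or lognormal")


def make_planted_samples(
    spec: PlantedShiftSpec,
) -> tuple[FluxSampleSet, FluxSampleSet, set[str]]:
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_null_reactions + spec.n_shifted_reactions
    ids = [f"R_null_{i:03d}" for i in range(spec.n_null_reactions)] + [
        f"R_shift_{i:03d}" for i in range(spec.n_shifted_reactions)
    ]

    def draw(size):
        if spec.base_distribution == "normal":
            return rng.normal(0.0, 1.0, size)
        return rng.lognormal(0.0, 1.0, size)

    low = draw((spec.n_samples, n_total))
    high = draw((spec.n_samples, n_total))
    if spec.n_shifted_reactions:
        sd = 1.0 if spec.base_distribution == "normal" else float(
            np.exp(0.5) * np.sqrt(np.exp(1.0) - 1.0)
        )
        high[:, spec.n_null_reactions:] += spec.shift_sd_units * sd
    meta = {"seed": spec.seed, "n_points": spec.n_samples, "step_count": 0}
    shifted = {i for i in ids if i.startswith("R_shift_")}
    return (
        FluxSampleSet(list(ids), low, dict(meta, condition="low")),
        FluxSampleSet(list(ids), high, dict(meta, condition="high")),
        shifted,
    )


# ---------------------------------------------------------------------------
# planted cluster fixtures
# ---------------------------------------------------------------------------

def make_planted_clusters(
    model: MetabolicModel,
    n_clusters: int = 8,
    overlap_matrix: np.ndarray | None = None,
    enriched_terms: dict[str, str] | None = None,
    seed: int = 0,
    genes_per_cluster: int = 10,
    carriers_per_term: int = 40,
    universe_size: int = 400,
    threshold: float = 0.9,
):
    """Clusters with planted product-set overlap and planted term enrichment.

    A copy of *model* is extended with one synthetic gene and one synthetic
    product-emitting reaction per cluster, so the downstream
    genes -> reactions -> product-sets path realizes the requested pairwise
    Jaccard overlaps.  ``overlap_matrix=None`` plants random product sets.

    Returns ``(clusters, gene_terms, extended_model, truth)`` where *truth*
    has the expected edges (at *threshold*, strict), component sizes and the
    per-cluster enriched term.
    """
    from .clusters import ClusterSet

    rng = np.random.default_rng(seed)
    cluster_ids = [f"cl{i:02d}" for i in range(1, n_clusters + 1)]

    # --- product sets realizing the overlap targets -----------------------
    if overlap_matrix is not None:
        overlap_matrix = np.asarray(overlap_matrix, float)
        if overlap_matrix.shape != (n_clusters, n_clusters):
            raise ValueError("overlap_matrix must be n_clusters x n_clusters")
        sets = _sets_from_targets(overlap_matrix, n_clusters, rng)
    else:
        vocab = [f"met_{k:03d}_c" for k in range(12 * n_clusters)]
        sets = []
        for _ in range(n_clusters):
            size = int(rng.integers(6, 14))
            sets.append(set(rng.choice(vocab, size=size, replace=False)))

    # --- extend the model: one gene + one emitting reaction per cluster ---
    ext = model.copy()
    known = set(ext.metabolite_ids)
    new_mets = []
    for s in sets:
        for mid in sorted(s):
            if mid not in known:
                new_mets.append(Metabolite(mid, compartment="c"))
                known.add(mid)
    # one private source metabolite per cluster keeps substrate sets disjoint,
    # so only the product side carries the planted overlap structure
    for cid in cluster_ids:
        new_mets.append(Metabolite(f"syn_src_{cid}_c", compartment="c"))
    ext_mets = list(ext.metabolites) + new_mets
    ext_rxns = list(ext.reactions)
    genes_by_cluster: dict[str, set[str]] = {}
    for cid, s in zip(cluster_ids, sets):
        gene = f"gene_{cid}_00"
        stoich = {f"syn_src_{cid}_c": -1.0}
        stoich.update({mid: 1.0 for mid in sorted(s)})
        ext_rxns.append(
            Reaction(f"SYN_{cid}", stoich, 0, 1000.0, gene, "synthetic")
        )
        genes_by_cluster[cid] = {gene} | {
            f"gene_{cid}_{k:02d}" for k in range(1, genes_per_cluster)
        }
    ext = MetabolicModel(
        id=ext.id + "_planted",
        metabolites=ext_mets,
        reactions=ext_rxns,
        objective_id=ext.objective_id,
        extracellular_compartment=ext.extracellular_compartment,
        currency=ext.currency,
    )
    clusters = ClusterSet({cid: set(g) for cid, g in genes_by_cluster.items()})

    # --- planted enrichment ----------------------------------------------
    if enriched_terms is None:
        enriched_terms = {cid: f"term_{cid}" for cid in cluster_ids}
    cluster_genes = sorted(set().union(*genes_by_cluster.values()))
    background = [f"gene_bg_{k:04d}" for k in range(max(0, universe_size - len(cluster_genes)))]
    universe = set(cluster_genes) | set(background)
    gene_terms: dict[str, set[str]] = {}
    n_in_cluster = max(1, int(round(0.8 * genes_per_cluster)))
    for cid in cluster_ids:
        term = enriched_terms[cid]
        members = sorted(genes_by_cluster[cid])
        carriers = set(members[:n_in_cluster])
        n_bg = max(0, carriers_per_term - len(carriers))
        carriers |= set(rng.choice(background, size=min(n_bg, len(background)), replace=False))
        for g in carriers:
            gene_terms.setdefault(g, set()).add(term)
    for g in universe:
        gene_terms.setdefault(g, set())

    # --- ground truth at the threshold (brute force) ----------------------
    edges = set()
    for i in range(n_clusters):
        for j in range(i + 1, n_clusters):
            a, b = sets[i], sets[j]
            union = len(a | b)
            score = len(a & b) / union if union else 0.0
            if score > threshold:
                edges.add((cluster_ids[i], cluster_ids[j]))
    comp_sizes = _component_sizes(cluster_ids, edges)
    truth = {
        "edges": edges,
        "component_sizes": comp_sizes,
        "enriched_terms": dict(enriched_terms),
        "product_sets": {cid: set(s) for cid, s in zip(cluster_ids, sets)},
    }
    return clusters, gene_terms, ext, truth


def _sets_from_targets(targets: np.ndarray, n: int, rng) -> list[set[str]]:
    """Construct product sets whose pairwise Jaccard hits the targets +-0.02.

    Each cluster gets a unique pool plus, per nonzero pair target, a shared
    pool sized to realize the requested overlap; a target of exactly 1.0
    aliases the two sets.  Interacting high targets can be unachievable, in
    which case the achieved matrix is checked and an error raised.
    """
    base_unique = 10
    sets: list[set[str]] = [
        {f"u{i:02d}_{k:02d}_c" for k in range(base_unique)} for i in range(n)
    ]
    # identical pairs first (transitive aliasing)
    for i in range(n):
        for j in range(i + 1, n):
            if targets[i, j] >= 1.0:
                sets[j] = sets[i]
    for i in range(n):
        for j in range(i + 1, n):
            t = targets[i, j]
            if t <= 0.0 or t >= 1.0 or sets[i] is sets[j]:
                continue
            # want |A∩B| / |A∪B| = t with shared pool of size s added to both:
            # s / (s + |A| + |B|) = t  ->  s = t (|A| + |B|) / (1 - t)
            s = int(round(t * (len(sets[i]) + len(sets[j])) / (1.0 - t)))
            shared = {f"s{i:02d}_{j:02d}_{k:03d}_c" for k in range(s)}
            sets[i] |= shared
            sets[j] |= shared
    achieved = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            achieved[i, j] = len(sets[i] & sets[j]) / union if union else 0.0
            if abs(achieved[i, j] - targets[i, j]) > 0.02:
                raise ValueError(
                    f"overlap target {targets[i, j]:.3f} for pair ({i},{j}) "
                    f"unachievable (got {achieved[i, j]:.3f}); interacting "
                    "targets constrain each other"
                )
    return [set(s) for s in sets]


def _component_sizes(nodes: list[str], edges: set[tuple[str, str]]) -> list[int]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return sorted((len(c) for c in nx.connected_components(g)), reverse=True)
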