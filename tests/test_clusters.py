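"""Cluster metrics: category map, enrichment, connectivity, topology."""

import numpy as np
import pytest
from scipy.special import comb

from cnflux import (
    ClusterSet,
    build_category_map,
    cluster_metabolite_sets,
    connectivity_graph,
    enrich,
    flag_cn_clusters,
    graph_topology,
    make_planted_clusters,
    make_toy_model,
)
from cnflux.clusters import EnrichmentRecord


def hypergeom_tail_oracle(k, N, K, n, upper):
    """Direct tail sum of the hypergeometric pmf (independent oracle)."""
    total = comb(N, n, exact=True)
    rng_k = range(k, min(K, n) + 1) if upper else range(0, k + 1)
    acc = 0
    for i in rng_k:
        if i <= K and n - i <= N - K:
            acc += comb(K, i, exact=True) * comb(N - K, n - i, exact=True)
    return acc / total


class TestCategoryMap:
    @pytest.mark.parametrize(
        "subsystem,expected",
        [
            ("urea cycle", {"nitrogen"}),
            ("Calvin-Benson cycle", {"carbon"}),
            ("tricarboxylic acid cycle", {"carbon", "nitrogen"}),
            ("photosynthesis", {"carbon"}),
            ("amino acid metabolism", {"nitrogen"}),
            ("made-up subsystem", set()),
        ],
    )
    def test_macro_assignments(self, subsystem, expected):
        cmap = build_category_map()
        assert set(cmap.macro_categories(subsystem)) == expected

    def test_display_group_lookup_is_overridable(self):
        cmap = build_category_map(display_lookup={"weird pathway": "carbon"})
        assert cmap.display_group("Weird Pathway") == "carbon"
        assert cmap.display_group("unknown thing") == "unmapped"


class TestEnrich:
    def test_matches_tail_sum_oracle(self):
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(120)}
        for trial in range(10):
            K = int(rng.integers(5, 60))
            n = int(rng.integers(3, 30))
            carriers = set(rng.choice(sorted(universe), K, replace=False))
            members = set(rng.choice(sorted(universe), n, replace=False))
            clusters = ClusterSet({"c": members})
            gene_terms = {g: ({"T"} if g in carriers else set()) for g in universe}
            (rec,) = enrich(clusters, gene_terms, universe=universe)
            k = len(members & carriers)
            p_over = hypergeom_tail_oracle(k, 120, K, n, upper=True)
            p_under = hypergeom_tail_oracle(k, 120, K, n, upper=False)
            if rec.direction == "enriched":
                assert rec.p_value == pytest.approx(p_over, abs=1e-12)
            else:
                assert rec.p_value == pytest.approx(p_under, abs=1e-12)

    def test_cluster_equal_to_universe_is_never_enriched(self):
        universe = {f"g{i}" for i in range(40)}
        clusters = ClusterSet({"all": set(universe)})
        gene_terms = {g: ({"T"} if int(g[1:]) < 10 else set()) for g in universe}
        (rec,) = [r for r in enrich(clusters, gene_terms, universe=universe)
                  if r.direction == "enriched" or True]
        assert rec.k == rec.K
        over = [r for r in enrich(clusters, gene_terms, universe=universe)]
        assert all(r.q_value > 0.05 for r in over)

    def test_planted_terms_recovered(self, toy_model):
        clusters, gene_terms, _, truth = make_planted_clusters(
            toy_model, n_clusters=6, seed=12
        )
        records = enrich(clusters, gene_terms, universe=set(gene_terms))
        sig = {
            (r.cluster_id, r.term)
            for r in records
            if r.q_value < 0.05 and r.direction == "enriched"
        }
        assert set(truth["enriched_terms"].items()) <= sig

    def test_gene_outside_universe_is_an_error(self):
        clusters = ClusterSet({"c": {"gX"}})
        with pytest.raises(ValueError, match="gX"):
            enrich(clusters, {}, universe={"gY"})


class TestFlagCn:
    def _rec(self, cid, term, q):
        return EnrichmentRecord(cid, term, "enriched", q, q, 1, 1, 1, 1)

    def test_flags_follow_macro_categories(self):
        cmap = build_category_map()
        records = [
            self._rec("c1", "photosynthesis", 0.001),
            self._rec("c2", "tricarboxylic acid cycle", 0.001),
            self._rec("c3", "photosynthesis", 0.5),
        ]
        flags = flag_cn_clusters(records, cmap)
        assert flags["c1"] == {"carbon"}
        assert flags["c2"] == {"carbon", "nitrogen"}
        assert flags["c3"] == set()

    def test_set_identity_carbon_plus_nitrogen_minus_both(self):
        rng = np.random.default_rng(3)
        cmap = build_category_map()
        terms = ["photosynthesis", "urea cycle", "tricarboxylic acid cycle",
                 "made up"]
        records = [
            self._rec(f"c{i}", terms[rng.integers(4)], float(rng.uniform(0, 0.1)))
            for i in range(60)
        ]
        flags = flag_cn_clusters(records, cmap)
        carbon = {c for c, f in flags.items() if "carbon" in f}
        nitrogen = {c for c, f in flags.items() if "nitrogen" in f}
        either = {c for c, f in flags.items() if f}
        assert len(carbon) + len(nitrogen) - len(carbon & nitrogen) == len(either)


class TestClusterMetaboliteSets:
    def test_gene_without_reactions_contributes_nothing(self, toy_model):
        sets = cluster_metabolite_sets(
            ClusterSet({"c": {"not_a_gene"}}), toy_model
        )
        assert sets["c"] == set()

    def test_biomass_cluster_substrates(self, toy_model):
        sets = cluster_metabolite_sets(
            ClusterSet({"c": {"gBOF"}}), toy_model, side="substrates"
        )
        assert sets["c"] == {"cfix_c", "orgN_c"}

    def test_reversible_reaction_feeds_both_sides(self, toy_model):
        # exchange reactions are reversible; gEXC tags EX_hco3_e
        for side in ("substrates", "products"):
            sets = cluster_metabolite_sets(
                ClusterSet({"c": {"gEXC"}}), toy_model, side=side
            )
            assert "hco3_e" in sets["c"]


class TestConnectivityGraph:
    def test_identical_sets_connect(self):
        a = {f"m{i}" for i in range(10)}
        cg = connectivity_graph({"A": set(a), "B": set(a)}, threshold=0.9)
        assert cg.edges == {("A", "B")}
        assert cg.graph.edges["A", "B"]["weight"] == pytest.approx(1.0)

    def test_nine_of_ten_boundary_is_strictly_excluded(self):
        a = {f"m{i}" for i in range(10)}
        b = {f"m{i}" for i in range(9)}  # |A∩B|=9, |A∪B|=10 -> score 0.9
        cg = connectivity_graph({"A": a, "B": b}, threshold=0.9)
        assert cg.edges == set()

    def test_disjoint_and_empty_sets_are_isolated(self):
        cg = connectivity_graph({"A": {"x"}, "B": {"y"}, "C": set()}, 0.9)
        assert cg.edges == set()
        assert set(cg.graph.nodes) == {"A", "B", "C"}

    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vocab = [f"m{i}" for i in range(30)]
            sets = {
                f"c{j}": set(rng.choice(vocab, rng.integers(3, 12), replace=False))
                for j in range(8)
            }
            threshold = 0.3
            cg = connectivity_graph(sets, threshold)
            expected = set()
            ids = sorted(sets)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    u = len(sets[a] | sets[b])
                    if u and len(sets[a] & sets[b]) / u > threshold:
                        expected.add((a, b))
            assert cg.edges == expected

    def test_sum_denominator_caps_at_half(self):
        a = {f"m{i}" for i in range(10)}
        cg = connectivity_graph({"A": set(a), "B": set(a)}, threshold=0.45,
                                denominator="sum")
        assert cg.graph.edges["A", "B"]["weight"] == pytest.approx(0.5)

    def test_symmetry_under_relabeling(self):
        sets = {"A": {"x", "y"}, "B": {"y", "x"}, "C": {"z"}}
        g1 = connectivity_graph(sets, 0.5).edges
        g2 = connectivity_graph(dict(reversed(list(sets.items()))), 0.5).edges
        assert g1 == g2


class TestGraphTopology:
    def test_two_disjoint_edges(self):
        cg = connectivity_graph(
            {"a": {"1"}, "b": {"1"}, "c": {"2"}, "d": {"2"}}, threshold=0.5
        )
        sizes, btw = graph_topology(cg)
        assert sizes == [2, 2]
        assert all(v == 0 for v in btw.values())

    def test_path_center_has_unit_betweenness(self):
        sets = {"a": {"1"}, "b": {"1", "2"}, "c": {"2"}}
        cg = connectivity_graph(sets, threshold=0.4)
        assert cg.edges == {("a", "b"), ("b", "c")}
        _, btw = graph_topology(cg)
        assert btw["b"] == pytest.approx(1.0)

    def test_planted_modules_recovered(self, toy_model):
        ov = np.zeros((6, 6))
        ov[0, 1] = ov[1, 0] = 0.95
        for i, j in ((2, 3), (3, 4), (2, 4)):  # identical triple
            ov[i, j] = ov[j, i] = 1.0
        clusters, _, ext, truth = make_planted_clusters(
            toy_model, n_clusters=6, overlap_matrix=ov, seed=21
        )
        sets = cluster_metabolite_sets(clusters, ext, side="products")
        cg = connectivity_graph(sets, threshold=0.9)
        sizes, _ = graph_topology(cg)
        assert cg.edges == truth["edges"]
        assert sizes == truth["component_sizes"] == [3, 2, 1]
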