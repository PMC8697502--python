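import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from enrichkit.core_model import AnalysisBundle, EnrichKitError, ExpressionData
from enrichkit.topology import (
    build_enrichment_map,
    build_gene_geneset_graph,
    detect_communities,
    extract_backbone,
    geneset_similarity,
    kappa_statistic,
    project_bipartite,
    write_graph,
)
from tests.conftest import make_enrichment, random_bundle


def two_set_bundle():
    """2 genesets {A,B,C} and {B,C,D}; every gene DE."""
    gene_ids = ["gA", "gB", "gC", "gD"]
    symbols = ["A", "B", "C", "D"]
    counts = pd.DataFrame(
        np.arange(1, 9).reshape(4, 2), index=gene_ids, columns=["s1", "s2"]
    )
    samples = pd.DataFrame({"condition": ["A", "B"]}, index=["s1", "s2"])
    de = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": [1.0, -1.0, 2.0, 0.5],
            "pvalue": [0.001] * 4,
            "padj": [0.01] * 4,
        }
    )
    enrichment = make_enrichment(
        [("GS1", "one", 0.001, ["A", "B", "C"]), ("GS2", "two", 0.01, ["B", "C", "D"])]
    )
    annotation = pd.DataFrame({"gene_id": gene_ids, "gene_name": symbols})
    return AnalysisBundle(
        expression=ExpressionData(counts=counts, samples=samples),
        de=de,
        enrichment=enrichment,
        annotation=annotation,
    )


class TestGeneGenesetGraph:
    def test_union_counts(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
        assert g.number_of_nodes() == 6  # 2 genesets + 4 genes
        assert g.number_of_edges() == 6

    def test_bipartite_and_degree_equals_member_count(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
        for u, v in g.edges():
            assert {g.nodes[u]["type"], g.nodes[v]["type"]} == {"geneset", "gene"}
        assert g.degree("GS1") == 3
        assert g.degree("GS2") == 3

    def test_disjoint_sets_give_two_components(self):
        bundle = two_set_bundle()
        bundle.enrichment.at[0, "gs_genes"] = ["A", "B"]
        bundle.enrichment.at[1, "gs_genes"] = ["C", "D"]
        g = build_gene_geneset_graph(bundle, n_gs=2)
        assert nx.number_connected_components(g) == 2

    def test_n_gs_one_is_star(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=1)
        genesets = [n for n, d in g.nodes(data=True) if d["type"] == "geneset"]
        assert genesets == ["GS1"]
        assert g.degree("GS1") == g.number_of_nodes() - 1

    def test_n_gs_clamped_with_warning(self, caplog):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=99)
        assert sum(1 for _, d in g.nodes(data=True) if d["type"] == "geneset") == 2

    def test_non_de_members_excluded(self):
        bundle = two_set_bundle()
        bundle.de.loc[bundle.de["gene_id"] == "gD", "padj"] = 0.9
        g = build_gene_geneset_graph(bundle, n_gs=2)
        assert "gD" not in g


class TestSimilarity:
    def test_jaccard_definition(self):
        enr = make_enrichment(
            [("A", "a", 0.01, ["a", "b", "c"]), ("B", "b", 0.02, ["b", "c", "d"])]
        )
        sim = geneset_similarity(enr, "jaccard")
        assert sim.at["A", "B"] == pytest.approx(0.5)

    def test_overlap_definition(self):
        enr = make_enrichment(
            [("A", "a", 0.01, ["a", "b", "c"]), ("B", "b", 0.02, ["b", "c", "d"])]
        )
        sim = geneset_similarity(enr, "overlap")
        assert sim.at["A", "B"] == pytest.approx(2 / 3)

    def test_kappa_hand_example(self):
        # universe 10, |A|=|B|=5, 4 shared: Po=0.8, Pe=0.5 -> kappa 0.6
        a = frozenset("abcde")
        b = frozenset("abcdf")
        assert kappa_statistic(a, b, 10) == pytest.approx(0.6)

    def test_kappa_via_matrix(self):
        enr = make_enrichment(
            [
                ("A", "a", 0.01, list("abcde")),
                ("B", "b", 0.02, list("abcdf")),
            ]
        )
        sim = geneset_similarity(enr, "kappa", universe_size=10)
        assert sim.at["A", "B"] == pytest.approx(0.6)

    def test_kappa_universe_too_small_errors(self):
        with pytest.raises(EnrichKitError, match="universe"):
            kappa_statistic(frozenset("abc"), frozenset("def"), 4)

    @pytest.mark.parametrize("measure", ["jaccard", "overlap", "kappa"])
    def test_symmetry_and_diagonal(self, measure):
        rng = np.random.default_rng(9)
        rows = []
        universe = [f"x{i}" for i in range(30)]
        for k in range(6):
            members = list(rng.choice(universe, size=rng.integers(3, 10), replace=False))
            rows.append((f"GS{k}", "d", float(rng.uniform(0, 1)), members))
        sim = geneset_similarity(make_enrichment(rows), measure, universe_size=30)
        mat = sim.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        if measure == "kappa":
            assert (mat >= -1 - 1e-12).all() and (mat <= 1 + 1e-12).all()
        else:
            assert (mat >= 0).all() and (mat <= 1).all()

    def test_unknown_measure_errors(self):
        enr = make_enrichment([("A", "a", 0.01, ["x"]), ("B", "b", 0.02, ["y"])])
        with pytest.raises(EnrichKitError, match="measure"):
            geneset_similarity(enr, "cosine")


class TestEnrichmentMap:
    @pytest.fixture
    def enr(self):
        return make_enrichment(
            [
                ("A", "a", 0.001, ["a", "b", "c"]),
                ("B", "b", 0.01, ["a", "b", "c"]),
                ("C", "c", 0.05, ["x", "y", "z"]),
            ]
        )

    def test_threshold_one_no_duplicates_edgeless(self):
        enr = make_enrichment(
            [("A", "a", 0.01, ["a", "b"]), ("B", "b", 0.02, ["b", "c"])]
        )
        g = build_enrichment_map(enr, n_gs=2, measure="jaccard", edge_threshold=1.0)
        assert g.number_of_edges() == 0

    def test_threshold_zero_complete(self, enr):
        g = build_enrichment_map(enr, n_gs=3, measure="jaccard", edge_threshold=0.0)
        assert g.number_of_edges() == 3

    def test_identical_sets_weight_one(self, enr):
        g = build_enrichment_map(enr, n_gs=3, measure="jaccard", edge_threshold=0.5)
        assert g["A"]["B"]["weight"] == pytest.approx(1.0)

    def test_out_of_range_threshold_errors(self, enr):
        with pytest.raises(EnrichKitError, match="edge_threshold"):
            build_enrichment_map(enr, n_gs=3, measure="jaccard", edge_threshold=-0.5)

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        universe = [f"x{i}" for i in range(25)]
        rows = [
            (
                f"GS{k}",
                "d",
                float(rng.uniform(0, 1)),
                list(rng.choice(universe, size=8, replace=False)),
            )
            for k in range(10)
        ]
        enr = make_enrichment(rows)
        counts = [
            build_enrichment_map(enr, n_gs=10, edge_threshold=t).number_of_edges()
            for t in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCommunities:
    def test_disconnected_triangles(self):
        g = nx.Graph()
        for offset, names in ((0, "abc"), (1, "xyz")):
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v, weight=1.0)
        for i, n in enumerate(sorted(g)):
            g.nodes[n]["gs_pvalue"] = 0.01 * (i + 1)
        labeled, table = detect_communities(g)
        assert len(table) == 2
        labels = nx.get_node_attributes(labeled, "community")
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["x"] == labels["y"] == labels["z"]
        assert labels["a"] != labels["x"]

    def test_singleton_is_own_representative(self):
        g = nx.Graph()
        g.add_node("solo", gs_pvalue=0.01)
        labeled, table = detect_communities(g)
        assert table.iloc[0]["representative"] == "solo"
        assert table.iloc[0]["n_members"] == 1

    def test_unknown_method_errors(self):
        g = nx.Graph()
        g.add_node("a", gs_pvalue=0.1)
        with pytest.raises(EnrichKitError, match="method"):
            detect_communities(g, method="louvainx")

    def test_planted_two_block_recovery(self):
        # 12-node two-block graph: within p=0.9, between p=0.05
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            g = nx.Graph()
            nodes = [f"n{i}" for i in range(12)]
            block = {n: (0 if i < 6 else 1) for i, n in enumerate(nodes)}
            for i, n in enumerate(nodes):
                g.add_node(n, gs_pvalue=0.01 * (i + 1))
            for u, v in itertools.combinations(nodes, 2):
                p = 0.9 if block[u] == block[v] else 0.05
                if rng.uniform() < p:
                    g.add_edge(u, v, weight=1.0)
            labeled, table = detect_communities(g, seed=seed)
            labels = nx.get_node_attributes(labeled, "community")
            if len(table) == 2:
                sets = [
                    {n for n in nodes if labels[n] == c} for c in table["community"]
                ]
                truth = [{n for n in nodes if block[n] == b} for b in (0, 1)]
                if sets in (truth, truth[::-1]):
                    hits += 1
        assert hits >= 0.95 * n_runs


class TestBackbone:
    def test_projection_weights_equal_shared_member_counts(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
        proj = project_bipartite(g, "geneset")
        assert proj["GS1"]["GS2"]["weight"] == 2  # shared: B, C

    def test_projection_matches_incidence_product_oracle(self):
        # brute-force pairwise intersection on a random <=20-set fixture
        rng = np.random.default_rng(4)
        bundle = random_bundle(4, n_genes=40, n_sets=15)
        bundle.de["padj"] = 0.01  # everything DE so all members resolve
        g = build_gene_geneset_graph(bundle, n_gs=15)
        proj = project_bipartite(g, "geneset")
        members = {
            gs: set(g.neighbors(gs))
            for gs, d in g.nodes(data=True)
            if d["type"] == "geneset"
        }
        for a, b in itertools.combinations(members, 2):
            expected = len(members[a] & members[b])
            actual = proj[a][b]["weight"] if proj.has_edge(a, b) else 0
            assert actual == expected

    def test_disparity_score_formula(self):
        # node with 4 equal-weight edges: p = 1/4, score = 0.75^3
        score = (1 - 0.25) ** (4 - 1)
        assert score == pytest.approx(0.421875)
        # alpha above the score keeps the edges; below drops them
        g = nx.Graph()
        g.add_node("hub", type="geneset")
        for i in range(4):
            g.add_node(f"gs{i}", type="geneset")
        for i in range(4):
            g.add_node(f"gene{i}", type="gene")
            g.add_edge("hub", f"gene{i}")
            g.add_edge(f"gs{i}", f"gene{i}")
        kept = extract_backbone(g, side="geneset", alpha=0.5)
        assert kept.number_of_edges() == 4  # leaf endpoints retain everything

    def test_degree_one_edge_always_retained(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
        backbone = extract_backbone(g, side="geneset", alpha=0.001)
        # single projected edge, both endpoints degree 1 -> retained
        assert backbone.has_edge("GS1", "GS2")

    def test_alpha_out_of_range_errors(self):
        g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
        with pytest.raises(EnrichKitError, match="alpha"):
            extract_backbone(g, alpha=0.0)

    def test_backbone_monotone_in_alpha(self):
        bundle = random_bundle(11, n_genes=40, n_sets=12)
        bundle.de["padj"] = 0.01
        g = build_gene_geneset_graph(bundle, n_gs=12)
        previous: set = set()
        for alpha in (0.01, 0.1, 0.5, 1.0):
            edges = set(map(frozenset, extract_backbone(g, alpha=alpha).edges()))
            assert previous <= edges
            previous = edges


def test_graphml_and_dot_export(tmp_path):
    g = build_gene_geneset_graph(two_set_bundle(), n_gs=2)
    write_graph(g, str(tmp_path / "g.graphml"))
    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_nodes() == g.number_of_nodes()
    write_graph(g, str(tmp_path / "g.dot"), fmt="dot")
    text = (tmp_path / "g.dot").read_text()
    assert '"GS1" [' in text and "--" in text
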