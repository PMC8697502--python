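import itertools

import numpy as np
import pandas as pd
import pytest

from enrichkit.core_model import EnrichKitError
from enrichkit.distill import (
    classical_mds,
    fuzzy_cluster_genesets,
    geneset_dendrogram,
    geneset_mds,
    reduce_by_overlap,
)
from enrichkit.topology import geneset_similarity
from tests.conftest import make_enrichment


def two_block_enrichment():
    """6 sets: two blocks of 3 near-identical sets over a 40-gene universe."""
    universe = [f"x{i}" for i in range(40)]
    block1 = universe[:10]
    block2 = universe[20:30]
    rows = [
        ("A1", "a", 0.001, block1),
        ("A2", "a", 0.002, block1[:9] + [universe[10]]),
        ("A3", "a", 0.003, block1[:9] + [universe[11]]),
        ("B1", "b", 0.004, block2),
        ("B2", "b", 0.005, block2[:9] + [universe[30]]),
        ("B3", "b", 0.006, block2[:9] + [universe[31]]),
    ]
    return make_enrichment(rows), 40


class TestFuzzyClustering:
    def test_identical_sets_single_cluster(self):
        members = ["a", "b", "c", "d", "e"]
        enr = make_enrichment(
            [("X", "x", 0.01, members), ("Y", "y", 0.001, members), ("Z", "z", 0.5, members)]
        )
        ca = fuzzy_cluster_genesets(enr, seed_size=2, universe_size=50)
        assert ca.table["cluster_id"].nunique() == 1
        rep = ca.table[ca.table["status"] == "Representative"]
        assert list(rep["gs_id"]) == ["Y"]  # lowest p

    def test_disjoint_sets_all_singletons(self):
        enr = make_enrichment(
            [
                ("X", "x", 0.01, ["a", "b"]),
                ("Y", "y", 0.02, ["c", "d"]),
                ("Z", "z", 0.03, ["e", "f"]),
            ]
        )
        ca = fuzzy_cluster_genesets(enr, universe_size=100)
        assert ca.table["cluster_id"].nunique() == 3
        assert (ca.table["status"] == "Representative").all()

    def test_planted_two_blocks_recovered(self):
        enr, universe = two_block_enrichment()
        # brute-force check of the kappa structure the algorithm sees
        kappa = geneset_similarity(enr, "kappa", universe_size=universe)
        for a, b in itertools.combinations(["A1", "A2", "A3"], 2):
            assert kappa.at[a, b] > 0.8
        for a in ["A1", "A2", "A3"]:
            for b in ["B1", "B2", "B3"]:
                assert kappa.at[a, b] < 0.1
        ca = fuzzy_cluster_genesets(
            enr, similarity_threshold=0.35, seed_size=2, multilinkage=0.5,
            universe_size=universe,
        )
        sizes = ca.table.groupby("cluster_id")["gs_id"].apply(set)
        multi = [s for s in sizes if len(s) > 1]
        assert len(multi) == 2
        assert {"A1", "A2", "A3"} in multi
        assert {"B1", "B2", "B3"} in multi

    def test_every_input_appears_and_one_rep_per_cluster(self):
        enr, universe = two_block_enrichment()
        ca = fuzzy_cluster_genesets(enr, seed_size=2, universe_size=universe)
        assert set(ca.table["gs_id"]) == set(enr["gs_id"])
        reps = ca.table[ca.table["status"] == "Representative"]
        assert reps.groupby("cluster_id").size().eq(1).all()
        assert len(reps) == ca.table["cluster_id"].nunique()

    def test_permutation_invariance_up_to_labels(self):
        enr, universe = two_block_enrichment()
        ca1 = fuzzy_cluster_genesets(enr, seed_size=2, universe_size=universe)
        shuffled = enr.sample(frac=1, random_state=3).reset_index(drop=True)
        ca2 = fuzzy_cluster_genesets(shuffled, seed_size=2, universe_size=universe)

        def as_partition(ca):
            return frozenset(
                frozenset(g["gs_id"]) for _, g in ca.table.groupby("cluster_id")
            )

        assert as_partition(ca1) == as_partition(ca2)

    def test_hard_assignment_forces_partition(self):
        enr, universe = two_block_enrichment()
        ca = fuzzy_cluster_genesets(enr, seed_size=2, universe_size=universe, hard=True)
        assert not ca.table["gs_id"].duplicated().any()

    def test_threshold_range_check(self):
        enr, _ = two_block_enrichment()
        with pytest.raises(EnrichKitError, match="similarity_threshold"):
            fuzzy_cluster_genesets(enr, similarity_threshold=1.5)


class TestReduceByOverlap:
    def test_identical_sets_keep_more_significant(self):
        enr = make_enrichment(
            [("worse", "d", 0.05, ["a", "b", "c"]), ("better", "d", 0.001, ["a", "b", "c"])]
        )
        out = reduce_by_overlap(enr, 0.75)
        assert list(out["gs_id"]) == ["better"]

    def test_disjoint_sets_all_retained(self):
        enr = make_enrichment(
            [("X", "x", 0.01, ["a", "b"]), ("Y", "y", 0.02, ["c", "d"])]
        )
        out = reduce_by_overlap(enr, 0.01)
        assert set(out["gs_id"]) == {"X", "Y"}

    def test_chain_drops_middle(self):
        # A ~ B and B ~ C overlap high, A ~ C low: keep A and C, drop B
        a = ["x1", "x2", "x3", "x4"]
        b = ["x3", "x4", "x5", "x6"]
        c = ["x5", "x6", "x7", "x8"]
        enr = make_enrichment(
            [("A", "a", 0.001, a), ("B", "b", 0.002, b), ("C", "c", 0.003, c)]
        )
        out = reduce_by_overlap(enr, overlap_threshold=0.5)
        assert list(out["gs_id"]) == ["A", "C"]
        # brute-force greedy trace oracle
        retained = []
        sets = {"A": set(a), "B": set(b), "C": set(c)}
        for gs in ["A", "B", "C"]:  # increasing p order
            if all(
                len(sets[gs] & sets[r]) / min(len(sets[gs]), len(sets[r])) < 0.5
                for r in retained
            ):
                retained.append(gs)
        assert list(out["gs_id"]) == retained

    def test_greedy_maximality(self):
        rng = np.random.default_rng(8)
        universe = [f"x{i}" for i in range(30)]
        rows = [
            (
                f"GS{k}",
                "d",
                float(rng.uniform(0, 1)),
                list(rng.choice(universe, size=8, replace=False)),
            )
            for k in range(12)
        ]
        enr = make_enrichment(rows)
        threshold = 0.5
        out = reduce_by_overlap(enr, threshold)
        retained = {
            gs: set(genes) for gs, genes in zip(out["gs_id"], out["gs_genes"])
        }
        dropped = enr[~enr["gs_id"].isin(retained)]
        for gs, genes in zip(dropped["gs_id"], dropped["gs_genes"]):
            s = set(genes)
            overlaps = [
                len(s & r) / min(len(s), len(r)) for r in retained.values()
            ]
            assert any(o >= threshold for o in overlaps)

    def test_range_check(self):
        enr = make_enrichment([("A", "a", 0.01, ["x"])])
        with pytest.raises(EnrichKitError, match="overlap_threshold"):
            reduce_by_overlap(enr, 0.0)


class TestMDS:
    def test_two_points(self):
        sim = pd.DataFrame(
            [[1.0, 0.4], [0.4, 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        out = geneset_mds(sim)
        d = 0.6
        assert sorted(out["x"].abs()) == pytest.approx([d / 2, d / 2])
        assert out["y"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_identical_sets_coincide(self):
        sim = pd.DataFrame(np.ones((3, 3)), index=list("ABC"), columns=list("ABC"))
        out = geneset_mds(sim)
        assert out[["x", "y"]].to_numpy() == pytest.approx(np.zeros((3, 2)), abs=1e-9)

    def test_planted_2d_configuration_recovered(self):
        # build dissimilarities from known 2D coordinates; stress must be tiny
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 0.4, size=(6, 2))
        dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        sim = pd.DataFrame(
            1 - dist, index=[f"G{i}" for i in range(6)], columns=[f"G{i}" for i in range(6)]
        )
        out = geneset_mds(sim)
        coords = out[["x", "y"]].to_numpy()
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        stress = np.sqrt(((recon - dist) ** 2).sum() / (dist**2).sum())
        assert stress < 0.05

    def test_permutation_invariance_procrustes(self):
        from scipy.spatial import procrustes

        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 0.4, size=(6, 2))
        dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"G{i}" for i in range(6)]
        sim = pd.DataFrame(1 - dist, index=ids, columns=ids)
        out1 = geneset_mds(sim).set_index("gs_id")
        perm = ids[::-1]
        out2 = geneset_mds(sim.loc[perm, perm]).set_index("gs_id")
        _, _, disparity = procrustes(
            out1.loc[ids, ["x", "y"]].to_numpy(), out2.loc[ids, ["x", "y"]].to_numpy()
        )
        assert disparity < 1e-6

    def test_asymmetric_input_errors(self):
        sim = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(EnrichKitError, match="symmetric"):
            geneset_mds(sim)

    def test_z_scores_carried(self):
        sim = pd.DataFrame(
            [[1.0, 0.4], [0.4, 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        out = geneset_mds(sim, z_scores={"A": 1.5, "B": -2.0})
        assert out.set_index("gs_id").at["A", "z_score"] == 1.5


class TestDendrogram:
    def test_nearest_pair_merges_first(self):
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        dendro = geneset_dendrogram(sim)
        assert dendro.merge_heights[0] == pytest.approx(0.1)
        assert set(dendro.linkage_matrix[0, :2].astype(int)) == {0, 1}  # A and B

    def test_identical_sets_merge_at_zero(self):
        sim = pd.DataFrame(np.ones((3, 3)), index=list("ABC"), columns=list("ABC"))
        dendro = geneset_dendrogram(sim)
        assert dendro.merge_heights[0] == pytest.approx(0.0)

    def test_average_linkage_matches_bruteforce(self):
        rng = np.random.default_rng(17)
        n = 5
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"G{i}" for i in range(n)]
        sim = pd.DataFrame(1 - d, index=ids, columns=ids)
        dendro = geneset_dendrogram(sim, linkage="average")

        # brute-force agglomeration oracle
        clusters = [[i] for i in range(n)]
        heights = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(range(len(clusters)), 2):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best[0]:
                    best = (avg, i, j)
            avg, i, j = best
            heights.append(avg)
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
        assert dendro.merge_heights == pytest.approx(heights, abs=1e-12)

    def test_monotone_heights_and_newick(self):
        enr, universe = two_block_enrichment()
        sim = geneset_similarity(enr, "jaccard")
        dendro = geneset_dendrogram(sim)
        h = dendro.merge_heights
        assert (np.diff(h) >= -1e-12).all()
        newick = dendro.to_newick()
        assert newick.endswith(";")
        for gs in enr["gs_id"]:
            assert gs in newick

    def test_unknown_linkage_errors(self):
        sim = pd.DataFrame(np.eye(2) * 0 + 1, index=["A", "B"], columns=["A", "B"])
        with pytest.raises(EnrichKitError, match="linkage"):
            geneset_dendrogram(sim, linkage="ward")


def test_kappa_disjoint_small_sets_nonpositive():
    enr = make_enrichment(
        [("A", "a", 0.01, ["a", "b", "c"]), ("B", "b", 0.02, ["d", "e", "f"])]
    )
    sim = geneset_similarity(enr, "kappa", universe_size=1000)
    assert sim.at["A", "B"] <= 0


def test_classical_mds_centering():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    coords = classical_mds(d)
    assert coords.mean(axis=0) == pytest.approx([0.0, 0.0], abs=1e-12)
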