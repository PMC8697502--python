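"""Redundancy reduction over enrichment results.

Functional-annotation results are notoriously redundant: many reported
terms are near-duplicates or nestings of one another. This module offers
four complementary distillations — kappa-based fuzzy clustering with
per-cluster representatives, a greedy overlap-threshold term reduction,
a classical-MDS 2D layout, and an agglomerative dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from enrichkit.core_model import EnrichKitError
from enrichkit.topology import geneset_similarity, _membership_sets

STATUS_REPRESENTATIVE = "Representative"
STATUS_MEMBER = "Member"


@dataclass
class ClusterAssignment:
    """Fuzzy-cluster membership table plus the parameters that produced it.

    ``table`` rows: (gs_id, cluster_id, status); every input gs_id appears
    at least once, possibly in several clusters (fuzzy), and each cluster
    has exactly one Representative.
    """

    table: pd.DataFrame
    similarity_threshold: float
    seed_size: int
    multilinkage: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _seed_for(
    idx: int, kappa: np.ndarray, threshold: float, seed_size: int
) -> frozenset[int] | None:
    neighbors = [j for j in range(kappa.shape[0]) if j != idx and kappa[idx, j] >= threshold]
    if len(neighbors) < seed_size:
        return None
    members = [idx, *neighbors]
    pairs = [
        (members[a], members[b])
        for a in range(len(members))
        for b in range(a + 1, len(members))
    ]
    good = sum(1 for a, b in pairs if kappa[a, b] >= threshold)
    if good <= 0.5 * len(pairs):
        return None
    return frozenset(members)


def _merge_seeds(seeds: list[frozenset[int]], multilinkage: float) -> list[frozenset[int]]:
    clusters = [set(s) for s in seeds]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                shared = len(a & b)
                if shared and shared / min(len(a), len(b)) >= multilinkage:
                    clusters[i] = a | b
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    # de-duplicate identical clusters left by the seeding phase
    unique: list[set[int]] = []
    for c in clusters:
        if c not in unique:
            unique.append(c)
    return [frozenset(c) for c in unique]


def fuzzy_cluster_genesets(
    enrichment: pd.DataFrame,
    similarity_threshold: float = 0.35,
    seed_size: int = 3,
    multilinkage: float = 0.5,
    universe_size: int | None = None,
    hard: bool = False,
) -> ClusterAssignment:
    """Kappa-based fuzzy clustering of redundant genesets.

    The procedure: (1) compute the pairwise kappa matrix over the gene
    universe (default: union of all memberships); (2) every geneset with
    at least ``seed_size`` neighbors at kappa >= ``similarity_threshold``
    proposes a seed, kept when more than half of the within-seed pairs
    also exceed the threshold; (3) seeds sharing at least a
    ``multilinkage`` fraction of members (relative to the smaller seed)
    are merged to fixpoint; (4) genesets in no surviving cluster become
    singletons. The cluster representative is its lowest-p member.

    With ``hard=True`` each geneset is kept only in the cluster whose
    representative it agrees with best (by kappa), forcing a partition.
    """
    for name, value in (
        ("similarity_threshold", similarity_threshold),
        ("multilinkage", multilinkage),
    ):
        if not (0 < value <= 1):
            raise EnrichKitError(f"{name} must be in (0, 1], got {value}")
    if len(enrichment) < 2:
        raise EnrichKitError("fuzzy clustering requires >= 2 genesets")

    kappa_df = geneset_similarity(enrichment, measure="kappa", universe_size=universe_size)
    ids = list(kappa_df.index)
    kappa = kappa_df.to_numpy()
    pvals = dict(zip(enrichment["gs_id"], enrichment["gs_pvalue"]))

    seeds = []
    for i in range(len(ids)):
        seed = _seed_for(i, kappa, similarity_threshold, seed_size)
        if seed is not None:
            seeds.append(seed)
    clusters = _merge_seeds(seeds, multilinkage)

    clustered = set().union(*clusters) if clusters else set()
    for i in range(len(ids)):
        if i not in clustered:
            clusters.append(frozenset([i]))

    def rep_of(cluster: frozenset[int]) -> int:
        return min(cluster, key=lambda i: (pvals.get(ids[i], 1.0), ids[i]))

    clusters = sorted(clusters, key=lambda c: (pvals.get(ids[rep_of(c)], 1.0), ids[rep_of(c)]))

    if hard:
        assigned: dict[int, int] = {}
        for label, cluster in enumerate(clusters):
            rep = rep_of(cluster)
            for i in cluster:
                if i not in assigned:
                    assigned[i] = label
                else:
                    cur_rep = rep_of(clusters[assigned[i]])
                    if kappa[i, rep] > kappa[i, cur_rep]:
                        assigned[i] = label
        clusters = [
            frozenset(i for i, lab in assigned.items() if lab == label)
            for label in range(len(clusters))
        ]
        clusters = [c for c in clusters if c]

    records = []
    for label, cluster in enumerate(clusters):
        rep = rep_of(cluster)
        for i in sorted(cluster, key=lambda i: (pvals.get(ids[i], 1.0), ids[i])):
            records.append(
                {
                    "gs_id": ids[i],
                    "cluster_id": label,
                    "status": STATUS_REPRESENTATIVE if i == rep else STATUS_MEMBER,
                }
            )
    table = pd.DataFrame(records, columns=["gs_id", "cluster_id", "status"])
    return ClusterAssignment(
        table=table,
        similarity_threshold=similarity_threshold,
        seed_size=seed_size,
        multilinkage=multilinkage,
    )


def reduce_by_overlap(
    enrichment: pd.DataFrame, overlap_threshold: float = 0.75
) -> pd.DataFrame:
    """Greedy term reduction by overlap coefficient.

    Genesets are visited in increasing gs_pvalue order (ties: larger
    gs_de_count, then id); a geneset is dropped when its overlap
    coefficient with any already-retained geneset reaches the threshold.
    The retained subset is returned in significance order.
    """
    if not (0 < overlap_threshold <= 1):
        raise EnrichKitError(
            f"overlap_threshold must be in (0, 1], got {overlap_threshold}"
        )
    from enrichkit.topology import rank_genesets

    ordered = rank_genesets(enrichment, len(enrichment))
    sets = _membership_sets(ordered)
    retained: list[str] = []
    for gs_id in ordered["gs_id"]:
        candidate = sets[gs_id]
        drop = False
        for kept in retained:
            other = sets[kept]
            m = min(len(candidate), len(other))
            coef = len(candidate & other) / m if m else 0.0
            if coef >= overlap_threshold:
                drop = True
                break
        if not drop:
            retained.append(gs_id)
    return ordered[ordered["gs_id"].isin(retained)].reset_index(drop=True)


def classical_mds(dissimilarity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a symmetric dissimilarity matrix."""
    n = dissimilarity.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dissimilarity**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, n_components))
    for k in range(min(n_components, n)):
        if eigvals[k] > 1e-12:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    return coords


def geneset_mds(
    similarity: pd.DataFrame, z_scores: pd.Series | dict | None = None
) -> pd.DataFrame:
    """2D classical-MDS layout of genesets on dissimilarity 1 - similarity.

    Returns a table (gs_id, x, y, z_score); coordinates are centered at
    the origin and z_score is carried along for coloring.
    """
    mat = similarity.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-9):
        raise EnrichKitError("geneset_mds requires a square symmetric similarity matrix")
    if mat.shape[0] < 2:
        raise EnrichKitError("geneset_mds requires >= 2 genesets")
    coords = classical_mds(1.0 - mat, n_components=2)
    out = pd.DataFrame(
        {"gs_id": similarity.index, "x": coords[:, 0], "y": coords[:, 1]}
    )
    if z_scores is not None:
        zmap = dict(z_scores) if not isinstance(z_scores, dict) else z_scores
        out["z_score"] = [zmap.get(g, np.nan) for g in out["gs_id"]]
    else:
        out["z_score"] = np.nan
    return out


@dataclass
class Dendrogram:
    """Agglomerative clustering result over genesets."""

    linkage_matrix: np.ndarray
    gs_ids: list[str]
    linkage_method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.gs_ids[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.gs_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def geneset_dendrogram(
    similarity: pd.DataFrame, linkage: str = "average"
) -> Dendrogram:
    """Hierarchical clustering of genesets on dissimilarity 1 - similarity."""
    if linkage not in ("average", "complete"):
        raise EnrichKitError(f"unknown linkage {linkage!r}; supported: average, complete")
    mat = similarity.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise EnrichKitError("geneset_dendrogram requires >= 2 genesets")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(
        linkage_matrix=z, gs_ids=list(similarity.index), linkage_method=linkage
    )
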