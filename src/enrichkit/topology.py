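"""Graph summaries: gene-geneset bipartite graph, backbone, enrichment map.

Nodes carry the attributes downstream renderers color by (geneset
z_score, gene log2fc, community label); graphs are plain
:mod:`networkx` objects exportable as GraphML/DOT.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from enrichkit.core_model import (
    AnalysisBundle,
    EnrichKitError,
    effective_padj,
    symbol_to_id_map,
)

logger = logging.getLogger(__name__)

SIMILARITY_MEASURES = ("jaccard", "overlap", "kappa")


def rank_genesets(enrichment: pd.DataFrame, n_gs: int) -> pd.DataFrame:
    """Top ``n_gs`` genesets by gs_pvalue.

    Ties broken by larger gs_de_count, then lexicographic gs_id, so the
    selection is deterministic.
    """
    if n_gs < 1:
        raise EnrichKitError("n_gs must be >= 1")
    if n_gs > len(enrichment):
        logger.warning(
            "n_gs=%d exceeds table size %d; clamping", n_gs, len(enrichment)
        )
        n_gs = len(enrichment)
    de_count = enrichment["gs_de_count"].fillna(-1)
    order = enrichment.assign(_neg_count=-de_count).sort_values(
        ["gs_pvalue", "_neg_count", "gs_id"], kind="mergesort"
    )
    return order.drop(columns="_neg_count").head(n_gs)


def build_gene_geneset_graph(
    bundle: AnalysisBundle,
    n_gs: int = 15,
    de_threshold: float = 0.05,
) -> nx.Graph:
    """Bipartite membership graph over the top genesets and their DE members.

    Geneset nodes carry id/description/z_score; gene nodes carry
    id/symbol/log2fc. Edges are unweighted membership links; a geneset
    node's degree equals its number of resolved DE members.
    """
    top = rank_genesets(bundle.enrichment, n_gs)
    sym2id, _ = symbol_to_id_map(bundle.annotation)
    de_idx = bundle.de.set_index("gene_id")
    padj = effective_padj(bundle.de)
    padj.index = bundle.de["gene_id"]

    graph = nx.Graph()
    for row in top.itertuples(index=False):
        graph.add_node(
            row.gs_id,
            type="geneset",
            description=row.gs_description,
            z_score=float(row.z_score) if pd.notna(row.z_score) else float("nan"),
            gs_pvalue=float(row.gs_pvalue),
            bipartite=0,
        )
        genes = row.gs_genes if isinstance(row.gs_genes, (list, tuple)) else []
        for sym in genes:
            gid = sym2id.get(sym)
            if gid is None or gid not in de_idx.index:
                continue
            if padj[gid] > de_threshold:
                continue
            if gid not in graph:
                graph.add_node(
                    gid,
                    type="gene",
                    symbol=sym,
                    log2fc=float(de_idx.loc[gid, "log2fc"]),
                    bipartite=1,
                )
            graph.add_edge(row.gs_id, gid)
    return graph


def _membership_sets(enrichment: pd.DataFrame) -> dict[str, frozenset[str]]:
    return {
        gs_id: frozenset(genes if isinstance(genes, (list, tuple)) else [])
        for gs_id, genes in zip(enrichment["gs_id"], enrichment["gs_genes"])
    }


def kappa_statistic(a: frozenset, b: frozenset, universe_size: int) -> float:
    """Cohen's kappa of two membership indicator vectors over the universe."""
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = universe_size - n11 - n10 - n01
    if n00 < 0:
        raise EnrichKitError(
            f"universe_size {universe_size} smaller than union of memberships"
        )
    total = universe_size
    po = (n11 + n00) / total
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / total**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def geneset_similarity(
    enrichment: pd.DataFrame,
    measure: str = "overlap",
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Square symmetric similarity matrix over gs_ids.

    jaccard = |A∩B|/|A∪B|; overlap = |A∩B|/min(|A|,|B|);
    kappa = chance-corrected agreement over the gene universe (requires
    ``universe_size``, defaulting to the union of all memberships).
    """
    if measure not in SIMILARITY_MEASURES:
        raise EnrichKitError(
            f"unknown measure {measure!r}; supported: {SIMILARITY_MEASURES}"
        )
    sets = _membership_sets(enrichment)
    ids = list(sets)
    if len(ids) < 2:
        raise EnrichKitError("geneset_similarity requires >= 2 genesets")
    if measure == "kappa" and universe_size is None:
        universe_size = len(frozenset().union(*sets.values()))
        if universe_size == 0:
            raise EnrichKitError("kappa requires a non-empty universe")
    mat = np.ones((len(ids), len(ids)))
    for i, gi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            a, b = sets[gi], sets[ids[j]]
            if measure == "jaccard":
                union = len(a | b)
                sim = len(a & b) / union if union else 0.0
            elif measure == "overlap":
                m = min(len(a), len(b))
                sim = len(a & b) / m if m else 0.0
            else:
                sim = kappa_statistic(a, b, universe_size)
            mat[i, j] = mat[j, i] = sim
    out = pd.DataFrame(mat, index=ids, columns=ids)
    out.attrs["measure"] = measure
    return out


def build_enrichment_map(
    enrichment: pd.DataFrame,
    n_gs: int = 15,
    measure: str = "overlap",
    edge_threshold: float = 0.25,
    universe_size: int | None = None,
) -> nx.Graph:
    """Geneset similarity graph: nodes = top genesets, edges where sim >= threshold."""
    lo = -1.0 if measure == "kappa" else 0.0
    if not (lo <= edge_threshold <= 1.0):
        raise EnrichKitError(
            f"edge_threshold {edge_threshold} outside [{lo}, 1] for measure {measure!r}"
        )
    top = rank_genesets(enrichment, n_gs)
    sim = geneset_similarity(top, measure=measure, universe_size=universe_size)
    graph = nx.Graph(measure=measure, edge_threshold=edge_threshold)
    sizes = top["gs_genes"].map(
        lambda g: len(g) if isinstance(g, (list, tuple)) else 0
    )
    for row, size in zip(top.itertuples(index=False), sizes):
        graph.add_node(
            row.gs_id,
            gs_pvalue=float(row.gs_pvalue),
            z_score=float(row.z_score) if pd.notna(row.z_score) else float("nan"),
            size=int(size),
            description=row.gs_description,
        )
    ids = list(sim.index)
    for i, gi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            w = sim.iat[i, j]
            if w >= edge_threshold:
                graph.add_edge(gi, ids[j], weight=float(w))
    return graph


def detect_communities(
    graph: nx.Graph,
    method: str = "greedy_modularity",
    seed: int = 0,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Partition the enrichment map and pick per-community representatives.

    Returns a copy of the graph with a ``community`` node attribute and a
    table (community, representative, n_members); the representative is the
    member with the lowest gs_pvalue (tie: lexicographic id). Community
    labels are numbered by their representative's significance.
    """
    if len(graph) == 0:
        raise EnrichKitError("detect_communities: empty graph")
    if method == "greedy_modularity":
        communities = nx.community.greedy_modularity_communities(graph, weight="weight")
    elif method == "label_propagation":
        communities = list(
            nx.community.asyn_lpa_communities(graph, weight="weight", seed=seed)
        )
    else:
        raise EnrichKitError(
            f"unknown method {method!r}; supported: greedy_modularity, label_propagation"
        )

    def representative(nodes: set) -> str:
        return min(nodes, key=lambda n: (graph.nodes[n].get("gs_pvalue", 1.0), n))

    ordered = sorted(
        (sorted(c) for c in communities),
        key=lambda c: (
            graph.nodes[representative(set(c))].get("gs_pvalue", 1.0),
            representative(set(c)),
        ),
    )
    out = graph.copy()
    records = []
    for label, members in enumerate(ordered):
        rep = representative(set(members))
        for node in members:
            out.nodes[node]["community"] = label
        records.append(
            {"community": label, "representative": rep, "n_members": len(members)}
        )
    table = pd.DataFrame(records, columns=["community", "representative", "n_members"])
    return out, table


def project_bipartite(graph: nx.Graph, side: str = "geneset") -> nx.Graph:
    """Unipartite projection; edge weight = number of shared neighbors."""
    if side not in ("gene", "geneset"):
        raise EnrichKitError(f"unknown side {side!r}; supported: gene, geneset")
    keep = [n for n, d in graph.nodes(data=True) if d.get("type") == side]
    other = [n for n, d in graph.nodes(data=True) if d.get("type") not in (side, None)]
    if len(keep) + len(other) != len(graph):
        raise EnrichKitError("projection requires a typed bipartite graph")
    proj = nx.bipartite.weighted_projected_graph(graph, keep)
    # networkx builds the projection from set iterations, so its node/edge
    # insertion order is hash-dependent; rebuild canonically for stable output
    out = nx.Graph()
    out.add_nodes_from((n, dict(proj.nodes[n])) for n in keep)
    for u, v, data in sorted(
        (tuple(sorted((u, v), key=str)) + (d,) for u, v, d in proj.edges(data=True)),
        key=lambda e: (str(e[0]), str(e[1])),
    ):
        out.add_edge(u, v, **data)
    return out


def extract_backbone(
    graph: nx.Graph,
    side: str = "geneset",
    alpha: float = 0.05,
) -> nx.Graph:
    """Salient-edge backbone of a bipartite projection (disparity filter).

    The bipartite graph is projected onto ``side`` with shared-neighbor
    edge weights; for each endpoint of degree k and strength s an edge of
    weight w scores ``(1 - w/s)^(k-1)``, and the edge is kept if the score
    is below ``alpha`` at either endpoint. Degree-1 endpoints always
    retain their single edge.
    """
    if not (0 < alpha <= 1):
        raise EnrichKitError(f"alpha must be in (0, 1], got {alpha}")
    proj = project_bipartite(graph, side=side)
    backbone = nx.Graph()
    backbone.add_nodes_from(proj.nodes(data=True))
    degrees = dict(proj.degree())
    strengths = dict(proj.degree(weight="weight"))
    for u, v, data in proj.edges(data=True):
        w = data["weight"]
        keep = False
        for end in (u, v):
            k = degrees[end]
            if k == 1:
                keep = True
                break
            p = w / strengths[end]
            score = (1 - p) ** (k - 1)
            if score < alpha:
                keep = True
                break
        if keep:
            backbone.add_edge(u, v, weight=w)
    return backbone


def write_graph(graph: nx.Graph, path: str, fmt: str = "graphml") -> None:
    """Export as GraphML or DOT; NaN attributes are stringified for GraphML."""
    if fmt == "graphml":
        clean = graph.copy()
        for _, data in clean.nodes(data=True):
            for key, value in list(data.items()):
                if isinstance(value, float) and np.isnan(value):
                    data[key] = "NA"
        nx.write_graphml(clean, path)
    elif fmt == "dot":
        lines = ["graph G {"]
        for node, data in graph.nodes(data=True):
            attrs = ", ".join(f'{k}="{v}"' for k, v in data.items())
            lines.append(f'  "{node}" [{attrs}];')
        for u, v, data in graph.edges(data=True):
            attrs = ", ".join(f'{k}="{v}"' for k, v in data.items())
            lines.append(f'  "{u}" -- "{v}"' + (f" [{attrs}];" if attrs else ";"))
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise EnrichKitError(f"unknown graph format {fmt!r}; supported: graphml, dot")
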