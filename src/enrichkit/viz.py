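"""Plot-data builders and static renderers for the visual summaries.

Every figure is computed in two stages: a pure builder returns a
:class:`PlotData` (coordinates, orderings, labels — the tested surface),
and a renderer turns a PlotData into an SVG/PNG without altering it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from enrichkit.core_model import (
    AnalysisBundle,
    EnrichKitError,
    effective_padj,
    symbol_to_id_map,
)
from enrichkit.scoring import GenesetScoreMatrix, TransformedMatrix
from enrichkit.topology import rank_genesets


@dataclass
class PlotData:
    """Computed data behind one visual summary.

    ``table`` holds point/record data; matrix-shaped summaries use
    ``matrix`` plus row/col orders. ``aesthetics`` maps source attributes
    to visual channels; ``labels`` is the subset of ids to annotate.
    """

    kind: str
    table: pd.DataFrame | None = None
    matrix: pd.DataFrame | None = None
    row_order: list[str] | None = None
    col_order: list[str] | None = None
    labels: list[str] = field(default_factory=list)
    aesthetics: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc: dict = {
            "kind": self.kind,
            "labels": list(self.labels),
            "aesthetics": dict(self.aesthetics),
            "meta": self.meta,
        }
        if self.table is not None:
            records = self.table.where(pd.notna(self.table), None)
            doc["records"] = records.to_dict(orient="records")
        if self.matrix is not None:
            values = self.matrix.to_numpy(dtype=float)
            doc["matrix"] = {
                "index": list(map(str, self.matrix.index)),
                "columns": list(map(str, self.matrix.columns)),
                "values": [
                    [None if np.isnan(v) else v for v in row] for row in values.tolist()
                ],
            }
        if self.row_order is not None:
            doc["row_order"] = list(self.row_order)
        if self.col_order is not None:
            doc["col_order"] = list(self.col_order)
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def gs_volcano_data(
    enrichment: pd.DataFrame, x: str = "z_score", n_labels: int = 5
) -> PlotData:
    """Geneset volcano: chosen score vs -log10 p, point size = DE-member count.

    Labels go to the ``n_labels`` most significant genesets; genesets with
    a missing score are excluded (counted in ``meta["n_excluded"]``).
    """
    if x not in ("z_score", "aggr_score"):
        raise EnrichKitError(f"x must be z_score or aggr_score, got {x!r}")
    if x not in enrichment.columns or enrichment[x].isna().all():
        raise EnrichKitError(
            f"column {x!r} not computed; run compute_aggregate_scores first"
        )
    keep = enrichment[enrichment[x].notna()].copy()
    n_excluded = len(enrichment) - len(keep)
    table = pd.DataFrame(
        {
            "gs_id": keep["gs_id"],
            "x": keep[x].astype(float),
            "y": -np.log10(keep["gs_pvalue"].astype(float)),
            "size": keep["gs_de_count"].fillna(0).astype(float),
            "description": keep["gs_description"],
        }
    ).reset_index(drop=True)
    labels = list(keep.sort_values(["gs_pvalue", "gs_id"]).head(n_labels)["gs_id"])
    return PlotData(
        kind="gs_volcano",
        table=table,
        labels=labels,
        aesthetics={x: "x", "neg_log10_pvalue": "y", "gs_de_count": "size"},
        meta={"x": x, "n_excluded": n_excluded},
    )


def _resolved_de_members(
    genes, sym2id: dict[str, str], de_idx: pd.DataFrame, de_threshold: float
) -> list[tuple[str, str, float]]:
    """(gene_id, symbol, log2fc) for members that are DE at the threshold."""
    genes = genes if isinstance(genes, (list, tuple)) else []
    out = []
    for sym in genes:
        gid = sym2id.get(sym)
        if gid is None or gid not in de_idx.index:
            continue
        padj = de_idx.loc[gid, "padj"]
        padj = 1.0 if pd.isna(padj) else padj
        if padj <= de_threshold:
            out.append((gid, sym, float(de_idx.loc[gid, "log2fc"])))
    return out


def enhanced_table_data(
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    n_gs: int = 15,
    de_threshold: float = 0.05,
) -> PlotData:
    """Per-gene contributions: one point per (geneset, DE member).

    x = member log2fc, y = geneset row index in significance order. Rows
    with zero DE members stay present (listed in ``meta["rows"]``).
    """
    top = rank_genesets(enrichment, n_gs)
    sym2id, _ = symbol_to_id_map(annotation)
    de_idx = de.set_index("gene_id")
    records = []
    rows = []
    for row_idx, row in enumerate(top.itertuples(index=False)):
        rows.append(row.gs_id)
        for gid, sym, lfc in _resolved_de_members(
            row.gs_genes, sym2id, de_idx, de_threshold
        ):
            records.append(
                {
                    "gs_id": row.gs_id,
                    "gene_id": gid,
                    "symbol": sym,
                    "x": lfc,
                    "y": row_idx,
                }
            )
    table = pd.DataFrame(records, columns=["gs_id", "gene_id", "symbol", "x", "y"])
    return PlotData(
        kind="enhanced_table",
        table=table,
        aesthetics={"log2fc": "x", "geneset_rank": "y"},
        meta={"rows": rows, "de_threshold": de_threshold},
    )


def scores_heatmap_data(
    scores: GenesetScoreMatrix,
    cluster_rows: bool = True,
    cluster_cols: bool = True,
) -> PlotData:
    """Matrix of sample-wise geneset scores, optionally average-linkage ordered."""
    values = scores.values
    if values.empty:
        raise EnrichKitError("scores_heatmap_data: empty score matrix")

    def order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 2:
            return list(frame.index)
        link = hierarchy.linkage(pdist(frame.to_numpy(), metric="euclidean"), "average")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    row_order = order(values) if cluster_rows else list(values.index)
    col_order = order(values.T) if cluster_cols else list(values.columns)
    return PlotData(
        kind="scores_heatmap",
        matrix=values,
        row_order=row_order,
        col_order=col_order,
        aesthetics={"geneset_score": "color"},
    )


def summary_heat_data(
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    n_gs: int = 15,
    de_threshold: float = 0.05,
) -> PlotData:
    """Membership/effect matrix showing redundancy between genesets.

    Rows = top genesets, columns = union of their DE members; a cell holds
    the member's log2fc, or NaN for non-members. Columns are ordered by
    how many genesets contain the gene, descending (ties: symbol).
    """
    top = rank_genesets(enrichment, n_gs)
    sym2id, _ = symbol_to_id_map(annotation)
    de_idx = de.set_index("gene_id")
    memberships: dict[str, dict[str, float]] = {}
    sym_of: dict[str, str] = {}
    for row in top.itertuples(index=False):
        memberships[row.gs_id] = {}
        for gid, sym, lfc in _resolved_de_members(
            row.gs_genes, sym2id, de_idx, de_threshold
        ):
            memberships[row.gs_id][gid] = lfc
            sym_of[gid] = sym
    union = sorted(sym_of)
    counts = {g: sum(1 for m in memberships.values() if g in m) for g in union}
    col_ids = sorted(union, key=lambda g: (-counts[g], sym_of[g]))
    mat = pd.DataFrame(
        [[memberships[gs].get(g, np.nan) for g in col_ids] for gs in memberships],
        index=list(memberships),
        columns=[sym_of[g] for g in col_ids],
    )
    return PlotData(
        kind="summary_heat",
        matrix=mat,
        row_order=list(mat.index),
        col_order=list(mat.columns),
        aesthetics={"log2fc": "color"},
        meta={"gene_ids": col_ids},
    )


def signature_volcano_data(bundle: AnalysisBundle, gs_id: str) -> PlotData:
    """DE volcano with one geneset's members flagged and labeled.

    Background = every DE-table gene with a non-missing padj; genes with
    missing padj are excluded with their count in ``meta``.
    """
    hit = bundle.enrichment[bundle.enrichment["gs_id"] == gs_id]
    if hit.empty:
        raise EnrichKitError(f"unknown geneset id {gs_id!r}")
    genes = hit.iloc[0]["gs_genes"]
    genes = genes if isinstance(genes, (list, tuple)) else []
    sym2id, _ = symbol_to_id_map(bundle.annotation)
    member_ids = {sym2id[s] for s in genes if s in sym2id}
    de = bundle.de
    keep = de["padj"].notna()
    n_excluded = int((~keep).sum())
    sub = de.loc[keep]
    table = pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "x": sub["log2fc"].astype(float),
            "y": -np.log10(sub["padj"].astype(float)),
            "member": sub["gene_id"].isin(member_ids),
        }
    ).reset_index(drop=True)
    labels = list(table.loc[table["member"], "gene_id"])
    return PlotData(
        kind="signature_volcano",
        table=table,
        labels=labels,
        aesthetics={"log2fc": "x", "neg_log10_padj": "y", "member": "color"},
        meta={"gs_id": gs_id, "n_excluded_missing_padj": n_excluded},
    )


def signature_heatmap_data(
    bundle: AnalysisBundle,
    gs_id: str,
    transformed: TransformedMatrix,
    standardize: bool = True,
) -> PlotData:
    """Members x samples heatmap of transformed expression for one geneset."""
    hit = bundle.enrichment[bundle.enrichment["gs_id"] == gs_id]
    if hit.empty:
        raise EnrichKitError(f"unknown geneset id {gs_id!r}")
    genes = hit.iloc[0]["gs_genes"]
    genes = genes if isinstance(genes, (list, tuple)) else []
    sym2id, _ = symbol_to_id_map(bundle.annotation)
    ids = [sym2id[s] for s in genes if s in sym2id]
    ids = [g for g in ids if g in transformed.values.index]
    if not ids:
        raise EnrichKitError(f"geneset {gs_id!r} has no resolvable member in the matrix")
    mat = transformed.values.loc[ids].copy()
    if standardize:
        arr = mat.to_numpy(dtype=float)
        sds = arr.std(axis=1, ddof=1)
        means = arr.mean(axis=1)
        safe = np.where(sds == 0, 1.0, sds)
        arr = (arr - means[:, None]) / safe[:, None]
        arr[sds == 0] = 0.0
        mat = pd.DataFrame(arr, index=mat.index, columns=mat.columns)
    samples = bundle.expression.samples
    cond_col = samples.columns[0]
    return PlotData(
        kind="signature_heatmap",
        matrix=mat,
        row_order=list(mat.index),
        col_order=list(mat.columns),
        aesthetics={"expression": "color", "condition": "column_annotation"},
        meta={
            "gs_id": gs_id,
            "standardize": standardize,
            "condition": dict(zip(samples.index.map(str), samples[cond_col].map(str))),
        },
    )


def spider_data(
    enrichments: pd.DataFrame | list[pd.DataFrame],
    n_gs: int = 10,
    value: str = "neg_log10_p",
    trace_names: list[str] | None = None,
) -> PlotData:
    """Radar comparison of one or more enrichment tables.

    Axes = union of the top-``n_gs`` gs_ids of every input, aligned by
    gs_id; one trace per input. A geneset absent from an input gets value
    0 with ``missing=True``.
    """
    if value not in ("neg_log10_p", "z_score"):
        raise EnrichKitError(f"unknown value {value!r}; supported: neg_log10_p, z_score")
    if isinstance(enrichments, pd.DataFrame):
        enrichments = [enrichments]
    if trace_names is None:
        trace_names = [f"enrichment_{i}" for i in range(len(enrichments))]
    axis_ids: list[str] = []
    best_p: dict[str, float] = {}
    for enr in enrichments:
        for row in rank_genesets(enr, min(n_gs, len(enr))).itertuples(index=False):
            if row.gs_id not in best_p or row.gs_pvalue < best_p[row.gs_id]:
                best_p[row.gs_id] = row.gs_pvalue
            if row.gs_id not in axis_ids:
                axis_ids.append(row.gs_id)
    if not axis_ids:
        raise EnrichKitError("spider_data: empty union of top genesets")
    axis_ids = sorted(axis_ids, key=lambda g: (best_p[g], g))
    records = []
    for name, enr in zip(trace_names, enrichments):
        lookup = enr.set_index("gs_id")
        for gs in axis_ids:
            if gs in lookup.index:
                if value == "neg_log10_p":
                    v = -np.log10(float(lookup.loc[gs, "gs_pvalue"]))
                else:
                    z = lookup.loc[gs, "z_score"]
                    v = float(z) if pd.notna(z) else 0.0
                records.append(
                    {"trace": name, "gs_id": gs, "value": v, "missing": False}
                )
            else:
                records.append(
                    {"trace": name, "gs_id": gs, "value": 0.0, "missing": True}
                )
    table = pd.DataFrame(records, columns=["trace", "gs_id", "value", "missing"])
    return PlotData(
        kind="spider",
        table=table,
        aesthetics={value: "radius"},
        meta={"axes": axis_ids, "value": value, "traces": list(trace_names)},
    )


# ---------------------------------------------------------------------------
# rendering — consumes PlotData, never modifies it

_SAVEFIG_KW = {"metadata": {"Date": None}}


def _finish(fig, path: str | Path) -> None:
    path = str(path)
    with plt.rc_context({"svg.hashsalt": "enrichkit"}):
        kw = _SAVEFIG_KW if path.endswith(".svg") else {}
        fig.savefig(path, **kw)
    plt.close(fig)


def render(data: PlotData, path: str | Path) -> None:
    """Render a PlotData to SVG/PNG (dispatch on kind)."""
    renderer = _RENDERERS.get(data.kind)
    if renderer is None:
        raise EnrichKitError(f"no renderer for plot kind {data.kind!r}")
    renderer(data, path)


def _render_scatter(data: PlotData, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    t = data.table
    if data.kind == "signature_volcano":
        bg = t[~t["member"]]
        fg = t[t["member"]]
        ax.scatter(bg["x"], bg["y"], s=8, c="lightgray")
        ax.scatter(fg["x"], fg["y"], s=20, c="crimson")
    elif data.kind == "gs_volcano":
        ax.scatter(t["x"], t["y"], s=10 + 2 * t["size"], c="steelblue", alpha=0.7)
        lookup = t.set_index("gs_id")
        for gs in data.labels:
            ax.annotate(gs, (lookup.loc[gs, "x"], lookup.loc[gs, "y"]), fontsize=7)
    else:  # enhanced_table
        ax.scatter(t["x"], t["y"], s=14, c="seagreen", alpha=0.7)
        ax.set_yticks(range(len(data.meta.get("rows", []))))
        ax.set_yticklabels(data.meta.get("rows", []), fontsize=7)
        ax.invert_yaxis()
    ax.set_xlabel(next((k for k, v in data.aesthetics.items() if v == "x"), "x"))
    ax.set_ylabel(next((k for k, v in data.aesthetics.items() if v == "y"), "y"))
    ax.set_title(data.kind)
    fig.tight_layout()
    _finish(fig, path)


def _render_heatmap(data: PlotData, path) -> None:
    mat = data.matrix.loc[data.row_order, data.col_order]
    fig, ax = plt.subplots(figsize=(6, 5))
    arr = np.ma.masked_invalid(mat.to_numpy(dtype=float))
    im = ax.imshow(arr, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.7)
    ax.set_title(data.kind)
    fig.tight_layout()
    _finish(fig, path)


def _render_spider(data: PlotData, path) -> None:
    axes = data.meta["axes"]
    angles = np.linspace(0, 2 * np.pi, len(axes), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"polar": True})
    for trace in data.meta["traces"]:
        sub = data.table[data.table["trace"] == trace].set_index("gs_id")
        values = [sub.loc[g, "value"] for g in axes]
        ax.plot(
            np.append(angles, angles[0]), values + [values[0]], label=trace, linewidth=1.5
        )
    ax.set_xticks(angles)
    ax.set_xticklabels(axes, fontsize=6)
    ax.legend(fontsize=7, loc="upper right")
    ax.set_title(data.kind)
    _finish(fig, path)


_RENDERERS = {
    "gs_volcano": _render_scatter,
    "enhanced_table": _render_scatter,
    "signature_volcano": _render_scatter,
    "scores_heatmap": _render_heatmap,
    "summary_heat": _render_heatmap,
    "signature_heatmap": _render_heatmap,
    "spider": _render_spider,
}
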