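"""Self-contained HTML report and reproducible command snippets.

The report embeds every figure as inline SVG and closes with a
reproducibility appendix: the exact configuration used plus, for each
figure, the command line that regenerates its underlying plot data.
Given a pinned ``timestamp`` the output bytes are fully deterministic.
"""

from __future__ import annotations

import hashlib
import html
import json
from datetime import datetime, timezone
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from enrichkit.app_report.bookmarks import Bookmarks
from enrichkit.core_model import (
    AnalysisBundle,
    EnrichKitError,
    describe_bundle,
    symbol_to_id_map,
)
from enrichkit.scoring import compute_aggregate_scores, transform_counts
from enrichkit.viz import (
    PlotData,
    render,
    signature_heatmap_data,
    signature_volcano_data,
)

GENE_LINK_TEMPLATES = {
    "NCBI Gene": "https://www.ncbi.nlm.nih.gov/gene/?term={symbol}",
    "GeneCards": "https://www.genecards.org/cgi-bin/carddisp.pl?gene={symbol}",
    "GTEx": "https://gtexportal.org/home/gene/{symbol}",
}
GENESET_LINK_TEMPLATES = {
    "AmiGO": "http://amigo.geneontology.org/amigo/term/{gs_id}",
}

#: op name -> (CLI subcommand, extra flag names pulled from kwargs)
_SNIPPET_OPS = {
    "gs_volcano_data": ("viz --kind gs_volcano", ()),
    "enhanced_table_data": ("viz --kind enhanced_table", ()),
    "scores_heatmap_data": ("viz --kind scores_heatmap", ()),
    "summary_heat_data": ("viz --kind summary_heat", ()),
    "signature_volcano_data": ("viz --kind signature_volcano", ("gs_id",)),
    "signature_heatmap_data": ("viz --kind signature_heatmap", ("gs_id",)),
    "spider_data": ("viz --kind spider", ()),
    "score": ("score", ()),
    "graph": ("graph", ()),
    "distill": ("distill", ()),
    "validate": ("validate", ()),
    "fixture": ("fixture", ()),
    "report": ("report", ()),
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def snippet_for(
    op_name: str,
    config: dict,
    bundle_path: str = "bundle.json",
    config_path: str = "config.yaml",
    out: str | None = None,
    **kwargs,
) -> str:
    """Command line that reproduces one operation's output.

    The emitted command runs the installed ``enrichkit`` CLI against the
    same bundle and config; a hash of the config is appended as a comment
    so drift is detectable.
    """
    if op_name not in _SNIPPET_OPS:
        raise EnrichKitError(
            f"unknown op {op_name!r}; known: {sorted(_SNIPPET_OPS)}"
        )
    sub, extra_flags = _SNIPPET_OPS[op_name]
    parts = [f"enrichkit {sub}"]
    if op_name != "fixture":
        parts.append(f"--bundle {bundle_path}")
    parts.append(f"--config {config_path}")
    for flag in extra_flags:
        if flag in kwargs:
            parts.append(f"--{flag.replace('_', '-')} {kwargs[flag]}")
    if out is None:
        out = f"out/{op_name}"
    parts.append(f"--out {out}")
    return " ".join(parts) + f"  # config sha256:{config_hash(config)}"


def _svg_string(plot_data: PlotData, tmp_dir: Path, name: str) -> str:
    path = tmp_dir / f"{name}.svg"
    render(plot_data, path)
    return path.read_text(encoding="utf-8")


def _gene_condition_figure(
    bundle: AnalysisBundle, gene_id: str, tmp_dir: Path
) -> str:
    counts = bundle.expression.counts.loc[gene_id]
    cond = bundle.expression.samples.iloc[:, 0]
    fig, ax = plt.subplots(figsize=(4, 3))
    levels = list(dict.fromkeys(cond))
    for i, level in enumerate(levels):
        vals = counts[cond == level].to_numpy(dtype=float)
        x = np.linspace(i - 0.15, i + 0.15, num=len(vals))
        ax.plot(x, vals, "o", label=str(level))
    ax.set_xticks(range(len(levels)))
    ax.set_xticklabels([str(lv) for lv in levels])
    ax.set_ylabel("counts")
    ax.set_title(gene_id)
    fig.tight_layout()
    path = tmp_dir / f"gene_{gene_id}.svg"
    with plt.rc_context({"svg.hashsalt": "enrichkit"}):
        fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path.read_text(encoding="utf-8")


def _table_html(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    body_rows = []
    for row in df.itertuples(index=False):
        cells = "".join(
            f"<td>{html.escape(f'{v:.4g}' if isinstance(v, float) else str(v))}</td>"
            for v in row
        )
        body_rows.append(f"<tr>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead><tbody>{''.join(body_rows)}</tbody></table>"
    )


def assemble_report(
    bundle: AnalysisBundle,
    bookmarks: Bookmarks,
    config: dict,
    out_path: str | Path,
    timestamp: str | None = None,
    bundle_path: str = "bundle.json",
    config_path: str = "config.yaml",
) -> Path:
    """Assemble the self-contained HTML report.

    One section per bookmarked geneset (description, member table,
    signature heatmap + volcano), one per bookmarked gene (DE row,
    expression-by-condition figure, external links), then a
    reproducibility appendix with the config and per-figure snippets.
    ``timestamp`` pins the embedded generation time for byte-identical
    reruns.
    """
    out_path = Path(out_path)
    de_threshold = float(config.get("de_threshold", 0.05))
    aggr = config.get("aggr", "mean")
    stamp = timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds")

    enriched = compute_aggregate_scores(
        bundle.enrichment, bundle.de, bundle.annotation, de_threshold, aggr
    )
    scored_bundle = AnalysisBundle(
        expression=bundle.expression,
        de=bundle.de,
        enrichment=enriched,
        annotation=bundle.annotation,
    )
    transformed = transform_counts(bundle.expression)

    tmp_dir = out_path.parent / (out_path.stem + "_assets")
    tmp_dir.mkdir(parents=True, exist_ok=True)

    summary = describe_bundle(bundle, de_threshold)
    snippets: list[tuple[str, str]] = []
    sections: list[str] = []

    for gs_id in bookmarks.genesets:
        row = enriched[enriched["gs_id"] == gs_id]
        if row.empty:
            raise EnrichKitError(f"bookmarked geneset {gs_id!r} not in enrichment table")
        row = row.iloc[0]
        sym2id, _ = symbol_to_id_map(bundle.annotation)
        de_idx = bundle.de.set_index("gene_id")
        genes = row["gs_genes"] if isinstance(row["gs_genes"], (list, tuple)) else []
        member_rows = []
        for sym in genes:
            gid = sym2id.get(sym)
            if gid is not None and gid in de_idx.index:
                lfc = float(de_idx.loc[gid, "log2fc"])
            else:
                lfc = float("nan")
            member_rows.append({"symbol": sym, "gene_id": gid or "?", "log2fc": lfc})
        members_df = pd.DataFrame(
            member_rows, columns=["symbol", "gene_id", "log2fc"]
        )
        heat = signature_heatmap_data(scored_bundle, gs_id, transformed)
        volc = signature_volcano_data(scored_bundle, gs_id)
        heat_svg = _svg_string(heat, tmp_dir, f"heat_{gs_id}")
        volc_svg = _svg_string(volc, tmp_dir, f"volcano_{gs_id}")
        heat_cmd = snippet_for(
            "signature_heatmap_data", config, bundle_path, config_path, gs_id=gs_id
        )
        volc_cmd = snippet_for(
            "signature_volcano_data", config, bundle_path, config_path, gs_id=gs_id
        )
        snippets += [
            (f"signature heatmap ({gs_id})", heat_cmd),
            (f"signature volcano ({gs_id})", volc_cmd),
        ]
        links = "".join(
            f'<a href="{html.escape(url.format(gs_id=gs_id))}">{name}</a> '
            for name, url in GENESET_LINK_TEMPLATES.items()
        )
        z = row["z_score"]
        sections.append(
            f'<section class="entity" id="gs-{html.escape(gs_id)}">'
            f"<h2>Geneset {html.escape(gs_id)}</h2>"
            f"<p>{html.escape(str(row['gs_description']))} — "
            f"p = {row['gs_pvalue']:.3g}, z = "
            f"{'NA' if pd.isna(z) else f'{z:.3f}'}</p>"
            f"<p>{links}</p>"
            f"{_table_html(members_df)}"
            f"<figure>{heat_svg}<figcaption><code>{html.escape(heat_cmd)}</code></figcaption></figure>"
            f"<figure>{volc_svg}<figcaption><code>{html.escape(volc_cmd)}</code></figcaption></figure>"
            "</section>"
        )

    ann_idx = bundle.annotation.set_index("gene_id")
    for gene_id in bookmarks.genes:
        de_row = bundle.de[bundle.de["gene_id"] == gene_id]
        if de_row.empty:
            raise EnrichKitError(f"bookmarked gene {gene_id!r} not in DE table")
        symbol = (
            str(ann_idx.loc[gene_id, "gene_name"])
            if gene_id in ann_idx.index
            else gene_id
        )
        fig_svg = _gene_condition_figure(bundle, gene_id, tmp_dir)
        links = "".join(
            f'<a href="{html.escape(url.format(symbol=symbol))}">{name}</a> '
            for name, url in GENE_LINK_TEMPLATES.items()
        )
        sections.append(
            f'<section class="entity" id="gene-{html.escape(gene_id)}">'
            f"<h2>Gene {html.escape(gene_id)} ({html.escape(symbol)})</h2>"
            f"<p>{links}</p>"
            f"{_table_html(de_row)}"
            f"<figure>{fig_svg}</figure>"
            "</section>"
        )

    if not sections:
        sections.append(
            "<section><p>No bookmarks were provided; the report contains "
            "only the bundle summary.</p></section>"
        )

    appendix_snippets = "".join(
        f"<li>{html.escape(label)}: <code>{html.escape(cmd)}</code></li>"
        for label, cmd in snippets
    )
    config_json = html.escape(json.dumps(config, indent=1, sort_keys=True, default=str))
    doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>enrichkit report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; font-size: 0.85em; }}
td, th {{ border: 1px solid #bbb; padding: 2px 6px; }}
section.entity {{ border-top: 2px solid #444; margin-top: 2em; padding-top: 1em; }}
figure {{ margin: 1em 0; }}
code {{ background: #f4f4f4; padding: 1px 4px; }}
</style>
</head>
<body>
<h1>enrichkit report</h1>
<p>Generated: {html.escape(stamp)}</p>
<section id="summary">
<h2>Bundle summary</h2>
<ul>
<li>genes: {summary["n_genes"]}</li>
<li>samples: {summary["n_samples"]}</li>
<li>DE genes (padj &le; {de_threshold:g}): {summary["n_de"]}</li>
<li>genesets: {summary["n_genesets"]}</li>
</ul>
</section>
{"".join(sections)}
<section id="reproducibility">
<h2>Reproducibility appendix</h2>
<p>Configuration (sha256:{config_hash(config)}):</p>
<pre>{config_json}</pre>
<ul>{appendix_snippets}</ul>
</section>
</body>
</html>
"""
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(doc, encoding="utf-8")
    return out_path
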