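"""Dialect converters: enrichment-tool output dialects -> harmonized schema.

Each supported tool writes its results with its own column names, gene
separators and "k/n" ratio encodings. A :class:`DialectSpec` captures
those conventions declaratively; :func:`shake` applies one to a raw table
and returns a harmonized enrichment table. Specs are data, not code:
they can be loaded from a YAML/JSON mapping and edited without touching
the converter.

The harmonized ``gs_pvalue`` takes the tool's adjusted p-value when the
tool reports one, else the raw p-value; the choice is recorded in the
result's ``attrs["pvalue_provenance"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from enrichkit.core_model import (
    ENRICHMENT_COLUMNS,
    EnrichKitError,
    symbol_to_id_map,
    _is_na_scalar,
)

logger = logging.getLogger(__name__)

GenesetCollection = dict[str, tuple[str, list[str]]]
"""gs_id -> (description, member gene symbols)."""


class DialectError(EnrichKitError):
    """Raised for unknown dialects or missing required columns."""


@dataclass(frozen=True)
class DialectSpec:
    """Declarative description of one tool's output format.

    ``column_map`` maps source column names to harmonized targets
    (gs_id, gs_description, gs_pvalue, gs_genes, gs_de_count,
    gs_bg_count). ``ratio_column`` names a "k/n" field parsed into
    (gs_de_count, gs_bg_count). ``id_description_split`` splits a single
    combined field (e.g. DAVID's ``GO:0006915~apoptotic process``) into
    id and description.
    """

    name: str
    column_map: dict[str, str] = field(default_factory=dict)
    gene_separator: str = ","
    ratio_column: str | None = None
    id_description_split: str | None = None
    pvalue_is_adjusted: bool = False
    description_defaults_to_id: bool = False

    @property
    def required_columns(self) -> list[str]:
        req = [
            src
            for src, tgt in self.column_map.items()
            if tgt in ("gs_id", "gs_pvalue", "gs_genes")
        ]
        if not self.description_defaults_to_id and self.id_description_split is None:
            req += [
                src for src, tgt in self.column_map.items() if tgt == "gs_description"
            ]
        return req


DIALECTS: dict[str, DialectSpec] = {
    "topgo": DialectSpec(
        name="topgo",
        column_map={
            "GO.ID": "gs_id",
            "Term": "gs_description",
            "p.value_elim": "gs_pvalue",
            "Significant": "gs_de_count",
            "Annotated": "gs_bg_count",
            "genes": "gs_genes",
        },
        gene_separator=",",
        pvalue_is_adjusted=False,
    ),
    "clusterprofiler": DialectSpec(
        name="clusterprofiler",
        column_map={
            "ID": "gs_id",
            "Description": "gs_description",
            "p.adjust": "gs_pvalue",
            "geneID": "gs_genes",
        },
        gene_separator="/",
        ratio_column="GeneRatio",
        pvalue_is_adjusted=True,
    ),
    "david": DialectSpec(
        name="david",
        column_map={
            "Term": "gs_id",
            "PValue": "gs_pvalue",
            "Count": "gs_de_count",
            "Genes": "gs_genes",
        },
        gene_separator=", ",
        id_description_split="~",
        pvalue_is_adjusted=False,
    ),
    "enrichr": DialectSpec(
        name="enrichr",
        column_map={
            "Term": "gs_id",
            "Adjusted.P.value": "gs_pvalue",
            "Genes": "gs_genes",
        },
        gene_separator=";",
        ratio_column="Overlap",
        pvalue_is_adjusted=True,
        description_defaults_to_id=True,
    ),
    "gprofiler": DialectSpec(
        name="gprofiler",
        column_map={
            "term_id": "gs_id",
            "term_name": "gs_description",
            "p_value": "gs_pvalue",
            "term_size": "gs_bg_count",
            "intersection_size": "gs_de_count",
            "intersection": "gs_genes",
        },
        gene_separator=",",
        pvalue_is_adjusted=True,
    ),
    "fgsea": DialectSpec(
        name="fgsea",
        column_map={
            "pathway": "gs_id",
            "padj": "gs_pvalue",
            "size": "gs_bg_count",
            "leadingEdge": "gs_genes",
        },
        gene_separator=",",
        pvalue_is_adjusted=True,
        description_defaults_to_id=True,
    ),
    "generic": DialectSpec(
        name="generic",
        column_map={
            "gs_id": "gs_id",
            "gs_description": "gs_description",
            "gs_pvalue": "gs_pvalue",
            "gs_genes": "gs_genes",
        },
        gene_separator=",",
        pvalue_is_adjusted=True,
    ),
}


def get_dialect(dialect: str | DialectSpec) -> DialectSpec:
    if isinstance(dialect, DialectSpec):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise DialectError(
            f"unknown dialect {dialect!r}; supported: {sorted(DIALECTS)}"
        ) from None


def dialect_from_config(config: dict) -> DialectSpec:
    """Build a DialectSpec from a YAML/JSON mapping, optionally extending a base."""
    base = get_dialect(config.get("base", "generic"))
    fields = {k: v for k, v in config.items() if k != "base"}
    return replace(base, **fields)


def _parse_ratio(value) -> tuple[float, float]:
    if _is_na_scalar(value):
        return np.nan, np.nan
    try:
        k, n = str(value).split("/")
        return float(int(k)), float(int(n))
    except ValueError:
        return np.nan, np.nan


def shake(
    table: pd.DataFrame,
    dialect: str | DialectSpec = "generic",
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Convert one tool's raw result table to the harmonized schema.

    Rows whose p-value cannot be parsed as a number in (0, 1] are dropped
    with a warning. Gene lists are split on the dialect separator with
    whitespace trimmed; ``case_insensitive=True`` additionally uppercases
    symbols (default preserves case — mouse symbols are mixed-case).
    """
    spec = get_dialect(dialect)
    missing = [c for c in spec.required_columns if c not in table.columns]
    if spec.ratio_column and spec.ratio_column not in table.columns:
        missing.append(spec.ratio_column)
    if missing:
        raise DialectError(
            f"dialect {spec.name!r}: missing required column(s) {missing} "
            f"(present: {list(table.columns)})"
        )

    out = pd.DataFrame(index=table.index)
    for src, tgt in spec.column_map.items():
        if src in table.columns:
            out[tgt] = table[src]

    if spec.id_description_split is not None:
        split = (
            out["gs_id"].astype(str).str.split(spec.id_description_split, n=1, expand=True)
        )
        out["gs_id"] = split[0].str.strip()
        desc = split[1] if split.shape[1] > 1 else split[0]
        out["gs_description"] = desc.fillna(out["gs_id"]).str.strip()
    if "gs_description" not in out.columns:
        out["gs_description"] = out["gs_id"]
    else:
        out["gs_description"] = out["gs_description"].fillna(out["gs_id"])

    if spec.ratio_column:
        parsed = table[spec.ratio_column].map(_parse_ratio)
        out["gs_de_count"] = [p[0] for p in parsed]
        out["gs_bg_count"] = [p[1] for p in parsed]

    pvals = pd.to_numeric(out["gs_pvalue"], errors="coerce")
    bad = pvals.isna() | (pvals <= 0) | (pvals > 1)
    if bad.any():
        logger.warning(
            "dialect %s: dropping %d row(s) with unparseable or out-of-range p-values",
            spec.name,
            int(bad.sum()),
        )
    out = out.loc[~bad].copy()
    out["gs_pvalue"] = pvals.loc[~bad]

    def split_genes(value) -> list[str]:
        if isinstance(value, (list, tuple, np.ndarray)):
            genes = [str(g).strip() for g in value]
        elif _is_na_scalar(value):
            genes = []
        else:
            genes = [g.strip() for g in str(value).split(spec.gene_separator)]
        genes = [g for g in genes if g]
        if case_insensitive:
            genes = [g.upper() for g in genes]
        return genes

    out["gs_genes"] = out["gs_genes"].map(split_genes)

    for col in ENRICHMENT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    if out["gs_de_count"].isna().all():
        out["gs_de_count"] = out["gs_genes"].map(len).astype(float)
    out = out[ENRICHMENT_COLUMNS].reset_index(drop=True)
    out.attrs["pvalue_provenance"] = (
        "adjusted" if spec.pvalue_is_adjusted else "raw"
    )
    out.attrs["dialect"] = spec.name
    return out


def render_dialect(enrichment: pd.DataFrame, dialect: str | DialectSpec) -> pd.DataFrame:
    """Inverse converter: write a harmonized table in a tool's raw format.

    Used to build multi-dialect fixtures of the same logical result; the
    harmonized p-value is placed in whatever column the dialect maps to
    ``gs_pvalue``.
    """
    spec = get_dialect(dialect)
    target_to_src = {tgt: src for src, tgt in spec.column_map.items()}
    raw = pd.DataFrame(index=enrichment.index)
    gs_id = enrichment["gs_id"].astype(str)
    if spec.id_description_split is not None:
        combined = gs_id + spec.id_description_split + enrichment["gs_description"].astype(str)
        raw[target_to_src["gs_id"]] = combined
    else:
        raw[target_to_src["gs_id"]] = gs_id
        if "gs_description" in target_to_src:
            raw[target_to_src["gs_description"]] = enrichment["gs_description"]
    raw[target_to_src["gs_pvalue"]] = enrichment["gs_pvalue"]
    raw[target_to_src["gs_genes"]] = enrichment["gs_genes"].map(
        lambda genes: spec.gene_separator.join(genes)
    )
    de_counts = enrichment["gs_genes"].map(len)
    if "gs_de_count" in enrichment.columns and enrichment["gs_de_count"].notna().any():
        de_counts = enrichment["gs_de_count"].fillna(de_counts).astype(int)
    bg_counts = de_counts
    if "gs_bg_count" in enrichment.columns and enrichment["gs_bg_count"].notna().any():
        bg_counts = enrichment["gs_bg_count"].fillna(de_counts).astype(int)
    if spec.ratio_column:
        raw[spec.ratio_column] = [
            f"{int(k)}/{int(n)}" for k, n in zip(de_counts, bg_counts)
        ]
    if "gs_de_count" in target_to_src:
        raw[target_to_src["gs_de_count"]] = de_counts.astype(int)
    if "gs_bg_count" in target_to_src:
        raw[target_to_src["gs_bg_count"]] = bg_counts.astype(int)
    return raw.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT

class GMTParseError(EnrichKitError):
    pass


def read_gmt(path: str | Path) -> GenesetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    collection: GenesetCollection = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTParseError(
                f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3"
            )
        name, description, *members = fields
        members = [m.strip() for m in members if m.strip()]
        collection[name] = (description, members)
    if not collection:
        logger.warning("%s: empty GMT file", path)
    return collection


def write_gmt(collection: GenesetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, description, *members])
        for name, (description, members) in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def collection_to_enrichment(collection: GenesetCollection) -> pd.DataFrame:
    """Skeleton harmonized table (p-values unset) from a geneset collection."""
    rows = [
        {
            "gs_id": name,
            "gs_description": description,
            "gs_pvalue": np.nan,
            "gs_genes": list(members),
        }
        for name, (description, members) in collection.items()
    ]
    df = pd.DataFrame(rows, columns=["gs_id", "gs_description", "gs_pvalue", "gs_genes"])
    for col in ENRICHMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[ENRICHMENT_COLUMNS]


# ---------------------------------------------------------------------------
# directional membership counts

def attach_membership_counts(
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    de_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fill up_count/down_count from the DE table.

    A member counts as up if its DE row has ``padj <= de_threshold`` (missing
    padj treated as 1.0) and ``log2fc > 0``; down analogously with
    ``log2fc < 0``. log2fc exactly 0 counts in neither direction.
    ``gs_de_count`` is left unchanged when already set, else filled with
    up_count + down_count.
    """
    if de.empty:
        raise EnrichKitError("attach_membership_counts: empty DE table")
    sym2id, _ = symbol_to_id_map(annotation)
    de_idx = de.set_index("gene_id")
    padj = de_idx["padj"].fillna(1.0)
    lfc = de_idx["log2fc"]

    out = enrichment.copy()
    up_counts, down_counts = [], []
    for genes in out["gs_genes"]:
        genes = genes if isinstance(genes, (list, tuple)) else []
        ids = [sym2id[g] for g in genes if g in sym2id]
        ids = [g for g in ids if g in de_idx.index]
        up = sum(1 for g in ids if padj[g] <= de_threshold and lfc[g] > 0)
        down = sum(1 for g in ids if padj[g] <= de_threshold and lfc[g] < 0)
        up_counts.append(up)
        down_counts.append(down)
    out["up_count"] = up_counts
    out["down_count"] = down_counts
    if "gs_de_count" not in out.columns or out["gs_de_count"].isna().all():
        out["gs_de_count"] = out["up_count"] + out["down_count"]
    else:
        out["gs_de_count"] = out["gs_de_count"].fillna(
            out["up_count"] + out["down_count"]
        )
    return out
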