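"""Validated four-component analysis bundle and its serialized interchange form.

The bundle joins four tabular inputs keyed by shared identifiers:

* expression — counts matrix (genes x samples) plus a sample table,
* de — differential-expression results (gene_id, log2fc, pvalue, padj),
* enrichment — harmonized geneset results (see :data:`ENRICHMENT_COLUMNS`),
* annotation — the gene_id -> gene_name bridge used to resolve the gene
  symbols reported by enrichment tools back to expression rows.

Expression and DE tables are keyed by stable gene ids; genesets carry
symbols as emitted by the enrichment tools; the annotation table is the
bridge between the two identifier universes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "enrichkit-bundle/1"

#: canonical column set of a harmonized enrichment table
ENRICHMENT_COLUMNS = [
    "gs_id",
    "gs_description",
    "gs_pvalue",
    "gs_genes",
    "gs_de_count",
    "gs_bg_count",
    "z_score",
    "aggr_score",
    "up_count",
    "down_count",
]


class EnrichKitError(Exception):
    """Base class for all package errors."""


class BundleValidationError(EnrichKitError):
    """Raised in strict validation when the bundle is inconsistent."""


class BundleParseError(EnrichKitError):
    """Raised when a serialized bundle file is malformed."""


class BundleSchemaError(BundleParseError):
    """Raised when the serialized schema version is unsupported."""


@dataclass
class ExpressionData:
    """Counts matrix plus sample metadata.

    Parameters
    ----------
    counts
        Non-negative matrix, index = gene ids, columns = sample ids.
    samples
        Sample table, index = sample ids, with at least one categorical
        covariate column (conventionally ``condition``).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise BundleValidationError("expression gene ids are not unique")
        if not self.counts.columns.is_unique:
            raise BundleValidationError("expression sample ids are not unique")
        if list(self.counts.columns) != list(self.samples.index):
            raise BundleValidationError(
                "counts columns and sample-table keys differ: "
                f"{list(self.counts.columns)} vs {list(self.samples.index)}"
            )
        values = self.counts.to_numpy()
        if np.isnan(values.astype(float)).any():
            raise BundleValidationError("counts contain missing entries")
        if (values < 0).any():
            raise BundleValidationError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionData):
            return NotImplemented
        return self.counts.equals(other.counts) and self.samples.equals(other.samples)


@dataclass
class AnalysisBundle:
    """The four matched inputs as one unit.

    ``de`` has columns gene_id/log2fc/pvalue/padj, ``enrichment`` the
    :data:`ENRICHMENT_COLUMNS`, ``annotation`` gene_id/gene_name.
    """

    expression: ExpressionData
    de: pd.DataFrame
    enrichment: pd.DataFrame
    annotation: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisBundle):
            return NotImplemented
        return (
            self.expression == other.expression
            and self.de.equals(other.de)
            and self.enrichment.equals(other.enrichment)
            and self.annotation.equals(other.annotation)
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_bundle`."""

    unmatched_de_ids: list[str] = field(default_factory=list)
    unresolved_symbols: list[tuple[str, str]] = field(default_factory=list)
    duplicated_ids: dict[str, list[str]] = field(default_factory=dict)
    empty_genesets: list[str] = field(default_factory=list)
    ambiguous_symbols: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)
    n_dropped_symbols: int = 0
    repaired: AnalysisBundle | None = None

    @property
    def has_errors(self) -> bool:
        return bool(
            self.unmatched_de_ids
            or self.unresolved_symbols
            or self.duplicated_ids
            or self.empty_genesets
            or self.fatal
        )


def symbol_to_id_map(annotation: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    """Map gene symbol -> gene id, first match in annotation order.

    Returns the map and the set of symbols that were ambiguous (mapped by
    more than one id); ambiguity is resolved first-match and reported.
    """
    mapping: dict[str, str] = {}
    ambiguous: set[str] = set()
    for gene_id, name in zip(annotation["gene_id"], annotation["gene_name"]):
        if name in mapping:
            if mapping[name] != gene_id:
                ambiguous.add(name)
        else:
            mapping[name] = gene_id
    return mapping, ambiguous


def _check_enrichment_frame(enrichment: pd.DataFrame) -> pd.DataFrame:
    out = enrichment.copy()
    for col in ENRICHMENT_COLUMNS:
        if col not in out.columns:
            out[col] = [None] * len(out) if col == "gs_genes" else np.nan
    return out[ENRICHMENT_COLUMNS]


def validate_bundle(bundle: AnalysisBundle, strict: bool = False) -> ValidationReport:
    """Cross-check the four components and optionally repair the genesets.

    In lax mode (default) geneset member symbols that cannot be resolved
    through the annotation are dropped from ``gs_genes`` in the returned
    ``repaired`` bundle, with the drop count logged. In strict mode any
    inconsistency raises :class:`BundleValidationError`.
    """
    report = ValidationReport()

    # enrichment may legitimately hold zero genesets; the other three may not
    for name in ("expression", "de", "enrichment", "annotation"):
        comp = getattr(bundle, name, None)
        if comp is None:
            report.fatal.append(f"missing component: {name}")
        elif name == "expression" and comp.counts.empty:
            report.fatal.append("empty component: expression")
        elif name in ("de", "annotation") and comp.empty:
            report.fatal.append(f"empty component: {name}")
    if report.fatal:
        raise BundleValidationError("; ".join(report.fatal))

    expr_ids = set(bundle.expression.counts.index)
    de_ids = list(bundle.de["gene_id"])

    dup_de = [g for g, n in pd.Series(de_ids).value_counts().items() if n > 1]
    if dup_de:
        report.duplicated_ids["de"] = sorted(dup_de)
    dup_ann = [
        g
        for g, n in bundle.annotation["gene_id"].value_counts().items()
        if n > 1
    ]
    if dup_ann:
        report.duplicated_ids["annotation"] = sorted(dup_ann)
    dup_gs = [
        g for g, n in bundle.enrichment["gs_id"].value_counts().items() if n > 1
    ]
    if dup_gs:
        report.duplicated_ids["enrichment"] = sorted(dup_gs)

    report.unmatched_de_ids = sorted(set(de_ids) - expr_ids)
    if de_ids and not (set(de_ids) & expr_ids):
        msg = "no overlap between DE gene ids and expression rows (mismatched identifier universes)"
        report.fatal.append(msg)
        raise BundleValidationError(msg)

    sym2id, ambiguous = symbol_to_id_map(bundle.annotation)
    report.ambiguous_symbols = sorted(ambiguous)

    enr = _check_enrichment_frame(bundle.enrichment)
    repaired_genes: list[list[str]] = []
    for gs_id, genes in zip(enr["gs_id"], enr["gs_genes"]):
        genes = list(genes) if genes is not None and not _is_na_scalar(genes) else []
        if not genes:
            report.empty_genesets.append(gs_id)
            repaired_genes.append(genes)
            continue
        kept = []
        for sym in genes:
            if sym in sym2id:
                kept.append(sym)
            else:
                report.unresolved_symbols.append((gs_id, sym))
        repaired_genes.append(kept)
    report.n_dropped_symbols = len(report.unresolved_symbols)

    if strict and report.has_errors:
        parts = []
        if report.unmatched_de_ids:
            parts.append(f"DE ids absent from expression: {report.unmatched_de_ids[:5]}")
        if report.unresolved_symbols:
            parts.append(
                f"unresolvable geneset symbols: {report.unresolved_symbols[:5]}"
            )
        if report.duplicated_ids:
            parts.append(f"duplicated ids: {report.duplicated_ids}")
        if report.empty_genesets:
            parts.append(f"empty genesets: {report.empty_genesets[:5]}")
        raise BundleValidationError("; ".join(parts))

    if report.n_dropped_symbols:
        logger.warning(
            "dropped %d unresolvable geneset symbols in lax validation",
            report.n_dropped_symbols,
        )
    repaired_enr = enr.copy()
    old_lens = [
        len(g) if g is not None and not _is_na_scalar(g) else 0
        for g in enr["gs_genes"]
    ]
    repaired_enr["gs_genes"] = repaired_genes
    # keep gs_de_count consistent with the repaired membership where it
    # tracked the membership before the repair
    new_counts = []
    for old_n, new_genes, cnt in zip(old_lens, repaired_genes, enr["gs_de_count"]):
        if not _is_na_scalar(cnt) and int(cnt) == old_n:
            new_counts.append(len(new_genes))
        else:
            new_counts.append(cnt)
    repaired_enr["gs_de_count"] = new_counts
    report.repaired = AnalysisBundle(
        expression=bundle.expression,
        de=bundle.de,
        enrichment=repaired_enr,
        annotation=bundle.annotation,
    )
    return report


def _is_na_scalar(x: Any) -> bool:
    if isinstance(x, (list, tuple, np.ndarray)):
        return False
    try:
        return bool(pd.isna(x))
    except (TypeError, ValueError):
        return False


def effective_padj(de: pd.DataFrame) -> pd.Series:
    """padj with missing values treated as 1.0 (conservative DE-calling)."""
    return de["padj"].fillna(1.0)


def de_gene_ids(de: pd.DataFrame, de_threshold: float = 0.05) -> pd.DataFrame:
    """Subset of the DE table called differential at ``padj <= de_threshold``.

    Direction is the sign of log2fc; genes with log2fc exactly 0 carry no
    direction and are excluded from both directional pools downstream.
    """
    mask = effective_padj(de) <= de_threshold
    return de.loc[mask]


def describe_bundle(
    bundle: AnalysisBundle, de_threshold: float = 0.05
) -> dict[str, int]:
    """Dimension summary: genes, samples, DE calls at the threshold, genesets."""
    return {
        "n_genes": bundle.expression.n_genes,
        "n_samples": bundle.expression.n_samples,
        "n_de": int(len(de_gene_ids(bundle.de, de_threshold))),
        "n_genesets": int(len(bundle.enrichment)),
    }


# ---------------------------------------------------------------------------
# serialization

def _frame_to_json(df: pd.DataFrame, list_columns: tuple[str, ...] = ()) -> dict:
    data: dict[str, list] = {}
    for col in df.columns:
        vals = df[col].tolist()
        if col in list_columns:
            data[col] = [list(v) if v is not None and not _is_na_scalar(v) else None for v in vals]
        else:
            data[col] = [None if _is_na_scalar(v) else _json_scalar(v) for v in vals]
    return {"columns": list(df.columns), "data": data}


def _json_scalar(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        f = float(v)
        return None if math.isnan(f) else f
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def _frame_from_json(
    obj: Mapping[str, Any], what: str, list_columns: tuple[str, ...] = ()
) -> pd.DataFrame:
    try:
        columns = obj["columns"]
        data = obj["data"]
    except (KeyError, TypeError) as exc:
        raise BundleParseError(f"{what}: missing 'columns'/'data'") from exc
    frame: dict[str, list] = {}
    n = None
    for col in columns:
        if col not in data:
            raise BundleParseError(f"{what}: declared column {col!r} has no data")
        vals = data[col]
        if n is None:
            n = len(vals)
        elif len(vals) != n:
            raise BundleParseError(
                f"{what}: column {col!r} has {len(vals)} values, expected {n}"
            )
        if col in list_columns:
            frame[col] = [list(v) if v is not None else [] for v in vals]
        else:
            frame[col] = [np.nan if v is None else v for v in vals]
    df = pd.DataFrame(frame, columns=columns)
    return df


def write_bundle(bundle: AnalysisBundle, path: str | Path) -> None:
    """Serialize to one versioned JSON container (UTF-8)."""
    report = validate_bundle(bundle, strict=False)
    if report.fatal:
        raise BundleValidationError("; ".join(report.fatal))
    counts = bundle.expression.counts
    samples = bundle.expression.samples
    doc = {
        "schema_version": SCHEMA_VERSION,
        "expression": {
            "gene_ids": list(map(str, counts.index)),
            "sample_ids": list(map(str, counts.columns)),
            "counts": [[_json_scalar(v) for v in row] for row in counts.to_numpy().tolist()],
            "samples": _frame_to_json(samples.reset_index(names="sample_id")),
        },
        "de": _frame_to_json(bundle.de),
        "enrichment": _frame_to_json(bundle.enrichment, list_columns=("gs_genes",)),
        "annotation": _frame_to_json(bundle.annotation),
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_bundle(path: str | Path) -> AnalysisBundle:
    """Read a bundle written by :func:`write_bundle`; inverse up to dtypes of NaN."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BundleParseError(
            f"{path}: not valid JSON (line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise BundleSchemaError(
            f"{path}: schema version {version!r}, this reader supports {SCHEMA_VERSION!r}"
        )
    try:
        expr = doc["expression"]
        gene_ids = expr["gene_ids"]
        sample_ids = expr["sample_ids"]
        rows = expr["counts"]
    except (KeyError, TypeError) as exc:
        raise BundleParseError(f"{path}: malformed expression block") from exc
    if len(rows) != len(gene_ids):
        raise BundleParseError(
            f"{path}: counts matrix has {len(rows)} rows but {len(gene_ids)} gene ids declared"
        )
    for i, row in enumerate(rows):
        if len(row) != len(sample_ids):
            raise BundleParseError(
                f"{path}: counts row {i} ({gene_ids[i]}) has {len(row)} values, "
                f"expected {len(sample_ids)}"
            )
    counts = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    samples = _frame_from_json(expr["samples"], "samples").set_index("sample_id")
    samples.index.name = None
    expression = ExpressionData(counts=counts, samples=samples)
    de = _frame_from_json(doc.get("de", {}), "de")
    enrichment = _frame_from_json(
        doc.get("enrichment", {}), "enrichment", list_columns=("gs_genes",)
    )
    annotation = _frame_from_json(doc.get("annotation", {}), "annotation")
    return AnalysisBundle(
        expression=expression, de=de, enrichment=enrichment, annotation=annotation
    )


# ---------------------------------------------------------------------------
# tabular readers for the external interfaces

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts TSV/CSV: first column gene_id, header = sample ids."""
    df = _read_table(path)
    return df.set_index(df.columns[0]).rename_axis(None)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Sample table TSV/CSV keyed by its first column (sample id)."""
    df = _read_table(path)
    return df.set_index(df.columns[0]).rename_axis(None)


DE_COLUMN_ALIASES = {
    "log2FoldChange": "log2fc",
    "log2fold_change": "log2fc",
    "lfc": "log2fc",
    "p_value": "pvalue",
    "adj_pvalue": "padj",
}


def read_de_table(path: str | Path) -> pd.DataFrame:
    """DE table TSV/CSV with gene_id, log2fc (alias log2FoldChange), pvalue, padj."""
    df = _read_table(path).rename(columns=DE_COLUMN_ALIASES)
    missing = {"gene_id", "log2fc", "pvalue"} - set(df.columns)
    if missing:
        raise BundleParseError(f"{path}: DE table missing columns {sorted(missing)}")
    if "padj" not in df.columns:
        df["padj"] = np.nan
    return df[["gene_id", "log2fc", "pvalue", "padj"]]


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = {"gene_id", "gene_name"} - set(df.columns)
    if missing:
        raise BundleParseError(f"{path}: annotation missing columns {sorted(missing)}")
    return df[["gene_id", "gene_name"]]
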