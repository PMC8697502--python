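"""Expression-aware geneset scores.

Two families of scores inject expression/DE information into the
enrichment results:

* per-geneset aggregates — a directionality Z-score
  ``(up - down) / sqrt(up + down)`` over the geneset's DE members, and an
  aggregated effect size (mean or median log2fc of those members);
* per-sample activity — counts are put through a homoscedasticity-improving
  transform, row-standardized per gene, and averaged over each geneset's
  members to give a genesets x samples score matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from enrichkit.core_model import EnrichKitError, ExpressionData, symbol_to_id_map

logger = logging.getLogger(__name__)


@dataclass
class TransformedMatrix:
    """Transformed expression, genes x samples, with size factors used."""

    values: pd.DataFrame
    transform_name: str
    size_factors: pd.Series | None = None


@dataclass
class GeneZMatrix:
    """Row-standardized transformed expression.

    ``constant_genes`` lists rows with zero variance; their Z rows are set
    to all-zero rather than NaN.
    """

    values: pd.DataFrame
    row_means: pd.Series
    row_sds: pd.Series
    constant_genes: list[str] = field(default_factory=list)


@dataclass
class GenesetScoreMatrix:
    """Genesets x samples activity scores plus the member ids actually averaged."""

    values: pd.DataFrame
    members_used: dict[str, list[str]]
    dropped_genesets: list[str] = field(default_factory=list)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per-gene geometric means are computed over genes expressed in every
    sample; each sample's factor is the median ratio of its counts to
    those reference means.
    """
    mat = counts.to_numpy(dtype=float)
    zero_cols = (mat.sum(axis=0) == 0)
    if zero_cols.any():
        bad = list(counts.columns[zero_cols])
        raise EnrichKitError(f"all-zero sample column(s): {bad} — size factor undefined")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise EnrichKitError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    log_geo = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def transform_counts(
    expression: ExpressionData, method: str = "shifted_log"
) -> TransformedMatrix:
    """Monotone per-gene transform of counts toward homoscedasticity.

    The default ``shifted_log`` computes ``log2(count / size_factor + 1)``
    with median-of-ratios size factors. A pre-transformed matrix can be
    passed downstream directly by wrapping it in :class:`TransformedMatrix`.
    """
    if method != "shifted_log":
        raise EnrichKitError(f"unknown transform method {method!r}; supported: shifted_log")
    counts = expression.counts
    sf = size_factors_median_of_ratios(counts)
    values = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return TransformedMatrix(values=out, transform_name="shifted_log", size_factors=sf)


def compute_gene_z(transformed: TransformedMatrix) -> GeneZMatrix:
    """Row-standardize: Z = (T - rowmean) / rowsd, sample (n-1) sd.

    Rows with zero variance are set to all-zero and flagged instead of
    propagating NaN.
    """
    values = transformed.values
    if values.shape[1] < 2:
        raise EnrichKitError("compute_gene_z requires at least 2 samples")
    mat = values.to_numpy(dtype=float)
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    constant = sds == 0
    safe_sds = np.where(constant, 1.0, sds)
    z = (mat - means[:, None]) / safe_sds[:, None]
    z[constant] = 0.0
    constant_genes = list(values.index[constant])
    if constant_genes:
        logger.info("%d constant gene row(s) set to zero Z", len(constant_genes))
    return GeneZMatrix(
        values=pd.DataFrame(z, index=values.index, columns=values.columns),
        row_means=pd.Series(means, index=values.index),
        row_sds=pd.Series(sds, index=values.index),
        constant_genes=constant_genes,
    )


def compute_aggregate_scores(
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    de_threshold: float = 0.05,
    aggr: str = "mean",
) -> pd.DataFrame:
    """Fill z_score and aggr_score for every geneset.

    z_score = (up_count - down_count) / sqrt(up_count + down_count);
    aggr_score = mean or median log2fc over the geneset's DE members.
    Genesets with no DE member get missing scores.
    """
    if aggr not in ("mean", "median"):
        raise EnrichKitError(f"unknown aggr {aggr!r}; supported: mean, median")
    from enrichkit.ingest import attach_membership_counts

    out = attach_membership_counts(enrichment, de, annotation, de_threshold)
    up = out["up_count"].to_numpy(dtype=float)
    down = out["down_count"].to_numpy(dtype=float)
    total = up + down
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (up - down) / np.sqrt(total)
    z[total == 0] = np.nan
    out["z_score"] = z

    sym2id, _ = symbol_to_id_map(annotation)
    de_idx = de.set_index("gene_id")
    padj = de_idx["padj"].fillna(1.0)
    lfc = de_idx["log2fc"]
    aggr_fn = np.mean if aggr == "mean" else np.median
    scores = []
    for genes in out["gs_genes"]:
        genes = genes if isinstance(genes, (list, tuple)) else []
        ids = [sym2id[g] for g in genes if g in sym2id]
        fcs = [
            lfc[g]
            for g in ids
            if g in de_idx.index and padj[g] <= de_threshold and lfc[g] != 0
        ]
        scores.append(float(aggr_fn(fcs)) if fcs else np.nan)
    out["aggr_score"] = scores
    return out


def geneset_z_score(up_count: int, down_count: int) -> float:
    """Closed form (up - down)/sqrt(up + down); NaN when both are zero."""
    total = up_count + down_count
    if total == 0:
        return float("nan")
    return (up_count - down_count) / np.sqrt(total)


def compute_geneset_scores(
    genez: GeneZMatrix,
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    members: str = "de_only",
    de_threshold: float = 0.05,
) -> GenesetScoreMatrix:
    """Sample-wise geneset activity: mean of member Z rows per sample.

    ``members="de_only"`` (default) restricts to members called DE at the
    threshold; ``"all"`` averages every resolvable member. Genes whose
    expression row was constant are included as zeros unless every member
    of the set is constant, in which case the set keeps a zero row but is
    flagged through ``members_used``. Genesets with no resolvable member
    are dropped with a warning.
    """
    if enrichment.empty:
        raise EnrichKitError("compute_geneset_scores: empty enrichment table")
    if members not in ("de_only", "all"):
        raise EnrichKitError(f"unknown members mode {members!r}; supported: de_only, all")
    sym2id, _ = symbol_to_id_map(annotation)
    de_idx = de.set_index("gene_id")
    padj = de_idx["padj"].fillna(1.0)
    z = genez.values

    rows: list[np.ndarray] = []
    index: list[str] = []
    members_used: dict[str, list[str]] = {}
    dropped: list[str] = []
    for gs_id, genes in zip(enrichment["gs_id"], enrichment["gs_genes"]):
        genes = genes if isinstance(genes, (list, tuple)) else []
        ids = [sym2id[g] for g in genes if g in sym2id]
        ids = [g for g in ids if g in z.index]
        if members == "de_only":
            ids = [g for g in ids if g in de_idx.index and padj[g] <= de_threshold]
        if not ids:
            dropped.append(gs_id)
            continue
        rows.append(z.loc[ids].to_numpy().mean(axis=0))
        index.append(gs_id)
        members_used[gs_id] = ids
    if dropped:
        logger.warning(
            "dropping %d geneset(s) with no resolvable %s members: %s",
            len(dropped),
            "DE" if members == "de_only" else "",
            dropped[:5],
        )
    values = pd.DataFrame(rows, index=index, columns=z.columns)
    return GenesetScoreMatrix(
        values=values, members_used=members_used, dropped_genesets=dropped
    )
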