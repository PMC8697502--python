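"""Ordered, de-duplicated bookmarks over genes and genesets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from enrichkit.core_model import AnalysisBundle, EnrichKitError

logger = logging.getLogger(__name__)


@dataclass
class Bookmarks:
    """Insertion-ordered unique ids of genes and genesets of interest."""

    genes: list[str] = field(default_factory=list)
    genesets: list[str] = field(default_factory=list)


def _resolve(bundle: AnalysisBundle, kind: str, item_id: str) -> bool:
    if kind == "gene":
        return item_id in set(bundle.expression.counts.index) or item_id in set(
            bundle.de["gene_id"]
        )
    if kind == "geneset":
        return item_id in set(bundle.enrichment["gs_id"])
    raise EnrichKitError(f"unknown bookmark kind {kind!r}; supported: gene, geneset")


def add_bookmark(
    bookmarks: Bookmarks, kind: str, item_id: str, bundle: AnalysisBundle
) -> Bookmarks:
    """Append the id if absent; errors on ids not resolvable in the bundle."""
    if not _resolve(bundle, kind, item_id):
        raise EnrichKitError(f"cannot bookmark unresolvable {kind} id {item_id!r}")
    target = bookmarks.genes if kind == "gene" else bookmarks.genesets
    if item_id not in target:
        target.append(item_id)
    return bookmarks


def remove_bookmark(bookmarks: Bookmarks, kind: str, item_id: str) -> Bookmarks:
    if kind not in ("gene", "geneset"):
        raise EnrichKitError(f"unknown bookmark kind {kind!r}; supported: gene, geneset")
    target = bookmarks.genes if kind == "gene" else bookmarks.genesets
    if item_id in target:
        target.remove(item_id)
    else:
        logger.warning("bookmark %s %r not present; remove is a no-op", kind, item_id)
    return bookmarks


def clear_bookmarks(bookmarks: Bookmarks) -> Bookmarks:
    bookmarks.genes.clear()
    bookmarks.genesets.clear()
    return bookmarks
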