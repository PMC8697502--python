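"""Synthetic fixture generator: a complete bundle with planted ground truth.

Counts are drawn negative-binomial around log-normal per-gene baselines;
a fraction of genes receives a multiplicative two-group effect of
2**(±lfc_effect). The DE table is filled by a two-group Welch test on
shifted-log normalized values with BH adjustment (support machinery for
fixtures, not a shipped DE method). Genesets are sampled from the gene
universe, with the planted-enriched ones drawing most of their members
from the up-regulated planted pool; their p-values come from a one-sided
hypergeometric tail on the DE overlap (again: fixture support only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from enrichkit.core_model import (
    AnalysisBundle,
    EnrichKitError,
    ExpressionData,
    write_bundle,
)
from enrichkit.ingest import GenesetCollection, write_gmt
from enrichkit.scoring import size_factors_median_of_ratios


@dataclass
class FixtureSpec:
    """Knobs of the synthetic dataset; ``seed`` fixes every draw."""

    n_genes: int = 500
    n_samples_per_group: int = 4
    n_genesets: int = 40
    geneset_size_range: tuple[int, int] = (5, 20)
    frac_de: float = 0.1
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.1
    n_planted_enriched: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_genesets", "n_planted_enriched"):
            if getattr(self, name) < 1:
                raise EnrichKitError(f"{name} must be >= 1")
        if not (0 < self.frac_de < 1):
            raise EnrichKitError("frac_de must be in (0, 1)")
        if self.geneset_size_range[1] > self.n_genes:
            raise EnrichKitError(
                f"geneset_size_range {self.geneset_size_range} exceeds n_genes {self.n_genes}"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # var = mu + dispersion * mu^2  ->  n = 1/dispersion, p = n/(n+mu)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _de_test(counts: pd.DataFrame, group: np.ndarray) -> pd.DataFrame:
    """Welch t-test on shifted-log normalized counts, BH-adjusted."""
    sf = size_factors_median_of_ratios(counts)
    logged = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    a = logged[:, group == 0]
    b = logged[:, group == 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(b, a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    padj = multipletests(pvals, method="fdr_bh")[1]
    padj = np.clip(padj, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    ).reset_index(drop=True)


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[AnalysisBundle, dict]:
    """Simulate a bundle + GMT + planted-truth record; optionally write all files.

    Returns ``(bundle, truth)``; with ``out_dir`` set, writes counts.tsv,
    samples.tsv, de.tsv, annotation.tsv, genesets.gmt, bundle.json and
    truth.json (all plain text, byte-deterministic for a fixed spec).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    gene_names = [f"SYM{i:05d}" for i in range(n)]
    annotation = pd.DataFrame({"gene_id": gene_ids, "gene_name": gene_names})
    name_of = dict(zip(gene_ids, gene_names))

    n_per = spec.n_samples_per_group
    sample_ids = [f"S{i + 1}" for i in range(2 * n_per)]
    group = np.array([0] * n_per + [1] * n_per)
    samples = pd.DataFrame(
        {"condition": ["A" if g == 0 else "B" for g in group]}, index=sample_ids
    )

    baseline = rng.lognormal(mean=4.0, sigma=1.0, size=n)
    n_de = max(1, round(spec.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n)
    effect[de_idx] = signs * spec.lfc_effect

    mean_a = np.tile(baseline[:, None], (1, n_per))
    mean_b = np.tile((baseline * 2.0**effect)[:, None], (1, n_per))
    counts = np.concatenate(
        [
            _nb_draw(rng, mean_a, spec.nb_dispersion),
            _nb_draw(rng, mean_b, spec.nb_dispersion),
        ],
        axis=1,
    )
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    expression = ExpressionData(counts=counts_df, samples=samples)
    de = _de_test(counts_df, group)

    called = set(de.loc[de["padj"] <= 0.05, "gene_id"])
    planted_up = [gene_ids[i] for i, s in zip(de_idx, signs) if s > 0]
    non_de_pool = [g for i, g in enumerate(gene_ids) if i not in set(de_idx)]

    lo, hi = spec.geneset_size_range
    collection: GenesetCollection = {}
    planted_ids = []
    for k in range(spec.n_genesets):
        size = int(rng.integers(lo, hi + 1))
        gs_id = f"GS{k:03d}"
        if k < spec.n_planted_enriched:
            n_from_up = min(len(planted_up), max(1, int(np.ceil(0.7 * size))))
            members = list(rng.choice(planted_up, size=n_from_up, replace=False))
            rest = [g for g in non_de_pool if g not in members]
            n_rest = min(size - n_from_up, len(rest))
            if n_rest > 0:
                members += list(rng.choice(rest, size=n_rest, replace=False))
            planted_ids.append(gs_id)
        else:
            members = list(rng.choice(gene_ids, size=size, replace=False))
        collection[gs_id] = (f"synthetic geneset {k}", [name_of[g] for g in members])

    # one-sided hypergeometric tail on the DE overlap (fixture filler only)
    n_called = len(called)
    rows = []
    id_of = dict(zip(gene_names, gene_ids))
    for gs_id, (description, member_names) in collection.items():
        member_ids = [id_of[m] for m in member_names]
        overlap = [g for g in member_ids if g in called]
        k_overlap = len(overlap)
        size = len(member_ids)
        pval = float(stats.hypergeom.sf(k_overlap - 1, n, n_called, size))
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "gs_id": gs_id,
                "gs_description": description,
                "gs_pvalue": pval,
                "gs_genes": [name_of[g] for g in overlap],
                "gs_de_count": float(k_overlap),
                "gs_bg_count": float(size),
                "z_score": np.nan,
                "aggr_score": np.nan,
                "up_count": np.nan,
                "down_count": np.nan,
            }
        )
    enrichment = pd.DataFrame(rows)

    bundle = AnalysisBundle(
        expression=expression, de=de, enrichment=enrichment, annotation=annotation
    )
    truth = {
        "spec": {**asdict(spec), "geneset_size_range": list(spec.geneset_size_range)},
        "planted_de": sorted(gene_ids[i] for i in de_idx),
        "planted_de_signs": {
            gene_ids[i]: int(s) for i, s in sorted(zip(de_idx, signs))
        },
        "planted_enriched": planted_ids,
        "n_de_called_at_0.05": n_called,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        counts_df.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
        samples.rename_axis("sample_id").to_csv(out / "samples.tsv", sep="\t")
        de.to_csv(out / "de.tsv", sep="\t", index=False)
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        write_gmt(collection, out / "genesets.gmt")
        write_bundle(bundle, out / "bundle.json")
        (out / "truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8"
        )
    return bundle, truth
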