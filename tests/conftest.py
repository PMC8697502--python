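import numpy as np
import pandas as pd
import pytest

from enrichkit.app_report.fixtures import FixtureSpec, generate_fixture
from enrichkit.core_model import AnalysisBundle, ExpressionData


def make_enrichment(rows):
    """Harmonized enrichment frame from (gs_id, description, pvalue, genes) tuples."""
    df = pd.DataFrame(
        [
            {
                "gs_id": gs_id,
                "gs_description": desc,
                "gs_pvalue": p,
                "gs_genes": list(genes),
            }
            for gs_id, desc, p, genes in rows
        ]
    )
    for col in ("gs_de_count", "gs_bg_count", "z_score", "aggr_score", "up_count", "down_count"):
        df[col] = np.nan
    df["gs_de_count"] = df["gs_genes"].map(len).astype(float)
    return df


@pytest.fixture
def tiny_bundle() -> AnalysisBundle:
    """Handcrafted 6-gene, 4-sample bundle with fully consistent identifiers."""
    gene_ids = [f"g{i}" for i in range(1, 7)]
    symbols = [f"S{i}" for i in range(1, 7)]
    counts = pd.DataFrame(
        [
            [10, 12, 30, 33],
            [5, 7, 6, 5],
            [100, 90, 40, 45],
            [8, 9, 8, 10],
            [20, 22, 21, 19],
            [3, 2, 50, 55],
        ],
        index=gene_ids,
        columns=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame(
        {"condition": ["A", "A", "B", "B"]}, index=["s1", "s2", "s3", "s4"]
    )
    de = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": [1.6, -0.2, -1.1, 0.1, 0.0, 4.0],
            "pvalue": [0.001, 0.6, 0.002, 0.7, 0.9, 0.0001],
            "padj": [0.01, 0.8, 0.02, 0.8, np.nan, 0.001],
        }
    )
    enrichment = make_enrichment(
        [
            ("GO:1", "setA", 0.001, ["S1", "S3", "S6"]),
            ("GO:2", "setB", 0.02, ["S3", "S4"]),
            ("GO:3", "setC", 0.5, ["S2", "S5"]),
        ]
    )
    annotation = pd.DataFrame({"gene_id": gene_ids, "gene_name": symbols})
    return AnalysisBundle(
        expression=ExpressionData(counts=counts, samples=samples),
        de=de,
        enrichment=enrichment,
        annotation=annotation,
    )


def random_bundle(seed: int, n_genes: int = 20, n_samples: int = 4, n_sets: int = 5):
    """Small random but internally consistent bundle (fast; for round-trips)."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    symbols = [f"SYM{i:03d}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    counts = pd.DataFrame(
        rng.poisson(30, size=(n_genes, n_samples)) + 1,
        index=gene_ids,
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {"condition": ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)},
        index=sample_ids,
    )
    de = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": rng.normal(0, 2, n_genes).round(4),
            "pvalue": np.clip(rng.uniform(1e-6, 1, n_genes), 1e-6, 1).round(6),
            "padj": np.clip(rng.uniform(1e-6, 1, n_genes), 1e-6, 1).round(6),
        }
    )
    rows = []
    for k in range(n_sets):
        size = int(rng.integers(2, max(3, n_genes // 3)))
        members = list(rng.choice(symbols, size=size, replace=False))
        rows.append((f"GS{k:02d}", f"set {k}", float(rng.uniform(1e-5, 1)), members))
    enrichment = make_enrichment(rows)
    annotation = pd.DataFrame({"gene_id": gene_ids, "gene_name": symbols})
    return AnalysisBundle(
        expression=ExpressionData(counts=counts, samples=samples),
        de=de,
        enrichment=enrichment,
        annotation=annotation,
    )


@pytest.fixture(scope="session")
def sim_bundle_truth():
    """One default-sized simulated bundle with its planted truth."""
    return generate_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def sim_bundle(sim_bundle_truth):
    return sim_bundle_truth[0]
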