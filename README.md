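# enrichkit

A toolkit for interpreting differential-expression (DE) results together
with functional-enrichment results. It harmonizes the outputs of six
enrichment tools into one schema, joins them with a count matrix, a DE
table and a gene annotation into a validated **bundle**, injects
expression information into the enrichment results (geneset Z-scores,
aggregated effect sizes, sample-wise geneset activity matrices), builds
gene–geneset and geneset–geneset graph summaries with redundancy
reduction, and renders static figures plus a reproducible self-contained
HTML report. A synthetic fixture generator with planted ground truth
makes every step exercisable without external data.

## Layout

| module | what it does |
| --- | --- |
| `enrichkit.core_model` | the four-component bundle (expression + samples, DE table, enrichment table, annotation), validation, versioned JSON serialization |
| `enrichkit.ingest` | dialect converters for topGO / clusterProfiler / DAVID / Enrichr / g:Profiler / fgsea dialects, GMT I/O, directional DE-member counts |
| `enrichkit.scoring` | geneset Z-score `(up−down)/√(up+down)`, mean/median log2FC aggregates, shifted-log transform, per-gene standardization, genesets × samples activity scores |
| `enrichkit.topology` | gene–geneset bipartite graph, disparity-filter backbone of its projections, similarity matrices (Jaccard / overlap / kappa), enrichment map with community detection |
| `enrichkit.distill` | kappa-based fuzzy clustering with representatives, greedy overlap-threshold term reduction, classical-MDS layout, dendrogram (Newick export) |
| `enrichkit.viz` | pure plot-data builders (volcano, enhanced table, score heatmaps, signature plots, spider) + SVG/PNG renderers |
| `enrichkit.app_report` | bookmarks, HTML report (`assemble_report`), reproducible snippets, synthetic fixture generator |
| `enrichkit.cli` | the `enrichkit` command |

## CLI

```sh
enrichkit fixture --seed 1 --out demo/            # synthetic bundle + GMT + truth
enrichkit validate --bundle demo/bundle.json
enrichkit score    --bundle demo/bundle.json --out demo/score
enrichkit graph    --bundle demo/bundle.json --out demo/graph
enrichkit distill  --bundle demo/bundle.json --out demo/distill
enrichkit viz      --bundle demo/bundle.json --kind gs_volcano --out demo/volcano
enrichkit shake    --dialect enrichr --in results.tsv --out harmonized.json
enrichkit report   --bundle demo/bundle.json --config config.yaml \
                   --out demo/report.html --timestamp 2026-01-01T00:00:00Z
```

All subcommands accept a YAML/JSON `--config` with keys such as
`de_threshold`, `aggr`, `transform.method`, `members`, `graph.*`,
`distill.*`, `viz.*` and `bookmarks.genes` / `bookmarks.genesets`.
With a pinned `--timestamp` (and fixed seed) the whole
fixture → score → graph → distill → report pipeline is byte-reproducible,
and every command embedded in the report regenerates its artifact
bit-exactly.

## Conventions

* Expression and DE tables are keyed by stable gene ids; genesets carry
  gene symbols as emitted by enrichment tools; the annotation table
  bridges the two (first match wins for ambiguous symbols, reported by
  validation).
* Missing `padj` is treated as 1.0; a gene is "DE" iff `padj ≤
  de_threshold` (default 0.05), with direction from the sign of log2FC.
* Harmonized `gs_pvalue` is the tool's adjusted p-value where one
  exists, else raw; recorded in the table's `attrs["pvalue_provenance"]`.
* Geneset activity scores average the row-standardized (n−1 sd)
  shifted-log expression of each geneset's DE members by default
  (`members="all"` switches to every member).
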