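# stringagg

Automated retrieval, aggregation and visualization of STRING functional
enrichment across many differential-expression comparisons.

## The problem

Functional enrichment puts a list of differentially expressed (DE) genes
into biological context: given a gene list, STRING reports annotation
terms — KEGG pathways, GO Biological Process / Molecular Function /
Cellular Component categories and Reactome pathways — that are
over-represented relative to a background, each with a false discovery
rate (FDR). For an experiment with more than a couple of contrasts
(genotypes × diets × time points quickly yields a dozen comparisons),
manually submitting every gene list, downloading five tables per list and
reconciling the hits across comparisons is slow and error-prone.

`stringagg` automates that workflow for bench scientists and
bioinformaticians alike:

1. **Parse** per-comparison DE tables (gene id + fold change; the file
   name labels the comparison) and split each into up-/down-regulated
   sets by the sign of the fold change.
2. **Retrieve** enrichment per gene list from the STRING API — or replay
   previously saved STRING-format enrichment tables fully offline.
3. **Aggregate** the per-comparison hits, per knowledge base, into two
   spreadsheet-ready TSVs:
   - a **summary** table: per term, the lowest FDR ever observed, the
     number of comparisons where the term is enriched (*occurrence*), the
     union of matched genes (*all_genes*) and their intersection over the
     comparisons where the term is significant (*common_genes*). If the
     intersection is empty the cell reads `No common gene`; if the term
     occurs once it reads `n/a: just one condition`.
   - a **results** table: per term, one FDR column per comparison, with
     the default value **1** filled in wherever a comparison did not
     enrich for the term. When up- and downregulated genes are analyzed
     separately and a term shows up in both, the lower FDR is recorded.
4. **Visualize**: a clustermap of the term × comparison −log10(FDR)
   matrix (optional significance cutoff: cutoff 5 keeps exactly the terms
   with minimum FDR < 1e−5; unwanted terms can be excluded by name), and
   a bubble plot of the summary (x = |all_genes|, bubble size =
   |common_genes|, color = lowest FDR).

Significance uses strict FDR < α with α = 0.05 by default; the default
species is *Mus musculus* (taxon 10090), and a custom statistical
background (one identifier per line) can be supplied.

## Worked example (fully offline)

The built-in fixture generator plants a synthetic dataset with known
structure, so the whole pipeline runs without a network connection:

```bash
stringagg make-fixtures -o fixtures --n-comparisons 4 --n-terms 5 --seed 42
stringagg run fixtures/de_tables/*.tsv -o output --offline fixtures/enrichment
stringagg clustermap output/results_KEGG.tsv -o kegg_clustermap --cutoff 2
stringagg bubble output/summary_KEGG.tsv -o kegg_bubble --log-color
```

The run prints one line per step (the same text goes to `output/run.log`)
and finishes with:

```
INFO stringagg: parsed fixtures/de_tables/comparison_01.tsv: 129 genes (0 rows skipped)
INFO stringagg: saved output/comparison_01/UP_KEGG.tsv (2 terms)
...
INFO stringagg: aggregated KEGG: 5 terms -> output/results_KEGG.tsv, output/summary_KEGG.tsv
INFO stringagg: run complete: 4 comparisons, 5 knowledge bases
aggregated 4 comparisons across 5 knowledge bases into output
```

Each input file gets a subfolder of saved per-direction enrichment tables
(`UP_KEGG.tsv`, `DOWN_Process.tsv`, ...), and the output folder holds
`results_<kind>.tsv` / `summary_<kind>.tsv` for the five knowledge bases.
The KEGG summary starts:

```
term ID     description            lowest FDR   occurrence  all_genes                common_genes
KEGG:0003   synthetic KEGG term 3  1.2692e-08   4           GENE00019,GENE00020,...  GENE00019,GENE00020
KEGG:0002   synthetic KEGG term 2  4.96328e-08  1           GENE00012,...            n/a: just one condition
```

Read: term `KEGG:0003` was significantly enriched in all 4 comparisons,
its best FDR anywhere was 1.27e−8, and genes `GENE00019`/`GENE00020`
matched it in every one of those comparisons. The corresponding results
row lists its FDR in each comparison (`1.0` where absent):

```
term ID     description            common_genes                    comparison_01  comparison_02  comparison_03  comparison_04
KEGG:0004   synthetic KEGG term 4  GENE00039,GENE00040,GENE00041   0.00114173     0.00036778     1.0            0.00777114
```

`kegg_clustermap.png/.svg` and `kegg_bubble.png/.svg` are the rendered
plots. For a live analysis drop `--offline` (and optionally set
`--species`, `--mode up|down|up-down-separate|all`, `--string-version`,
`--background`, `--alpha`).

## Library use

```python
from stringagg import (parse_de_table, split_directions, AnalysisSettings,
                       DirectoryTransport, fetch_enrichment, summarize_all_kinds)

table = parse_de_table("fixtures/de_tables/comparison_01.tsv")
genesets = split_directions(table)            # sign-based up/down split
transport = DirectoryTransport("fixtures/enrichment")
enrichments = fetch_enrichment(table.label, genesets, AnalysisSettings(), transport)
tables = summarize_all_kinds(enrichments)     # {kind: AggregateTables}
```

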