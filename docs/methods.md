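# Methods

## Scope and model of the data

`stringagg` does not compute enrichment statistics itself. The
hypergeometric testing and multiple-testing correction are performed
server-side by STRING for each submitted gene list against the selected
background; this package's job is everything around that call: preparing
the gene lists, issuing one request per comparison × direction,
persisting the per-comparison tables, and aggregating the per-term hits
across comparisons into consistent summary and results views.

A *comparison* is one DE contrast, represented by a delimited text file
of (gene id, fold change) rows; the file name is the comparison label.
The enrichment server returns, per gene list, records spanning several
annotation categories; only five knowledge bases are retained and
aggregated: KEGG Pathways (`KEGG`), GO Biological Process (`Process`),
GO Molecular Function (`Function`), GO Cellular Component (`Component`)
and Reactome Pathways (`RCTM`). Other categories (protein domains etc.)
are dropped at parse time and counted in the log.

## Aggregation rules

All aggregation operates on records already filtered at the significance
threshold (strict FDR < α, default α = 0.05), so "the term is present in
a comparison" and "the term is significantly enriched there" coincide.

Per knowledge base and term:

- **lowest FDR** — the minimum FDR over the comparisons containing the
  term;
- **occurrence** — the number of comparisons containing the term;
- **all_genes** — the union of the matched gene labels over those
  comparisons;
- **common_genes** — the intersection of the matched gene labels over
  the comparisons *where the term is significant* (not over every
  comparison in the run: intersecting with a comparison that never
  enriched the term would always empty the set). An empty intersection is
  rendered as the literal `No common gene`; a term seen in exactly one
  comparison as `n/a: just one condition`, with its genes still available
  in all_genes.
- the **results** view carries one FDR column per comparison in input
  order, with the value **exactly 1** where a comparison lacks the term —
  a deliberate "not significant" placeholder that also makes the −log10
  transform map absences to 0.

When the analysis mode submits up- and downregulated genes separately
(the default), the per-comparison UP and DOWN record lists are merged
before aggregation: a term present in both directions keeps the lower of
the two FDRs. The merged record's gene labels are the union of the two
lists — the minimum-FDR rule alone says nothing about genes, and the
union is the only choice under which downstream all_genes/common_genes
see every gene that contributed to the term in that comparison.

Terms are keyed by term id; if the same id arrives with different
descriptions across comparisons the first-seen description wins and a
warning is logged. Output rows are ordered by descending occurrence,
then ascending lowest FDR, then term id — the most recurrent, most
significant terms first; the ordering is a presentation choice with no
effect on any value.

Both views are built from the same index, which guarantees the
cross-invariants checked by `aggregator.check_consistency`: identical
term sets, summary lowest FDR = row-wise minimum of the results view,
occurrence = count of results entries below α.

## Inputs and directions

Fold-change convention is configurable because DE pipelines emit either
log ratios or linear ratios and the two have different boundaries:

- `log-ratio` (default): fold change > 0 → up, < 0 → down. The sign
  split is well-defined for the negative values ubiquitous in DE output,
  which is why it is the default.
- `linear-ratio`: > 1 → up, < 1 → down; non-positive values are a
  malformed input and rejected.

Boundary genes (0, or 1 under linear) belong to neither direction but
remain in the combined ("all genes") list. Within one file, duplicate
gene ids keep the first occurrence with a warning. A single header row is
tolerated (detected as a non-numeric second field on the first row);
the delimiter is sniffed among tab, comma and semicolon.

Four analysis modes control what is submitted per comparison: upregulated
only, downregulated only, both separately (default; two requests, merged
as above) or all genes together (one request).

## The STRING client

Requests carry the newline-delimited identifiers, the species taxon
(default 10090, *Mus musculus*; any positive integer accepted), a caller
identity string and, when set, the background identifier list. `latest`
targets the main STRING host; a pinned version tag (e.g. `11.0`) maps to
the corresponding archived host. The live transport spaces requests ≥ 1 s
apart and retries 3 times with exponential backoff — etiquette defaults
chosen to be polite to a shared public service.

Transports are pluggable behind one interface, so live HTTP, replayed
payloads keyed by gene set (`FixtureTransport`) and saved STRING-format
TSV folders (`DirectoryTransport`) are interchangeable; tests assert that
identical payloads produce identical downstream tables regardless of the
route. Saved tables use the column layout of STRING website downloads
(term id, description, observed count, background count, FDR, matched
labels) with FDR at 6 significant digits; per-comparison files are named
`<UP|DOWN|ALL>_<kind>.tsv` inside a folder named after the input file.

The server reports both a raw p-value and an FDR; downloaded tables
expose only the FDR, and everything here (filtering, aggregation,
plots, the "lowest" score in summaries) consistently uses the adjusted
value, i.e. the FDR. The raw p-value is kept on the record when a live
payload provides it, but nothing downstream consumes it.

## Visualization

- **Clustermap**: the results view becomes a dense term × comparison
  matrix. With the transform flag each cell becomes −log10(FDR) (an FDR
  of 1 maps to exactly 0). A cutoff *c* (transform required, since it is
  expressed on the transformed scale) retains a term iff its *best*
  transformed value reaches *c* — equivalently, iff its minimum FDR is
  below 10⁻ᶜ; "best value" rather than mean is used because the cutoff's
  purpose is to keep the most significant terms, and a term's strongest
  comparison is what makes it interesting. Explicit term exclusion (by id
  or description) is applied before anything else. Rows/columns are
  reordered by average-linkage hierarchical clustering on Euclidean
  distances of the matrix as plotted (transformed if transformed) —
  unweighted pair-group averages are a neutral default for heatmaps and
  both axes are clustered unless disabled; clustering only permutes
  cells. An axis with fewer than two entries falls back to input order
  with a warning; a cutoff that removes every term is an explicit error
  suggesting a lower cutoff, never an empty image.
- **Bubble plot**: per summary row, x = |all_genes|, marker area scales
  with |common_genes| (0 for sentinel rows, drawn as a rimmed point so
  the term remains visible), color = lowest FDR (optionally on the
  −log10 scale). Default order is descending x; a selection list
  restricts and orders terms, and unknown names in it are reported as a
  usage error.

Rendering writes PNG (300 dpi) and SVG side by side, with a fixed font,
a fixed SVG hash salt and no embedded timestamps, so repeated renders of
the same data are byte-identical — a property the tests rely on.
Transformed matrices use a sequential colormap anchored at 0; raw-FDR
matrices use the reversed map so that smaller (more significant) values
are more intense.

## Synthetic fixtures and what they show

The fixture generator is constructive, not statistical: every term gets
an explicit plan — the comparisons where it is enriched, one exact FDR
per planned occurrence (log-uniform in [10⁻⁸, 0.9α] unless pinned,
rounded to the 6-significant-digit file precision so round trips are
exact), a planted common gene set repeated in each planned comparison,
and decoy genes unique to one (term, comparison) pair. Decoy uniqueness
makes the cross-comparison intersection *exactly* the planted set, so
the expected aggregation output (including both sentinels — the default
plan always plants a single-condition term and an empty-intersection
term per knowledge base) is known by construction and emitted as a
ground-truth object next to the files. Defaults model a moderately sized
study: 12 comparisons, 8 terms per knowledge base, 4–8 genes per term
occurrence, 30 extra background-only genes per DE table. Generation is a
pure function of the spec (seed included), hence byte-identical across
reruns.

Passing against these fixtures demonstrates that the bookkeeping —
splitting, request routing, filtering, merging, set algebra, defaults,
serialization, plotting transforms — is exact. It deliberately says
nothing about STRING's statistics (no hypergeometric sampling is
simulated), about identifier mapping, or about how real enrichment
results are correlated across comparisons.

## Numerical and degenerate-input choices

- Significance is strict (FDR < α); an FDR equal to α is not significant.
- Absent-term cells are exactly 1.0 and transform to exactly 0.
- File FDRs are written at 6 significant digits; aggregated tables use
  shortest round-trip float formatting so read(write(x)) == x.
- Empty files, all-blank backgrounds, zero parseable rows, empty gene
  lists at request time, duplicate comparison labels, mixed-kind writes
  and cutoff-without-transform are all explicit errors; an empty gene
  list for one *direction* of a comparison is not (it yields an empty
  record map and the run continues).
- One failing comparison does not abort a run: it is logged, reported in
  the run summary, and the exit status distinguishes clean (0), partial
  (1) and usage (2) failures.

## Known limitations

- The live transport is synchronous and single-threaded; a dozen
  comparisons means ~a minute of network time at the 1 s request spacing.
- Gene labels are compared case-sensitively, trusting the server-side
  preferred names to be canonical; lists from different STRING versions
  may therefore not intersect cleanly.
- The clustermap renders the matrix with the dendrogram leaf order but
  does not draw the dendrograms themselves.
- Offline replay requires the saved folder names to match the input file
  labels exactly.
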