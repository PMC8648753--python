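"""Aggregation of per-comparison enrichment into results and summary tables.

For each knowledge base two aggregated views are produced:

* a **summary** table: per term, the lowest FDR ever observed across
  comparisons, the number of comparisons in which the term is enriched
  ("occurrence"), the union of matched gene labels ("all_genes") and their
  intersection over the comparisons where the term is significant
  ("common_genes");
* a **results** table: per term, the common genes plus one FDR column per
  comparison, with 1 filled in where a comparison did not enrich for the
  term.

When up- and downregulated genes are analyzed separately, a term found in
both directions of one comparison keeps the lower of the two FDR values.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable

from .errors import FormatError, InputError, StringaggError
from .string_client import KINDS, ComparisonEnrichment, EnrichmentRecord

logger = logging.getLogger(__name__)


class Sentinel(enum.Enum):
    """Markers used in the common_genes column instead of a gene set."""

    NO_COMMON_GENE = "No common gene"
    SINGLE_CONDITION = "n/a: just one condition"

    def __str__(self) -> str:  # serialized verbatim in output tables
        return self.value


@dataclass
class SummaryRow:
    term_id: str
    description: str
    min_fdr: float
    occurrence: int
    all_genes: frozenset[str]
    common_genes: frozenset[str] | Sentinel

    def __post_init__(self) -> None:
        if self.occurrence < 1:
            raise InputError(f"{self.term_id}: occurrence must be >= 1")
        if isinstance(self.common_genes, frozenset):
            if not self.common_genes or not self.common_genes <= self.all_genes:
                raise InputError(
                    f"{self.term_id}: common_genes must be a non-empty subset of all_genes"
                )
        elif self.common_genes is Sentinel.SINGLE_CONDITION and self.occurrence != 1:
            raise InputError(f"{self.term_id}: SINGLE_CONDITION requires occurrence 1")
        elif self.common_genes is Sentinel.NO_COMMON_GENE and self.occurrence < 2:
            raise InputError(f"{self.term_id}: NO_COMMON_GENE requires occurrence >= 2")


@dataclass
class ResultsRow:
    term_id: str
    description: str
    common_genes: frozenset[str] | Sentinel
    fdr_by_comparison: dict[str, float]


@dataclass
class AggregateTables:
    """Summary and results views of one knowledge base, mutually consistent."""

    kind: str
    summary: list[SummaryRow]
    results: list[ResultsRow]


def merge_directions(
    up: list[EnrichmentRecord], down: list[EnrichmentRecord]
) -> list[EnrichmentRecord]:
    """Merge UP and DOWN record lists for one comparison and kind.

    A term present in both directions keeps the smaller FDR and the union
    of the two gene-label lists; terms in only one direction pass through
    unchanged.  Order: UP terms first (in order), then DOWN-only terms.
    """
    kinds = {r.kind for r in up} | {r.kind for r in down}
    if len(kinds) > 1:
        raise StringaggError(f"cannot merge directions across kinds {sorted(kinds)}")
    down_by_id = {r.term_id: r for r in down}
    merged: list[EnrichmentRecord] = []
    for rec in up:
        other = down_by_id.pop(rec.term_id, None)
        if other is None:
            merged.append(rec)
            continue
        best = rec if rec.fdr <= other.fdr else other
        labels = tuple(dict.fromkeys(list(rec.gene_labels) + list(other.gene_labels)))
        merged.append(
            EnrichmentRecord(
                kind=rec.kind,
                term_id=rec.term_id,
                description=best.description,
                number_of_genes=len(labels),
                number_of_genes_in_background=max(
                    rec.number_of_genes_in_background, other.number_of_genes_in_background
                ),
                fdr=min(rec.fdr, other.fdr),
                gene_labels=labels,
                p_value=best.p_value,
            )
        )
    merged.extend(r for r in down if r.term_id in down_by_id)
    return merged


def merge_by_label(enrichments: list[ComparisonEnrichment]) -> list[ComparisonEnrichment]:
    """Collapse per-direction enrichments into one entry per comparison label.

    Labels keep their first-seen order.  For a label retrieved in both
    directions the per-kind record lists are merged with
    :func:`merge_directions`.
    """
    by_label: dict[str, ComparisonEnrichment] = {}
    for ce in enrichments:
        if ce.label not in by_label:
            by_label[ce.label] = ComparisonEnrichment(
                label=ce.label,
                direction=ce.direction,
                records={k: list(v) for k, v in ce.records.items()},
            )
            continue
        acc = by_label[ce.label]
        acc.direction = "MERGED"
        for kind in KINDS:
            a = acc.records.get(kind, [])
            b = ce.records.get(kind, [])
            if not b:
                continue
            # order the pair as (UP, DOWN) when directions say so
            if ce.direction == "UP":
                a, b = b, a
            acc.records[kind] = merge_directions(a, b)
    return list(by_label.values())


def _check_labels(comparisons: list[ComparisonEnrichment]) -> list[str]:
    labels = [c.label for c in comparisons]
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate comparison labels: {labels}")
    return labels


def _term_index(
    comparisons: list[ComparisonEnrichment], kind: str
) -> dict[str, dict[str, EnrichmentRecord]]:
    """term_id -> {comparison label -> record}, in first-appearance order."""
    index: dict[str, dict[str, EnrichmentRecord]] = {}
    descriptions: dict[str, str] = {}
    for comp in comparisons:
        for rec in comp.records.get(kind, []):
            per_comp = index.setdefault(rec.term_id, {})
            per_comp[comp.label] = rec
            if rec.term_id in descriptions and descriptions[rec.term_id] != rec.description:
                logger.warning(
                    "term %s: differing descriptions across comparisons; keeping first",
                    rec.term_id,
                )
            descriptions.setdefault(rec.term_id, rec.description)
    return index


def _common_genes(per_comp: dict[str, EnrichmentRecord]) -> frozenset[str] | Sentinel:
    if len(per_comp) == 1:
        return Sentinel.SINGLE_CONDITION
    sets = [frozenset(r.gene_labels) for r in per_comp.values()]
    common = frozenset.intersection(*sets)
    return common if common else Sentinel.NO_COMMON_GENE


def _row_sort_key(row):
    return (-row.occurrence, row.min_fdr, row.term_id)


def build_summary(
    comparisons: list[ComparisonEnrichment], kind: str, alpha: float = 0.05
) -> list[SummaryRow]:
    """Build summary rows for one kind from direction-merged comparisons.

    common_genes intersects over the comparisons *where the term is
    significantly enriched* (records are expected pre-filtered at
    ``alpha``), not over every comparison in the run.  Rows are ordered by
    descending occurrence, then ascending min FDR, then term id.
    """
    _check_labels(comparisons)
    rows: list[SummaryRow] = []
    index = _term_index(comparisons, kind)
    for term_id, per_comp in index.items():
        recs = list(per_comp.values())
        rows.append(
            SummaryRow(
                term_id=term_id,
                description=recs[0].description,
                min_fdr=min(r.fdr for r in recs),
                occurrence=len(per_comp),
                all_genes=frozenset().union(*(r.gene_labels for r in recs)),
                common_genes=_common_genes(per_comp),
            )
        )
    rows.sort(key=_row_sort_key)
    return rows


def build_results(
    comparisons: list[ComparisonEnrichment], kind: str, alpha: float = 0.05
) -> list[ResultsRow]:
    """Build results rows for one kind: one FDR column per comparison.

    A comparison that did not enrich significantly for a term contributes
    the default value 1 exactly.  Column order follows the input
    comparison order; row order matches :func:`build_summary`.
    """
    labels = _check_labels(comparisons)
    index = _term_index(comparisons, kind)
    rows: list[ResultsRow] = []
    for term_id, per_comp in index.items():
        recs = list(per_comp.values())
        rows.append(
            ResultsRow(
                term_id=term_id,
                description=recs[0].description,
                common_genes=_common_genes(per_comp),
                fdr_by_comparison={
                    lab: (per_comp[lab].fdr if lab in per_comp else 1.0) for lab in labels
                },
            )
        )
    rows.sort(
        key=lambda r: (
            -sum(v < alpha for v in r.fdr_by_comparison.values()),
            min(r.fdr_by_comparison.values()),
            r.term_id,
        )
    )
    return rows


def aggregate(
    comparisons: list[ComparisonEnrichment], kind: str, alpha: float = 0.05
) -> AggregateTables:
    return AggregateTables(
        kind=kind,
        summary=build_summary(comparisons, kind, alpha),
        results=build_results(comparisons, kind, alpha),
    )


# --------------------------------------------------------------------------
# (de)serialization — tab-separated, spreadsheet-friendly


def _genes_cell(value: frozenset[str] | Sentinel) -> str:
    if isinstance(value, Sentinel):
        return value.value
    return ",".join(sorted(value))


def _genes_from_cell(cell: str) -> frozenset[str] | Sentinel:
    for sentinel in Sentinel:
        if cell == sentinel.value:
            return sentinel
    return frozenset(g for g in cell.split(",") if g)


def _write_text(text: str, destination: str | os.PathLike | IO[str]) -> None:
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
    else:
        with open(os.fspath(destination), "w", encoding="utf-8") as fh:
            fh.write(text)


def write_summary(rows: list[SummaryRow], destination: str | os.PathLike | IO[str]) -> None:
    """Write a summary table as TSV; floats use shortest round-trip form."""
    lines = ["term ID\tdescription\tlowest FDR\toccurrence\tall_genes\tcommon_genes"]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    r.description,
                    repr(r.min_fdr),
                    str(r.occurrence),
                    ",".join(sorted(r.all_genes)),
                    _genes_cell(r.common_genes),
                ]
            )
        )
    _write_text("\n".join(lines) + "\n", destination)


def read_summary(source: str | os.PathLike | IO[str]) -> list[SummaryRow]:
    lines = _read_lines(source)
    rows: list[SummaryRow] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 6:
            raise FormatError(f"summary line {lineno}: expected 6 fields, got {len(fields)}")
        rows.append(
            SummaryRow(
                term_id=fields[0],
                description=fields[1],
                min_fdr=float(fields[2]),
                occurrence=int(fields[3]),
                all_genes=frozenset(g for g in fields[4].split(",") if g),
                common_genes=_genes_from_cell(fields[5]),
            )
        )
    return rows


def write_results(rows: list[ResultsRow], destination: str | os.PathLike | IO[str]) -> None:
    """Write a results table as TSV, one FDR column per comparison."""
    if rows:
        labels = list(rows[0].fdr_by_comparison)
    else:
        labels = []
    lines = ["\t".join(["term ID", "description", "common_genes", *labels])]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    r.description,
                    _genes_cell(r.common_genes),
                    *(repr(r.fdr_by_comparison[lab]) for lab in labels),
                ]
            )
        )
    _write_text("\n".join(lines) + "\n", destination)


def read_results(source: str | os.PathLike | IO[str]) -> list[ResultsRow]:
    lines = _read_lines(source)
    header = lines[0].split("\t")
    if header[:3] != ["term ID", "description", "common_genes"]:
        raise FormatError("results file: unexpected header")
    labels = header[3:]
    rows: list[ResultsRow] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 3 + len(labels):
            raise FormatError(
                f"results line {lineno}: expected {3 + len(labels)} fields, got {len(fields)}"
            )
        rows.append(
            ResultsRow(
                term_id=fields[0],
                description=fields[1],
                common_genes=_genes_from_cell(fields[2]),
                fdr_by_comparison={
                    lab: float(v) for lab, v in zip(labels, fields[3:], strict=True)
                },
            )
        )
    return rows


def _read_lines(source: str | os.PathLike | IO[str]) -> list[str]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(os.fspath(source), encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty aggregated table file")
    return lines


def check_consistency(tables: AggregateTables, alpha: float = 0.05) -> None:
    """Assert the summary/results cross-invariants for one kind.

    Every term appears in both views; each term's summary min FDR equals
    the minimum over its results row; occurrence equals the count of
    results entries below ``alpha``.
    """
    s_by_id = {r.term_id: r for r in tables.summary}
    r_by_id = {r.term_id: r for r in tables.results}
    if set(s_by_id) != set(r_by_id):
        raise StringaggError(f"{tables.kind}: summary/results term sets differ")
    for term_id, srow in s_by_id.items():
        rrow = r_by_id[term_id]
        values = list(rrow.fdr_by_comparison.values())
        if min(values) != srow.min_fdr:
            raise StringaggError(f"{tables.kind}/{term_id}: min FDR mismatch")
        if sum(v < alpha for v in values) != srow.occurrence:
            raise StringaggError(f"{tables.kind}/{term_id}: occurrence mismatch")


def summarize_all_kinds(
    comparisons: Iterable[ComparisonEnrichment], alpha: float = 0.05
) -> dict[str, AggregateTables]:
    """Aggregate every kind with at least one enriched term."""
    merged = merge_by_label(list(comparisons))
    out: dict[str, AggregateTables] = {}
    for kind in KINDS:
        if any(c.records.get(kind) for c in merged):
            out[kind] = aggregate(merged, kind, alpha)
    return out
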