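"""Constructive synthetic fixtures with exact, planted ground truth.

The generator emulates the two inputs of a full analysis run:

* per-comparison differential-expression tables (gene id + signed fold
  change), and
* per-comparison STRING-format enrichment tables, one file per direction
  and knowledge base, as if downloaded from the server.

Everything is planted, not simulated: each term is assigned the exact set
of comparisons where it is enriched (its occurrence plan), an exact FDR
per planned occurrence, a "common" gene set repeated in every planned
comparison, and decoy genes unique to one (term, comparison) pair so the
cross-comparison intersection is exactly the planted set.  The expected
aggregation output (minimum FDR, occurrence, gene union/intersection or
sentinel) is therefore known by construction and returned as a
:class:`GroundTruth` alongside the files — an exact oracle, not a
statistical one.

The default plan covers the degenerate cases the aggregation must handle:
at least one single-condition term and one term with no common gene per
knowledge base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .aggregator import Sentinel
from .de_input import DETable, write_de_table
from .errors import InputError
from .string_client import (
    KINDS,
    EnrichmentRecord,
    FixtureTransport,
    records_to_payload,
    write_enrichment_tsv,
)

_DEFAULT_KINDS = KINDS


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror a moderately sized multi-arm expression study: twelve
    pairwise comparisons, eight terms per knowledge base, four to eight
    genes per term occurrence, significant FDR values between 1e-8 and
    just under the 0.05 threshold.
    """

    n_comparisons: int = 12
    n_terms_per_kind: int = 8
    genes_per_term: tuple[int, int] = (4, 8)
    kinds: tuple[str, ...] = _DEFAULT_KINDS
    alpha: float = 0.05
    seed: int = 0
    n_background_genes: int = 30
    occurrence_plan: dict[str, tuple[str, ...]] | None = None
    planted_common: dict[str, frozenset[str]] | None = None
    fdr_plan: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.n_comparisons < 1 or self.n_terms_per_kind < 1:
            raise InputError("need at least one comparison and one term per kind")
        lo, hi = self.genes_per_term
        if not 1 <= lo <= hi:
            raise InputError(f"invalid genes_per_term range {self.genes_per_term}")

    @property
    def labels(self) -> list[str]:
        return [f"comparison_{i + 1:02d}" for i in range(self.n_comparisons)]


@dataclass(frozen=True)
class ExpectedTerm:
    """Ground-truth aggregation fields for one (kind, term)."""

    kind: str
    term_id: str
    description: str
    min_fdr: float
    occurrence: int
    all_genes: frozenset[str]
    common_genes: frozenset[str] | Sentinel
    fdr_by_comparison: dict[str, float]


@dataclass
class GroundTruth:
    """Exact expected aggregation output, keyed by (kind, term_id)."""

    labels: list[str]
    expected: dict[tuple[str, str], ExpectedTerm] = field(default_factory=dict)

    def for_kind(self, kind: str) -> dict[str, ExpectedTerm]:
        return {tid: e for (k, tid), e in self.expected.items() if k == kind}


@dataclass(frozen=True)
class _PlannedTerm:
    kind: str
    term_id: str
    description: str
    direction: str  # UP or DOWN
    comparisons: tuple[str, ...]
    common: tuple[str, ...]
    decoys: dict[str, tuple[str, ...]]  # per comparison
    fdr: dict[str, float]  # per comparison


@dataclass
class _Plan:
    spec: FixtureSpec
    terms: list[_PlannedTerm]
    background_fc: dict[str, dict[str, float]]  # label -> gene -> fold change

    @property
    def labels(self) -> list[str]:
        return self.spec.labels


def _round6(x: float) -> float:
    # fixture FDRs are representable at the 6-significant-digit precision
    # used by the enrichment TSV writer, keeping round trips exact
    return float(f"{x:.6g}")


def build_plan(spec: FixtureSpec) -> _Plan:
    """Derive the full deterministic plan for a spec (pure function of it)."""
    rng = np.random.default_rng([spec.seed % (2**31), 2025])
    labels = spec.labels
    lo, hi = spec.genes_per_term
    gene_counter = 0

    def new_genes(n: int) -> tuple[str, ...]:
        nonlocal gene_counter
        genes = tuple(f"GENE{gene_counter + i:05d}" for i in range(n))
        gene_counter += n
        return genes

    terms: list[_PlannedTerm] = []
    for kind in spec.kinds:
        for j in range(spec.n_terms_per_kind):
            term_id = f"{kind}:{j:04d}"
            description = f"synthetic {kind} term {j}"
            if spec.occurrence_plan and term_id in spec.occurrence_plan:
                planned = tuple(spec.occurrence_plan[term_id])
            elif j == 0:
                planned = (labels[j % len(labels)],)  # guaranteed single-condition term
            else:
                occ = int(rng.integers(1, spec.n_comparisons + 1))
                planned = tuple(
                    labels[i] for i in sorted(rng.choice(len(labels), occ, replace=False))
                )
            if spec.planted_common and term_id in spec.planted_common:
                common = tuple(sorted(spec.planted_common[term_id]))
                gene_counter += len(common)  # keep the counter advancing deterministically
            elif j == 1 and len(planned) >= 2:
                common = ()  # guaranteed no-common-gene term
            else:
                n_common = int(rng.integers(1, max(2, lo)))
                common = new_genes(n_common)
            if len(common) > hi:
                raise InputError(
                    f"{term_id}: planted common set ({len(common)}) exceeds "
                    f"genes_per_term maximum ({hi})"
                )
            decoys: dict[str, tuple[str, ...]] = {}
            fdr: dict[str, float] = {}
            for lab in planned:
                n_total = int(rng.integers(max(lo, len(common) + 1), hi + 1))
                decoys[lab] = new_genes(n_total - len(common))
                if spec.fdr_plan and (term_id, lab) in spec.fdr_plan:
                    fdr[lab] = _round6(spec.fdr_plan[(term_id, lab)])
                else:
                    # log-uniform in [1e-8, 0.9 * alpha]: strictly significant
                    exponent = rng.uniform(-8, np.log10(0.9 * spec.alpha))
                    fdr[lab] = _round6(10.0**exponent)
            terms.append(
                _PlannedTerm(
                    kind=kind,
                    term_id=term_id,
                    description=description,
                    direction="UP" if j % 2 == 0 else "DOWN",
                    comparisons=planned,
                    common=common,
                    decoys=decoys,
                    fdr=fdr,
                )
            )

    background_fc: dict[str, dict[str, float]] = {}
    for lab in labels:
        bg = new_genes(spec.n_background_genes)
        signs = rng.choice([-1.0, 1.0], size=len(bg))
        mags = rng.uniform(0.1, 4.0, size=len(bg))
        background_fc[lab] = {g: round(float(s * m), 3) for g, s, m in zip(bg, signs, mags)}
    return _Plan(spec=spec, terms=terms, background_fc=background_fc)


def ground_truth(plan: _Plan) -> GroundTruth:
    gt = GroundTruth(labels=plan.labels)
    for t in plan.terms:
        all_genes = frozenset(t.common).union(*(t.decoys[lab] for lab in t.comparisons))
        common: frozenset[str] | Sentinel
        if len(t.comparisons) == 1:
            common = Sentinel.SINGLE_CONDITION
        elif not t.common:
            common = Sentinel.NO_COMMON_GENE
        else:
            common = frozenset(t.common)
        gt.expected[(t.kind, t.term_id)] = ExpectedTerm(
            kind=t.kind,
            term_id=t.term_id,
            description=t.description,
            min_fdr=min(t.fdr.values()),
            occurrence=len(t.comparisons),
            all_genes=all_genes,
            common_genes=common,
            fdr_by_comparison={
                lab: t.fdr.get(lab, 1.0) for lab in plan.labels
            },
        )
    return gt


def _term_genes(term: _PlannedTerm, label: str) -> tuple[str, ...]:
    return term.common + term.decoys[label]


def _de_table_for(plan: _Plan, label: str) -> DETable:
    """All genes of one comparison, signed by their term's direction."""
    rng = np.random.default_rng([plan.spec.seed % (2**31), 11, plan.labels.index(label)])
    entries: list[tuple[str, float]] = []
    seen: set[str] = set()
    for t in plan.terms:
        if label not in t.comparisons:
            continue
        sign = 1.0 if t.direction == "UP" else -1.0
        for g in _term_genes(t, label):
            if g in seen:
                continue
            seen.add(g)
            entries.append((g, round(float(sign * rng.uniform(0.2, 5.0)), 3)))
    for g, fc in plan.background_fc[label].items():
        entries.append((g, fc))
    return DETable(label=label, entries=entries)


def generate_de_tables(spec: FixtureSpec, outdir: str | os.PathLike) -> list[str]:
    """Write one gene/fold-change TSV per comparison; returns the paths.

    Byte-identical output for identical specs.
    """
    plan = build_plan(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for label in plan.labels:
        path = os.path.join(os.fspath(outdir), f"{label}.tsv")
        write_de_table(_de_table_for(plan, label), path)
        paths.append(path)
    return paths


def _records_for(plan: _Plan, label: str, direction: str, kind: str) -> list[EnrichmentRecord]:
    records = []
    for t in plan.terms:
        if t.kind != kind or t.direction != direction or label not in t.comparisons:
            continue
        genes = _term_genes(t, label)
        records.append(
            EnrichmentRecord(
                kind=kind,
                term_id=t.term_id,
                description=t.description,
                number_of_genes=len(genes),
                number_of_genes_in_background=len(genes) * 10,
                fdr=t.fdr[label],
                gene_labels=genes,
            )
        )
    return records


def generate_enrichment_fixture(
    spec: FixtureSpec, outdir: str | os.PathLike
) -> tuple[list[str], GroundTruth]:
    """Write per-comparison enrichment folders plus a ground-truth table.

    Layout: ``<outdir>/<label>/<DIRECTION>_<kind>.tsv`` for every kind and
    direction with at least one planned term, readable by
    ``string_client.read_enrichment_tsv`` and servable offline through
    ``string_client.DirectoryTransport``.
    """
    plan = build_plan(spec)
    gt = ground_truth(plan)
    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []
    for label in plan.labels:
        folder = os.path.join(os.fspath(outdir), label)
        os.makedirs(folder, exist_ok=True)
        for direction in ("UP", "DOWN"):
            for kind in spec.kinds:
                records = _records_for(plan, label, direction, kind)
                if not records:
                    continue
                path = os.path.join(folder, f"{direction}_{kind}.tsv")
                write_enrichment_tsv(records, path)
                paths.append(path)
    write_ground_truth(gt, os.path.join(os.fspath(outdir), "ground_truth.tsv"))
    return paths, gt


def write_ground_truth(gt: GroundTruth, destination: str | os.PathLike) -> None:
    """Human-inspectable TSV view of the planted expectations."""
    lines = ["kind\tterm ID\tlowest FDR\toccurrence\tall_genes\tcommon_genes"]
    for (kind, term_id), e in sorted(gt.expected.items()):
        common = (
            e.common_genes.value
            if isinstance(e.common_genes, Sentinel)
            else ",".join(sorted(e.common_genes))
        )
        lines.append(
            f"{kind}\t{term_id}\t{e.min_fdr!r}\t{e.occurrence}\t"
            f"{','.join(sorted(e.all_genes))}\t{common}"
        )
    with open(os.fspath(destination), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def fixture_transport(spec: FixtureSpec) -> FixtureTransport:
    """Build an offline transport answering exactly this spec's requests.

    Payloads are registered under the UP/DOWN gene sets of the generated
    DE tables, so a pipeline that parses those tables and splits them by
    sign receives the planned enrichment.
    """
    plan = build_plan(spec)
    transport = FixtureTransport()
    for label in plan.labels:
        table = _de_table_for(plan, label)
        up = [g for g, fc in table.entries if fc > 0]
        down = [g for g, fc in table.entries if fc < 0]
        payloads: dict[str, list[dict]] = {"UP": [], "DOWN": []}
        for direction, genes in (("UP", up), ("DOWN", down)):
            for kind in spec.kinds:
                payloads[direction].extend(
                    records_to_payload(_records_for(plan, label, direction, kind))
                )
            transport.register(genes, payloads[direction])
        # ALL mode submits the whole table; serve the union of both directions
        transport.register(table.genes, payloads["UP"] + payloads["DOWN"])
    return transport
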