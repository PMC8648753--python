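"""STRING enrichment-API client with pluggable transports.

The enrichment endpoint accepts a newline-delimited identifier list plus a
species taxon and returns one JSON record per (term, category) hit.  Only
the five knowledge bases aggregated downstream are kept: KEGG Pathways
("KEGG"), GO Biological Process ("Process"), GO Molecular Function
("Function"), GO Cellular Component ("Component") and Reactome ("RCTM").

Transports decouple the wire from the logic: :class:`HTTPTransport` talks
to the live server, :class:`FixtureTransport` replays registered payloads
keyed by the submitted gene set, and :class:`DirectoryTransport` serves
previously saved STRING-format TSV files.  All three yield identical
downstream results for identical payloads.
"""

from __future__ import annotations

import json
import logging
import os
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import IO, Protocol

from .de_input import BackgroundList, DirectionalGeneSets
from .errors import FormatError, InputError, ProtocolError, RetrievalError

logger = logging.getLogger(__name__)

#: The five knowledge bases ("kinds") retained from enrichment payloads.
KINDS = ("KEGG", "Process", "Function", "Component", "RCTM")

#: Aliases occasionally seen in payloads / files, normalized to KINDS.
_KIND_ALIASES = {
    "KEGG": "KEGG",
    "KEGG Pathways": "KEGG",
    "Process": "Process",
    "Biological Process (Gene Ontology)": "Process",
    "Function": "Function",
    "Molecular Function (Gene Ontology)": "Function",
    "Component": "Component",
    "Cellular Component (Gene Ontology)": "Component",
    "RCTM": "RCTM",
    "Reactome": "RCTM",
    "Reactome Pathways": "RCTM",
}

DIRECTIONS = ("UP", "DOWN", "ALL")

#: Analysis modes and the request directions each one issues.
MODES = {
    "UP_ONLY": ("UP",),
    "DOWN_ONLY": ("DOWN",),
    "UP_DOWN_SEPARATE": ("UP", "DOWN"),
    "ALL_TOGETHER": ("ALL",),
}

_CALLER_IDENTITY = "stringagg"
_MAIN_HOST = "https://string-db.org"

#: Column header mimicking the files downloadable from the STRING website.
_TSV_HEADER = (
    "#term ID\tterm description\tobserved gene count\t"
    "background gene count\tfalse discovery rate\t"
    "matching proteins in your network (labels)"
)


@dataclass
class AnalysisSettings:
    """Settings governing one enrichment run.

    Parameters
    ----------
    species_taxon
        NCBI taxonomy identifier; defaults to 10090 (*Mus musculus*).
    api_version
        ``"latest"`` for the main STRING host, or a pinned version tag such
        as ``"11.0"`` that maps to the archived version-specific host.
    background
        Optional identifier universe; the server defaults to the whole
        genome of the selected species when unset.
    alpha
        Significance threshold; terms are kept when FDR is strictly below.
    mode
        One of ``UP_ONLY``, ``DOWN_ONLY``, ``UP_DOWN_SEPARATE`` (default)
        or ``ALL_TOGETHER``.
    """

    species_taxon: int = 10090
    api_version: str = "latest"
    background: BackgroundList | None = None
    alpha: float = 0.05
    mode: str = "UP_DOWN_SEPARATE"

    def __post_init__(self) -> None:
        if self.species_taxon < 1:
            raise InputError(f"invalid species taxon {self.species_taxon}")
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in MODES:
            raise InputError(f"unknown mode {self.mode!r}; choose from {sorted(MODES)}")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One enriched term as returned by STRING for one gene list."""

    kind: str
    term_id: str
    description: str
    number_of_genes: int
    number_of_genes_in_background: int
    fdr: float
    gene_labels: tuple[str, ...]
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.number_of_genes != len(self.gene_labels):
            raise ProtocolError(
                f"{self.term_id}: number_of_genes={self.number_of_genes} "
                f"but {len(self.gene_labels)} gene labels"
            )
        if not 0 < self.fdr <= 1:
            raise ProtocolError(f"{self.term_id}: fdr {self.fdr} outside (0, 1]")


@dataclass
class ComparisonEnrichment:
    """Per-kind enrichment records for one comparison and direction."""

    label: str
    direction: str
    records: dict[str, list[EnrichmentRecord]] = field(default_factory=dict)

    def kinds(self) -> list[str]:
        return [k for k in KINDS if self.records.get(k)]


@dataclass(frozen=True)
class RequestDescriptor:
    """A prepared enrichment request: endpoint URL plus form parameters."""

    url: str
    params: dict[str, str]

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(self.params["identifiers"].split("\n"))


def host_for_version(api_version: str) -> str:
    if api_version in ("latest", "", None):
        return _MAIN_HOST
    tag = str(api_version).replace(".", "-")
    return f"https://version-{tag}.string-db.org"


def build_enrichment_request(
    genes: list[str], settings: AnalysisSettings
) -> RequestDescriptor:
    """Prepare the enrichment request for one gene list.

    Raises
    ------
    InputError
        If ``genes`` is empty.
    """
    if not genes:
        raise InputError("cannot build an enrichment request for an empty gene list")
    params = {
        "identifiers": "\n".join(genes),
        "species": str(settings.species_taxon),
        "caller_identity": _CALLER_IDENTITY,
    }
    if settings.background is not None:
        params["background_string_identifiers"] = "\n".join(
            settings.background.identifiers
        )
    url = f"{host_for_version(settings.api_version)}/api/json/enrichment"
    return RequestDescriptor(url=url, params=params)


def _normalize_gene_labels(raw) -> tuple[str, ...]:
    if raw is None:
        return ()
    if isinstance(raw, str):
        return tuple(g for g in raw.split(",") if g)
    return tuple(raw)


def parse_enrichment_payload(payload: list[dict]) -> list[EnrichmentRecord]:
    """Decode an enrichment payload into :class:`EnrichmentRecord` objects.

    Entries whose category is not one of the five supported knowledge bases
    (e.g. Pfam, InterPro domains) are dropped; the drop is logged.

    Raises
    ------
    ProtocolError
        If a retained entry lacks a required field.
    """
    records: list[EnrichmentRecord] = []
    dropped = 0
    for entry in payload:
        category = entry.get("category")
        if category is None:
            raise ProtocolError("payload entry missing required field 'category'")
        kind = _KIND_ALIASES.get(category)
        if kind is None:
            dropped += 1
            continue
        for req in ("term", "fdr"):
            if req not in entry:
                raise ProtocolError(f"payload entry missing required field {req!r}")
        labels = _normalize_gene_labels(entry.get("preferredNames"))
        n_genes = int(entry.get("number_of_genes", len(labels)))
        records.append(
            EnrichmentRecord(
                kind=kind,
                term_id=str(entry["term"]),
                description=str(entry.get("description", "")),
                number_of_genes=n_genes,
                number_of_genes_in_background=int(
                    entry.get("number_of_genes_in_background", 0)
                ),
                fdr=float(entry["fdr"]),
                gene_labels=labels,
                p_value=float(entry["p_value"]) if "p_value" in entry else None,
            )
        )
    if dropped:
        logger.info("dropped %d payload entries from unsupported categories", dropped)
    return records


def filter_significant(
    records: list[EnrichmentRecord], alpha: float
) -> list[EnrichmentRecord]:
    """Keep records with FDR strictly below ``alpha``, preserving order."""
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    return [r for r in records if r.fdr < alpha]


# --------------------------------------------------------------------------
# transports


class Transport(Protocol):
    """Anything that can turn a prepared request into a raw payload list."""

    def fetch(
        self, request: RequestDescriptor, *, label: str, direction: str
    ) -> list[dict]: ...


class HTTPTransport:
    """Live transport against the STRING server.

    Requests are spaced at least ``min_interval`` seconds apart and retried
    with exponential backoff.
    """

    def __init__(self, retries: int = 3, min_interval: float = 1.0, timeout: float = 60.0):
        self.retries = retries
        self.min_interval = min_interval
        self.timeout = timeout
        self._last_request = 0.0

    def fetch(self, request: RequestDescriptor, *, label: str, direction: str) -> list[dict]:
        data = urllib.parse.urlencode(request.params).encode()
        delay = 1.0
        for attempt in range(self.retries + 1):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(request.url, data=data, timeout=self.timeout) as resp:
                    return json.loads(resp.read().decode())
            except Exception as exc:  # noqa: BLE001 - network errors are opaque
                if attempt == self.retries:
                    raise RetrievalError(
                        f"{label}/{direction}: enrichment retrieval failed: {exc}",
                        label=label,
                    ) from exc
                logger.warning("%s/%s: retrying after %s", label, direction, exc)
                time.sleep(delay)
                delay *= 2
        raise AssertionError("unreachable")


class FixtureTransport:
    """Offline transport replaying payloads registered per gene set.

    The lookup key is the (unordered) set of submitted identifiers, so the
    transport is insensitive to gene order but strict about content.
    """

    def __init__(self, strict: bool = True):
        self._payloads: dict[frozenset[str], list[dict]] = {}
        self.strict = strict

    def register(self, genes: list[str] | frozenset[str], payload: list[dict]) -> None:
        self._payloads[frozenset(genes)] = payload

    def fetch(self, request: RequestDescriptor, *, label: str, direction: str) -> list[dict]:
        key = frozenset(request.identifiers)
        if key not in self._payloads:
            if self.strict:
                raise RetrievalError(
                    f"{label}/{direction}: no fixture payload for submitted gene set",
                    label=label,
                )
            return []
        return self._payloads[key]


class DirectoryTransport:
    """Offline transport serving saved STRING-format enrichment tables.

    Expects ``<root>/<label>/<DIRECTION>_<kind>.tsv`` files as written by
    :func:`write_enrichment_tsv` (or downloaded from STRING by hand).
    Missing files mean "no enrichment for that kind" and yield nothing.
    """

    def __init__(self, root: str | os.PathLike):
        self.root = os.fspath(root)
        if not os.path.isdir(self.root):
            raise InputError(f"fixture directory {self.root!r} does not exist")

    def fetch(self, request: RequestDescriptor, *, label: str, direction: str) -> list[dict]:
        folder = os.path.join(self.root, label)
        if not os.path.isdir(folder):
            raise RetrievalError(f"{label}: no saved enrichment folder", label=label)
        payload: list[dict] = []
        for kind in KINDS:
            path = os.path.join(folder, f"{direction}_{kind}.tsv")
            if not os.path.exists(path):
                continue
            _, records = read_enrichment_tsv(path)
            payload.extend(records_to_payload(records))
        return payload


def records_to_payload(records: list[EnrichmentRecord]) -> list[dict]:
    """Re-encode records as raw payload entries (inverse of parsing)."""
    out = []
    for r in records:
        entry = {
            "category": r.kind,
            "term": r.term_id,
            "description": r.description,
            "number_of_genes": r.number_of_genes,
            "number_of_genes_in_background": r.number_of_genes_in_background,
            "fdr": r.fdr,
            "preferredNames": list(r.gene_labels),
        }
        if r.p_value is not None:
            entry["p_value"] = r.p_value
        out.append(entry)
    return out


def _bucket_by_kind(records: list[EnrichmentRecord]) -> dict[str, list[EnrichmentRecord]]:
    buckets: dict[str, list[EnrichmentRecord]] = {}
    for rec in records:
        bucket = buckets.setdefault(rec.kind, [])
        clash = next((b for b in bucket if b.term_id == rec.term_id), None)
        if clash is not None:
            logger.warning("duplicate term %s in kind %s; keeping lower FDR", rec.term_id, rec.kind)
            if rec.fdr < clash.fdr:
                bucket[bucket.index(clash)] = rec
            continue
        bucket.append(rec)
    return buckets


def fetch_enrichment(
    label: str,
    genesets: DirectionalGeneSets,
    settings: AnalysisSettings,
    transport: Transport,
) -> list[ComparisonEnrichment]:
    """Retrieve significance-filtered enrichment for one comparison.

    One request is issued per direction applicable under ``settings.mode``
    (UP and DOWN for the default separate mode, a single request
    otherwise).  A direction with an empty gene list yields an empty record
    map rather than an error.
    """
    out: list[ComparisonEnrichment] = []
    for direction in MODES[settings.mode]:
        genes = genesets.for_direction(direction)
        if not genes:
            logger.info("%s/%s: empty gene list, skipping request", label, direction)
            out.append(ComparisonEnrichment(label=label, direction=direction))
            continue
        request = build_enrichment_request(genes, settings)
        payload = transport.fetch(request, label=label, direction=direction)
        records = filter_significant(parse_enrichment_payload(payload), settings.alpha)
        out.append(
            ComparisonEnrichment(
                label=label, direction=direction, records=_bucket_by_kind(records)
            )
        )
    return out


# --------------------------------------------------------------------------
# STRING-format enrichment tables


def kind_from_filename(name: str) -> str | None:
    stem = os.path.splitext(os.path.basename(name))[0]
    for prefix in ("UP_", "DOWN_", "ALL_"):
        if stem.startswith(prefix):
            stem = stem[len(prefix):]
            break
    return _KIND_ALIASES.get(stem)


def write_enrichment_tsv(
    records: list[EnrichmentRecord], destination: str | os.PathLike | IO[str]
) -> None:
    """Write records of one kind as a STRING-style tab-delimited table.

    FDR (and p-value, when present) are formatted to 6 significant digits,
    matching the precision of server downloads.
    """
    kinds = {r.kind for r in records}
    if len(kinds) > 1:
        raise InputError(f"records mix kinds {sorted(kinds)}; write one kind per file")
    lines = [_TSV_HEADER]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    r.description,
                    str(r.number_of_genes),
                    str(r.number_of_genes_in_background),
                    f"{r.fdr:.6g}",
                    ",".join(r.gene_labels),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
    else:
        with open(os.fspath(destination), "w", encoding="utf-8") as fh:
            fh.write(text)


def read_enrichment_tsv(
    source: str | os.PathLike | IO[str], kind: str | None = None
) -> tuple[str, list[EnrichmentRecord]]:
    """Read one STRING-style enrichment table.

    The kind is taken from the file name (``UP_KEGG.tsv`` → ``KEGG``)
    unless passed explicitly.

    Raises
    ------
    FormatError
        On a malformed row (reported with its line number) or when the
        kind cannot be determined.
    """
    if hasattr(source, "read"):
        name = getattr(source, "name", "<stream>")
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        name = os.fspath(source)
        with open(name, encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    kind = kind or kind_from_filename(name)
    if kind not in KINDS:
        raise FormatError(f"{name}: cannot determine knowledge base (kind) for this file")

    records: list[EnrichmentRecord] = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip() or ln.startswith("#") or lineno == 1:
            continue  # header (always line 1) or blank
        fields = ln.split("\t")
        if len(fields) != 6:
            raise FormatError(f"{name}:{lineno}: expected 6 tab-separated fields, got {len(fields)}")
        try:
            records.append(
                EnrichmentRecord(
                    kind=kind,
                    term_id=fields[0],
                    description=fields[1],
                    number_of_genes=int(fields[2]),
                    number_of_genes_in_background=int(fields[3]),
                    fdr=float(fields[4]),
                    gene_labels=_normalize_gene_labels(fields[5]),
                )
            )
        except (ValueError, ProtocolError) as exc:
            raise FormatError(f"{name}:{lineno}: {exc}") from exc
    return kind, records
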