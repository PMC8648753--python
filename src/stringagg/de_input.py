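"""Parsing of differential-expression tables and direction splitting.

Input tables are plain delimited text with one gene identifier and one
fold-change value per row (extra columns are ignored).  The file name,
stripped of directory and extension, labels the comparison.  Genes are
split into up- and downregulated sets either by the sign of a log ratio
(default) or by comparison of a linear ratio against 1.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import InputError

logger = logging.getLogger(__name__)

#: Delimiters tried, in order, when sniffing the first line.
DELIMITERS = ("\t", ",", ";")

#: Supported fold-change conventions.
CONVENTIONS = ("log-ratio", "linear-ratio")


@dataclass
class DETable:
    """One comparison's gene identifiers and fold changes.

    Parameters
    ----------
    label
        Comparison name, normally the source file name without extension.
    entries
        Ordered ``(gene_id, fold_change)`` pairs.
    skipped
        Number of data rows dropped because the fold change did not parse.
    """

    label: str
    entries: list[tuple[str, float]] = field(default_factory=list)
    skipped: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise InputError("comparison label must be non-empty")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]


@dataclass
class DirectionalGeneSets:
    """Up-, down-regulated and combined gene lists for one comparison.

    ``all`` is the union of every parsed gene in input order (including
    boundary genes excluded from both directions); ``up`` and ``down``
    are disjoint and duplicate-free.
    """

    up: list[str]
    down: list[str]
    all: list[str]

    def for_direction(self, direction: str) -> list[str]:
        return {"UP": self.up, "DOWN": self.down, "ALL": self.all}[direction]


@dataclass
class BackgroundList:
    """Statistical-background identifiers (one per line in the source file)."""

    identifiers: list[str]


def _label_from_name(name: str) -> str:
    base = os.path.basename(name)
    stem, ext = os.path.splitext(base)
    return stem or base


def _sniff_delimiter(line: str) -> str:
    for d in DELIMITERS:
        if d in line:
            return d
    return "\t"


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def parse_de_table(
    source: str | os.PathLike | IO[str],
    dialect: str | None = None,
) -> DETable:
    """Parse a delimited gene/fold-change table into a :class:`DETable`.

    Column 1 is the gene identifier, column 2 the fold change; further
    columns are ignored.  A single header row — the first row whose second
    field is non-numeric — is skipped.  Data rows with an unparseable fold
    change are skipped and counted in ``DETable.skipped``.

    Parameters
    ----------
    source
        Path, or an open text stream with a ``name`` attribute.
    dialect
        Field delimiter; sniffed from the first line when ``None``.

    Raises
    ------
    InputError
        If the file is empty or yields no parseable rows.
    """
    if hasattr(source, "read"):
        stream: IO[str] = source  # type: ignore[assignment]
        name = getattr(stream, "name", "<stream>")
        lines = stream.read().splitlines()
    else:
        name = os.fspath(source)
        with open(name, encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    label = _label_from_name(name)
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise InputError(f"{name}: file is empty")

    delim = dialect or _sniff_delimiter(lines[0])
    table = DETable(label=label)
    seen: set[str] = set()
    for row_no, ln in enumerate(lines):
        fields = [f.strip() for f in ln.split(delim)]
        if len(fields) < 2:
            table.skipped += 1
            continue
        gene, fc_text = fields[0], fields[1]
        if row_no == 0 and not _is_number(fc_text):
            # a non-numeric second field on the first row is the header
            continue
        if not gene or not _is_number(fc_text):
            table.skipped += 1
            continue
        fc = float(fc_text)
        if fc != fc or fc in (float("inf"), float("-inf")):
            table.skipped += 1
            continue
        if gene in seen:
            logger.warning("%s: duplicate gene %r, keeping first occurrence", name, gene)
            continue
        seen.add(gene)
        table.entries.append((gene, fc))

    if not table.entries:
        raise InputError(f"{name}: no parseable gene/fold-change rows")
    return table


def split_directions(table: DETable, convention: str = "log-ratio") -> DirectionalGeneSets:
    """Split a comparison's genes into up-/down-regulated sets.

    Under the ``log-ratio`` convention a positive fold change is up, a
    negative one down, and exactly zero belongs to neither (but stays in
    ``all``).  Under ``linear-ratio`` the boundary is 1 and non-positive
    values are rejected.
    """
    if convention not in CONVENTIONS:
        raise InputError(f"unknown fold-change convention {convention!r}")
    up: list[str] = []
    down: list[str] = []
    allg: list[str] = []
    for gene, fc in table.entries:
        allg.append(gene)
        if convention == "log-ratio":
            if fc > 0:
                up.append(gene)
            elif fc < 0:
                down.append(gene)
        else:
            if fc <= 0:
                raise InputError(
                    f"{table.label}: fold change {fc} for {gene!r} is not a valid linear ratio"
                )
            if fc > 1:
                up.append(gene)
            elif fc < 1:
                down.append(gene)
    return DirectionalGeneSets(up=up, down=down, all=allg)


def load_background(source: str | os.PathLike | IO[str] | Iterable[str]) -> BackgroundList:
    """Read a headerless one-identifier-per-line background file.

    Blank lines are skipped, identifiers are whitespace-trimmed and
    deduplicated (first occurrence kept).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    elif isinstance(source, (str, os.PathLike)):
        with open(os.fspath(source), encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(source)

    out: list[str] = []
    seen: set[str] = set()
    for ln in lines:
        ident = ln.strip()
        if not ident or ident in seen:
            continue
        seen.add(ident)
        out.append(ident)
    if not out:
        raise InputError("background file contains no identifiers")
    return BackgroundList(identifiers=out)


def write_de_table(table: DETable, destination: str | os.PathLike | IO[str]) -> None:
    """Write a :class:`DETable` back out as a two-column TSV with header."""
    buf = io.StringIO()
    buf.write("gene\tfold_change\n")
    for gene, fc in table.entries:
        buf.write(f"{gene}\t{fc!r}\n")
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
    else:
        with open(os.fspath(destination), "w", encoding="utf-8") as fh:
            fh.write(text)
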