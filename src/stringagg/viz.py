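"""Clustermaps from results-type tables and bubble plots from summaries.

The clustermap path turns a results table into a dense term × comparison
FDR matrix, optionally −log10-transforms it, applies a significance cutoff
(a term survives cutoff *c* iff its best transformed value is ≥ *c*, i.e.
its minimum FDR is below 10^−c) and reorders rows/columns by hierarchical
clustering before rendering.  The bubble path encodes, per term, the size
of the gene union on x, the size of the gene intersection as marker area
and the best FDR as color.

Rendering is deterministic (fixed fonts, salted SVG ids, no timestamps) so
repeated renders of the same data are byte-identical.
"""

from __future__ import annotations

import math
import os
import textwrap
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .aggregator import ResultsRow, Sentinel, SummaryRow  # noqa: E402
from .errors import InputError, UsageError  # noqa: E402

_RC = {
    "svg.hashsalt": "stringagg",
    "font.family": "DejaVu Sans",
    "figure.dpi": 100,
}


@dataclass
class TermMatrix:
    """Dense term × comparison matrix of FDR (or −log10 FDR) values."""

    term_labels: list[str]
    comparison_labels: list[str]
    values: np.ndarray
    transformed: bool = False
    row_linkage: np.ndarray | None = field(default=None, repr=False)
    col_linkage: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.term_labels), len(self.comparison_labels)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.term_labels)} terms x {len(self.comparison_labels)} comparisons"
            )


@dataclass(frozen=True)
class BubbleDatum:
    """One term's bubble: x = |all_genes|, size = |common_genes|, color = min FDR."""

    term_label: str
    x: int
    size: int
    color_value: float

    def __post_init__(self) -> None:
        if self.size > self.x:
            raise InputError(f"{self.term_label}: common-gene count exceeds all-gene count")


def _display_labels(rows: list[ResultsRow]) -> list[str]:
    # descriptions label the plot; disambiguate collisions with the term id
    counts: dict[str, int] = {}
    for r in rows:
        counts[r.description] = counts.get(r.description, 0) + 1
    return [
        r.description if counts[r.description] == 1 else f"{r.description} ({r.term_id})"
        for r in rows
    ]


def results_to_matrix(
    results: list[ResultsRow],
    transform: bool = False,
    cutoff: float | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> TermMatrix:
    """Convert results rows into a :class:`TermMatrix`.

    Parameters
    ----------
    results
        Non-empty list of results rows sharing one comparison set.
    transform
        Replace each FDR cell with −log10(FDR); an FDR of 1 maps to 0.
    cutoff
        Minimum best transformed value a term needs to be retained;
        requires ``transform``.  Cutoff 5 keeps exactly the terms with
        minimum FDR below 1e−5.
    exclude
        Term labels (descriptions or term ids) dropped before anything else.

    Raises
    ------
    UsageError
        If a cutoff is given without the transform.
    InputError
        If no rows are given, or every term is filtered out.
    """
    if not results:
        raise InputError("results table is empty")
    if cutoff is not None and not transform:
        raise UsageError("a cutoff requires the -log10 transform")

    rows = [r for r in results if r.term_id not in exclude and r.description not in exclude]
    if not rows:
        raise InputError("all terms were excluded from the plot")

    comparisons = list(rows[0].fdr_by_comparison)
    values = np.array(
        [[r.fdr_by_comparison[c] for c in comparisons] for r in rows], dtype=float
    )
    if transform:
        values = -np.log10(values)
        values[values == 0.0] = 0.0  # normalize -0.0 from fdr == 1
    if cutoff is not None:
        keep = values.max(axis=1) >= cutoff
        if not keep.any():
            raise InputError(
                f"no term reaches the cutoff {cutoff}; lower the cutoff to retain terms"
            )
        rows = [r for r, k in zip(rows, keep) if k]
        values = values[keep]
    return TermMatrix(
        term_labels=_display_labels(rows),
        comparison_labels=comparisons,
        values=values,
        transformed=transform,
    )


def cluster_matrix(
    matrix: TermMatrix, cluster_rows: bool = True, cluster_cols: bool = True
) -> TermMatrix:
    """Reorder a matrix by average-linkage Euclidean clustering leaf order.

    Cell values are only permuted, never altered.  An axis with fewer than
    two entries falls back to its input order with a warning.
    """

    def _order(data: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if data.shape[0] < 2:
            warnings.warn("not enough entries to cluster this axis; keeping input order",
                          stacklevel=3)
            return np.arange(data.shape[0]), None
        linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        return np.asarray(hierarchy.leaves_list(linkage)), linkage

    row_order = np.arange(matrix.values.shape[0])
    col_order = np.arange(matrix.values.shape[1])
    row_linkage = col_linkage = None
    if cluster_rows:
        row_order, row_linkage = _order(matrix.values)
    if cluster_cols:
        col_order, col_linkage = _order(matrix.values.T)
    return TermMatrix(
        term_labels=[matrix.term_labels[i] for i in row_order],
        comparison_labels=[matrix.comparison_labels[j] for j in col_order],
        values=matrix.values[np.ix_(row_order, col_order)],
        transformed=matrix.transformed,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )


def _wrap(label: str, width: int = 40) -> str:
    return "\n".join(textwrap.wrap(label, width=width)) or label


def _save(fig, destination: str | os.PathLike, formats: tuple[str, ...]) -> list[str]:
    stem, ext = os.path.splitext(os.fspath(destination))
    if ext:
        formats = (ext.lstrip("."),)
    written = []
    for fmt in formats:
        path = f"{stem}.{fmt}"
        fig.savefig(path, format=fmt, dpi=300, metadata=_no_date_metadata(fmt))
        written.append(path)
    plt.close(fig)
    return written


def _no_date_metadata(fmt: str) -> dict | None:
    if fmt == "svg":
        return {"Date": None}
    return None


def render_clustermap(
    matrix: TermMatrix,
    destination: str | os.PathLike,
    figsize: tuple[float, float] | None = None,
    cmap: str | None = None,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[str]:
    """Render a term × comparison heatmap to image file(s).

    Returns the list of files written (PNG and SVG side-by-side unless the
    destination carries an explicit extension).  Transformed matrices use a
    sequential colormap anchored at 0; raw-FDR matrices use the inverted
    map so that smaller (more significant) FDR is more intense.
    """
    if matrix.values.size == 0:
        raise InputError("cannot render an empty matrix")
    n_rows, n_cols = matrix.values.shape
    if figsize is None:
        figsize = (max(4.0, 1.0 + 0.6 * n_cols + 2.5), max(3.0, 0.4 * n_rows + 1.5))
    if cmap is None:
        cmap = "viridis" if matrix.transformed else "viridis_r"

    with plt.rc_context(_RC):
        fig, ax = plt.subplots(figsize=figsize)
        vmin = 0.0 if matrix.transformed else float(matrix.values.min())
        mesh = ax.pcolormesh(matrix.values, cmap=cmap, vmin=vmin,
                             vmax=float(matrix.values.max()))
        ax.set_xticks(np.arange(n_cols) + 0.5)
        ax.set_xticklabels(matrix.comparison_labels, rotation=90, fontsize=8)
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels([_wrap(t) for t in matrix.term_labels], fontsize=8)
        ax.invert_yaxis()
        cbar = fig.colorbar(mesh, ax=ax, shrink=0.8)
        cbar.set_label("-log10(FDR)" if matrix.transformed else "FDR")
        fig.tight_layout()
        return _save(fig, destination, formats)


def summary_to_bubbles(
    summary: list[SummaryRow], selection: list[str] | None = None
) -> list[BubbleDatum]:
    """Map summary rows to bubble data.

    ``selection`` (term ids or descriptions) restricts and orders the
    terms; by default all terms are kept, ordered by descending x.
    Sentinel common_genes rows get bubble size 0.

    Raises
    ------
    UsageError
        If the selection names unknown terms (they are listed).
    InputError
        If the summary is empty.
    """
    if not summary:
        raise InputError("summary table is empty")

    def datum(row: SummaryRow) -> BubbleDatum:
        size = len(row.common_genes) if isinstance(row.common_genes, frozenset) else 0
        return BubbleDatum(
            term_label=row.description or row.term_id,
            x=len(row.all_genes),
            size=size,
            color_value=row.min_fdr,
        )

    if selection is None:
        return sorted((datum(r) for r in summary), key=lambda d: (-d.x, d.term_label))

    by_key: dict[str, SummaryRow] = {}
    for row in summary:
        by_key.setdefault(row.term_id, row)
        by_key.setdefault(row.description, row)
    unknown = [term for term in selection if term not in by_key]
    if unknown:
        raise UsageError(f"unknown terms in selection: {', '.join(unknown)}")
    return [datum(by_key[term]) for term in selection]


def render_bubble_plot(
    data: list[BubbleDatum],
    destination: str | os.PathLike,
    log_color: bool = False,
    figsize: tuple[float, float] | None = None,
    cmap: str | None = None,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[str]:
    """Render a bubble plot to image file(s); returns the files written.

    With ``log_color`` the color scale runs over −log10 of the FDR values
    instead of the raw values.
    """
    if not data:
        raise InputError("no bubble data to render")
    if figsize is None:
        figsize = (8.0, max(3.0, 0.45 * len(data) + 1.5))
    if cmap is None:
        cmap = "viridis" if log_color else "viridis_r"

    y = np.arange(len(data))[::-1]
    x = np.array([d.x for d in data], dtype=float)
    sizes = np.array([d.size for d in data], dtype=float)
    colors = np.array([d.color_value for d in data], dtype=float)
    if log_color:
        colors = -np.log10(colors)

    with plt.rc_context(_RC):
        fig, ax = plt.subplots(figsize=figsize)
        # area proportional to the common-gene count; zero-size rows get a rim
        marker_area = 30.0 + 40.0 * sizes
        sc = ax.scatter(x, y, s=marker_area, c=colors, cmap=cmap,
                        edgecolors="black", linewidths=0.5)
        ax.set_yticks(y)
        ax.set_yticklabels([_wrap(d.term_label) for d in data], fontsize=8)
        ax.set_xlabel("genes annotated across all conditions")
        ax.set_xlim(0, max(1.0, x.max()) * 1.1)
        cbar = fig.colorbar(sc, ax=ax, shrink=0.8)
        cbar.set_label("-log10(lowest FDR)" if log_color else "lowest FDR")
        fig.tight_layout()
        return _save(fig, destination, formats)


def cutoff_for_fdr(fdr_threshold: float) -> float:
    """Transformed-scale cutoff equivalent to an FDR threshold (e.g. 1e-5 → 5)."""
    if not 0 < fdr_threshold <= 1:
        raise InputError("FDR threshold must be in (0, 1]")
    return -math.log10(fdr_threshold)
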