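"""Tabular (TSV), plain-text and SVG views of an enumeration.

The matrix layout mirrors the tool's figure convention: one column per
gene (the source order, anchored at a reference gene), one row per
origin showing that origin's displayed labeling.  A cell's glyph says
whether the gene keeps its first copy (F, white circle / ``o``) or its
second copy (S, black circle / ``x``); a box around the glyph marks
membership in the minimal duplicated window.  Row-end markers flag TDRLs
passing the conserved-group filter (``*``), the intergenic filter
(``~``) and the minimum-duplication set (``#``).  All renderers are pure:
identical inputs give byte-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .enumeration import (
    SINGLE_TDRL_CASE,
    EnumerationResult,
)

TSV_COLUMNS = (
    "direction",
    "origin",
    "labeling",
    "F",
    "S",
    "window",
    "window_size",
    "conserved_pass",
    "intergenic_pass",
    "is_min_dup",
)


def _fmt_yes(flag: bool) -> str:
    return "yes" if flag else "no"


def to_tsv(result: EnumerationResult) -> str:
    """Lossless tab-separated table: both labelings of every origin.

    Gene lists are comma-joined in origin-representative order, so every
    enumerated TDRL (triple, window, flags) can be reconstructed exactly.
    """
    buf = io.StringIO()
    buf.write("\t".join(TSV_COLUMNS) + "\n")
    for e in result.entries:
        rep = result.source.representative_starting_at(e.origin)
        f_genes = ",".join(str(g) for g in rep if g in e.tdrl.first)
        s_genes = ",".join(str(g) for g in rep if g in e.tdrl.second)
        window = ",".join(map(str, e.partial.window)) if e.partial else ""
        conserved = ";".join(
            f"{label}={_fmt_yes(ok)}" for label, ok in e.conserved_pass.items()
        )
        intergenic = ";".join(
            f"{label}={_fmt_yes(ok)}" + (f"(z={z})" if z is not None else "")
            for label, (ok, z) in e.intergenic_pass.items()
        )
        buf.write(
            "\t".join(
                (
                    result.direction,
                    str(e.origin),
                    "F-first" if e.labeling in ("direct", "cut") else "S-first",
                    f_genes,
                    s_genes,
                    window,
                    str(e.window_size),
                    conserved,
                    intergenic,
                    _fmt_yes(e.is_min_duplication),
                )
            )
            + "\n"
        )
    return buf.getvalue()


@dataclass(frozen=True)
class MatrixLayout:
    """Row/column skeleton of the figure: genes as columns, origins as rows."""

    columns: tuple  # genes, source order from the reference gene
    rows: tuple  # (origin, entry) pairs, displayed labeling only
    has_conserved: bool
    has_intergenic: bool
    has_min_dup: bool


def build_layout(result: EnumerationResult, reference=None) -> MatrixLayout:
    if result.case != SINGLE_TDRL_CASE:
        raise ValueError(
            "identity case has no single-TDRL matrix; report the 2n^2 count "
            "summary instead"
        )
    if reference is None:
        reference = result.source.canonical[0]
    columns = result.source.representative_starting_at(reference)
    rows = tuple(
        (e.origin, e) for e in result.entries if e.displayed
    )
    # rows follow the column (reference) rotation for visual alignment
    order_idx = {g: i for i, g in enumerate(columns)}
    rows = tuple(sorted(rows, key=lambda r: order_idx[r[0]]))
    some = result.entries[0]
    return MatrixLayout(
        columns=columns,
        rows=rows,
        has_conserved=bool(some.conserved_pass),
        has_intergenic=bool(some.intergenic_pass),
        has_min_dup=any(e.is_min_duplication for e in result.entries),
    )


def render_text(result: EnumerationResult, reference=None) -> str:
    """Diff-friendly character grid of the enumeration."""
    layout = build_layout(result, reference)
    width = max(len(str(g)) for g in layout.columns) + 2
    owidth = max(len(str(o)) for o, _ in layout.rows) + 1
    lines = [
        " " * owidth
        + "".join(str(g).center(width) for g in layout.columns)
    ]
    for origin, e in layout.rows:
        cells = []
        window = set(e.partial.window) if e.partial else set()
        for g in layout.columns:
            glyph = "o" if g in e.tdrl.first else "x"
            cells.append(
                (f"[{glyph}]" if g in window else f" {glyph} ").center(width)
            )
        markers = []
        if layout.has_conserved:
            markers.append("*" if e.passes_all_conserved() else " ")
        if layout.has_intergenic:
            markers.append("~" if e.passes_all_intergenic() else " ")
        if layout.has_min_dup:
            markers.append("#" if e.is_min_duplication else " ")
        lines.append(
            str(origin).rjust(owidth - 1)
            + " "
            + "".join(cells)
            + ("  " + "".join(markers) if markers else "")
        )
    legend = "legend: o = kept in first copy (F), x = kept in second copy (S), [.] = duplicated window"
    if layout.has_conserved or layout.has_intergenic or layout.has_min_dup:
        legend += "; * conserved-groups pass, ~ intergenic pass, # minimum duplication"
    lines.append(legend)
    return "\n".join(lines) + "\n"


CELL = 26  # px per matrix cell


def render_svg(result: EnumerationResult, reference=None) -> str:
    """Standalone SVG figure of the enumeration matrix.

    White circles = F, black circles = S, a square outline boxes the
    genes of the row's minimal duplicated window; star / tilde / diamond
    glyphs to the right mark filter-passing and minimum-duplication rows.
    """
    layout = build_layout(result, reference)
    left = 30 + 8 * max(len(str(o)) for o, _ in layout.rows)
    top = 30 + 7 * max(len(str(g)) for g in layout.columns)
    ncols = len(layout.columns)
    nrows = len(layout.rows)
    nmark = layout.has_conserved + layout.has_intergenic + layout.has_min_dup
    width = left + CELL * ncols + 20 + nmark * 16 + 10
    height = top + CELL * nrows + 20
    out = io.StringIO()
    out.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">\n'
    )
    out.write(
        '<style>text{font-family:monospace;font-size:11px;}</style>\n'
    )
    for ci, g in enumerate(layout.columns):
        x = left + CELL * ci + CELL // 2
        out.write(
            f'<text x="{x}" y="{top - 8}" text-anchor="start" '
            f'transform="rotate(-60 {x} {top - 8})">{g}</text>\n'
        )
    for ri, (origin, e) in enumerate(layout.rows):
        cy = top + CELL * ri + CELL // 2
        out.write(
            f'<text x="{left - 8}" y="{cy + 4}" text-anchor="end">{origin}</text>\n'
        )
        window = set(e.partial.window) if e.partial else set()
        for ci, g in enumerate(layout.columns):
            cx = left + CELL * ci + CELL // 2
            if g in window:
                out.write(
                    f'<rect x="{cx - 11}" y="{cy - 11}" width="22" height="22" '
                    f'fill="none" stroke="black"/>\n'
                )
            fill = "white" if g in e.tdrl.first else "black"
            out.write(
                f'<circle cx="{cx}" cy="{cy}" r="8" fill="{fill}" '
                f'stroke="black"/>\n'
            )
        mx = left + CELL * ncols + 14
        if layout.has_conserved and e.passes_all_conserved():
            out.write(f'<text x="{mx}" y="{cy + 4}">&#9733;</text>\n')  # star
        mx += 16 if layout.has_conserved else 0
        if layout.has_intergenic and e.passes_all_intergenic():
            out.write(f'<text x="{mx}" y="{cy + 4}">&#8764;</text>\n')  # tilde
        mx += 16 if layout.has_intergenic else 0
        if layout.has_min_dup and e.is_min_duplication:
            out.write(f'<text x="{mx}" y="{cy + 4}">&#9670;</text>\n')  # diamond
    out.write("</svg>\n")
    return out.getvalue()
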