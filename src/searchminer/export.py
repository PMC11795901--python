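"""CSV export of analysis tables in two locale dialects.

The default ("western") dialect is the Western European CSV convention:
semicolon value separator, comma decimal separator, CRLF line endings —
what European spreadsheet installations open correctly by default. The
"standard" dialect uses commas and dot decimals. Reals are rendered with 4
decimal places; the z = 10000 / -10000 sentinels are rendered as plain
integers so they remain visually distinct from computed scores.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .analysis import Z_ABSENT, Z_NEG_CLAMP, TermStats
from .context import SkipGramStat
from .errors import DataError


@dataclass(frozen=True)
class ExportDialect:
    field_separator: str = ";"
    decimal_separator: str = ","
    newline: str = "\r\n"
    name: str = "western"

    def __post_init__(self):
        if self.field_separator == self.decimal_separator:
            raise ValueError("field and decimal separators must differ")


WESTERN = ExportDialect()
STANDARD = ExportDialect(
    field_separator=",", decimal_separator=".", newline="\n", name="standard"
)

DIALECTS = {"western": WESTERN, "standard": STANDARD}

HEADER_TERM = "Candidate terms"
HEADER_DOCS = "Documents"
HEADER_PCT = "Documents in %"
HEADER_Z = "Z-Score"
HEADER_TF = "Term frequency"


def format_number(value, dialect: ExportDialect) -> str:
    """Render a cell value: integers plain, reals at 4 decimals."""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if value in (Z_ABSENT, Z_NEG_CLAMP):
            return str(int(value))
        return f"{value:.4f}".replace(".", dialect.decimal_separator)
    return str(value)


def parse_number(cell: str, dialect: ExportDialect) -> float | int | str:
    """Inverse of :func:`format_number` for round-trip checks."""
    normalized = cell.replace(dialect.decimal_separator, ".")
    try:
        if "." in normalized:
            return float(normalized)
        return int(normalized)
    except ValueError:
        return cell


def _rows_to_cells(rows) -> tuple[list[str], list[list]]:
    """Turn any supported table into a header plus cell rows."""
    first = rows[0]
    if isinstance(first, TermStats):
        with_tf = first.term_frequency is not None
        header = [HEADER_TERM, HEADER_DOCS, HEADER_PCT, HEADER_Z]
        if with_tf:
            header.append(HEADER_TF)
        out = []
        for r in rows:
            cells = [r.term, r.documents, r.documents_pct, r.z]
            if with_tf:
                cells.append(r.term_frequency)
            out.append(cells)
        return header, out
    if isinstance(first, SkipGramStat):
        skips = sorted({k for r in rows for k in r.counts_by_skip})
        header = ["First word", "Second word", "Total"] + [
            f"Skip-{k}" for k in skips
        ]
        out = [
            [r.first, r.second, r.total] + [r.counts_by_skip.get(k, 0) for k in skips]
            for r in rows
        ]
        return header, out
    if isinstance(first, tuple) and len(first) == 2:
        return ["Keyword", "Frequency"], [list(r) for r in rows]
    raise TypeError(f"cannot export rows of type {type(first).__name__}")


def render_table(rows, dialect: ExportDialect = WESTERN) -> str:
    """Render a table to CSV text in the given dialect."""
    if not rows:
        raise DataError("refusing to export an empty table")
    header, cell_rows = _rows_to_cells(rows)
    buf = io.StringIO()
    writer = csv.writer(
        buf,
        delimiter=dialect.field_separator,
        lineterminator=dialect.newline,
        quoting=csv.QUOTE_MINIMAL,
    )
    writer.writerow(header)
    for cells in cell_rows:
        writer.writerow([format_number(c, dialect) for c in cells])
    return buf.getvalue()


def export_table(rows, dialect: ExportDialect = WESTERN, path=None) -> str:
    """Write a table as CSV to *path* (or just return the text)."""
    text = render_table(rows, dialect)
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


def read_table(text: str, dialect: ExportDialect = WESTERN):
    """Parse exported CSV back into (header, rows-of-parsed-values)."""
    reader = csv.reader(io.StringIO(text), delimiter=dialect.field_separator)
    rows = [row for row in reader if row]
    if not rows:
        raise DataError("empty CSV")
    header, data = rows[0], rows[1:]
    parsed = [
        [cell if i == 0 else parse_number(cell, dialect) for i, cell in enumerate(row)]
        for row in data
    ]
    return header, parsed
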