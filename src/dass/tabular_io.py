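"""Reading and writing the user-facing tabular formats.

Supported formats: RFC-4180-style CSV, tab-delimited text (no quoting
dialect — a tab can never occur inside a TSV cell), and XLSX (first
worksheet only). All cells are kept as text at this layer so that
validation sees the user's literal input.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path

from .errors import ConfigError, EmptyTableError, TableReadError
from .types import TEMPLATE_HEADER, ColumnMap, EndpointKey, RawTable

_EXT_FORMATS = {".tsv": "tsv", ".txt": "tsv", ".tab": "tsv", ".csv": "csv", ".xlsx": "xlsx"}


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower()
        if fmt not in {"tsv", "csv", "xlsx"}:
            raise ConfigError(f"unknown table format {format_hint!r} (expected tsv, csv or xlsx)")
        return fmt
    fmt = _EXT_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ConfigError(
            f"cannot infer table format from {path.name!r}; pass format_hint='tsv'|'csv'|'xlsx'"
        )
    return fmt


def _render_xlsx_value(value: object) -> str:
    """Render a spreadsheet cell to the text a user would see."""
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


def _read_text(path: Path) -> str:
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise TableReadError(f"cannot read {path}: {exc}") from exc
    try:
        return raw.decode("utf-8-sig")
    except UnicodeDecodeError as exc:
        line = raw[: exc.start].count(b"\n") + 1
        raise TableReadError(f"{path}: undecodable bytes on line {line}") from exc


def _normalize_grid(grid: list[list[str]], source_format: str) -> RawTable:
    # drop rows that are entirely empty (trailing blank lines etc.)
    grid = [row for row in grid if any(cell.strip() for cell in row)]
    if not grid:
        raise EmptyTableError("empty table: no header row found")
    header = [cell.strip() for cell in grid[0]]
    notes: list[str] = []
    rows: list[list[str]] = []
    width = len(header)
    for i, row in enumerate(grid[1:]):
        if len(row) < width:
            notes.append(f"row {i + 1}: padded from {len(row)} to {width} cells")
            row = row + [""] * (width - len(row))
        elif len(row) > width:
            notes.append(f"row {i + 1}: truncated from {len(row)} to {width} cells")
            row = row[:width]
        rows.append(row)
    return RawTable(header=header, rows=rows, source_format=source_format, notes=notes)


def read_table(path: str | Path, format_hint: str | None = None) -> RawTable:
    """Read a TSV/CSV/XLSX file into a RawTable of text cells.

    The first row is the header (whitespace-trimmed); short data rows are
    padded with empty cells, over-long rows truncated, both recorded in
    ``table.notes``. For spreadsheets only the first worksheet is read and
    every cell is rendered to its displayed text.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "xlsx":
        try:
            from openpyxl import load_workbook

            wb = load_workbook(path, read_only=True, data_only=True)
        except OSError as exc:
            raise TableReadError(f"cannot read {path}: {exc}") from exc
        ws = wb.worksheets[0]
        grid = [[_render_xlsx_value(v) for v in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
    elif fmt == "csv":
        text = _read_text(path)
        grid = [list(row) for row in csv.reader(io.StringIO(text))]
    else:  # tsv: plain tab splitting, no quoting dialect
        text = _read_text(path)
        grid = [line.split("\t") for line in text.splitlines()]
    return _normalize_grid(grid, fmt)


def template_table() -> RawTable:
    """The canonical empty-bodied data template (one column per endpoint)."""
    return RawTable(header=list(TEMPLATE_HEADER), rows=[], source_format="tsv")


def _norm_header(name: str) -> str:
    """Case-insensitive matching key: spaces, hyphens and underscores are equivalent."""
    return name.strip().lower().replace(" ", "").replace("-", "").replace("_", "")


def auto_map_columns(table: RawTable) -> ColumnMap:
    """Bind every endpoint whose canonical name matches a header name.

    Matching is case-insensitive and ignores space/hyphen/underscore
    differences. If several headers match one endpoint the leftmost is bound
    and a duplicate-candidate note is attached; unmatched endpoints stay
    unbound (not an error at this stage).
    """
    cmap = ColumnMap(header=tuple(table.header))
    normed = [_norm_header(h) for h in table.header]
    for key in EndpointKey:
        target = _norm_header(key.value)
        hits = [i for i, h in enumerate(normed) if h == target]
        if hits:
            cmap.bindings[key] = hits[0]
            if len(hits) > 1:
                others = ", ".join(repr(table.header[i]) for i in hits[1:])
                cmap.notes.append(
                    f"{key.value}: bound to leftmost of several matching headers; also matched {others}"
                )
    return cmap


def write_table(table: RawTable, path: str | Path, format: str | None = None) -> None:
    """Write a RawTable to TSV, CSV or XLSX (format inferred from suffix).

    In TSV output any tab inside a cell is replaced by a space (tabs are
    delimiters in this dialect); validation flags such cells beforehand.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    grid = [table.header] + table.rows
    if fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "data"
        for row in grid:
            ws.append(list(row))
        wb.save(path)
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh, lineterminator="\n").writerows(grid)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in grid:
                fh.write("\t".join(cell.replace("\t", " ") for cell in row) + "\n")


def write_results(results, path: str | Path, format: str | None = None) -> None:
    """Write an AnnotatedResults table to TSV or XLSX.

    The column-role legend (input / calculated / prediction / flags) is
    encoded in the column-name prefixes; XLSX output additionally gets a
    ``legend`` worksheet with one (column, role) row per column.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        raise ConfigError("results are written as TSV or XLSX")
    table = results.to_raw_table()
    if fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "results"
        ws.append(list(table.header))
        for row in table.rows:
            ws.append(list(row))
        legend = wb.create_sheet("legend")
        legend.append(["column", "role"])
        for col, role in results.legend.items():
            legend.append([col, role])
        wb.save(path)
    else:
        write_table(table, path, "tsv")
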