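"""Validation of user-selected columns against the DA data requirements.

All problems are returned as machine-readable :class:`ValidationFlag`
objects, never raised: the caller decides what to do with them. ERROR flags
block prediction only for the (chemical, DA) pairs whose inputs they
corrupt; WARNING flags are informational.
"""

from __future__ import annotations

from .constants import (
    DA_MIN_SOURCES,
    DA_SOURCE_REQUIREMENTS,
    DEPLETION_RANGE,
    DOMAIN_IN_TOKENS,
    DOMAIN_OUT_TOKENS,
    MISSING_TOKENS,
    MIT_NEGATIVE_TOKENS,
    MIT_RANGE,
    NEGATIVE_TOKENS,
    POSITIVE_TOKENS,
    POTENCY_TOKENS,
)
from .types import DA, ColumnMap, EndpointKey, FlagCode, RawTable, Severity, ValidationFlag

_NUMERIC_KEYS = {EndpointKey.DPRA_CYS_PCT, EndpointKey.DPRA_LYS_PCT}
_CALL_KEYS = {
    EndpointKey.DPRA_CALL,
    EndpointKey.HCLAT_CALL,
    EndpointKey.KS_CALL,
    EndpointKey.INSILICO_CALL,
    EndpointKey.REFERENCE_HAZARD,
}


def check_bindings(cmap: ColumnMap, selected_das: set[DA] | list[DA]) -> list[ValidationFlag]:
    """Column-level checks: duplicate bindings and per-DA completeness.

    A source requirement is satisfied if any one of its alternative endpoint
    sets is fully bound; for the ITS, at least two of its three sources must
    be bound (the two-source tables cover the rest).
    """
    flags: list[ValidationFlag] = []
    by_col: dict[int, list[EndpointKey]] = {}
    for key, idx in cmap.bindings.items():
        by_col.setdefault(idx, []).append(key)
    for idx in sorted(by_col):
        keys = by_col[idx]
        if len(keys) > 1:
            names = ", ".join(sorted(k.value for k in keys))
            col = cmap.header[idx] if idx < len(cmap.header) else f"column {idx}"
            flags.append(
                ValidationFlag(
                    endpoint=None,
                    column_name=col,
                    row_index=None,
                    code=FlagCode.DUPLICATE_BINDING,
                    severity=Severity.ERROR,
                    message=f"column {col!r} is bound to more than one endpoint: {names}",
                )
            )

    for da in sorted(selected_das, key=lambda d: d.value):
        requirements = DA_SOURCE_REQUIREMENTS[da]
        satisfied = {
            source: any(all(cmap.bound(k) for k in alt) for alt in alternatives)
            for source, alternatives in requirements.items()
        }
        n_needed = DA_MIN_SOURCES[da]
        if da is DA.ITS:
            if sum(satisfied.values()) >= n_needed:
                continue
            missing = [s for s, ok in satisfied.items() if not ok]
        else:
            missing = [s for s, ok in satisfied.items() if not ok]
        for source in missing:
            alts = " or ".join(
                "+".join(k.value for k in sorted(alt, key=lambda k: k.value))
                for alt in requirements[source]
            )
            flags.append(
                ValidationFlag(
                    endpoint=sorted(requirements[source][0], key=lambda k: k.value)[0],
                    column_name="",
                    row_index=None,
                    code=FlagCode.MISSING_REQUIRED_COLUMN,
                    severity=Severity.ERROR,
                    message=f"{da.value}: no column bound for the {source} source (needs {alts})",
                    da=da,
                )
            )
    return flags


def _is_missing(token: str) -> bool:
    return token in MISSING_TOKENS


def check_values(table: RawTable, cmap: ColumnMap) -> list[ValidationFlag]:
    """Per-cell checks of every bound column.

    Numeric endpoints must parse as decimal numbers (the h-CLAT MIT also
    accepts a negative-outcome token); call endpoints must be in the call
    lexicon. Depletions outside [−100, 100] % and MITs outside (0, 5000]
    µg/mL draw OUT_OF_RANGE warnings; empty cells draw EMPTY_CELL warnings
    and are treated as missing downstream. Ordering is deterministic: by
    column index, then row index.
    """
    flags: list[ValidationFlag] = []
    for key, col in sorted(cmap.bindings.items(), key=lambda kv: (kv[1], kv[0].value)):
        col_name = cmap.header[col] if col < len(cmap.header) else f"column {col}"
        for i, row in enumerate(table.rows):
            cell = row[col] if col < len(row) else ""
            if "\t" in cell:
                flags.append(
                    ValidationFlag(key, col_name, i, FlagCode.TAB_IN_CELL, Severity.WARNING,
                                   "cell contains a tab character; it will not survive TSV output")
                )
            token = cell.strip().lower()
            if key is EndpointKey.CHEM_ID:
                continue
            if _is_missing(token):
                flags.append(
                    ValidationFlag(key, col_name, i, FlagCode.EMPTY_CELL, Severity.WARNING,
                                   "empty cell; value treated as missing")
                )
                continue
            if key in _NUMERIC_KEYS:
                flags.extend(_check_numeric(key, col_name, i, cell, DEPLETION_RANGE, low_inclusive=True))
            elif key is EndpointKey.HCLAT_MIT:
                if token in MIT_NEGATIVE_TOKENS:
                    continue
                flags.extend(_check_numeric(key, col_name, i, cell, MIT_RANGE, low_inclusive=False))
            elif key in _CALL_KEYS:
                if token not in POSITIVE_TOKENS and token not in NEGATIVE_TOKENS:
                    flags.append(_bad_token(key, col_name, i, cell))
            elif key is EndpointKey.INSILICO_DOMAIN:
                if token not in DOMAIN_IN_TOKENS and token not in DOMAIN_OUT_TOKENS:
                    flags.append(_bad_token(key, col_name, i, cell))
            elif key is EndpointKey.REFERENCE_POTENCY:
                if token not in POTENCY_TOKENS:
                    flags.append(_bad_token(key, col_name, i, cell))
    return flags


def _bad_token(key: EndpointKey, col_name: str, row: int, cell: str) -> ValidationFlag:
    return ValidationFlag(key, col_name, row, FlagCode.UNRECOGNIZED_CALL_TOKEN, Severity.ERROR,
                          f"unrecognized token {cell.strip()!r}")


def _check_numeric(key, col_name, row, cell, value_range, low_inclusive) -> list[ValidationFlag]:
    try:
        value = float(cell.strip())
    except ValueError:
        return [ValidationFlag(key, col_name, row, FlagCode.NON_NUMERIC, Severity.ERROR,
                               f"{cell.strip()!r} is not a decimal number")]
    low, high = value_range
    in_range = (value >= low if low_inclusive else value > low) and value <= high
    if not in_range:
        bracket = "[" if low_inclusive else "("
        return [ValidationFlag(key, col_name, row, FlagCode.OUT_OF_RANGE, Severity.WARNING,
                               f"{value:g} outside plausible range {bracket}{low:g}, {high:g}]")]
    return []


def sort_flags(flags: list[ValidationFlag], cmap: ColumnMap) -> list[ValidationFlag]:
    """Stable canonical ordering: column-level flags first, then by (column, row)."""
    def key(f: ValidationFlag):
        col = cmap.bindings.get(f.endpoint, -1) if f.endpoint else -1
        return (f.row_index is not None, col, f.row_index if f.row_index is not None else -1,
                f.code.value)

    return sorted(flags, key=key)
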