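"""Translation of validated raw cells into standardized calls and numbers.

This layer produces the "calculated input" the DA engine consumes: parsed
calls, the mean DPRA depletion, calls derived from quantitative endpoints
via the published prediction models, and the effective h-CLAT MIT. Cells
carrying ERROR flags are treated as missing here; the block they cause is
applied per (chemical, DA) by the DA engine.

Precedence rule: when a user-supplied call column and a call derived from
the quantitative endpoints are both available and disagree, the derived
call wins and a CALL_CONFLICT warning is recorded — the quantitative
endpoints are the DAs' primary inputs.
"""

from __future__ import annotations

from .constants import (
    DOMAIN_IN_TOKENS,
    DOMAIN_OUT_TOKENS,
    DPRA_CYS_ONLY_NEGATIVE_MAX,
    DPRA_MEAN_NEGATIVE_MAX,
    HCLAT_MAX_TEST_CONC,
    MISSING_TOKENS,
    MIT_NEGATIVE_TOKENS,
    NEGATIVE_TOKENS,
    POSITIVE_TOKENS,
    POTENCY_TOKENS,
)
from .types import (
    NEGATIVE_MIT,
    Call,
    ChemicalRecord,
    ColumnMap,
    EndpointKey,
    FlagCode,
    PotencyClass,
    RawTable,
    Severity,
    ValidationFlag,
)


def parse_call(raw: str) -> Call:
    """Parse a binary-call cell through the case-insensitive call lexicon."""
    token = raw.strip().lower()
    if token in MISSING_TOKENS:
        return Call.MISSING
    if token in POSITIVE_TOKENS:
        return Call.POSITIVE
    if token in NEGATIVE_TOKENS:
        return Call.NEGATIVE
    return Call.MISSING  # unrecognized tokens are flagged upstream and blocked


def parse_mit(raw: str):
    """Parse an h-CLAT MIT cell: numeric µg/mL, NEGATIVE_MIT, or None."""
    token = raw.strip().lower()
    if token in MISSING_TOKENS:
        return None
    if token in MIT_NEGATIVE_TOKENS:
        return NEGATIVE_MIT
    try:
        return float(token)
    except ValueError:
        return None  # flagged upstream as NON_NUMERIC


def parse_domain(raw: str) -> bool | None:
    token = raw.strip().lower()
    if token in DOMAIN_IN_TOKENS:
        return True
    if token in DOMAIN_OUT_TOKENS:
        return False
    return None


def parse_potency(raw: str) -> PotencyClass | None:
    token = raw.strip().lower()
    label = POTENCY_TOKENS.get(token)
    return PotencyClass(label) if label else None


def dpra_mean(cys_pct: float, lys_pct: float) -> float:
    """Arithmetic mean of %Cys and %Lys depletion; negative inputs participate unmodified."""
    return (cys_pct + lys_pct) / 2.0


def derive_dpra_call(cys_pct: float | None, lys_pct: float | None) -> Call:
    """DPRA hazard call from quantitative depletions (prediction models of TG 442C).

    Both values: negative iff mean ≤ 6.38 %. %Cys alone: negative iff
    ≤ 13.89 %. %Lys alone has no published model → MISSING.
    """
    if cys_pct is not None and lys_pct is not None:
        return Call.NEGATIVE if dpra_mean(cys_pct, lys_pct) <= DPRA_MEAN_NEGATIVE_MAX else Call.POSITIVE
    if cys_pct is not None:
        return Call.NEGATIVE if cys_pct <= DPRA_CYS_ONLY_NEGATIVE_MAX else Call.POSITIVE
    return Call.MISSING


def effective_mit(mit):
    """Map a parsed MIT onto the value the rules consume.

    Numeric in (0, 5000] stays numeric; above the 5000 µg/mL maximum test
    concentration the outcome is negative by definition; a non-positive
    number is physically impossible and unusable (None).
    """
    if mit is None or mit is NEGATIVE_MIT:
        return mit
    if mit <= 0:
        return None
    if mit > HCLAT_MAX_TEST_CONC:
        return NEGATIVE_MIT
    return mit


def derive_hclat_call(mit) -> Call:
    """h-CLAT call from the effective MIT: numeric → positive, negative marker → negative."""
    mit = effective_mit(mit)
    if mit is NEGATIVE_MIT:
        return Call.NEGATIVE
    if mit is None:
        return Call.MISSING
    return Call.POSITIVE


def _resolve_call(derived: Call, user: Call, key: EndpointKey, cmap: ColumnMap,
                  row: int, flags: list[ValidationFlag]) -> Call:
    if derived is Call.MISSING:
        return user
    if user is not Call.MISSING and user is not derived:
        flags.append(ValidationFlag(
            endpoint=key,
            column_name=cmap.column_name(key),
            row_index=row,
            code=FlagCode.CALL_CONFLICT,
            severity=Severity.WARNING,
            message=(f"user-supplied call {user.value!r} disagrees with the call derived "
                     f"from quantitative data ({derived.value!r}); derived call used"),
        ))
    return derived


def harmonize(table: RawTable, cmap: ColumnMap,
              flags: list[ValidationFlag]) -> list[ChemicalRecord]:
    """Build one ChemicalRecord per row from validated cells.

    ``flags`` is the list produced by validation; cells carrying ERROR flags
    become missing in the record, and any user-vs-derived call conflicts
    found here are appended to it as warnings (the list is mutated).
    """
    errored: set[tuple[int, EndpointKey]] = {
        (f.row_index, f.endpoint)
        for f in flags
        if f.severity is Severity.ERROR and f.row_index is not None and f.endpoint is not None
    }

    def cell(row_idx: int, key: EndpointKey) -> str:
        col = cmap.column_index(key)
        if col is None or (row_idx, key) in errored:
            return ""
        row = table.rows[row_idx]
        return row[col] if col < len(row) else ""

    def number(row_idx: int, key: EndpointKey) -> float | None:
        token = cell(row_idx, key).strip().lower()
        if token in MISSING_TOKENS:
            return None
        try:
            return float(token)
        except ValueError:
            return None

    records: list[ChemicalRecord] = []
    for i in range(table.n_rows):
        chem_id = cell(i, EndpointKey.CHEM_ID).strip() or f"row{i + 1}"
        cys = number(i, EndpointKey.DPRA_CYS_PCT)
        lys = number(i, EndpointKey.DPRA_LYS_PCT)
        mean = dpra_mean(cys, lys) if cys is not None and lys is not None else None
        dpra = _resolve_call(derive_dpra_call(cys, lys),
                             parse_call(cell(i, EndpointKey.DPRA_CALL)),
                             EndpointKey.DPRA_CALL, cmap, i, flags)
        mit = effective_mit(parse_mit(cell(i, EndpointKey.HCLAT_MIT)))
        hclat = _resolve_call(derive_hclat_call(mit),
                              parse_call(cell(i, EndpointKey.HCLAT_CALL)),
                              EndpointKey.HCLAT_CALL, cmap, i, flags)
        records.append(ChemicalRecord(
            row_index=i,
            chem_id=chem_id,
            cys_pct=cys,
            lys_pct=lys,
            dpra_mean_pct=mean,
            dpra_call=dpra,
            hclat_mit=mit,
            hclat_call=hclat,
            ks_call=parse_call(cell(i, EndpointKey.KS_CALL)),
            insilico_call=parse_call(cell(i, EndpointKey.INSILICO_CALL)),
            insilico_in_domain=parse_domain(cell(i, EndpointKey.INSILICO_DOMAIN)),
            ref_hazard=parse_call(cell(i, EndpointKey.REFERENCE_HAZARD)),
            ref_potency=parse_potency(cell(i, EndpointKey.REFERENCE_POTENCY)),
        ))
    return records
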