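"""The three data-interpretation procedures: 2o3, KE 3/1 STS, and ITS.

Each procedure is a total function on its harmonized inputs; every outcome
carries a plain-text rationale tracing the rule path taken. ``run_dass``
applies the selected procedures to a batch of records and assembles the
annotated output table, withholding (blocking) a prediction only for the
(chemical, DA) pairs whose inputs an ERROR flag actually deprived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    DA_SOURCE_ENDPOINTS,
    ITS_DPRA_CYS_BANDS,
    ITS_DPRA_MEAN_BANDS,
    ITS_HCLAT_MIT_BANDS,
    ITS_POTENCY_2SOURCE,
    ITS_POTENCY_3SOURCE,
    STS_MIT_STRONG_MAX,
    rulebook_checksum,
)
from .harmonization import dpra_mean, effective_mit, harmonize
from .types import (
    DA,
    NEGATIVE_MIT,
    Blocked,
    Call,
    ChemicalRecord,
    ColumnMap,
    DAPrediction,
    EndpointKey,
    FlagCode,
    Hazard,
    ITSScheme,
    ITSScores,
    PotencyClass,
    RawTable,
    Severity,
    ValidationFlag,
)

_POTENCY_TO_HAZARD = {
    PotencyClass.GHS_1A: Hazard.SENSITIZER,
    PotencyClass.GHS_1B: Hazard.SENSITIZER,
    PotencyClass.ONE_STAR: Hazard.SENSITIZER,
    PotencyClass.NC: Hazard.NON_SENSITIZER,
    PotencyClass.INCONCLUSIVE: Hazard.INCONCLUSIVE,
}


def predict_2o3(dpra: Call, hclat: Call, ks: Call) -> DAPrediction:
    """Two-out-of-three: hazard by concordance of at least two assay calls.

    The result is independent of assay order. With three available calls a
    2–1 split resolves to the majority; with exactly two available and
    discordant calls, or fewer than two available, the chemical cannot be
    classified. 2o3 never predicts potency.
    """
    calls = (dpra, hclat, ks)
    n_pos = sum(c is Call.POSITIVE for c in calls)
    n_neg = sum(c is Call.NEGATIVE for c in calls)
    available = n_pos + n_neg
    if n_pos >= 2:
        hazard, why = Hazard.SENSITIZER, f"{n_pos} of {available} available calls positive"
    elif n_neg >= 2:
        hazard, why = Hazard.NON_SENSITIZER, f"{n_neg} of {available} available calls negative"
    elif available <= 1:
        hazard, why = Hazard.INCONCLUSIVE, "insufficient sources"
    else:
        hazard, why = Hazard.INCONCLUSIVE, "two available calls are discordant"
    return DAPrediction(DA.TWO_OF_THREE, hazard, PotencyClass.NOT_APPLICABLE,
                        rationale=f"2o3: {why}")


def predict_sts(hclat_mit, dpra: Call, hclat_call: Call = Call.MISSING) -> DAPrediction:
    """KE 3/1 sequential testing strategy: h-CLAT first, DPRA second.

    A positive h-CLAT settles the outcome (MIT ≤ 10 µg/mL → 1A, else 1B)
    with no further testing; a negative h-CLAT defers to the DPRA (positive
    → 1B, negative → NC). Without any h-CLAT result the sequence cannot
    start. A positive h-CLAT *call* without a numeric MIT gives a conclusive
    sensitizer hazard but unresolved potency.
    """
    mit = effective_mit(hclat_mit)
    if isinstance(mit, (int, float)):
        if mit <= STS_MIT_STRONG_MAX:
            pot, why = PotencyClass.GHS_1A, f"MIT {mit:g} ≤ {STS_MIT_STRONG_MAX:g} µg/mL"
        else:
            pot, why = PotencyClass.GHS_1B, f"MIT {mit:g} > {STS_MIT_STRONG_MAX:g} µg/mL"
        return DAPrediction(DA.KE31STS, Hazard.SENSITIZER, pot,
                            rationale=f"STS: h-CLAT positive ({why}); no further testing required")
    if mit is NEGATIVE_MIT or (mit is None and hclat_call is Call.NEGATIVE):
        if dpra is Call.POSITIVE:
            return DAPrediction(DA.KE31STS, Hazard.SENSITIZER, PotencyClass.GHS_1B,
                                rationale="STS: h-CLAT negative, DPRA positive")
        if dpra is Call.NEGATIVE:
            return DAPrediction(DA.KE31STS, Hazard.NON_SENSITIZER, PotencyClass.NC,
                                rationale="STS: h-CLAT negative, DPRA negative")
        return DAPrediction(DA.KE31STS, Hazard.INCONCLUSIVE, PotencyClass.INCONCLUSIVE,
                            rationale="STS: h-CLAT negative, DPRA unavailable")
    if mit is None and hclat_call is Call.POSITIVE:
        return DAPrediction(DA.KE31STS, Hazard.SENSITIZER, PotencyClass.INCONCLUSIVE,
                            rationale="STS: h-CLAT positive call without MIT; potency unresolved")
    return DAPrediction(DA.KE31STS, Hazard.INCONCLUSIVE, PotencyClass.INCONCLUSIVE,
                        rationale="STS: h-CLAT unavailable; sequence cannot start")


def score_its_hclat(hclat_mit) -> int | None:
    """ITS h-CLAT score: negative → 0; MIT banded 3/2/1 (lower MIT → higher score)."""
    mit = hclat_mit
    if mit is NEGATIVE_MIT:
        return 0
    if mit is None:
        return None
    if mit <= 0:
        raise ValueError("MIT must be positive (flagged upstream as OUT_OF_RANGE)")
    for edge, score in ITS_HCLAT_MIT_BANDS:
        if mit <= edge:
            return score
    return 0  # beyond the maximum test concentration: negative outcome


def score_its_dpra(cys_pct: float | None, lys_pct: float | None) -> tuple[int | None, ITSScheme]:
    """ITS DPRA score with the conditional scheme for %Cys-only data."""
    if cys_pct is not None and lys_pct is not None:
        mean = dpra_mean(cys_pct, lys_pct)
        return _band_geq(mean, ITS_DPRA_MEAN_BANDS), ITSScheme.TWO_VALUE_DPRA
    if cys_pct is not None:
        return _band_geq(cys_pct, ITS_DPRA_CYS_BANDS), ITSScheme.CYS_ONLY_DPRA
    return None, ITSScheme.NO_DPRA


def _band_geq(value: float, bands: tuple[tuple[float, int], ...]) -> int:
    for edge, score in bands:
        if value >= edge:
            return score
    return 0


def score_its_insilico(call: Call, in_domain: bool | None) -> int | None:
    """ITS in silico score: 1/0 within the applicability domain, unusable outside.

    An unstated domain is taken as in-domain (the user supplied the
    prediction without a domain column).
    """
    if in_domain is False:
        return None
    if call is Call.POSITIVE:
        return 1
    if call is Call.NEGATIVE:
        return 0
    return None


def its_scores(record: ChemicalRecord) -> ITSScores:
    """Component ITS scores for one harmonized record."""
    dpra, scheme = score_its_dpra(record.cys_pct, record.lys_pct)
    return ITSScores(
        dpra_score=dpra,
        hclat_score=score_its_hclat(record.hclat_mit),
        insilico_score=score_its_insilico(record.insilico_call, record.insilico_in_domain),
        scheme=scheme,
    )


def predict_its(scores: ITSScores) -> DAPrediction:
    """ITS: summed component scores looked up in the classification tables.

    With all three sources the total (0–7) maps 6–7 → 1A, 2–5 → 1B,
    0–1 → NC. With two sources the table for the specific missing source
    applies; its cells include "1*" (sensitizer, potency unresolved) and
    "Inconclusive". Fewer than two sources → inconclusive.
    """
    if scores.available < 2:
        return DAPrediction(DA.ITS, Hazard.INCONCLUSIVE, PotencyClass.INCONCLUSIVE,
                            its_total=None, its_source_count=scores.available,
                            rationale="ITS: insufficient sources")
    total = scores.total
    if scores.available == 3:
        label = ITS_POTENCY_3SOURCE[total]
        table_name = "3-source"
    else:
        if scores.dpra_score is None:
            key = "dpra_missing"
        elif scores.hclat_score is None:
            key = "hclat_missing"
        else:
            key = "insilico_missing"
        label = ITS_POTENCY_2SOURCE[key][total]
        table_name = f"2-source ({key.replace('_', ' ')})"
    potency = PotencyClass(label)
    hazard = _POTENCY_TO_HAZARD[potency]
    return DAPrediction(DA.ITS, hazard, potency, its_total=total,
                        its_source_count=scores.available,
                        rationale=f"ITS: total {total} in {table_name} table → {label}")


# --------------------------------------------------------------------------
# Batch execution


@dataclass
class AnnotatedResults:
    """Input columns, calculated intermediates, per-DA predictions and flags.

    ``legend`` maps every output column to its role (input / calculated /
    prediction / flags); the roles are also encoded in the ``calc_`` and
    ``pred_`` column-name prefixes.
    """

    header: list[str]
    rows: list[list[str]]
    legend: dict[str, str]
    das: list[DA]
    flags: list[ValidationFlag]
    predictions: list[dict[DA, DAPrediction | Blocked]]
    records: list[ChemicalRecord]
    constants_checksum: str = field(default_factory=rulebook_checksum)

    def to_raw_table(self) -> RawTable:
        return RawTable(header=list(self.header), rows=[list(r) for r in self.rows],
                        source_format="tsv")


def _fmt_num(value: float | None) -> str:
    return "" if value is None else format(value, ".6g")


def _fmt_mit(mit) -> str:
    if mit is NEGATIVE_MIT:
        return "Negative"
    return _fmt_num(mit)


def _fmt_call(call: Call) -> str:
    return "" if call is Call.MISSING else call.value


def _row_error_endpoints(flags: list[ValidationFlag], row: int) -> set[EndpointKey]:
    return {f.endpoint for f in flags
            if f.severity is Severity.ERROR and f.endpoint is not None
            and (f.row_index == row or f.row_index is None)}


def _source_resolved(da: DA, source: str, record: ChemicalRecord, scores: ITSScores | None) -> bool:
    if da is DA.ITS:
        value = {"DPRA": scores.dpra_score, "h-CLAT": scores.hclat_score,
                 "in silico": scores.insilico_score}[source]
        return value is not None
    if source == "DPRA":
        return record.dpra_call is not Call.MISSING
    if source == "h-CLAT":
        return record.hclat_mit is not None or record.hclat_call is not Call.MISSING
    return record.ks_call is not Call.MISSING


def _blocked_for(da: DA, record: ChemicalRecord, scores: ITSScores | None,
                 error_endpoints: set[EndpointKey], cmap: ColumnMap) -> Blocked | None:
    """A DA is blocked when a source it consults is unresolved *because of* an ERROR.

    For the STS a positive h-CLAT settles the outcome, so a corrupted DPRA
    cell does not block the pair ("no further testing required").
    """
    bound = set(cmap.bindings)
    dupes = cmap.duplicated_endpoints()
    reasons: list[str] = []
    for source, endpoints in DA_SOURCE_ENDPOINTS[da].items():
        if da is DA.KE31STS and source == "DPRA":
            mit = record.hclat_mit
            if isinstance(mit, (int, float)):
                continue  # DPRA never consulted
        tainted = (endpoints & error_endpoints & bound) | (endpoints & dupes)
        if tainted and not _source_resolved(da, source, record, scores):
            names = ", ".join(sorted(k.value for k in tainted))
            reasons.append(f"{source} unavailable due to ERROR-flagged input ({names})")
    if reasons:
        return Blocked(da, tuple(reasons))
    return None


def run_dass(records: list[ChemicalRecord], selected_das: set[DA] | list[DA],
             cmap: ColumnMap, flags: list[ValidationFlag],
             table: RawTable | None = None) -> AnnotatedResults:
    """Apply the selected DAs to every record and assemble the output table.

    Output columns: the input columns verbatim (when ``table`` is given),
    ``calc_`` intermediates (plus ITS score columns when the ITS is
    selected), one ``pred_<da>_hazard`` / ``pred_<da>_potency`` pair per
    executed DA, and a flag-summary column.
    """
    das = [da for da in (DA.TWO_OF_THREE, DA.KE31STS, DA.ITS) if da in set(selected_das)]
    if not das:
        raise ValueError("selected_das must be non-empty")
    da_missing_cols: dict[DA, list[ValidationFlag]] = {}
    for f in flags:
        if f.code is FlagCode.MISSING_REQUIRED_COLUMN and f.da is not None:
            da_missing_cols.setdefault(f.da, []).append(f)

    predictions: list[dict[DA, DAPrediction | Blocked]] = []
    all_scores: list[ITSScores] = []
    for record in records:
        errs = _row_error_endpoints(flags, record.row_index)
        scores = its_scores(record)
        all_scores.append(scores)
        row_pred: dict[DA, DAPrediction | Blocked] = {}
        for da in das:
            if da in da_missing_cols:
                row_pred[da] = Blocked(da, tuple(f.message for f in da_missing_cols[da]))
                continue
            blocked = _blocked_for(da, record, scores, errs, cmap)
            if blocked is not None:
                row_pred[da] = blocked
            elif da is DA.TWO_OF_THREE:
                row_pred[da] = predict_2o3(record.dpra_call, record.hclat_call, record.ks_call)
            elif da is DA.KE31STS:
                row_pred[da] = predict_sts(record.hclat_mit, record.dpra_call, record.hclat_call)
            else:
                row_pred[da] = predict_its(scores)
        predictions.append(row_pred)

    # ---- assemble the annotated table
    header: list[str] = []
    legend: dict[str, str] = {}
    if table is not None:
        header.extend(table.header)
        legend.update({h: "input" for h in table.header})
    else:
        header.append("chem_id")
        legend["chem_id"] = "input"
    calc_cols = ["calc_dpra_mean", "calc_dpra_call", "calc_hclat_call"]
    if DA.ITS in das:
        calc_cols += ["calc_its_dpra_score", "calc_its_hclat_score",
                      "calc_its_insilico_score", "calc_its_total", "calc_its_scheme"]
    header.extend(calc_cols)
    legend.update({c: "calculated" for c in calc_cols})
    for da in das:
        for col in (f"pred_{da.value}_hazard", f"pred_{da.value}_potency"):
            header.append(col)
            legend[col] = "prediction"
    header.append("flags")
    legend["flags"] = "flags"

    flags_by_row: dict[int, list[ValidationFlag]] = {}
    for f in flags:
        if f.row_index is not None:
            flags_by_row.setdefault(f.row_index, []).append(f)

    rows: list[list[str]] = []
    for record, scores, row_pred in zip(records, all_scores, predictions):
        i = record.row_index
        out: list[str] = []
        if table is not None:
            src = table.rows[i]
            out.extend(src[c] if c < len(src) else "" for c in range(len(table.header)))
        else:
            out.append(record.chem_id)
        out.append(_fmt_num(record.dpra_mean_pct))
        out.append(_fmt_call(record.dpra_call))
        out.append(_fmt_call(record.hclat_call))
        if DA.ITS in das:
            its = row_pred.get(DA.ITS)
            out.append("" if scores.dpra_score is None else str(scores.dpra_score))
            out.append("" if scores.hclat_score is None else str(scores.hclat_score))
            out.append("" if scores.insilico_score is None else str(scores.insilico_score))
            total = its.its_total if isinstance(its, DAPrediction) else None
            out.append("" if total is None else str(total))
            out.append(scores.scheme.value)
        for da in das:
            pred = row_pred[da]
            if isinstance(pred, Blocked):
                out.extend(["Blocked", "Blocked"])
            else:
                out.extend([pred.hazard.value, pred.potency.value])
        summary = "; ".join(
            f"{f.code.value}:{f.column_name}"
            for f in sorted(flags_by_row.get(i, []),
                            key=lambda f: (f.column_name, f.code.value))
        )
        out.append(summary)
        rows.append(out)

    return AnnotatedResults(header=header, rows=rows, legend=legend, das=das,
                            flags=flags, predictions=predictions, records=records)


def analyze_table(table: RawTable, selected_das: set[DA] | list[DA],
                  cmap: ColumnMap | None = None) -> AnnotatedResults:
    """Convenience pipeline: map (if needed) → validate → harmonize → predict."""
    from .tabular_io import auto_map_columns
    from .validation import check_bindings, check_values, sort_flags

    if cmap is None:
        cmap = auto_map_columns(table)
    flags = check_bindings(cmap, selected_das) + check_values(table, cmap)
    records = harmonize(table, cmap, flags)
    flags[:] = sort_flags(flags, cmap)
    return run_dass(records, selected_das, cmap, flags, table=table)
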