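"""Independent reference transcription of the DA rulebook (cross-check oracle).

This module is a deliberate second, self-contained implementation of the
decision rules: every band edge and table cell was transcribed separately
from the same public guideline documents as ``constants.py``, and the
two-source ITS classification is *derived* here by interval propagation of
the missing source through the three-source table rather than looked up.
The fixture generator uses it to compute expected outcomes, and the test
suite requires the main implementation to agree with it cell-for-cell.
It imports nothing from the rest of the package on purpose.

Values are plain strings/floats/None so that no shared enum can mask a
transcription error. MIT convention: float, the string "neg", or None.
"""

from __future__ import annotations

from dataclasses import dataclass

_POS = {"p", "pos", "positive", "1", "a", "active", "sensitizer"}
_NEG = {"n", "neg", "negative", "0", "i", "inactive", "non-sensitizer"}
_NA = {"", "na", "n/a", "nan"}
_MIT_NEG = {"n", "neg", "negative", "inf"}
_DOM_IN = {"in", "id", "1", "t", "true", "yes", "in domain"}
_DOM_OUT = {"out", "od", "0", "f", "false", "no", "out of domain"}
_POTENCY = {"1a": "1A", "1b": "1B", "nc": "NC", "not classified": "NC"}

_ENDPOINTS = ("chem_id", "dpra_cys_pct", "dpra_lys_pct", "dpra_call", "hclat_mit",
              "hclat_call", "ks_call", "insilico_call", "insilico_domain",
              "ref_hazard", "ref_potency")


# --------------------------------------------------------------------------
# Elementary rules

def ref_parse_call(raw: str) -> str:
    t = raw.strip().lower()
    if t in _POS:
        return "pos"
    if t in _NEG:
        return "neg"
    return "missing"


def ref_dpra_call(cys, lys) -> str:
    if cys is not None and lys is not None:
        return "pos" if (cys + lys) / 2.0 > 6.38 else "neg"
    if cys is not None:
        return "pos" if cys > 13.89 else "neg"
    return "missing"


def ref_effective_mit(mit):
    """float in (0, 5000] | "neg" | None."""
    if mit is None or mit == "neg":
        return mit
    if mit <= 0:
        return None
    if mit > 5000.0:
        return "neg"
    return mit


def ref_2o3(dpra: str, hclat: str, ks: str) -> str:
    """Majority vote over available calls; < 2 concordant → Inconclusive."""
    avail = [c for c in (dpra, hclat, ks) if c in ("pos", "neg")]
    if avail.count("pos") >= 2:
        return "Sensitizer"
    if avail.count("neg") >= 2:
        return "Non-sensitizer"
    return "Inconclusive"


def ref_sts(mit, dpra: str, hclat_call: str = "missing") -> tuple[str, str]:
    mit = ref_effective_mit(mit)
    if isinstance(mit, (int, float)):
        return ("Sensitizer", "1A") if mit <= 10.0 else ("Sensitizer", "1B")
    if mit == "neg" or (mit is None and hclat_call == "neg"):
        if dpra == "pos":
            return ("Sensitizer", "1B")
        if dpra == "neg":
            return ("Non-sensitizer", "NC")
        return ("Inconclusive", "Inconclusive")
    if mit is None and hclat_call == "pos":
        return ("Sensitizer", "Inconclusive")
    return ("Inconclusive", "Inconclusive")


def ref_its_hclat_score(mit):
    mit = ref_effective_mit(mit)
    if mit == "neg":
        return 0
    if mit is None:
        return None
    if mit > 5000.0:
        return 0
    if mit > 150.0:
        return 1
    if mit > 10.0:
        return 2
    return 3


def ref_its_dpra_score(cys, lys):
    if cys is not None and lys is not None:
        m = (cys + lys) / 2.0
        if m < 6.38:
            return 0
        if m < 22.62:
            return 1
        if m < 42.47:
            return 2
        return 3
    if cys is not None:
        if cys < 13.89:
            return 0
        if cys < 23.09:
            return 1
        if cys < 98.24:
            return 2
        return 3
    return None


def ref_its_insilico_score(call: str, in_domain):
    if in_domain is False:
        return None
    if call == "pos":
        return 1
    if call == "neg":
        return 0
    return None


def _three_source_category(total: int) -> str:
    if total >= 6:
        return "1A"
    if total >= 2:
        return "1B"
    return "NC"


def ref_its(dpra_score, hclat_score, insilico_score) -> tuple[str, str, int | None]:
    """(hazard, potency, total). Two-source cells derived by interval propagation."""
    scores = (dpra_score, hclat_score, insilico_score)
    avail = [s for s in scores if s is not None]
    if len(avail) < 2:
        return ("Inconclusive", "Inconclusive", None)
    total = sum(avail)
    if len(avail) == 3:
        cat = _three_source_category(total)
    else:
        max_extra = 1 if insilico_score is None else 3
        reachable = {_three_source_category(total + x) for x in range(max_extra + 1)}
        if reachable == {"1A"}:
            cat = "1A"
        elif reachable == {"1B"}:
            cat = "1B"
        elif reachable == {"NC"}:
            cat = "NC"
        elif reachable == {"1A", "1B"}:
            cat = "1*"
        else:
            cat = "Inconclusive"
    if cat in ("1A", "1B", "1*"):
        return ("Sensitizer", cat, total)
    if cat == "NC":
        return ("Non-sensitizer", cat, total)
    return ("Inconclusive", cat, total)


# --------------------------------------------------------------------------
# Full reference pipeline over a text table

@dataclass
class RefOutcome:
    blocked: bool
    hazard: str | None
    potency: str | None
    its_total: int | None = None


def _norm(name: str) -> str:
    return name.strip().lower().replace(" ", "").replace("-", "").replace("_", "")


def _map_columns(header: list[str]) -> dict[str, int]:
    normed = [_norm(h) for h in header]
    out: dict[str, int] = {}
    for ep in _ENDPOINTS:
        target = _norm(ep)
        for i, h in enumerate(normed):
            if h == target:
                out[ep] = i
                break
    return out


def _ref_float(cell: str):
    try:
        return float(cell.strip())
    except ValueError:
        return None


_SOURCES = {
    "2o3": {"DPRA": {"dpra_cys_pct", "dpra_lys_pct", "dpra_call"},
            "h-CLAT": {"hclat_mit", "hclat_call"},
            "KeratinoSens": {"ks_call"}},
    "sts": {"h-CLAT": {"hclat_mit", "hclat_call"},
            "DPRA": {"dpra_cys_pct", "dpra_lys_pct", "dpra_call"}},
    "its": {"DPRA": {"dpra_cys_pct", "dpra_lys_pct"},
            "h-CLAT": {"hclat_mit"},
            "in silico": {"insilico_call", "insilico_domain"}},
}

_REQUIREMENT_FLAG_ENDPOINT = {
    ("2o3", "DPRA"): "dpra_call", ("2o3", "h-CLAT"): "hclat_call", ("2o3", "KeratinoSens"): "ks_call",
    ("sts", "h-CLAT"): "hclat_mit", ("sts", "DPRA"): "dpra_call",
    ("its", "DPRA"): "dpra_cys_pct", ("its", "h-CLAT"): "hclat_mit", ("its", "in silico"): "insilico_call",
}


def reference_analyze(header: list[str], rows: list[list[str]],
                      selected_das: tuple[str, ...] = ("2o3", "sts", "its")):
    """Expected flags and per-row DA outcomes for a canonical-template table.

    Returns (flags, outcomes): flags as tuples
    (endpoint, row_index_or_None, code, severity) and outcomes as one
    {da: RefOutcome} dict per row.
    """
    cmap = _map_columns(header)
    flags: list[tuple] = []

    # binding completeness
    missing_for_da: dict[str, bool] = {}
    for da in selected_das:
        missing_sources = []
        if da == "2o3":
            checks = [("DPRA", "dpra_call" in cmap or "dpra_cys_pct" in cmap),
                      ("h-CLAT", "hclat_call" in cmap or "hclat_mit" in cmap),
                      ("KeratinoSens", "ks_call" in cmap)]
            missing_sources = [s for s, ok in checks if not ok]
        elif da == "sts":
            checks = [("h-CLAT", "hclat_mit" in cmap or "hclat_call" in cmap),
                      ("DPRA", "dpra_call" in cmap or "dpra_cys_pct" in cmap)]
            missing_sources = [s for s, ok in checks if not ok]
        else:
            bound = [("DPRA", "dpra_cys_pct" in cmap), ("h-CLAT", "hclat_mit" in cmap),
                     ("in silico", "insilico_call" in cmap)]
            if sum(ok for _, ok in bound) < 2:
                missing_sources = [s for s, ok in bound if not ok]
        for source in missing_sources:
            flags.append((_REQUIREMENT_FLAG_ENDPOINT[(da, source)], None,
                          "MISSING_REQUIRED_COLUMN", "ERROR"))
        missing_for_da[da] = bool(missing_sources)

    # per-cell checks
    error_cells: set[tuple[int, str]] = set()
    for ep, col in sorted(cmap.items(), key=lambda kv: kv[1]):
        for i, row in enumerate(rows):
            cell = row[col] if col < len(row) else ""
            if "\t" in cell:
                flags.append((ep, i, "TAB_IN_CELL", "WARNING"))
            t = cell.strip().lower()
            if ep == "chem_id":
                continue
            if t in _NA:
                flags.append((ep, i, "EMPTY_CELL", "WARNING"))
                continue
            if ep in ("dpra_cys_pct", "dpra_lys_pct"):
                v = _ref_float(cell)
                if v is None:
                    flags.append((ep, i, "NON_NUMERIC", "ERROR"))
                    error_cells.add((i, ep))
                elif not (-100.0 <= v <= 100.0):
                    flags.append((ep, i, "OUT_OF_RANGE", "WARNING"))
            elif ep == "hclat_mit":
                if t in _MIT_NEG:
                    continue
                v = _ref_float(cell)
                if v is None:
                    flags.append((ep, i, "NON_NUMERIC", "ERROR"))
                    error_cells.add((i, ep))
                elif not (0.0 < v <= 5000.0):
                    flags.append((ep, i, "OUT_OF_RANGE", "WARNING"))
            elif ep in ("dpra_call", "hclat_call", "ks_call", "insilico_call", "ref_hazard"):
                if t not in _POS and t not in _NEG:
                    flags.append((ep, i, "UNRECOGNIZED_CALL_TOKEN", "ERROR"))
                    error_cells.add((i, ep))
            elif ep == "insilico_domain":
                if t not in _DOM_IN and t not in _DOM_OUT:
                    flags.append((ep, i, "UNRECOGNIZED_CALL_TOKEN", "ERROR"))
                    error_cells.add((i, ep))
            elif ep == "ref_potency":
                if t not in _POTENCY:
                    flags.append((ep, i, "UNRECOGNIZED_CALL_TOKEN", "ERROR"))
                    error_cells.add((i, ep))

    # harmonization + predictions
    outcomes: list[dict[str, RefOutcome]] = []
    for i, row in enumerate(rows):
        def cell(ep: str) -> str:
            col = cmap.get(ep)
            if col is None or (i, ep) in error_cells:
                return ""
            return row[col] if col < len(row) else ""

        def num(ep: str):
            t = cell(ep).strip().lower()
            return None if t in _NA else _ref_float(t)

        cys, lys = num("dpra_cys_pct"), num("dpra_lys_pct")
        derived_dpra = ref_dpra_call(cys, lys)
        user_dpra = ref_parse_call(cell("dpra_call"))
        if derived_dpra == "missing":
            dpra = user_dpra
        else:
            if user_dpra != "missing" and user_dpra != derived_dpra:
                flags.append(("dpra_call", i, "CALL_CONFLICT", "WARNING"))
            dpra = derived_dpra

        mit_t = cell("hclat_mit").strip().lower()
        if mit_t in _NA:
            mit = None
        elif mit_t in _MIT_NEG:
            mit = "neg"
        else:
            mit = _ref_float(mit_t)
        mit = ref_effective_mit(mit)
        if mit == "neg":
            derived_hclat = "neg"
        elif isinstance(mit, (int, float)):
            derived_hclat = "pos"
        else:
            derived_hclat = "missing"
        user_hclat = ref_parse_call(cell("hclat_call"))
        if derived_hclat == "missing":
            hclat = user_hclat
        else:
            if user_hclat != "missing" and user_hclat != derived_hclat:
                flags.append(("hclat_call", i, "CALL_CONFLICT", "WARNING"))
            hclat = derived_hclat

        ks = ref_parse_call(cell("ks_call"))
        insilico = ref_parse_call(cell("insilico_call"))
        dom_t = cell("insilico_domain").strip().lower()
        in_domain = True if dom_t in _DOM_IN else False if dom_t in _DOM_OUT else None

        d_score = ref_its_dpra_score(cys, lys)
        h_score = ref_its_hclat_score(mit)
        s_score = ref_its_insilico_score(insilico, in_domain)

        row_errs = {ep for (r, ep) in error_cells if r == i}
        resolved = {
            "2o3": {"DPRA": dpra != "missing", "h-CLAT": hclat != "missing",
                    "KeratinoSens": ks != "missing"},
            "sts": {"h-CLAT": mit is not None or hclat != "missing",
                    "DPRA": dpra != "missing"},
            "its": {"DPRA": d_score is not None, "h-CLAT": h_score is not None,
                    "in silico": s_score is not None},
        }

        row_out: dict[str, RefOutcome] = {}
        for da in selected_das:
            if missing_for_da.get(da):
                row_out[da] = RefOutcome(blocked=True, hazard=None, potency=None)
                continue
            blocked = False
            for source, endpoints in _SOURCES[da].items():
                if da == "sts" and source == "DPRA" and isinstance(mit, (int, float)):
                    continue
                if (endpoints & row_errs & set(cmap)) and not resolved[da][source]:
                    blocked = True
            if blocked:
                row_out[da] = RefOutcome(blocked=True, hazard=None, potency=None)
            elif da == "2o3":
                row_out[da] = RefOutcome(False, ref_2o3(dpra, hclat, ks), "N/A")
            elif da == "sts":
                hz, pot = ref_sts(mit, dpra, hclat)
                row_out[da] = RefOutcome(False, hz, pot)
            else:
                hz, pot, total = ref_its(d_score, h_score, s_score)
                row_out[da] = RefOutcome(False, hz, pot, total)
        outcomes.append(row_out)

    return flags, outcomes
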