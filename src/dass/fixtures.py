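"""Synthetic assay tables with known ground truth.

The generator emulates a laboratory upload on the canonical template:
depletions uniform over [−5, 100] % (small negative measured depletions
occur in practice), h-CLAT negative with probability 0.4 or an MIT drawn
log-uniformly over (0.1, 5000] µg/mL, binary calls Bernoulli(0.5), and the
in silico prediction out of its applicability domain with probability 0.1.
Call columns are written consistently with the quantitative endpoints, the
way the assay reports would be. Reference classifications are derived from
the complete pre-corruption data via the independent reference
transcription, so every generated table carries its own oracle.

Missingness blanks cells; defects corrupt cells and are recorded in a
ledger, making validation completeness testable as exact multiset equality.
A single integer seed drives all sampling; identical specs generate
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._reference import (
    RefOutcome,
    ref_2o3,
    ref_dpra_call,
    ref_its,
    ref_its_dpra_score,
    ref_its_hclat_score,
    ref_its_insilico_score,
    reference_analyze,
)
from .types import TEMPLATE_HEADER, RawTable

_POS_TOKENS = ("p", "pos", "positive", "1")
_NEG_TOKENS = ("n", "neg", "negative", "0")
_MIT_NEG_TOKENS = ("negative", "neg", "n", "inf")
_DOM_IN_TOKENS = ("in", "1", "true", "yes")
_DOM_OUT_TOKENS = ("out", "0", "false", "no")

_DATA_ENDPOINTS = ("dpra_cys_pct", "dpra_lys_pct", "dpra_call", "hclat_mit",
                   "hclat_call", "ks_call", "insilico_call", "insilico_domain")

_NON_NUMERIC_JUNK = ("twelve", "#VALUE!", "1,2")
_MIT_JUNK = ("err", "#NA!", "1;5")
_BAD_CALL_TOKENS = ("maybe", "?", "unknown")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic table."""

    n_chemicals: int
    seed: int
    missingness_rate: float = 0.05
    defect_rate: float = 0.0
    p_hclat_negative: float = 0.4
    p_ks_positive: float = 0.5
    p_insilico_positive: float = 0.5
    p_out_of_domain: float = 0.1


@dataclass
class FixtureResult:
    """Generated table plus its oracle: expected flags, outcomes, defect ledger."""

    table: RawTable
    expected_outcomes: list[dict[str, RefOutcome]]
    expected_flags: list[tuple]
    defect_ledger: list[tuple] = field(default_factory=list)  # (row, endpoint, code, severity)

    def clean_rows(self) -> list[int]:
        """Row indices untouched by injected defects."""
        dirty = {entry[0] for entry in self.defect_ledger}
        return [i for i in range(self.table.n_rows) if i not in dirty]


def _call_token(rng: np.random.Generator, call: str) -> str:
    pool = _POS_TOKENS if call == "pos" else _NEG_TOKENS
    return pool[rng.integers(len(pool))]


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Generate a canonical-template table with known expected outcomes."""
    for rate in (spec.missingness_rate, spec.defect_rate, spec.p_hclat_negative,
                 spec.p_ks_positive, spec.p_insilico_positive, spec.p_out_of_domain):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("all rates must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    header = list(TEMPLATE_HEADER)
    col = {name: i for i, name in enumerate(header)}

    rows: list[list[str]] = []
    for i in range(spec.n_chemicals):
        cys = round(float(rng.uniform(-5.0, 100.0)), 2)
        lys = round(float(rng.uniform(-5.0, 100.0)), 2)
        if rng.random() < spec.p_hclat_negative:
            mit = None
        else:
            mit = round(float(np.exp(rng.uniform(np.log(0.1), np.log(5000.0)))), 2)
            mit = min(mit, 5000.0)
        ks = "pos" if rng.random() < spec.p_ks_positive else "neg"
        insilico = "pos" if rng.random() < spec.p_insilico_positive else "neg"
        in_domain = rng.random() >= spec.p_out_of_domain

        dpra = ref_dpra_call(cys, lys)
        hclat = "pos" if mit is not None else "neg"

        # reference classifications from the complete, uncorrupted data
        ref_haz = ref_2o3(dpra, hclat, ks)
        ref_haz_cell = {"Sensitizer": "positive", "Non-sensitizer": "negative"}.get(ref_haz, "")
        _, ref_pot, _ = ref_its(
            ref_its_dpra_score(cys, lys),
            ref_its_hclat_score(mit if mit is not None else "neg"),
            ref_its_insilico_score(insilico, in_domain),
        )
        ref_pot_cell = ref_pot if ref_pot in ("1A", "1B", "NC") else ""

        row = [""] * len(header)
        row[col["chem_id"]] = f"CHEM-{i + 1:04d}"
        row[col["dpra_cys_pct"]] = format(cys, "g")
        row[col["dpra_lys_pct"]] = format(lys, "g")
        row[col["dpra_call"]] = _call_token(rng, dpra)
        row[col["hclat_mit"]] = (format(mit, "g") if mit is not None
                                 else _MIT_NEG_TOKENS[rng.integers(len(_MIT_NEG_TOKENS))])
        row[col["hclat_call"]] = _call_token(rng, hclat)
        row[col["ks_call"]] = _call_token(rng, ks)
        row[col["insilico_call"]] = _call_token(rng, insilico)
        row[col["insilico_domain"]] = (_DOM_IN_TOKENS[rng.integers(len(_DOM_IN_TOKENS))]
                                       if in_domain
                                       else _DOM_OUT_TOKENS[rng.integers(len(_DOM_OUT_TOKENS))])
        row[col["ref_hazard"]] = ref_haz_cell
        row[col["ref_potency"]] = ref_pot_cell
        rows.append(row)

    # missingness: blank data cells independently
    for i in range(spec.n_chemicals):
        for ep in _DATA_ENDPOINTS:
            if rng.random() < spec.missingness_rate:
                rows[i][col[ep]] = ""

    # defect injection, every location recorded
    ledger: list[tuple] = []
    for i in range(spec.n_chemicals):
        for ep in _DATA_ENDPOINTS:
            if rng.random() >= spec.defect_rate:
                continue
            if ep in ("dpra_cys_pct", "dpra_lys_pct"):
                if rng.random() < 0.5:
                    rows[i][col[ep]] = _NON_NUMERIC_JUNK[rng.integers(len(_NON_NUMERIC_JUNK))]
                    ledger.append((i, ep, "NON_NUMERIC", "ERROR"))
                else:
                    rows[i][col[ep]] = "250" if rng.random() < 0.5 else "-150"
                    ledger.append((i, ep, "OUT_OF_RANGE", "WARNING"))
            elif ep == "hclat_mit":
                if rng.random() < 0.5:
                    rows[i][col[ep]] = _MIT_JUNK[rng.integers(len(_MIT_JUNK))]
                    ledger.append((i, ep, "NON_NUMERIC", "ERROR"))
                else:
                    rows[i][col[ep]] = "6000" if rng.random() < 0.5 else "7500"
                    ledger.append((i, ep, "OUT_OF_RANGE", "WARNING"))
            else:
                rows[i][col[ep]] = _BAD_CALL_TOKENS[rng.integers(len(_BAD_CALL_TOKENS))]
                ledger.append((i, ep, "UNRECOGNIZED_CALL_TOKEN", "ERROR"))

    table = RawTable(header=header, rows=rows, source_format="tsv")
    flags, outcomes = reference_analyze(header, rows)
    return FixtureResult(table=table, expected_outcomes=outcomes,
                         expected_flags=flags, defect_ledger=ledger)
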