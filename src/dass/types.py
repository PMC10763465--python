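"""Domain types shared across the package.

The vocabulary follows the skin-sensitization defined-approach (DA) literature:
assay endpoints from the DPRA (direct peptide reactivity assay, key event 1),
KeratinoSens (keratinocyte activation, key event 2), and h-CLAT (human cell
line activation test, key event 3), optionally complemented by an in silico
structural prediction, feed three fixed data-interpretation procedures — the
two-out-of-three (2o3), the key event 3/1 sequential testing strategy
(KE 3/1 STS), and the integrated testing strategy (ITS) — that classify a
chemical as a sensitizer or non-sensitizer and, for STS and ITS, assign a
GHS potency category (1A strong, 1B moderate/weak, NC not classified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class EndpointKey(str, Enum):
    """Closed set of endpoints a user table may provide.

    The enum value is the canonical template header for that endpoint.
    """

    CHEM_ID = "chem_id"
    DPRA_CYS_PCT = "dpra_cys_pct"
    DPRA_LYS_PCT = "dpra_lys_pct"
    DPRA_CALL = "dpra_call"
    HCLAT_MIT = "hclat_mit"
    HCLAT_CALL = "hclat_call"
    KS_CALL = "ks_call"
    INSILICO_CALL = "insilico_call"
    INSILICO_DOMAIN = "insilico_domain"
    REFERENCE_HAZARD = "ref_hazard"
    REFERENCE_POTENCY = "ref_potency"


#: Canonical template column order.
TEMPLATE_HEADER: tuple[str, ...] = tuple(k.value for k in EndpointKey)


class Call(Enum):
    """Binary assay outcome; absence of information is MISSING, never a third call."""

    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    MISSING = "Missing"


class Hazard(Enum):
    """Skin-sensitization hazard classification produced by a DA."""

    SENSITIZER = "Sensitizer"
    NON_SENSITIZER = "Non-sensitizer"
    INCONCLUSIVE = "Inconclusive"


class PotencyClass(Enum):
    """GHS potency category.

    ONE_STAR ("1*") marks a conclusive sensitizer hazard whose potency could
    not be resolved between 1A and 1B (it arises in the two-source ITS
    tables). NOT_APPLICABLE is used for DAs that never predict potency (2o3).
    """

    GHS_1A = "1A"
    GHS_1B = "1B"
    NC = "NC"
    ONE_STAR = "1*"
    INCONCLUSIVE = "Inconclusive"
    NOT_APPLICABLE = "N/A"


class DA(str, Enum):
    """The three defined approaches implemented here."""

    TWO_OF_THREE = "2o3"
    KE31STS = "sts"
    ITS = "its"


class ITSScheme(Enum):
    """Which DPRA scoring scheme the ITS used for a record."""

    TWO_VALUE_DPRA = "two-value"
    CYS_ONLY_DPRA = "cys-only"
    NO_DPRA = "none"


class _NegativeMIT:
    """Singleton marker: the h-CLAT was run and was negative (no MIT determined)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "NEGATIVE_MIT"


NEGATIVE_MIT = _NegativeMIT()


class FlagCode(str, Enum):
    DUPLICATE_BINDING = "DUPLICATE_BINDING"
    MISSING_REQUIRED_COLUMN = "MISSING_REQUIRED_COLUMN"
    NON_NUMERIC = "NON_NUMERIC"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    UNRECOGNIZED_CALL_TOKEN = "UNRECOGNIZED_CALL_TOKEN"
    EMPTY_CELL = "EMPTY_CELL"
    TAB_IN_CELL = "TAB_IN_CELL"
    CALL_CONFLICT = "CALL_CONFLICT"


class Severity(str, Enum):
    ERROR = "ERROR"      # blocks prediction for the affected (chemical, DA) pairs
    WARNING = "WARNING"  # reported, never blocks


@dataclass(frozen=True)
class ValidationFlag:
    """One formatting/consistency problem at a (column, row) location.

    ``row_index`` is 0-based over data rows; ``None`` marks a column-level
    flag. ``da`` is set on flags that pertain to a single defined approach
    (currently only MISSING_REQUIRED_COLUMN).
    """

    endpoint: EndpointKey | None
    column_name: str
    row_index: int | None
    code: FlagCode
    severity: Severity
    message: str
    da: DA | None = None


@dataclass
class RawTable:
    """A user table with every cell kept as text.

    Validation must see the user's literal input, so nothing is coerced at
    this layer. Short rows are padded with empty cells on read; ``notes``
    records such repairs.
    """

    header: list[str]
    rows: list[list[str]]
    source_format: str = "tsv"
    notes: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.header)


@dataclass
class ColumnMap:
    """Partial binding from endpoints to column indices of a RawTable.

    ``header`` is a snapshot of the table header so flags can name columns.
    ``notes`` records auto-mapping ambiguities (duplicate header candidates).
    """

    bindings: dict[EndpointKey, int] = field(default_factory=dict)
    header: tuple[str, ...] = ()
    notes: list[str] = field(default_factory=list)

    def bound(self, key: EndpointKey) -> bool:
        return key in self.bindings

    def column_index(self, key: EndpointKey) -> int | None:
        return self.bindings.get(key)

    def column_name(self, key: EndpointKey) -> str:
        idx = self.bindings.get(key)
        if idx is None:
            return ""
        if 0 <= idx < len(self.header):
            return self.header[idx]
        return f"column {idx}"

    def duplicated_endpoints(self) -> set[EndpointKey]:
        """Endpoints sharing a column index with another endpoint."""
        by_col: dict[int, list[EndpointKey]] = {}
        for key, idx in self.bindings.items():
            by_col.setdefault(idx, []).append(key)
        dupes: set[EndpointKey] = set()
        for keys in by_col.values():
            if len(keys) > 1:
                dupes.update(keys)
        return dupes


@dataclass
class ChemicalRecord:
    """One chemical's harmonized endpoint values across all information sources.

    ``hclat_mit`` holds the *effective* MIT used by the rules: a numeric value
    in (0, 5000] µg/mL, NEGATIVE_MIT for a negative h-CLAT (including a
    reported MIT above the 5000 µg/mL maximum test concentration), or None.
    """

    row_index: int
    chem_id: str
    cys_pct: float | None = None
    lys_pct: float | None = None
    dpra_mean_pct: float | None = None
    dpra_call: Call = Call.MISSING
    hclat_mit: object = None  # float | NEGATIVE_MIT | None
    hclat_call: Call = Call.MISSING
    ks_call: Call = Call.MISSING
    insilico_call: Call = Call.MISSING
    insilico_in_domain: bool | None = None
    ref_hazard: Call = Call.MISSING
    ref_potency: PotencyClass | None = None


@dataclass
class ITSScores:
    """Component scores of the integrated testing strategy for one chemical."""

    dpra_score: int | None
    hclat_score: int | None
    insilico_score: int | None
    scheme: ITSScheme

    @property
    def available(self) -> int:
        return sum(s is not None for s in (self.dpra_score, self.hclat_score, self.insilico_score))

    @property
    def total(self) -> int:
        return sum(s for s in (self.dpra_score, self.hclat_score, self.insilico_score) if s is not None)


@dataclass
class DAPrediction:
    """Outcome of one defined approach for one chemical."""

    da: DA
    hazard: Hazard
    potency: PotencyClass
    its_total: int | None = None
    its_source_count: int | None = None
    rationale: str = ""


@dataclass(frozen=True)
class Blocked:
    """Prediction withheld because ERROR flags corrupt a needed input."""

    da: DA
    reasons: tuple[str, ...]
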