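"""Contingency tables and performance metrics against reference classifications.

Predictions that carry no resolved class (inconclusive, blocked, or the
"1*" unresolved-potency state) and records without a reference value are
excluded from the table, never silently dropped: every exclusion is counted
under a named reason and conservation (cell counts + exclusions = records)
always holds. Undefined ratios are reported as NOT_DEFINED (None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import EvaluationError
from .types import DA, Blocked, Call, DAPrediction, Hazard, PotencyClass

NOT_DEFINED = None

HAZARD_LABELS = (Hazard.SENSITIZER.value, Hazard.NON_SENSITIZER.value)
POTENCY_LABELS = (PotencyClass.GHS_1A.value, PotencyClass.GHS_1B.value, PotencyClass.NC.value)


@dataclass
class ContingencyTable:
    """Cross-tabulation of predicted (rows) vs reference (columns) classes."""

    mode: str  # "HAZARD" or "POTENCY"
    labels: tuple[str, ...]
    counts: pd.DataFrame  # index = predicted, columns = reference
    excluded: dict[str, int] = field(default_factory=dict)
    n_records: int = 0

    @property
    def n_evaluated(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


@dataclass
class PerformanceMetrics:
    """Summary statistics of one contingency table.

    Hazard (2×2) tables report accuracy, sensitivity, specificity and
    balanced accuracy; potency (3×3) tables report accuracy and per-class
    sensitivity. A None value means the ratio's denominator was zero
    (NOT_DEFINED).
    """

    accuracy: float | None
    sensitivity: float | None = None
    specificity: float | None = None
    balanced_accuracy: float | None = None
    per_class_sensitivity: dict[str, float | None] | None = None
    n_evaluated: int = 0
    n_excluded: int = 0


def _hazard_label(pred: DAPrediction) -> tuple[str | None, str | None]:
    if pred.hazard is Hazard.INCONCLUSIVE:
        return None, "inconclusive_prediction"
    return pred.hazard.value, None


def _potency_label(pred: DAPrediction) -> tuple[str | None, str | None]:
    if pred.potency is PotencyClass.ONE_STAR:
        return None, "one_star_potency_unresolved"
    if pred.potency in (PotencyClass.INCONCLUSIVE, PotencyClass.NOT_APPLICABLE):
        return None, "inconclusive_prediction"
    return pred.potency.value, None


def build_contingency(predictions: list[DAPrediction | Blocked],
                      references: list[Call | PotencyClass | None],
                      mode: str) -> ContingencyTable:
    """Tally aligned prediction/reference pairs into a contingency table.

    ``mode`` is "HAZARD" (references are Calls) or "POTENCY" (references are
    PotencyClass values). Requesting a potency table for 2o3 predictions is
    a structured error: that DA does not predict GHS potency.
    """
    mode = mode.upper()
    if mode not in {"HAZARD", "POTENCY"}:
        raise ValueError(f"unknown mode {mode!r}")
    if len(predictions) != len(references):
        raise ValueError("predictions and references must be aligned by record")
    if mode == "POTENCY" and any(
        isinstance(p, (DAPrediction, Blocked)) and p.da is DA.TWO_OF_THREE for p in predictions
    ):
        raise EvaluationError("The 2o3 DA does not predict GHS potency")

    labels = HAZARD_LABELS if mode == "HAZARD" else POTENCY_LABELS
    pairs: list[tuple[str, str]] = []
    excluded: dict[str, int] = {}

    def exclude(reason: str) -> None:
        excluded[reason] = excluded.get(reason, 0) + 1

    for pred, ref in zip(predictions, references):
        if pred is None or isinstance(pred, Blocked):
            exclude("blocked_prediction")
            continue
        label, reason = _hazard_label(pred) if mode == "HAZARD" else _potency_label(pred)
        if label is None:
            exclude(reason)
            continue
        if mode == "HAZARD":
            if ref is Call.POSITIVE:
                ref_label = Hazard.SENSITIZER.value
            elif ref is Call.NEGATIVE:
                ref_label = Hazard.NON_SENSITIZER.value
            else:
                ref_label = None
        else:
            ref_label = ref.value if isinstance(ref, PotencyClass) and ref.value in labels else None
        if ref_label is None:
            exclude("missing_reference")
            continue
        pairs.append((label, ref_label))

    if pairs:
        df = pd.DataFrame(pairs, columns=["predicted", "reference"])
        counts = pd.crosstab(df["predicted"], df["reference"])
    else:
        counts = pd.DataFrame()
    counts = counts.reindex(index=list(labels), columns=list(labels), fill_value=0).astype(int)
    return ContingencyTable(mode=mode, labels=labels, counts=counts,
                            excluded=excluded, n_records=len(predictions))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(table: ContingencyTable) -> PerformanceMetrics:
    """Accuracy and class-conditional rates from a contingency table.

    For 2×2 hazard tables the positive class is "Sensitizer": sensitivity =
    TP/(TP+FN) over reference sensitizers, specificity = TN/(TN+FP) over
    reference non-sensitizers, balanced accuracy their mean. Potency tables
    report accuracy and per-class sensitivity (recall of each reference
    class).
    """
    m = table.counts
    total = int(m.to_numpy().sum())
    if total == 0:
        raise EvaluationError("no evaluable records")
    trace = sum(int(m.at[lbl, lbl]) for lbl in table.labels)
    accuracy = trace / total
    if table.mode == "HAZARD":
        pos, neg = table.labels
        tp = int(m.at[pos, pos])
        fn = int(m.at[neg, pos])
        tn = int(m.at[neg, neg])
        fp = int(m.at[pos, neg])
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        balanced = None if sens is None or spec is None else (sens + spec) / 2
        return PerformanceMetrics(accuracy=accuracy, sensitivity=sens, specificity=spec,
                                  balanced_accuracy=balanced,
                                  n_evaluated=total, n_excluded=table.n_excluded)
    per_class = {
        lbl: _ratio(int(m.at[lbl, lbl]), int(m[lbl].sum())) for lbl in table.labels
    }
    return PerformanceMetrics(accuracy=accuracy, per_class_sensitivity=per_class,
                              n_evaluated=total, n_excluded=table.n_excluded)


def format_metrics(table: ContingencyTable, metrics: PerformanceMetrics) -> str:
    """Plain-text rendering of a table and its metrics (CLI / report output)."""
    def fmt(v: float | None) -> str:
        return "NOT_DEFINED" if v is None else f"{v:.3f}"

    lines = [f"{table.mode} contingency table (rows: predicted, cols: reference)",
             table.counts.to_string()]
    if table.excluded:
        lines.append("excluded: " + ", ".join(f"{k}={v}" for k, v in sorted(table.excluded.items())))
    lines.append(f"n_evaluated={metrics.n_evaluated} n_excluded={metrics.n_excluded}")
    lines.append(f"accuracy={fmt(metrics.accuracy)}")
    if table.mode == "HAZARD":
        lines.append(f"sensitivity={fmt(metrics.sensitivity)} specificity={fmt(metrics.specificity)} "
                     f"balanced_accuracy={fmt(metrics.balanced_accuracy)}")
    else:
        assert metrics.per_class_sensitivity is not None
        lines.append("per-class sensitivity: " + ", ".join(
            f"{k}={fmt(v)}" for k, v in metrics.per_class_sensitivity.items()))
    return "\n".join(lines)
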