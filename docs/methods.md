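# Methods

## Scope and model

The package implements the three rule-based data interpretation procedures
used in regulatory skin-sensitization assessment. Each defined approach
(DA) is a fixed, expert-judgment-free function from a small set of
information sources to a hazard call and, for two of the three, a GHS
potency category. The information sources map onto the adverse outcome
pathway for skin sensitization: DPRA peptide depletion (covalent protein
binding, key event 1), KeratinoSens (keratinocyte activation, key event
2), h-CLAT (dendritic-cell activation, key event 3), and a structure-based
in silico prediction.

The procedures themselves are total functions: every combination of
available/missing inputs has a defined outcome (`Inconclusive` where the
rules cannot classify), and no rule contains a tie. Absence of information
is always represented as `MISSING`, never as a third call value.

## Decision thresholds

All numeric decision constants live in `src/dass/constants.py` with their
boundary directions and sources; `rulebook_checksum()` digests them so
every run log records exactly which rulebook produced it. The key values:

| constant | value | meaning |
|---|---|---|
| DPRA two-value negativity | mean depletion ≤ 6.38 % | hazard call negative (OECD TG 442C) |
| DPRA Cys-only negativity | %Cys ≤ 13.89 % | used when %Lys is unavailable |
| STS 1A cutoff | MIT ≤ 10 µg/mL | strong sensitizer in the sequential strategy |
| ITS h-CLAT bands | ≤ 10 / ≤ 150 / ≤ 5000 µg/mL | scores 3 / 2 / 1; negative → 0 |
| ITS DPRA mean bands | ≥ 42.47 / ≥ 22.62 / ≥ 6.38 % | scores 3 / 2 / 1; below → 0 |
| ITS DPRA Cys-only bands | ≥ 98.24 / ≥ 23.09 / ≥ 13.89 % | scores 3 / 2 / 1; below → 0 |
| ITS 3-source totals | 6–7 / 2–5 / 0–1 | 1A / 1B / NC |

The two-source ITS tables (used when exactly one source is missing)
contain the `1*` and `Inconclusive` cells. They are stored as explicit
tables, and the test suite independently *derives* every cell by interval
propagation: with observed total *t* and a missing source that could have
added 0…*m* points (m = 1 for in silico, 3 otherwise), the cell is the
unique three-source category reachable for all of *t*…*t+m*, `1*` when
only 1A/1B are reachable, and `Inconclusive` when the NC boundary is
straddled. Both transcriptions agree cell-for-cell; any future edit that
breaks the agreement fails the build.

Anti-drift design: `dass._reference` is a deliberately independent second
transcription of the entire rulebook (re-typed literals, if-chains instead
of table lookups, derived two-source cells). It is the oracle for the
fixture generator and the exhaustive grid tests, never the implementation.

## Harmonization rules

* All cells are text until harmonization, so validation can flag the
  user's literal input.
* `dpra_mean = (cys + lys)/2`; negative measured depletions participate
  unmodified (they occur in practice and are warned, not clamped).
* A user-supplied call column is honoured when nothing contradicts it; if
  a call derived from the quantitative endpoints disagrees, the derived
  call wins and a `CALL_CONFLICT` warning is recorded. Rationale: the
  quantitative endpoints are the DAs' primary inputs.
* Effective MIT: numeric in (0, 5000] µg/mL is used as-is; a value above
  the 5000 µg/mL maximum test concentration is a negative outcome by
  definition; a non-positive value is physically impossible and treated as
  unusable (it is also warned as out-of-range).
* An in silico prediction outside its applicability domain is unusable for
  the ITS; an *unstated* domain is taken as in-domain.
* %Lys alone has no published DPRA prediction model: it yields a MISSING
  call and no ITS DPRA score.

## Validation and blocking policy

Validation emits deterministic, machine-readable flags (stable order:
column-level first, then by column and row). Severities implement an
unattended batch policy:

* **ERROR** (non-numeric value, unrecognized call token, duplicate column
  binding, missing required column) makes the affected cell unusable and
  blocks prediction for a (chemical, DA) pair **only when it actually
  deprives a source that the DA consults for that chemical** — a corrupted
  %Cys blocks the ITS but not a 2o3 run that has a clean DPRA call column;
  a corrupted DPRA cell never blocks an STS row whose h-CLAT is positive
  (no further testing is required there); a corrupted %Lys with a clean
  %Cys degrades the ITS to the Cys-only scheme rather than blocking.
* **WARNING** (empty cell, out-of-range value, call conflict, tab in cell)
  never blocks. Plausible ranges — depletion in [−100, 100] %, MIT in
  (0, 5000] µg/mL — warn rather than reject because the assays' operating
  ranges bound plausibility, not validity of the file format.

Blocked predictions appear as `Blocked` markers naming the responsible
flags; inconclusive predictions are genuine rule outcomes and are kept
distinct from blocks.

## Performance evaluation

Hazard comparisons are 2×2 over {Sensitizer, Non-sensitizer} with
accuracy, sensitivity, specificity, and balanced accuracy; potency
comparisons are 3×3 over {1A, 1B, NC} with accuracy and per-class
sensitivity. Inconclusive or blocked predictions, `1*` potency
predictions, and missing references are excluded under named reasons
(exclusion precedence: blocked → inconclusive/`1*` → missing reference),
and conservation (cells + exclusions = records) is asserted. A ratio with
a zero denominator is reported as `NOT_DEFINED`, never as 0. Requesting a
potency table for 2o3 is a structured error, because that DA does not
predict potency.

## Synthetic data generator

`generate_fixture` emulates a laboratory upload on the canonical template:
depletions uniform on [−5, 100] %, h-CLAT negative with probability 0.4 or
an MIT log-uniform on (0.1, 5000] µg/mL, binary calls Bernoulli(0.5), in
silico out-of-domain with probability 0.1, and call columns written
consistently with the quantitative endpoints using varied surface tokens.
Reference classifications are derived from the complete pre-corruption
data (2o3 consensus for hazard, ITS category for potency), so performance
metrics measure inter-DA concordance, not agreement with animal or human
data. Missingness blanks cells; defects corrupt cells and are recorded in
a ledger, making validation completeness testable as exact multiset
equality. One integer seed drives everything; identical specifications
generate byte-identical tables.

What the generator deliberately does **not** emulate: real chemical
structure–activity relationships, correlated assay errors, borderline
analytical variability, or reference data from LLNA/human studies.
Passing tests therefore demonstrate that the rules, plumbing, validation
and bookkeeping are correct — not that the DAs predict human outcomes.

## Verification problem sizes

The exhaustive 2o3 grid covers all 27 call combinations (and all 6
argument orders each); the ITS grid covers every band edge ± 0.01 of all
three scoring tables crossed with the in silico and domain states (> 1000
cells); STS dominance uses 1000 seeded random MIT draws; monotonicity uses
10 000 seeded ordered pairs; validation completeness uses a 500-row
fixture with 5 % defects; end-to-end reproducibility uses a 1000-row
fixture with 5 % missingness and 5 % defects run twice through the CLI.
`scripts/acceptance.py` re-runs the same computations from scratch at a
user-supplied seed.

## Known limitations

* Borderline-range evaluation of individual assay results (as discussed in
  guideline annexes) is not implemented.
* Only the KeratinoSens binary call is consumed; there is no quantitative
  KS model (Imax/EC1.5).
* Alternative information sources beyond the three assays + in silico pair
  are not implemented; the scoring functions are small and pluggable by
  design.
* XLSX ingestion reads the first worksheet only and renders cells to their
  displayed text; no styled/colored output is produced — column roles are
  conveyed by the `calc_`/`pred_` prefixes and the legend sheet.
* No statistical inference (confidence intervals, tests) on performance
  metrics.
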