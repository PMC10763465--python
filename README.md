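# dass — defined approaches for skin sensitization

`dass` is a Python library and command-line tool for applying the three
internationally harmonized **defined approaches (DAs) for skin
sensitization** — the Two-out-of-Three (2o3), the Integrated Testing
Strategy (ITS), and the Key Event 3/1 Sequential Testing Strategy
(KE 3/1 STS) — to batches of per-chemical non-animal assay results.

It is written for toxicologists, regulatory scientists, and data engineers
who have results from the assays of the skin-sensitization adverse outcome
pathway and need reproducible hazard and GHS potency predictions without
applying the decision rules by hand:

* **DPRA** (direct peptide reactivity assay, key event 1): %-cysteine and
  %-lysine peptide depletion;
* **KeratinoSens** (keratinocyte activation, key event 2): a binary call;
* **h-CLAT** (human cell line activation test, key event 3): the minimum
  induction threshold (MIT, µg/mL) or a negative outcome;
* an **in silico** structural prediction (e.g. Derek Nexus or the OECD QSAR
  Toolbox) with its applicability-domain status.

## The data interpretation procedures

**2o3** — hazard by concordance: a chemical is a sensitizer
(non-sensitizer) when at least two of the DPRA, h-CLAT, and KeratinoSens
calls are positive (negative); two available but discordant calls are
inconclusive. 2o3 never predicts potency, and the result is independent of
assay order.

**KE 3/1 STS** — sequential: if the h-CLAT is positive, MIT ≤ 10 µg/mL ⇒
GHS 1A, otherwise 1B, with no further testing; if the h-CLAT is negative,
the DPRA decides 1B (positive) vs NC (negative).

**ITS** — additive scoring: the mean DPRA depletion (or %Cys alone, via a
dedicated scheme) scores 0–3, the h-CLAT MIT scores 0–3, and an in-domain
in silico call scores 0–1. With all three sources the total maps
6–7 ⇒ 1A, 2–5 ⇒ 1B, 0–1 ⇒ NC; with two sources, dedicated tables apply
whose cells include `1*` (conclusive sensitizer, potency unresolved) and
`Inconclusive`. All band edges are transcribed, with their boundary
directions, from OECD Guideline 497 and Test Guideline 442C in
`src/dass/constants.py`, and the test suite checks them cell-for-cell
against a second, independent transcription
(`src/dass/_reference.py`) that derives the two-source tables by interval
propagation.

Around the rule engine the package provides tabular ingestion (TSV/CSV/
XLSX, all cells kept as text), tolerant column auto-mapping against a
canonical template, machine-readable validation flags (an ERROR blocks
only the chemical/DA pairs it actually deprives), harmonization of raw
cells into calls and quantitative inputs, contingency tables and
performance metrics against reference classifications, and a seeded
synthetic-data generator with a built-in oracle.

## Worked example

```sh
$ cat demo.tsv
chem_id  dpra_cys_pct  dpra_lys_pct  hclat_mit  ks_call  insilico_call  insilico_domain
cinnamal   70.9   57.4   8.9        p  p  in
glycerol   1.2    0.3    negative   n  n  in
limonene   14.1   1.0    negative   p  p  out

$ dass run --input demo.tsv --da 2o3,sts,its --output demo_results.tsv
rulebook checksum: a9c736a9aafc
defined approaches: 2o3, sts, its
chemicals: 3; flags: 0 error, 0 warning; blocked predictions: 0
results written to demo_results.tsv
```

Selected columns of `demo_results.tsv`:

| chem_id  | calc_dpra_mean | calc_dpra_call | calc_its_total | pred_2o3_hazard | pred_sts_potency | pred_its_potency |
|----------|---------------|----------------|----------------|-----------------|------------------|------------------|
| cinnamal | 64.15         | Positive       | 7              | Sensitizer      | 1A               | 1A               |
| glycerol | 0.75          | Negative       | 0              | Non-sensitizer  | NC               | NC               |
| limonene | 7.55          | Positive       | 1              | Sensitizer      | 1B               | Inconclusive     |

Reading the rows: cinnamal is positive everywhere (mean depletion 64.15 %
scores 3, MIT 8.9 µg/mL scores 3, in silico scores 1; total 7 ⇒ 1A, and
the STS reaches 1A directly from MIT ≤ 10). Glycerol is negative
everywhere. Limonene shows why the DAs differ: its mean depletion
(7.55 %) is just above the 6.38 % DPRA positivity threshold, so 2o3
(DPRA+KS positive) calls it a sensitizer and the STS assigns 1B, but the
ITS only has two usable sources (the in silico prediction is out of its
applicability domain) and a total of 1 in the two-source table is
inconclusive.

Other commands: `dass template --output template.csv` writes the canonical
data template whose headers auto-map; `dass fixture --n 100 --seed 7
--output fx.tsv` generates a synthetic table; `dass run ...
--reference-hazard ref_hazard --reference-potency ref_potency` adds
contingency tables and accuracy/sensitivity/specificity/balanced-accuracy
metrics against reference columns.

The same pipeline is available as a library:

```python
from dass import DA, analyze_table, read_table

results = analyze_table(read_table("demo.tsv"), [DA.TWO_OF_THREE, DA.ITS])
for row in results.predictions:
    print(row[DA.ITS].hazard, row[DA.ITS].potency, row[DA.ITS].rationale)
```

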