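"""Numeric decision thresholds and lexicons for the defined approaches.

Every band edge below is transcribed verbatim, with its boundary direction,
from the public guideline documents that define the approaches:

* OECD Test Guideline 442C (DPRA) — peptide-depletion prediction models.
* OECD Guideline 497 (defined approaches for skin sensitization), Annex on
  the ITS — component scoring tables and total-score classification tables,
  including the two-source tables with their "1*" and "Inconclusive" cells.
* The KE 3/1 sequential testing strategy as accepted in the U.S. EPA interim
  science policy on skin sensitization — the 10 µg/mL MIT cutoff between
  GHS 1A and 1B.

They are configuration constants, not tunables: changing any of them changes
which regulatory procedure the package implements. ``rulebook_checksum()``
digests all of them so a run can record exactly which rulebook produced it.
The test suite checks this transcription cell-for-cell against a second,
independently written transcription.
"""

from __future__ import annotations

import hashlib
import json

from .types import DA, EndpointKey

# --------------------------------------------------------------------------
# DPRA hazard-call prediction models (OECD TG 442C).
# Mean of %Cys and %Lys depletion ≤ 6.38 % → negative (positive above).
DPRA_MEAN_NEGATIVE_MAX = 6.38
# %Cys-only depletion ≤ 13.89 % → negative, when %Lys is unavailable.
DPRA_CYS_ONLY_NEGATIVE_MAX = 13.89

# --------------------------------------------------------------------------
# KE 3/1 STS potency cutoff: h-CLAT MIT ≤ 10 µg/mL → GHS 1A, else 1B.
STS_MIT_STRONG_MAX = 10.0

# h-CLAT operational ceiling (µg/mL): the highest concentration tested.
# A reported MIT above it is treated as a negative outcome; an MIT ≤ 0 is
# physically impossible and treated as unusable.
HCLAT_MAX_TEST_CONC = 5000.0

# --------------------------------------------------------------------------
# ITS component scoring tables (OECD GL 497).
# h-CLAT: MIT ≤ 10 → 3; 10 < MIT ≤ 150 → 2; 150 < MIT ≤ 5000 → 1; negative → 0.
# Encoded as (upper_edge_inclusive, score), checked in order.
ITS_HCLAT_MIT_BANDS: tuple[tuple[float, int], ...] = ((10.0, 3), (150.0, 2), (5000.0, 1))

# DPRA, two-value scheme on mean %Cys/%Lys depletion:
# mean ≥ 42.47 → 3; 22.62 ≤ mean < 42.47 → 2; 6.38 ≤ mean < 22.62 → 1; < 6.38 → 0.
# Encoded as (lower_edge_inclusive, score), checked in order.
ITS_DPRA_MEAN_BANDS: tuple[tuple[float, int], ...] = ((42.47, 3), (22.62, 2), (6.38, 1))

# DPRA, %Cys-only scheme:
# ≥ 98.24 → 3; 23.09 ≤ x < 98.24 → 2; 13.89 ≤ x < 23.09 → 1; < 13.89 → 0.
ITS_DPRA_CYS_BANDS: tuple[tuple[float, int], ...] = ((98.24, 3), (23.09, 2), (13.89, 1))

# In silico prediction (within applicability domain): positive → 1, negative → 0.

# --------------------------------------------------------------------------
# ITS total-score classification, all three sources available (total 0–7):
# 6–7 → 1A; 2–5 → 1B; 0–1 → NC.
ITS_POTENCY_3SOURCE: dict[int, str] = {
    7: "1A", 6: "1A",
    5: "1B", 4: "1B", 3: "1B", 2: "1B",
    1: "NC", 0: "NC",
}

# ITS total-score classification with one source missing (GL 497 two-source
# tables). "1*" = conclusive sensitizer, potency unresolved between 1A and 1B;
# "Inconclusive" = hazard itself unresolved. The cells equal what interval
# propagation of the missing source's possible scores through the three-source
# table yields; that derivation is the independent cross-check in the tests.
ITS_POTENCY_2SOURCE: dict[str, dict[int, str]] = {
    # DPRA + h-CLAT available (in silico missing; it could add 0–1):
    "insilico_missing": {6: "1A", 5: "1*", 4: "1B", 3: "1B", 2: "1B",
                         1: "Inconclusive", 0: "NC"},
    # DPRA + in silico available (h-CLAT missing; it could add 0–3):
    "hclat_missing": {4: "1*", 3: "1*", 2: "1B", 1: "Inconclusive", 0: "Inconclusive"},
    # h-CLAT + in silico available (DPRA missing; it could add 0–3):
    "dpra_missing": {4: "1*", 3: "1*", 2: "1B", 1: "Inconclusive", 0: "Inconclusive"},
}

# --------------------------------------------------------------------------
# Plausible-value ranges used by validation (warn, never block):
# measured depletion in [−100, 100] %; MIT in (0, 5000] µg/mL.
DEPLETION_RANGE = (-100.0, 100.0)
MIT_RANGE = (0.0, HCLAT_MAX_TEST_CONC)  # exclusive low edge, inclusive high edge

# --------------------------------------------------------------------------
# Call lexicons (matched case-insensitively on the stripped cell text).
POSITIVE_TOKENS = frozenset({"p", "pos", "positive", "1", "a", "active", "sensitizer"})
NEGATIVE_TOKENS = frozenset({"n", "neg", "negative", "0", "i", "inactive", "non-sensitizer"})
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan"})
MIT_NEGATIVE_TOKENS = frozenset({"n", "neg", "negative", "inf"})
DOMAIN_IN_TOKENS = frozenset({"in", "id", "1", "t", "true", "yes", "in domain"})
DOMAIN_OUT_TOKENS = frozenset({"out", "od", "0", "f", "false", "no", "out of domain"})
POTENCY_TOKENS = {"1a": "1A", "1b": "1B", "nc": "NC", "not classified": "NC"}

# --------------------------------------------------------------------------
# Which endpoints satisfy each DA's information sources. A source requirement
# is met when ANY one alternative set is fully bound (e.g. a DPRA hazard call
# can be supplied directly or derived from the quantitative depletions; %Cys
# alone suffices via the Cys-only prediction model, %Lys alone does not).
DA_SOURCE_REQUIREMENTS: dict[DA, dict[str, tuple[frozenset[EndpointKey], ...]]] = {
    DA.TWO_OF_THREE: {
        "DPRA": (frozenset({EndpointKey.DPRA_CALL}), frozenset({EndpointKey.DPRA_CYS_PCT})),
        "h-CLAT": (frozenset({EndpointKey.HCLAT_CALL}), frozenset({EndpointKey.HCLAT_MIT})),
        "KeratinoSens": (frozenset({EndpointKey.KS_CALL}),),
    },
    DA.KE31STS: {
        "h-CLAT": (frozenset({EndpointKey.HCLAT_MIT}), frozenset({EndpointKey.HCLAT_CALL})),
        "DPRA": (frozenset({EndpointKey.DPRA_CALL}), frozenset({EndpointKey.DPRA_CYS_PCT})),
    },
    # The ITS runs with any two of its three sources; the requirement is
    # "at least two bound", enforced specially in check_bindings.
    DA.ITS: {
        "DPRA": (frozenset({EndpointKey.DPRA_CYS_PCT}),),
        "h-CLAT": (frozenset({EndpointKey.HCLAT_MIT}),),
        "in silico": (frozenset({EndpointKey.INSILICO_CALL}),),
    },
}

#: Minimum number of bound sources per DA (ITS tolerates one missing source).
DA_MIN_SOURCES: dict[DA, int] = {DA.TWO_OF_THREE: 3, DA.KE31STS: 2, DA.ITS: 2}

#: Endpoints that feed each DA source at run time (used to decide whether an
#: ERROR flag on a cell deprives that source for that row).
DA_SOURCE_ENDPOINTS: dict[DA, dict[str, frozenset[EndpointKey]]] = {
    DA.TWO_OF_THREE: {
        "DPRA": frozenset({EndpointKey.DPRA_CYS_PCT, EndpointKey.DPRA_LYS_PCT, EndpointKey.DPRA_CALL}),
        "h-CLAT": frozenset({EndpointKey.HCLAT_MIT, EndpointKey.HCLAT_CALL}),
        "KeratinoSens": frozenset({EndpointKey.KS_CALL}),
    },
    DA.KE31STS: {
        "h-CLAT": frozenset({EndpointKey.HCLAT_MIT, EndpointKey.HCLAT_CALL}),
        "DPRA": frozenset({EndpointKey.DPRA_CYS_PCT, EndpointKey.DPRA_LYS_PCT, EndpointKey.DPRA_CALL}),
    },
    DA.ITS: {
        "DPRA": frozenset({EndpointKey.DPRA_CYS_PCT, EndpointKey.DPRA_LYS_PCT}),
        "h-CLAT": frozenset({EndpointKey.HCLAT_MIT}),
        "in silico": frozenset({EndpointKey.INSILICO_CALL, EndpointKey.INSILICO_DOMAIN}),
    },
}


def rulebook_checksum() -> str:
    """Short digest of every decision constant, recorded in run logs/results."""
    payload = {
        "dpra_mean_neg_max": DPRA_MEAN_NEGATIVE_MAX,
        "dpra_cys_neg_max": DPRA_CYS_ONLY_NEGATIVE_MAX,
        "sts_mit_strong_max": STS_MIT_STRONG_MAX,
        "hclat_max_conc": HCLAT_MAX_TEST_CONC,
        "its_hclat_bands": ITS_HCLAT_MIT_BANDS,
        "its_dpra_mean_bands": ITS_DPRA_MEAN_BANDS,
        "its_dpra_cys_bands": ITS_DPRA_CYS_BANDS,
        "its_3source": ITS_POTENCY_3SOURCE,
        "its_2source": ITS_POTENCY_2SOURCE,
        "lexicons": [sorted(POSITIVE_TOKENS), sorted(NEGATIVE_TOKENS),
                     sorted(MISSING_TOKENS), sorted(MIT_NEGATIVE_TOKENS),
                     sorted(DOMAIN_IN_TOKENS), sorted(DOMAIN_OUT_TOKENS),
                     sorted(POTENCY_TOKENS.items())],
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
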