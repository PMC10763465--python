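import pytest
from hypothesis import given, settings, strategies as st

from dass import (
    Call,
    FlagCode,
    NEGATIVE_MIT,
    Severity,
    auto_map_columns,
    check_values,
    derive_dpra_call,
    dpra_mean,
    effective_mit,
    harmonize,
    parse_call,
    parse_mit,
)
from conftest import make_table

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestLexicons:
    @pytest.mark.parametrize("raw,expected", [
        ("Positive", Call.POSITIVE), ("p", Call.POSITIVE), ("1", Call.POSITIVE),
        ("A", Call.POSITIVE), ("sensitizer", Call.POSITIVE),
        ("0", Call.NEGATIVE), ("neg", Call.NEGATIVE), ("Inactive", Call.NEGATIVE),
        ("non-sensitizer", Call.NEGATIVE),
        ("", Call.MISSING), ("NA", Call.MISSING), ("n/a", Call.MISSING),
    ])
    def test_parse_call_lexicon(self, raw, expected):
        assert parse_call(raw) is expected

    @pytest.mark.parametrize("raw,expected", [
        ("10", 10.0), ("0.5", 0.5), (" 150 ", 150.0),
    ])
    def test_parse_mit_numeric(self, raw, expected):
        assert parse_mit(raw) == expected

    @pytest.mark.parametrize("raw", ["negative", "NEG", "n", "inf"])
    def test_parse_mit_negative_marker(self, raw):
        assert parse_mit(raw) is NEGATIVE_MIT

    def test_parse_mit_empty_is_missing(self):
        assert parse_mit("") is None


class TestDpraMean:
    @pytest.mark.parametrize("cys,lys,expected", [(0, 0, 0), (30.0, 10.0, 20.0), (-2.0, 6.0, 2.0)])
    def test_examples(self, cys, lys, expected):
        assert dpra_mean(cys, lys) == expected

    @given(a=finite, b=finite)
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_idempotent_on_diagonal(self, a, b):
        assert dpra_mean(a, b) == dpra_mean(b, a)
        assert dpra_mean(a, a) == a


class TestDeriveDpraCall:
    def test_zero_depletion_is_negative(self):
        assert derive_dpra_call(0.0, 0.0) is Call.NEGATIVE

    def test_mean_exactly_at_threshold_is_negative(self):
        # two-value model: mean ≤ 6.38 % → negative
        assert derive_dpra_call(6.38, 6.38) is Call.NEGATIVE
        assert derive_dpra_call(6.39, 6.39) is Call.POSITIVE

    def test_cys_only_model(self):
        assert derive_dpra_call(50.0, None) is Call.POSITIVE
        assert derive_dpra_call(13.89, None) is Call.NEGATIVE
        assert derive_dpra_call(13.90, None) is Call.POSITIVE

    def test_lys_only_has_no_model(self):
        assert derive_dpra_call(None, 80.0) is Call.MISSING
        assert derive_dpra_call(None, None) is Call.MISSING

    @given(cys=finite, lys=finite, bump=st.floats(min_value=0, max_value=50, allow_nan=False))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_either_depletion(self, cys, lys, bump):
        base = derive_dpra_call(cys, lys)
        if base is Call.POSITIVE:
            assert derive_dpra_call(cys + bump, lys) is Call.POSITIVE
            assert derive_dpra_call(cys, lys + bump) is Call.POSITIVE


class TestEffectiveMit:
    def test_rules(self):
        assert effective_mit(50.0) == 50.0
        assert effective_mit(NEGATIVE_MIT) is NEGATIVE_MIT
        assert effective_mit(None) is None
        assert effective_mit(6000.0) is NEGATIVE_MIT  # beyond max test concentration
        assert effective_mit(0.0) is None             # physically impossible


def _harmonized(rows):
    table = make_table(rows)
    cmap = auto_map_columns(table)
    flags = check_values(table, cmap)
    return harmonize(table, cmap, flags), flags


class TestHarmonize:
    def test_composes_translated_and_calculated_input(self):
        records, _ = _harmonized([{
            "chem_id": "A", "dpra_cys_pct": "30", "dpra_lys_pct": "10",
            "hclat_mit": "negative", "ks_call": "p",
        }])
        rec = records[0]
        assert rec.dpra_mean_pct == 20.0
        assert rec.dpra_call is Call.POSITIVE
        assert rec.hclat_mit is NEGATIVE_MIT
        assert rec.hclat_call is Call.NEGATIVE
        assert rec.ks_call is Call.POSITIVE

    def test_all_empty_row_is_all_missing(self):
        records, _ = _harmonized([{"chem_id": "X"}])
        rec = records[0]
        assert rec.dpra_call is rec.hclat_call is rec.ks_call is Call.MISSING
        assert rec.cys_pct is rec.lys_pct is rec.dpra_mean_pct is rec.hclat_mit is None

    def test_derived_call_beats_conflicting_user_call_with_warning(self):
        records, flags = _harmonized([{
            "chem_id": "A", "dpra_cys_pct": "30", "dpra_lys_pct": "10", "dpra_call": "n",
        }])
        assert records[0].dpra_call is Call.POSITIVE
        conflicts = [f for f in flags if f.code is FlagCode.CALL_CONFLICT]
        assert len(conflicts) == 1
        assert conflicts[0].severity is Severity.WARNING

    def test_agreeing_user_call_raises_no_conflict(self):
        records, flags = _harmonized([{
            "chem_id": "A", "dpra_cys_pct": "30", "dpra_lys_pct": "10", "dpra_call": "p",
        }])
        assert records[0].dpra_call is Call.POSITIVE
        assert not [f for f in flags if f.code is FlagCode.CALL_CONFLICT]

    def test_user_call_stands_in_when_quantitative_missing(self):
        records, _ = _harmonized([{"chem_id": "A", "dpra_call": "n"}])
        assert records[0].dpra_call is Call.NEGATIVE

    def test_error_flagged_cell_becomes_missing(self):
        records, flags = _harmonized([{"chem_id": "A", "dpra_cys_pct": "abc",
                                       "dpra_lys_pct": "40"}])
        rec = records[0]
        assert rec.cys_pct is None
        assert rec.lys_pct == 40.0
        assert rec.dpra_call is Call.MISSING  # no Lys-only prediction model

    def test_numeric_mit_forces_positive_call(self):
        records, _ = _harmonized([{"chem_id": "A", "hclat_mit": "12", "hclat_call": "p"}])
        assert records[0].hclat_call is Call.POSITIVE
        assert records[0].hclat_mit == 12.0

    def test_row_permutation_permutes_records(self):
        rows = [
            {"chem_id": "A", "dpra_cys_pct": "30", "dpra_lys_pct": "10"},
            {"chem_id": "B", "hclat_mit": "7"},
            {"chem_id": "C", "ks_call": "n"},
        ]
        fwd, _ = _harmonized(rows)
        rev, _ = _harmonized(rows[::-1])
        for a, b in zip(fwd, rev[::-1]):
            assert (a.chem_id, a.dpra_call, a.hclat_call, a.ks_call, a.dpra_mean_pct) == \
                   (b.chem_id, b.dpra_call, b.hclat_call, b.ks_call, b.dpra_mean_pct)
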