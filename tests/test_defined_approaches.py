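import itertools

import numpy as np
import pytest

from dass import (
    DA,
    Blocked,
    Call,
    Hazard,
    ITSScheme,
    ITSScores,
    NEGATIVE_MIT,
    PotencyClass,
    RawTable,
    analyze_table,
    predict_2o3,
    predict_its,
    predict_sts,
    score_its_dpra,
    score_its_hclat,
    score_its_insilico,
)
from dass._reference import ref_2o3, ref_its
from conftest import make_table

CALLS = (Call.POSITIVE, Call.NEGATIVE, Call.MISSING)
_CALL_TO_REF = {Call.POSITIVE: "pos", Call.NEGATIVE: "neg", Call.MISSING: "missing"}


class TestTwoOfThree:
    @pytest.mark.parametrize("calls,expected", [
        ((Call.POSITIVE, Call.POSITIVE, Call.NEGATIVE), Hazard.SENSITIZER),
        ((Call.POSITIVE, Call.NEGATIVE, Call.MISSING), Hazard.INCONCLUSIVE),
        ((Call.NEGATIVE, Call.NEGATIVE, Call.NEGATIVE), Hazard.NON_SENSITIZER),
        ((Call.MISSING, Call.MISSING, Call.POSITIVE), Hazard.INCONCLUSIVE),
    ])
    def test_concordance_rule(self, calls, expected):
        assert predict_2o3(*calls).hazard is expected

    def test_never_predicts_potency(self):
        for calls in itertools.product(CALLS, repeat=3):
            assert predict_2o3(*calls).potency is PotencyClass.NOT_APPLICABLE

    def test_matches_majority_vote_oracle_on_full_grid(self):
        for calls in itertools.product(CALLS, repeat=3):
            expected = ref_2o3(*(_CALL_TO_REF[c] for c in calls))
            assert predict_2o3(*calls).hazard.value == expected, calls

    def test_invariant_under_all_argument_orders(self):
        for calls in itertools.product(CALLS, repeat=3):
            outcomes = {predict_2o3(*perm).hazard for perm in itertools.permutations(calls)}
            assert len(outcomes) == 1, calls


class TestSts:
    def test_positive_hclat_settles_without_dpra(self):
        pred = predict_sts(5.0, Call.MISSING)
        assert (pred.hazard, pred.potency) == (Hazard.SENSITIZER, PotencyClass.GHS_1A)

    def test_mit_cutoff_between_1a_and_1b(self):
        assert predict_sts(10.0, Call.MISSING).potency is PotencyClass.GHS_1A
        assert predict_sts(10.01, Call.MISSING).potency is PotencyClass.GHS_1B

    def test_negative_hclat_defers_to_dpra(self):
        assert predict_sts(NEGATIVE_MIT, Call.POSITIVE).potency is PotencyClass.GHS_1B
        pred = predict_sts(NEGATIVE_MIT, Call.NEGATIVE)
        assert (pred.hazard, pred.potency) == (Hazard.NON_SENSITIZER, PotencyClass.NC)
        assert predict_sts(NEGATIVE_MIT, Call.MISSING).hazard is Hazard.INCONCLUSIVE

    def test_missing_hclat_cannot_start_the_sequence(self):
        assert predict_sts(None, Call.POSITIVE).hazard is Hazard.INCONCLUSIVE

    def test_positive_call_without_mit_gives_hazard_but_not_potency(self):
        pred = predict_sts(None, Call.MISSING, hclat_call=Call.POSITIVE)
        assert (pred.hazard, pred.potency) == (Hazard.SENSITIZER, PotencyClass.INCONCLUSIVE)

    def test_negative_call_without_mit_defers_to_dpra(self):
        pred = predict_sts(None, Call.POSITIVE, hclat_call=Call.NEGATIVE)
        assert (pred.hazard, pred.potency) == (Hazard.SENSITIZER, PotencyClass.GHS_1B)

    def test_dpra_invariance_under_positive_hclat(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            mit = float(np.exp(rng.uniform(np.log(0.1), np.log(5000.0))))
            outcomes = {
                (predict_sts(mit, dpra).hazard, predict_sts(mit, dpra).potency)
                for dpra in CALLS
            }
            assert len(outcomes) == 1


class TestItsScoring:
    @pytest.mark.parametrize("mit,score", [
        (NEGATIVE_MIT, 0), (5.0, 3), (10.0, 3), (10.01, 2), (150.0, 2),
        (150.01, 1), (4000.0, 1), (5000.0, 1), (None, None),
    ])
    def test_hclat_bands(self, mit, score):
        assert score_its_hclat(mit) == score

    def test_nonpositive_mit_is_a_domain_error(self):
        with pytest.raises(ValueError):
            score_its_hclat(0.0)

    @pytest.mark.parametrize("cys,lys,score,scheme", [
        (0.0, 0.0, 0, ITSScheme.TWO_VALUE_DPRA),
        (60.0, 40.0, 3, ITSScheme.TWO_VALUE_DPRA),       # mean 50 ≥ 42.47
        (42.47, 42.47, 3, ITSScheme.TWO_VALUE_DPRA),
        (42.46, 42.46, 2, ITSScheme.TWO_VALUE_DPRA),
        (6.38, 6.38, 1, ITSScheme.TWO_VALUE_DPRA),
        (6.37, 6.37, 0, ITSScheme.TWO_VALUE_DPRA),
        (15.0, None, 1, ITSScheme.CYS_ONLY_DPRA),
        (13.88, None, 0, ITSScheme.CYS_ONLY_DPRA),
        (98.24, None, 3, ITSScheme.CYS_ONLY_DPRA),
        (None, 80.0, None, ITSScheme.NO_DPRA),
        (None, None, None, ITSScheme.NO_DPRA),
    ])
    def test_dpra_bands_and_schemes(self, cys, lys, score, scheme):
        assert score_its_dpra(cys, lys) == (score, scheme)

    @pytest.mark.parametrize("call,domain,score", [
        (Call.POSITIVE, True, 1), (Call.NEGATIVE, True, 0),
        (Call.POSITIVE, False, None), (Call.POSITIVE, None, 1),
        (Call.MISSING, True, None),
    ])
    def test_insilico_score_with_domain_gating(self, call, domain, score):
        assert score_its_insilico(call, domain) == score


def _grid_scores():
    for d in (0, 1, 2, 3, None):
        for h in (0, 1, 2, 3, None):
            for s in (0, 1, None):
                yield ITSScores(dpra_score=d, hclat_score=h, insilico_score=s,
                                scheme=ITSScheme.TWO_VALUE_DPRA if d is not None
                                else ITSScheme.NO_DPRA)


class TestItsPrediction:
    def test_top_and_bottom_of_three_source_table(self):
        top = predict_its(ITSScores(3, 3, 1, ITSScheme.TWO_VALUE_DPRA))
        assert (top.potency, top.its_total) == (PotencyClass.GHS_1A, 7)
        bottom = predict_its(ITSScores(0, 0, 0, ITSScheme.TWO_VALUE_DPRA))
        assert (bottom.hazard, bottom.potency) == (Hazard.NON_SENSITIZER, PotencyClass.NC)

    def test_two_source_example_without_insilico(self):
        pred = predict_its(ITSScores(2, 1, None, ITSScheme.TWO_VALUE_DPRA))
        assert (pred.potency, pred.its_source_count) == (PotencyClass.GHS_1B, 2)

    def test_fewer_than_two_sources_is_inconclusive(self):
        pred = predict_its(ITSScores(3, None, None, ITSScheme.TWO_VALUE_DPRA))
        assert pred.hazard is Hazard.INCONCLUSIVE
        assert "insufficient sources" in pred.rationale

    def test_matches_interval_propagation_oracle_on_score_grid(self):
        for scores in _grid_scores():
            expected = ref_its(scores.dpra_score, scores.hclat_score, scores.insilico_score)
            pred = predict_its(scores)
            got = (pred.hazard.value, pred.potency.value if pred.its_total is not None
                   else "Inconclusive", pred.its_total)
            assert got == expected, scores

    def test_score_bounds_and_total_coherence(self):
        for scores in _grid_scores():
            pred = predict_its(scores)
            if pred.its_total is None:
                continue
            assert pred.its_total == scores.total
            assert 0 <= pred.its_total <= (7 if scores.available == 3 else 6)

    def test_hazard_potency_coherence(self):
        for scores in _grid_scores():
            pred = predict_its(scores)
            if pred.potency is PotencyClass.ONE_STAR:
                assert pred.hazard is Hazard.SENSITIZER
            if pred.hazard is Hazard.NON_SENSITIZER:
                assert pred.potency is PotencyClass.NC
            if pred.potency in (PotencyClass.GHS_1A, PotencyClass.GHS_1B):
                assert pred.hazard is Hazard.SENSITIZER


class TestRunDass:
    def test_clean_record_gets_all_three_predictions(self, small_table):
        results = analyze_table(small_table, [DA.TWO_OF_THREE, DA.KE31STS, DA.ITS])
        row = results.predictions[1]  # chemical B: complete, clean
        assert not any(isinstance(p, Blocked) for p in row.values())
        assert row[DA.KE31STS].potency is PotencyClass.GHS_1A  # MIT 5 ≤ 10

    def test_empty_record_is_inconclusive_everywhere(self, small_table):
        row = analyze_table(small_table, [DA.TWO_OF_THREE, DA.KE31STS, DA.ITS]).predictions[2]
        for pred in row.values():
            assert not isinstance(pred, Blocked)
            assert pred.hazard is Hazard.INCONCLUSIVE

    def test_error_blocks_only_the_das_it_deprives(self):
        # corrupted %Cys: the ITS loses its DPRA source, but 2o3 still has a
        # user-supplied DPRA call and STS has a positive h-CLAT
        table = make_table([{
            "chem_id": "A", "dpra_cys_pct": "abc", "dpra_call": "p",
            "hclat_mit": "8", "ks_call": "n", "insilico_call": "p", "insilico_domain": "in",
        }])
        row = analyze_table(table, [DA.TWO_OF_THREE, DA.KE31STS, DA.ITS]).predictions[0]
        assert isinstance(row[DA.ITS], Blocked)
        assert not isinstance(row[DA.TWO_OF_THREE], Blocked)
        assert not isinstance(row[DA.KE31STS], Blocked)

    def test_corrupt_lys_degrades_its_to_cys_only_scheme(self):
        table = make_table([{
            "chem_id": "A", "dpra_cys_pct": "50", "dpra_lys_pct": "oops",
            "hclat_mit": "negative", "insilico_call": "n", "insilico_domain": "in",
        }])
        results = analyze_table(table, [DA.ITS])
        pred = results.predictions[0][DA.ITS]
        assert not isinstance(pred, Blocked)
        scheme_col = results.header.index("calc_its_scheme")
        assert results.rows[0][scheme_col] == ITSScheme.CYS_ONLY_DPRA.value

    def test_missing_required_column_blocks_the_whole_da(self):
        table = RawTable(header=["chem_id", "ks_call"], rows=[["A", "p"]])
        row = analyze_table(table, [DA.TWO_OF_THREE]).predictions[0]
        assert isinstance(row[DA.TWO_OF_THREE], Blocked)

    def test_out_of_domain_insilico_drops_to_two_sources(self):
        table = make_table([{
            "chem_id": "A", "dpra_cys_pct": "60", "dpra_lys_pct": "40",
            "hclat_mit": "negative", "insilico_call": "p", "insilico_domain": "out",
        }])
        pred = analyze_table(table, [DA.ITS]).predictions[0][DA.ITS]
        assert pred.its_source_count == 2
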