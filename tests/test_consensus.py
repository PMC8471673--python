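"""Five-tool verdicts, the at-most-one-dissent consensus, and its overrides."""

import itertools

import numpy as np
import pytest

from aldoprio.consensus import (
    TOOLS,
    ToolVerdict,
    classify_table,
    consensus_call,
    retained_sample_counts,
    tool_verdicts,
)
from aldoprio.models import GeneCutoffs

from oracles import consensus_route_oracle, random_variant
from test_variant_model import make_variant


def by_sample(table, sample_id):
    return next(r for r in table if r.sample_id == sample_id)


def verdict_map(verdicts):
    return {v.tool: v.verdict for v in verdicts}


class TestToolVerdicts:
    def test_single_dissent_missense(self, table1, cutoffs):
        # ATP2B3 Phe868Leu: benign PolyPhen-2 category is the only dissent
        rec = by_sample(table1, "NGS04")
        vm = verdict_map(tool_verdicts(rec, cutoffs["ATP2B3"]))
        assert vm == {
            "CADD": "damaging",
            "MSC_CADD": "damaging",
            "PP2": "not_damaging",
            "MSC_PP2": "damaging",
            "SIFT": "not_applicable",
        }

    def test_nonsense_with_tolerated_sift(self, table1, cutoffs):
        # CACNA1H Trp482Ter: no PolyPhen-2 input, SIFT 0.17 tolerated
        rec = by_sample(table1, "NGS18")
        vm = verdict_map(tool_verdicts(rec, cutoffs["CACNA1H"]))
        assert vm == {
            "CADD": "damaging",
            "MSC_CADD": "damaging",
            "PP2": "not_applicable",
            "MSC_PP2": "not_applicable",
            "SIFT": "not_damaging",
        }

    def test_all_scores_absent_gives_five_not_applicable(self, cutoffs):
        rec = make_variant(cadd=None, pp2_score=None, pp2_category=None,
                           sift_score=None)
        vm = verdict_map(tool_verdicts(rec, cutoffs["CACNA1D"]))
        assert set(vm.values()) == {"not_applicable"}

    def test_cutoff_boundaries_inclusive_for_damaging(self, cutoffs):
        cut = cutoffs["CACNA1D"]
        rec = make_variant(cadd=20.0, pp2_score=cut.msc_pp2, sift_score=0.05)
        vm = verdict_map(tool_verdicts(rec, cut))
        assert vm["CADD"] == "damaging"
        assert vm["MSC_PP2"] == "damaging"
        assert vm["SIFT"] == "damaging"

    def test_gene_mismatch_raises(self, cutoffs):
        with pytest.raises(ValueError, match="gene"):
            tool_verdicts(make_variant(), cutoffs["CLCN2"])


def verdicts_from_codes(codes):
    states = ("damaging", "not_damaging", "not_applicable")
    return tuple(
        ToolVerdict(tool, states[code], basis="enumerated")
        for tool, code in zip(TOOLS, codes)
    )


class TestConsensusCall:
    def test_one_dissent_is_retained_as_novel(self, table1, cutoffs):
        rec = by_sample(table1, "NGS04")
        call = consensus_call(rec, tool_verdicts(rec, cutoffs["ATP2B3"]))
        assert (call.route, call.final, call.dissent_count) == (
            "consensus_novel", "retained", 1,
        )

    def test_nonsense_retained_via_null_route(self, table1, cutoffs):
        rec = by_sample(table1, "NGS18")
        call = consensus_call(rec, tool_verdicts(rec, cutoffs["CACNA1H"]))
        assert (call.route, call.final) == ("null_variant", "retained")

    def test_three_dissents_rejected(self, cutoffs):
        rec = make_variant(cadd=30.0, pp2_score=0.1, pp2_category="benign",
                           sift_score=0.8)
        call = consensus_call(rec, tool_verdicts(rec, cutoffs["CACNA1D"]))
        assert (call.route, call.final, call.dissent_count) == (
            "rejected", "excluded", 3,
        )

    def test_disease_db_overrides_dissents(self, cutoffs):
        rec = make_variant(cadd=30.0, pp2_score=0.1, pp2_category="benign",
                           sift_score=0.8, in_disease_db=True)
        call = consensus_call(rec, tool_verdicts(rec, cutoffs["CACNA1D"]))
        assert (call.route, call.final) == ("disease_db", "retained")

    def test_exhaustive_enumeration_matches_oracle(self):
        """All 3^5 verdict combinations x disease-db x null-consequence."""
        for codes in itertools.product(range(3), repeat=5):
            verdicts = verdicts_from_codes(codes)
            dissents = sum(c == 1 for c in codes)
            for in_db in (False, True):
                for is_null in (False, True):
                    rec = make_variant(
                        consequence="nonsense" if is_null else "missense",
                        protein_change="Gln9Ter" if is_null else "Leu9Ile",
                        in_disease_db=in_db,
                    )
                    call = consensus_call(rec, verdicts)
                    assert call.route == consensus_route_oracle(
                        in_db, is_null, dissents
                    )
                    assert call.dissent_count == dissents
                    assert (call.final == "retained") == (call.route != "rejected")

    def test_dissent_to_not_applicable_never_rejects(self):
        """Turning a dissenting vote into a missing input cannot flip a
        retained call to rejected (missing inputs are neutral)."""
        for codes in itertools.product(range(3), repeat=5):
            rec = make_variant()
            call = consensus_call(rec, verdicts_from_codes(codes))
            for i, code in enumerate(codes):
                if code != 1:
                    continue
                relaxed = list(codes)
                relaxed[i] = 2
                relaxed_call = consensus_call(rec, verdicts_from_codes(relaxed))
                assert relaxed_call.dissent_count == call.dissent_count - 1
                if call.final == "retained":
                    assert relaxed_call.final == "retained"

    def test_configurable_dissent_threshold(self):
        rec = make_variant()
        verdicts = verdicts_from_codes((0, 0, 1, 1, 0))  # two dissents
        assert consensus_call(rec, verdicts).route == "rejected"
        assert consensus_call(rec, verdicts, dissent_threshold=2).route == "consensus_novel"

    def test_determinism(self, table1, cutoffs):
        calls_a = classify_table(table1, cutoffs)
        calls_b = classify_table(table1, cutoffs)
        assert calls_a == calls_b


class TestClassifyTable:
    def test_published_set_fully_retained(self, table1, cutoffs):
        calls = classify_table(table1, cutoffs)
        assert len(calls) == 21
        assert all(c.final == "retained" for c in calls)

    def test_per_gene_retained_sample_counts(self, table1, cutoffs):
        counts = retained_sample_counts(classify_table(table1, cutoffs))
        assert counts == {
            "CACNA1D": 9, "CACNA1H": 5, "ATP2B3": 3,
            "CLCN2": 2, "ATP1A1": 1, "CTNNB1": 1,
        }

    def test_empty_table_empty_output(self, cutoffs):
        from aldoprio.models import VariantTable

        assert classify_table(VariantTable(), cutoffs) == []

    def test_random_variants_always_get_exactly_five_verdicts(self, cutoffs):
        rng = np.random.default_rng(3)
        full = dict(cutoffs)
        full["KCNJ5"] = GeneCutoffs(gene="KCNJ5", msc_cadd=5.0, msc_pp2=0.3)
        for i in range(200):
            rec = random_variant(rng, f"S{i}", 10_000 + i)
            verdicts = tool_verdicts(rec, full[rec.gene])
            assert len(verdicts) == 5
            call = consensus_call(rec, verdicts)
            assert 0 <= call.dissent_count <= 5
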