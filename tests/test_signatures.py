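import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trialomics.signatures import (
    assign_quartiles,
    classify_carriers,
    classify_tmb,
    derive_signatures,
    evaluate_signature,
    stratify_by_pathway,
    summarize_alterations,
)


def brute_force_signatures(records: pd.DataFrame, q1_ids, q4_ids):
    """Literal double loop over genes x patients: the derivation oracle."""
    res, sens = set(), set()
    genes = set(records["gene"])
    for g in genes:
        in_q1 = any(
            ((records["patient_id"] == p) & (records["gene"] == g)).any()
            for p in q1_ids
        )
        in_q4 = any(
            ((records["patient_id"] == p) & (records["gene"] == g)).any()
            for p in q4_ids
        )
        if in_q1 and not in_q4:
            res.add(g)
        if in_q4 and not in_q1:
            sens.add(g)
    return res, sens


class TestAssignQuartiles:
    def make_clinical(self, clinical_frame, n, times=None, events=None, ids=None):
        ids = ids or [f"P{i:02d}" for i in range(n)]
        times = times if times is not None else list(range(1, n + 1))
        events = events if events is not None else [True] * n
        return clinical_frame(
            [(ids[i], "MSS", "mut", "wt", times[i], events[i], "PR") for i in range(n)]
        )

    def test_group_sizes_for_49(self, clinical_frame):
        q = assign_quartiles(self.make_clinical(clinical_frame, 49), None)
        assert q.sizes == {"Q1": 12, "Q2": 13, "Q3": 12, "Q4": 12}

    @pytest.mark.parametrize("n,expected", [
        (8, (2, 2, 2, 2)), (9, (2, 3, 2, 2)), (10, (2, 3, 3, 2)),
        (11, (2, 4, 3, 2)), (12, (3, 3, 3, 3)), (55, (13, 15, 14, 13)),
    ])
    def test_remainder_rule(self, clinical_frame, n, expected):
        q = assign_quartiles(self.make_clinical(clinical_frame, n), None)
        assert tuple(q.sizes[k] for k in ("Q1", "Q2", "Q3", "Q4")) == expected

    def test_rank_partition_small(self, clinical_frame):
        q = assign_quartiles(self.make_clinical(clinical_frame, 8), None)
        assert set(q.patients("Q1")) == {"P00", "P01"}
        assert set(q.patients("Q4")) == {"P06", "P07"}

    def test_tie_break_event_first_then_id(self, clinical_frame):
        # two patients tied at the Q1/Q2 boundary: the observed event
        # outranks the censored one; among equals the id decides
        times = [1, 2, 3, 3, 5, 6, 7, 8, 9]
        events = [True, True, False, True, True, True, True, True, True]
        table = self.make_clinical(clinical_frame, 9, times, events)
        q = assign_quartiles(table, None)
        # ranks: P00, P01, then at t=3 the event (P03) before the censored (P02)
        assert q.patients("Q1") == ["P00", "P01"]
        assert q.patients("Q2")[0] == "P03"
        # deterministic across repeated calls and row permutations
        shuffled = table.data.sample(frac=1, random_state=3).reset_index(drop=True)
        from trialomics.io import ClinicalTable
        q2 = assign_quartiles(ClinicalTable(shuffled), None)
        assert q.labels.sort_index().equals(q2.labels.sort_index())

    def test_small_subcohort_refused(self, clinical_frame):
        with pytest.raises(ValueError, match=">= 8"):
            assign_quartiles(self.make_clinical(clinical_frame, 7), None)


class TestDeriveSignatures:
    def test_set_difference_by_definition(self, clinical_frame, alteration_frame):
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1, True, "PR") for i in range(8)]
        )
        q = assign_quartiles(table, None)  # Q1={P0,P1}, Q4={P6,P7}
        alt = alteration_frame([
            ("P0", "A", "SNV"), ("P1", "B", "CNV"), ("P0", "C", "SNV"),
            ("P6", "C", "LOH"), ("P7", "D", "INDEL"),
        ])
        res, sens = derive_signatures(alt, q)
        assert res == {"A", "B"}
        assert sens == {"D"}  # C altered in both quartiles joins neither

    def test_no_alterations_empty_signature(self, clinical_frame, alteration_frame):
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1, True, "PR") for i in range(8)]
        )
        q = assign_quartiles(table, None)
        alt = alteration_frame([("P3", "X", "SNV")])  # only middle quartiles
        res, sens = derive_signatures(alt, q)
        assert res == frozenset() and sens == frozenset()

    def test_exhaustive_small_instances_match_brute_force(
        self, clinical_frame, alteration_frame
    ):
        # all alteration patterns of 8 patients x 3 genes (2^... sampled
        # exhaustively over gene-presence per quartile-relevant patients)
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1, True, "PR") for i in range(8)]
        )
        q = assign_quartiles(table, None)
        rng = np.random.default_rng(0)
        genes = [f"G{j}" for j in range(12)]
        for _ in range(30):
            records = [
                (f"P{i}", g, "SNV")
                for i in range(8)
                for g in genes
                if rng.random() < 0.3
            ]
            if not records:
                continue
            alt = alteration_frame(records)
            res, sens = derive_signatures(alt, q)
            b_res, b_sens = brute_force_signatures(
                alt.records, q.patients("Q1"), q.patients("Q4")
            )
            assert res == b_res and sens == b_sens
            assert not (res & sens)

    def test_patient_order_invariance(self, cohort):
        sub = list(cohort.clinical.data.loc[
            cohort.clinical.data.msi_status == "MSS", "patient_id"])
        q = assign_quartiles(cohort.clinical, sub)
        res1, sens1 = derive_signatures(cohort.alterations, q)
        from trialomics.io import AlterationTable
        shuffled = AlterationTable(
            cohort.alterations.records.sample(frac=1, random_state=9).reset_index(drop=True),
            cohort.alterations.tmb,
        )
        res2, sens2 = derive_signatures(shuffled, q)
        assert res1 == res2 and sens1 == sens2


class TestCarriersAndEvaluation:
    def test_carrier_rules(self, alteration_frame):
        alt = alteration_frame([("P1", "A", "SNV"), ("P2", "X", "CNV")])
        flags = classify_carriers(alt, {"A", "B"}, ["P1", "P2", "P3"])
        assert flags.tolist() == [True, False, False]
        empty = classify_carriers(alt, set(), ["P1", "P2"])
        assert not empty.any()

    def test_identical_flags_degenerate(self, clinical_frame):
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1, True, "PR") for i in range(4)]
        )
        flags = pd.Series(True, index=[f"P{i}" for i in range(4)])
        comp = evaluate_signature(table, flags)
        assert comp.degenerate and comp.logrank is None

    def test_toy_matches_logrank_module(self, clinical_frame):
        table = clinical_frame([
            ("P0", "MSS", "mut", "wt", 2.0, True, "PR"),
            ("P1", "MSS", "mut", "wt", 4.0, True, "PR"),
            ("P2", "MSS", "mut", "wt", 9.0, True, "PR"),
            ("P3", "MSS", "mut", "wt", 12.0, False, "PR"),
        ])
        flags = pd.Series([True, True, False, False], index=["P0", "P1", "P2", "P3"])
        comp = evaluate_signature(table, flags)
        from trialomics.survival import logrank_test
        ref = logrank_test([(2, True), (4, True)], [(9, True), (12, False)])
        assert comp.logrank.chi_square == pytest.approx(ref.chi_square)
        # S(2) = 0.5 already satisfies the <= 0.5 median rule
        assert comp.median_positive == 2.0
        assert comp.median_negative == 9.0

    def test_holdout_removes_only_positive_quartile_patients(
        self, clinical_frame
    ):
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1, True, "PR") for i in range(8)]
        )
        q = assign_quartiles(table, None)  # Q1 = {P0, P1}
        ids = [f"P{i}" for i in range(8)]
        flags = pd.Series([True, False, True, False, True, False, True, False], index=ids)
        comp = evaluate_signature(table, flags, "drop_Q1_positives", q)
        # P0 (Q1, positive) dropped; P1 (Q1, negative) retained
        assert comp.n_positive == 3
        assert comp.n_negative == 4


class TestTMBAndPathway:
    def test_cutoff_boundary_inclusive(self):
        tmb = pd.Series([10.4, 6.71, 35.57, 0.95], index=list("abcd"))
        cls = classify_tmb(tmb)
        assert cls.labels.tolist() == ["high", "low", "high", "low"]

    def test_missing_tmb_names_patient(self):
        tmb = pd.Series([5.0, np.nan], index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            classify_tmb(tmb)

    def test_disjoint_pathway_all_wt(self, clinical_frame, alteration_frame):
        table = clinical_frame(
            [(f"P{i}", "MSS", "mut", "wt", i + 1.0, True, "PR") for i in range(4)]
        )
        alt = alteration_frame(
            [(f"P{i}", "KRAS", "SNV") for i in range(4)],
            tmb=pd.Series([5, 5, 15, 15.0], index=[f"P{i}" for i in range(4)]),
        )
        strat = stratify_by_pathway(alt, {"PIK3CA"}, table)
        assert (strat.labels == "WT").all()
        assert strat.fisher_degenerate and strat.fisher_p == 1.0

    def test_fisher_table_enumeration(self, clinical_frame, alteration_frame):
        # 2x2 (3,1;1,3): two-sided Fisher p = 0.48571...
        ids = [f"P{i}" for i in range(8)]
        table = clinical_frame(
            [(p, "MSS", "mut", "wt", i + 1.0, True, "PR") for i, p in enumerate(ids)]
        )
        # MUT patients: P0-P3; TMB high: P0,P1,P2 (MUT) + P4 (WT)
        tmb = pd.Series([20, 20, 20, 5, 20, 5, 5, 5.0], index=ids)
        alt = alteration_frame([(p, "PIK3CA", "SNV") for p in ids[:4]]
                               + [(p, "KRAS", "SNV") for p in ids[4:]], tmb=tmb)
        strat = stratify_by_pathway(alt, {"PIK3CA"}, table)
        assert strat.contingency.tolist() == [[3, 1], [1, 3]]
        assert strat.fisher_p == pytest.approx(0.485714285714, rel=1e-9)

    def test_extreme_table_smallest_p(self, clinical_frame, alteration_frame):
        ids = [f"P{i}" for i in range(8)]
        table = clinical_frame(
            [(p, "MSS", "mut", "wt", i + 1.0, True, "PR") for i, p in enumerate(ids)]
        )
        tmb = pd.Series([20, 20, 20, 20, 5, 5, 5, 5.0], index=ids)
        alt = alteration_frame([(p, "PIK3CA", "SNV") for p in ids[:4]]
                               + [(p, "KRAS", "SNV") for p in ids[4:]], tmb=tmb)
        strat = stratify_by_pathway(alt, {"PIK3CA"}, table)
        # most extreme table for these margins: p = 2/C(8,4) = 1/35
        assert strat.fisher_p == pytest.approx(2 / 70, rel=1e-9)


class TestSummarize:
    def test_empty_and_small_tables(self, alteration_frame):
        alt = alteration_frame([
            ("P1", "A", "SNV"), ("P1", "B", "CNV"), ("P1", "C", "LOH"),
            ("P2", "A", "SNV"), ("P2", "D", "INDEL"), ("P2", "E", "SNV"),
        ])
        s = summarize_alterations(alt)
        assert s["mean_per_patient"] == 3.0
        assert s["n_genes"] == 5
        assert s["n_SNV"] == 3 and s["n_LOH"] == 1

    def test_duplicate_record_counted_once(self, alteration_frame):
        alt = alteration_frame([("P1", "A", "SNV"), ("P1", "A", "SNV")])
        assert summarize_alterations(alt)["n_alterations"] == 1
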