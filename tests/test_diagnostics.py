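"""Paired diagnostic statistics: tables, exact CIs, McNemar, Fisher, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from scipy.stats import hypergeom

from csflmd.diagnostics import (
    Confusion,
    PairedDiagnosticTable,
    SampleRecord,
    build_tables,
    clopper_pearson,
    diagnostic_metrics,
    fisher_exact,
    group_summaries,
    mcnemar_asymptotic,
    mcnemar_exact,
    route_association,
)


def study_records():
    """The published paired outcomes: among 43 LMD samples 30 both-positive,
    10 cfDNA-only-positive, 1 cytology-only-positive, 2 both-negative; plus
    5 PT samples negative on both tests; 3 PTACSF samples cfDNA-positive."""
    recs = []
    i = 0

    def add(n, group, cyto, cfdna):
        nonlocal i
        for _ in range(n):
            recs.append(
                SampleRecord(
                    sample_id=f"S{i:03d}", patient_id=f"P{i:03d}", group=group,
                    cytology=cyto, cfdna_call=cfdna,
                )
            )
            i += 1

    add(30, "LMD", "positive", "positive")
    add(10, "LMD", "negative", "positive")
    add(1, "LMD", "positive", "negative")
    add(2, "LMD", "negative", "negative")
    add(5, "PT", "negative", "negative")
    add(3, "PTACSF", "negative", "positive")
    return recs


class TestBuildTables:
    def test_study_counts_confusions(self):
        conf, paired = build_tables(study_records(), exclude_ptacsf=True)
        assert conf["cfdna"] == Confusion(tp=40, fp=0, fn=3, tn=5)
        assert conf["cytology"] == Confusion(tp=31, fp=0, fn=12, tn=5)
        assert (paired.a, paired.b, paired.c, paired.d) == (30, 10, 1, 7)
        assert paired.n == 48

    def test_ptacsf_included_as_false_positives(self):
        conf, _ = build_tables(study_records(), exclude_ptacsf=False)
        assert conf["cfdna"].fp == 3
        assert conf["cfdna"].tn == 5

    def test_all_ptacsf_with_exclusion_raises(self):
        recs = [
            SampleRecord(f"S{i}", f"P{i}", "PTACSF", cytology="negative",
                         cfdna_call="positive")
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="empty cohort"):
            build_tables(recs, exclude_ptacsf=True)

    def test_missing_field_names_sample(self):
        recs = study_records()
        recs[7].cfdna_call = None
        with pytest.raises(ValueError, match="S007"):
            build_tables(recs)


class TestDiagnosticMetrics:
    def test_cfdna_column_of_published_table(self):
        m = diagnostic_metrics(Confusion(tp=40, fp=0, fn=3, tn=5))
        assert m.sensitivity.display() == "0.93 (0.81-0.99)"
        assert m.specificity.display() == "1.00 (0.48-1.00)"
        assert m.ppv.display() == "1.00 (0.91-1.00)"
        assert m.npv.display() == "0.63 (0.24-0.91)"
        assert m.accuracy.display() == "0.94 (0.83-0.99)"

    def test_cytology_column_of_published_table(self):
        m = diagnostic_metrics(Confusion(tp=31, fp=0, fn=12, tn=5))
        assert m.sensitivity.display() == "0.72 (0.56-0.85)"
        assert m.specificity.display() == "1.00 (0.48-1.00)"
        assert m.ppv.display() == "1.00 (0.89-1.00)"
        assert m.npv.display() == "0.29 (0.10-0.56)"
        assert m.accuracy.display() == "0.75 (0.60-0.86)"

    def test_perfect_classifier(self):
        m = diagnostic_metrics(Confusion(tp=10, fp=0, fn=0, tn=0))
        assert m.sensitivity.point == 1.0 and m.ppv.point == 1.0
        assert m.accuracy.point == 1.0
        assert not m.specificity.defined and not m.npv.defined

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_metric_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = diagnostic_metrics(Confusion(tp, fp, fn, tn))
        if m.accuracy.defined:
            assert m.accuracy.point * (tp + fp + fn + tn) == pytest.approx(tp + tn)
        if m.sensitivity.defined:
            assert m.sensitivity.point * (tp + fn) == pytest.approx(tp)


class TestClopperPearson:
    def test_five_of_five_closed_form(self):
        lo, hi = clopper_pearson(5, 5)
        assert lo == pytest.approx(0.025 ** (1 / 5), abs=1e-12)
        assert hi == 1.0

    def test_forty_of_fortythree_rounds_to_printed_interval(self):
        lo, hi = clopper_pearson(40, 43)
        assert round(lo, 2) == 0.81 and round(hi, 2) == 0.99

    def test_zero_successes_lower_bound_exact_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_intervals_nest_with_confidence(self):
        lo95, hi95 = clopper_pearson(7, 20, alpha=0.05)
        lo99, hi99 = clopper_pearson(7, 20, alpha=0.01)
        assert lo99 < lo95 and hi99 > hi95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(3, 2)
        with pytest.raises(ValueError):
            clopper_pearson(1, 2, alpha=1.5)


class TestMcNemar:
    def test_published_discordant_counts(self):
        # 10 cfDNA-only vs 1 cytology-only discordant samples
        p = mcnemar_exact(10, 1)
        assert p == pytest.approx(0.01171875, abs=1e-12)

    def test_symmetric_discordance_is_one(self):
        for k in (1, 4, 9):
            assert mcnemar_exact(k, k) == 1.0

    def test_three_zero_hand_enumeration(self):
        assert mcnemar_exact(3, 0) == pytest.approx(0.25, abs=1e-12)

    def test_no_discordance_convention(self):
        assert mcnemar_exact(0, 0) == 1.0

    @given(b=st.integers(0, 25), c=st.integers(0, 25))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_symmetry_and_range(self, b, c):
        p = mcnemar_exact(b, c)
        assert p == mcnemar_exact(c, b)
        assert 0 < p <= 1

    @given(b=st.integers(0, 20), c=st.integers(0, 20))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_exact_matches_binomial_enumeration(self, b, c):
        n = b + c
        if n == 0:
            return
        k = max(b, c)
        tail = sum(comb(n, j, exact=True) for j in range(k, n + 1)) / 2**n
        assert mcnemar_exact(b, c) == pytest.approx(min(1.0, 2 * tail), abs=1e-12)

    def test_asymptotic_agrees_roughly_for_moderate_counts(self):
        assert mcnemar_asymptotic(10, 1) == pytest.approx(0.0159, abs=0.001)


def fisher_enumeration(table):
    """Independent oracle: sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(k, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestFisherExact:
    def test_two_by_two_hand_enumeration(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_margin_is_one(self):
        assert fisher_exact([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact([[3, 0], [5, 0]]) == 1.0

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(fisher_enumeration(t), abs=1e-12)

    def test_route_association(self):
        recs = study_records()
        p = route_association(recs, "cfdna_call")
        assert 0 < p <= 1


class TestGroupSummaries:
    def _records(self):
        recs = []
        for i, (g, cf, conc) in enumerate(
            [("LMD", 0.6, 0.8), ("LMD", 0.5, 0.3), ("LMD", 0.7, 1.2),
             ("PT", 0.0, 0.02), ("PT", 0.0, 0.03), ("PTACSF", 0.65, 0.07)]
        ):
            recs.append(SampleRecord(f"S{i}", f"P{i}", g, cancer_fraction=cf,
                                     concentration=conc, cytology="negative",
                                     cfdna_call="negative"))
        return recs

    def test_constant_group_iqr_zero(self):
        out = group_summaries(self._records())
        pt = out["summaries"]["cancer_fraction"]["PT"]
        assert pt["q3"] - pt["q1"] == 0.0

    def test_medians_linear_interpolation(self):
        out = group_summaries(self._records())
        lmd = out["summaries"]["cancer_fraction"]["LMD"]
        assert lmd["median"] == pytest.approx(0.6)
        assert lmd["q1"] == pytest.approx(0.55)  # type-7 interpolation

    def test_identical_groups_p_one_no_crash(self):
        recs = []
        for i in range(4):
            recs.append(SampleRecord(f"A{i}", f"A{i}", "LMD", cancer_fraction=0.5,
                                     concentration=1.0, cytology="positive",
                                     cfdna_call="positive"))
            recs.append(SampleRecord(f"B{i}", f"B{i}", "PTACSF", cancer_fraction=0.5,
                                     concentration=1.0, cytology="negative",
                                     cfdna_call="positive"))
        out = group_summaries(recs)
        assert out["pairwise"]["cancer_fraction"]["LMD_vs_PTACSF"] == 1.0

    def test_absent_group_warns_and_omits(self):
        recs = [r for r in self._records() if r.group != "PTACSF"]
        with pytest.warns(UserWarning, match="PTACSF"):
            out = group_summaries(recs)
        assert "PTACSF" not in out["summaries"]["cancer_fraction"]

    def test_zero_values_handled_under_log2(self):
        # PT group has cancer fraction exactly 0; log2 -> -inf must not crash
        out = group_summaries(self._records())
        p = out["pairwise"]["cancer_fraction"]["LMD_vs_PT"]
        assert 0 < p <= 1


class TestRecordValidation:
    def test_bad_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SampleRecord("S1", "P1", "UNKNOWN")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            SampleRecord("S1", "P1", "LMD", concentration=-1.0)

    def test_paired_table_validation(self):
        with pytest.raises(ValueError):
            PairedDiagnosticTable(0, 0, 0, 0)
        with pytest.raises(ValueError):
            PairedDiagnosticTable(-1, 1, 1, 1)
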