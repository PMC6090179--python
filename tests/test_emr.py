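"""Case-crossover windows, per-window counting, and OR signals."""

import pandas as pd
import pytest
from scipy import stats

from pharmsig.core import ContingencyTable, TableContext
from pharmsig.emr import (
    CaseCrossoverWindows,
    ClinicalEvent,
    CohortError,
    PatientTimeline,
    bonferroni,
    build_windows,
    count_outcome,
    detect_signals_emr,
    extract_cohort,
    filter_concepts_semantic,
    or_score,
    outcome_pvalue,
)

DRUG, IND = "RX", "C_IND"


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "kind", "code", "semantic_type"])


def _patient(pid, dx, exposures, mentions=()):
    rows = [(pid, dx, "DIAGNOSIS", IND, "T047")]
    rows += [(pid, e, "DRUG_EXPOSURE", DRUG, "") for e in exposures]
    rows += [(pid, d, "CONCEPT_MENTION", cui, "T184") for d, cui in mentions]
    return rows


class TestSemanticFilter:
    def test_allowed_type_kept_disallowed_dropped(self):
        ev = _events(
            [
                ("P1", 10, "CONCEPT_MENTION", "C1", "T184"),
                ("P1", 11, "CONCEPT_MENTION", "C2", "T121"),
            ]
        )
        out = filter_concepts_semantic(ev)
        assert out["code"].tolist() == ["C1"]

    def test_non_mention_kinds_pass_through(self):
        ev = _events([("P1", 10, "DRUG_EXPOSURE", DRUG, "")])
        assert len(filter_concepts_semantic(ev)) == 1

    def test_custom_allowed_types(self):
        ev = _events([("P1", 10, "CONCEPT_MENTION", "C1", "T184")])
        assert filter_concepts_semantic(ev, allowed_types={"T047"}).empty


class TestExtractCohort:
    def test_diagnosis_before_exposure_included(self):
        ev = _events(_patient("P1", 0, [100, 400]))
        cohort = extract_cohort(ev, DRUG, IND)
        assert cohort["patient_id"].tolist() == ["P1"]

    def test_exposure_before_diagnosis_excluded(self):
        ev = _events(_patient("P1", 80, [50]) + _patient("P2", 0, [100]))
        cohort = extract_cohort(ev, DRUG, IND)
        assert cohort["patient_id"].tolist() == ["P2"]

    def test_diagnosed_but_never_exposed_excluded(self):
        ev = _events(
            [("P1", 0, "DIAGNOSIS", IND, "T047")] + _patient("P2", 0, [100])
        )
        assert extract_cohort(ev, DRUG, IND)["patient_id"].tolist() == ["P2"]

    def test_empty_cohort_raises_with_diagnostics(self):
        ev = _events(_patient("P1", 80, [50]))
        with pytest.raises(CohortError, match="diagnosed"):
            extract_cohort(ev, DRUG, IND)


class TestBuildWindows:
    def test_windows_from_definitions(self):
        ev = _events(_patient("P1", 0, [100, 250, 400]))
        w = build_windows(ev, DRUG, IND)
        assert (w.t_dx, w.t_first, w.t_last) == (0, 100, 400)
        assert w.in_control(99) and not w.in_control(100)
        assert w.in_case(100) and w.in_case(400) and not w.in_case(401)

    def test_single_exposure_gives_one_day_case_window(self):
        ev = _events(_patient("P1", 0, [100]))
        w = build_windows(ev, DRUG, IND)
        assert w.t_first == w.t_last == 100
        assert w.in_case(100)

    def test_mention_on_first_exposure_day_is_case_event(self):
        ev = _events(_patient("P1", 0, [100, 400], mentions=[(100, "C_E")]))
        cohort = extract_cohort(ev, DRUG, IND)
        t = count_outcome(cohort, "C_E", ev)
        assert (t.a, t.c) == (1, 0)

    def test_empty_control_window_rejected(self):
        with pytest.raises(ValueError, match="control"):
            CaseCrossoverWindows("P1", t_dx=100, t_first=100, t_last=200)


class TestCountOutcome:
    def _cohort_events(self):
        rows = []
        for i in range(10):
            mentions = []
            if i < 3:
                mentions.append((150, "C_E"))  # case window
            if i == 0:
                mentions.append((50, "C_E"))  # also in control window
            rows += _patient(f"P{i}", 0, [100, 400], mentions)
        return _events(rows)

    def test_direct_counts_and_conservation(self):
        ev = self._cohort_events()
        cohort = extract_cohort(ev, DRUG, IND)
        t = count_outcome(cohort, "C_E", ev)
        assert t.cells == (3, 7, 1, 9)
        assert t.a + t.b == t.c + t.d == len(cohort)

    def test_unmentioned_outcome_is_all_zero_rows(self):
        ev = self._cohort_events()
        cohort = extract_cohort(ev, DRUG, IND)
        t = count_outcome(cohort, "C_NONE", ev)
        assert t.cells == (0, 10, 0, 10)

    def test_patient_in_both_windows_counted_in_a_and_c(self):
        ev = _events(_patient("P1", 0, [100, 400], [(50, "C_E"), (150, "C_E")]))
        cohort = extract_cohort(ev, DRUG, IND)
        t = count_outcome(cohort, "C_E", ev)
        assert t.cells == (1, 0, 1, 0)


class TestOrScore:
    def _t(self, a, b, c, d):
        return ContingencyTable(a, b, c, d, context=TableContext.CASE_CROSSOVER)

    def test_worked_example(self):
        s = or_score(self._t(3, 7, 1, 9))
        assert s.estimate == pytest.approx(27 / 7)

    def test_balanced_table_is_null(self):
        for k in (1, 5, 50):
            s = or_score(self._t(k, k, k, k))
            assert s.estimate == pytest.approx(1.0)
            assert not s.is_signal

    def test_zero_cell_correction(self):
        s = or_score(self._t(3, 7, 0, 10))
        assert s.zero_corrected
        assert s.estimate == pytest.approx((3.5 * 10.5) / (7.5 * 0.5))

    def test_signal_requires_both_ci_and_p(self):
        s = or_score(self._t(300, 700, 100, 900))
        assert s.ci_low > 1 and s.p_value < 0.05 and s.is_signal

    def test_reports_table_rejected(self):
        with pytest.raises(ValueError, match="CASE_CROSSOVER"):
            or_score(ContingencyTable(3, 7, 1, 9))


class TestPValue:
    def _t(self, a, b, c, d):
        return ContingencyTable(a, b, c, d, context=TableContext.CASE_CROSSOVER)

    def test_no_association_gives_p_one(self):
        assert outcome_pvalue(self._t(50, 50, 50, 50)) == pytest.approx(1.0)

    def test_pearson_chi_square_worked_example(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 12.5 on 1 df
        p = outcome_pvalue(self._t(30, 70, 10, 90), method="chi2")
        assert p == pytest.approx(0.00040695201744495946)

    def test_auto_switches_to_fisher_for_small_expected_cells(self):
        t = self._t(3, 7, 1, 9)  # min expected cell = 2 < 5
        auto = outcome_pvalue(t, method="auto")
        fisher = stats.fisher_exact([[3, 7], [1, 9]]).pvalue
        assert auto == pytest.approx(float(fisher))

    def test_degenerate_margin_gives_p_one(self):
        assert outcome_pvalue(self._t(0, 10, 0, 10)) == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            outcome_pvalue(self._t(1, 1, 1, 1), method="bayes")


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [
            (1.23e-24, 40, 4.92e-23),
            (0.01, 40, 0.40),
            (0.05, 40, 1.0),
        ],
    )
    def test_correction(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_m_below_one_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)


class TestDetectSignals:
    def test_ranked_by_or_then_p_then_cui(self, small_scenario):
        scn = small_scenario
        signals = detect_signals_emr(
            scn.events, scn.config.drug, scn.vocab.indication_cui
        )
        keys = [
            (-s.estimate, s.p_value, cui) for cui, s in signals.entries.items()
        ]
        assert keys == sorted(keys)

    def test_conservation_across_all_outcomes(self, small_scenario):
        scn = small_scenario
        signals = detect_signals_emr(
            scn.events, scn.config.drug, scn.vocab.indication_cui
        )
        sizes = {s.table.a + s.table.b for s in signals.entries.values()}
        assert len(sizes) == 1
        for s in signals.entries.values():
            assert s.table.a + s.table.b == s.table.c + s.table.d

    def test_min_patients_above_cohort_size_gives_empty_set(self, small_scenario):
        scn = small_scenario
        signals = detect_signals_emr(
            scn.events,
            scn.config.drug,
            scn.vocab.indication_cui,
            min_patients=10**6,
        )
        assert len(signals) == 0

    def test_translation_invariance(self, small_scenario):
        scn = small_scenario
        base = detect_signals_emr(scn.events, scn.config.drug, scn.vocab.indication_cui)
        shifted_events = scn.events.assign(date=scn.events["date"] + 1000)
        shifted = detect_signals_emr(
            shifted_events, scn.config.drug, scn.vocab.indication_cui
        )
        assert list(base.entries) == list(shifted.entries)
        for cui in base.entries:
            assert base.entries[cui].table == shifted.entries[cui].table
            assert base.entries[cui].estimate == shifted.entries[cui].estimate
            assert base.entries[cui].p_value == shifted.entries[cui].p_value

    def test_removing_silent_patient_shifts_only_b_and_d(self):
        rows = []
        for i in range(6):
            mentions = [(150, "C_E")] if i < 3 else []
            if i == 1:
                mentions.append((50, "C_E"))
            rows += _patient(f"P{i}", 0, [100, 400], mentions)
        ev = _events(rows)
        base = count_outcome(extract_cohort(ev, DRUG, IND), "C_E", ev)
        trimmed = ev[ev["patient_id"] != "P5"]  # P5 has no mention in either window
        smaller = count_outcome(extract_cohort(trimmed, DRUG, IND), "C_E", trimmed)
        assert (smaller.a, smaller.c) == (base.a, base.c)
        assert (smaller.b, smaller.d) == (base.b - 1, base.d - 1)

    def test_indication_descendant_flagged_as_confounder(self, vasculitis_hierarchy):
        # Indication coded at the HLT; an LLT descendant mention must carry
        # the confounder flag while an unrelated outcome must not.
        ind = "MDV02"
        rows = []
        for i in range(8):
            mentions = [(150, "C0V04"), (160, "C_OTHER")]
            rows.append((f"P{i}", 0, "DIAGNOSIS", ind, "T047"))
            rows.append((f"P{i}", 100, "DRUG_EXPOSURE", DRUG, ""))
            rows.append((f"P{i}", 400, "DRUG_EXPOSURE", DRUG, ""))
            rows += [(f"P{i}", d, "CONCEPT_MENTION", c, "T184") for d, c in mentions]
        signals = detect_signals_emr(
            _events(rows), DRUG, ind, hierarchy=vasculitis_hierarchy
        )
        assert signals.entries["C0V04"].possible_indication_confounder
        assert not signals.entries["C_OTHER"].possible_indication_confounder


class TestTimelineTypes:
    def test_events_sorted_and_single_patient_enforced(self):
        events = [
            ClinicalEvent("P1", 5, "DIAGNOSIS", IND, "T047"),
            ClinicalEvent("P1", 1, "DRUG_EXPOSURE", DRUG, ""),
        ]
        tl = PatientTimeline("P1", events)
        assert [e.date for e in tl.events] == [1, 5]
        with pytest.raises(ValueError):
            PatientTimeline("P2", events)

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(ValueError):
            ClinicalEvent("P1", 1, "SURGERY", "C1")
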