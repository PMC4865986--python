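from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugtally.engine import (
    cabinet_days_on_hand,
    count_drugs,
    drug_keys,
    in_scope,
    inpatient_days_in_gap,
    observed_index_gap,
)
from drugtally.measures import (
    CabinetSupplyRule,
    TimeframeSpec,
    UniquenessSpec,
    preset,
)
from drugtally.model import (
    DrugProduct,
    FillRecord,
    Hospitalization,
    IndexEvent,
    PatientHistory,
)

from _oracles import cabinet_oracle, inpatient_days_oracle

from conftest import HYPOTHETICAL_COUNTS


class TestScope:
    def test_transdermal_patch_fails_oral_only_scope(self, table3):
        _, dictionary = table3
        assert not in_scope(dictionary["EST"], preset("v2").scope)
        assert in_scope(dictionary["MET"], preset("v2").scope)

    def test_as_needed_drug_fails_regular_use_scope(self, table3):
        _, dictionary = table3
        assert not in_scope(dictionary["NTG"], preset("v4").scope)

    def test_default_scope_admits_any_prescription_product(self, table3):
        _, dictionary = table3
        assert all(in_scope(p, preset("default").scope)
                   for p in dictionary.values())

    def test_otc_excluded_by_default_admitted_by_rx_otc_scope(self):
        otc = DrugProduct("O", ("ibuprofen",), "oral", "tablet",
                          rx_status="otc")
        assert not in_scope(otc, preset("default").scope)
        assert in_scope(otc, preset("v1").scope)


class TestDrugKeys:
    combo = DrugProduct("C", ("ezetimibe", "simvastatin"), "oral", "tablet",
                        "10/10 mg")

    def test_combination_splits_under_ingredient_basis(self):
        keys = drug_keys(self.combo, UniquenessSpec(basis="ingredient",
                                                    level="ingredient"))
        assert keys == {"ezetimibe", "simvastatin"}

    def test_combination_is_one_key_under_product_basis(self):
        keys = drug_keys(self.combo, UniquenessSpec())
        assert keys == {"ezetimibe/simvastatin-oral-tablet"}

    def test_ingredient_route_level_distinguishes_routes(self):
        # classic illustration: combo inhaler + nebulizer solution + oral
        # tablets of the same bronchodilator -> 3 ingredient-route keys
        inhaler = DrugProduct("I", ("albuterol", "ipratropium"),
                              "inhalation", "aerosol",
                              is_metered_dose_inhaler=True)
        neb = DrugProduct("N", ("albuterol",), "inhalation", "solution")
        tab = DrugProduct("T", ("albuterol",), "oral", "tablet")
        uniq = UniquenessSpec(basis="ingredient", level="ingredient_route")
        keys = set().union(*(drug_keys(p, uniq) for p in (inhaler, neb, tab)))
        assert keys == {"albuterol-inhalation", "ipratropium-inhalation",
                        "albuterol-oral"}
        # and only 2 at the bare-ingredient level
        uniq_ing = UniquenessSpec(basis="ingredient", level="ingredient")
        keys_ing = set().union(*(drug_keys(p, uniq_ing)
                                 for p in (inhaler, neb, tab)))
        assert keys_ing == {"albuterol", "ipratropium"}

    def test_key_is_order_and_case_independent(self):
        a = DrugProduct("A", ("Simvastatin", "Ezetimibe"), "oral", "tablet")
        assert drug_keys(a, UniquenessSpec()) == drug_keys(
            self.combo, UniquenessSpec())


class TestGapArithmetic:
    @pytest.mark.parametrize("fill_date,expected", [
        (date(2008, 6, 18), 13),
        (date(2008, 4, 19), 73),
        (date(2008, 6, 30), 1),
    ])
    def test_observed_index_gap_calendar_days(self, fill_date, expected):
        fill = FillRecord("p", "X", fill_date, 30)
        assert observed_index_gap(fill, date(2008, 7, 1)) == expected

    def test_anchor_on_or_after_index_is_contract_violation(self):
        fill = FillRecord("p", "X", date(2008, 7, 1), 30)
        with pytest.raises(ValueError):
            observed_index_gap(fill, date(2008, 7, 1))


class TestCabinetSupply:
    anchor = date(2008, 6, 18)

    def test_worked_example_three_days_on_hand(self):
        # 30-day supply filled 27 days before the anchor -> 3 days left
        fills = [(self.anchor - timedelta(days=27), 30)]
        assert cabinet_days_on_hand(fills, self.anchor, 180) == 3

    def test_no_prior_fills_in_window_gives_zero(self):
        assert cabinet_days_on_hand([], self.anchor, 180) == 0
        outside = [(self.anchor - timedelta(days=200), 30)]
        assert cabinet_days_on_hand(outside, self.anchor, 180) == 0

    def test_exhausted_supply_does_not_go_negative(self):
        # DS=30 at -60 runs out before the -30 refill; carry floors at 0
        fills = [(self.anchor - timedelta(days=60), 30),
                 (self.anchor - timedelta(days=30), 30)]
        assert cabinet_days_on_hand(fills, self.anchor, 180) == 0

    def test_stockpiling_accumulates_uncapped(self):
        # early refills stack: 3 x 90-day supplies 30 days apart
        fills = [(self.anchor - timedelta(days=d), 90) for d in (90, 60, 30)]
        assert cabinet_days_on_hand(fills, self.anchor, 180) == 180

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_day_by_day_replay_oracle(self, data):
        n = data.draw(st.integers(0, 6))
        anchor = date(2008, 6, 18)
        fills = [
            (anchor - timedelta(days=data.draw(st.integers(1, 250))),
             data.draw(st.integers(1, 120)))
            for _ in range(n)
        ]
        lookback = data.draw(st.sampled_from([30, 90, 180]))
        got = cabinet_days_on_hand(fills, anchor, lookback)
        assert got == cabinet_oracle(fills, anchor, lookback)


class TestInpatientDays:
    anchor, index = date(2008, 4, 19), date(2008, 7, 1)

    def test_no_hospitalizations_gives_zero(self):
        assert inpatient_days_in_gap([], self.anchor, self.index) == 0

    def test_half_open_stay_convention(self):
        stay = Hospitalization("p", self.anchor + timedelta(days=5),
                               self.anchor + timedelta(days=8))
        assert inpatient_days_in_gap([stay], self.anchor, self.index) == 3

    def test_stay_after_index_does_not_contribute(self):
        stay = Hospitalization("p", self.index, self.index + timedelta(days=5))
        assert inpatient_days_in_gap([stay], self.anchor, self.index) == 0

    def test_overlapping_stays_are_unioned(self):
        s1 = Hospitalization("p", date(2008, 5, 1), date(2008, 5, 10))
        s2 = Hospitalization("p", date(2008, 5, 5), date(2008, 5, 12))
        got = inpatient_days_in_gap([s1, s2], self.anchor, self.index)
        assert got == inpatient_days_oracle([s1, s2], self.anchor, self.index)
        assert got == 11

    def test_alternative_day_conventions(self):
        stay = Hospitalization("p", date(2008, 5, 1), date(2008, 5, 4))
        args = ([stay], self.anchor, self.index)
        assert inpatient_days_in_gap(*args, "admit_inclusive") == 3
        assert inpatient_days_in_gap(*args, "both_inclusive") == 4
        assert inpatient_days_in_gap(*args, "both_exclusive") == 2
        with pytest.raises(ValueError):
            inpatient_days_in_gap(*args, "weekends_only")


class TestCountDrugs:
    @pytest.mark.parametrize("name,expected",
                             sorted(HYPOTHETICAL_COUNTS.items()))
    def test_hypothetical_patient_counts_all_presets(self, table3, name,
                                                     expected):
        history, dictionary = table3
        assert count_drugs(history, preset(name), dictionary).count == expected

    def test_default_evidence_trail(self, table3):
        history, dictionary = table3
        result = count_drugs(history, preset("default"), dictionary)
        ev = {e.key: e for e in result.evidence}
        # three chronic drugs pass the flexible gap; nitroglycerin fails
        assert ev["estradiol-transdermal-patch"].counted
        assert ev["estradiol-transdermal-patch"].observed_index_gap == 13
        assert ev["estradiol-transdermal-patch"].allowable_index_gap == 28
        ntg = ev["nitroglycerin-sublingual-tablet"]
        assert not ntg.counted and ntg.rule_fired == "none"
        assert ntg.observed_index_gap == 73 and ntg.allowable_index_gap == 9
        # lisinopril has no pre-index anchor: no evidence entry at all
        assert not any("lisinopril" in k for k in ev)
        assert result.count == sum(e.counted for e in result.evidence)

    def test_fixed_gap_rescues_infrequent_drug(self, table3):
        history, dictionary = table3
        result = count_drugs(history, preset("v8"), dictionary)
        ntg = {e.key: e for e in result.evidence}["nitroglycerin-sublingual-tablet"]
        assert ntg.counted and ntg.rule_fired == "base_gap"
        assert ntg.allowable_index_gap == 90

    def test_override_fires_only_for_matching_products(self, table3):
        history, dictionary = table3
        result = count_drugs(history, preset("v13"), dictionary)
        ev = {e.key: e for e in result.evidence}
        assert ev["nitroglycerin-sublingual-tablet"].rule_fired == "override_gap"
        assert ev["metoprolol succinate-oral-tablet"].rule_fired == "base_gap"

    def test_post_index_rescue_requires_pre_index_anchor(self):
        # one drug: pre-index fill far back, post-index fill soon after
        pid = "p"
        prod = DrugProduct("X", ("drugx",), "oral", "tablet")
        # anchor 37 days before index (fails 30-day flexible gap)
        fills = (
            FillRecord(pid, "X", date(2008, 5, 25), 30),
            FillRecord(pid, "X", date(2008, 7, 30), 30),
        )
        history = PatientHistory(pid, fills, (),
                                 IndexEvent(pid, date(2008, 7, 1)))
        dictionary = {"X": prod}
        assert count_drugs(history, preset("default"), dictionary).count == 0
        # pre-post gap = 66 days >= 2*30: still out
        assert count_drugs(history, preset("v10"), dictionary).count == 0
        # closer post-index fill (pre-post gap 41 < 60) rescues it
        fills2 = (fills[0], FillRecord(pid, "X", date(2008, 7, 5), 30))
        history2 = PatientHistory(pid, fills2, (),
                                  IndexEvent(pid, date(2008, 7, 1)))
        result = count_drugs(history2, preset("v10"), dictionary)
        assert result.count == 1
        assert result.evidence[0].rule_fired == "post_index"
        assert result.evidence[0].observed_pre_post_gap == 41

    def test_same_day_split_fills_sum_days_supply(self):
        pid = "p"
        prod = DrugProduct("X", ("drugx",), "oral", "tablet")
        fills = (
            FillRecord(pid, "X", date(2008, 6, 1), 15),
            FillRecord(pid, "X", date(2008, 6, 1), 15),
        )
        history = PatientHistory(pid, fills, (),
                                 IndexEvent(pid, date(2008, 7, 1)))
        # gap 30 < 15+15 is false (strict); gap 30 < 31 with one more day
        assert count_drugs(history, preset("default"), {"X": prod}).count == 0
        fills31 = (FillRecord(pid, "X", date(2008, 6, 1), 16), fills[1])
        h31 = PatientHistory(pid, fills31, (), IndexEvent(pid, date(2008, 7, 1)))
        assert count_drugs(h31, preset("default"), {"X": prod}).count == 1

    def test_supply_exhausted_on_index_day_does_not_count(self):
        # strict comparison: observed gap equal to allowable gap fails
        pid = "p"
        prod = DrugProduct("X", ("drugx",), "oral", "tablet")
        history = PatientHistory(
            pid, (FillRecord(pid, "X", date(2008, 6, 1), 30),), (),
            IndexEvent(pid, date(2008, 7, 1)))
        assert count_drugs(history, preset("default"), {"X": prod}).count == 0

    def test_empty_history_counts_zero(self):
        history = PatientHistory("p", (), (), IndexEvent("p", date(2008, 7, 1)))
        assert count_drugs(history, preset("default"), {}).count == 0

    def test_ingredient_counts_if_any_product_passes(self):
        # shared ingredient: stale product fails, fresh combo passes
        pid = "p"
        old = DrugProduct("OLD", ("shared",), "oral", "tablet")
        combo = DrugProduct("NEW", ("shared", "other"), "oral", "tablet")
        fills = (
            FillRecord(pid, "OLD", date(2008, 1, 1), 30),
            FillRecord(pid, "NEW", date(2008, 6, 20), 30),
        )
        history = PatientHistory(pid, fills, (),
                                 IndexEvent(pid, date(2008, 7, 1)))
        dictionary = {"OLD": old, "NEW": combo}
        result = count_drugs(history, preset("v5"), dictionary)
        assert result.count == 2
        assert {e.key for e in result.evidence if e.counted} == {"shared", "other"}

    def test_longitudinal_counts_distinct_keys_in_window(self, table3):
        history, dictionary = table3
        measure = preset("default").model_copy(update=dict(
            measure_id="long",
            timeframe=TimeframeSpec(orientation="longitudinal",
                                    longitudinal_window=(-180, 0)),
        ))
        assert count_drugs(history, measure, dictionary).count == 4
        wider = measure.model_copy(update=dict(
            timeframe=TimeframeSpec(orientation="longitudinal",
                                    longitudinal_window=(-180, 30)),
        ))
        # post-discharge lisinopril now falls inside the window
        assert count_drugs(history, wider, dictionary).count == 5

    def test_cabinet_extends_allowable_gap(self):
        # fills at -80 (DS 60) and -40 (DS 30): 20 days left at the anchor,
        # so a 40-day observed gap passes 30+20 only with the cabinet rule
        pid = "p"
        prod = DrugProduct("X", ("drugx",), "oral", "tablet")
        fills = (
            FillRecord(pid, "X", date(2008, 7, 1) - timedelta(days=80), 60),
            FillRecord(pid, "X", date(2008, 7, 1) - timedelta(days=40), 30),
        )
        history = PatientHistory(pid, fills, (),
                                 IndexEvent(pid, date(2008, 7, 1)))
        assert count_drugs(history, preset("default"), {"X": prod}).count == 0
        result = count_drugs(history, preset("v11"), {"X": prod})
        assert result.count == 1
        assert result.evidence[0].cabinet_days == 20
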