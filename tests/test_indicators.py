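"""Indicator engine: eligibility, attribution, dedup, aggregation, filters."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import overuse_index as oi
from overuse_index.indicators import (
    CELL_COLUMNS,
    EngineLog,
    IndicatorDefinition,
    aggregate_cells,
    apply_min_eligible_filter,
    count_cells,
    deduplicate_first_occurrence,
    detect_events,
    exclude_specialty_hospitals,
    find_eligible,
)


def claims_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["beneficiary_id", "service_date", "ccn", "diagnosis_codes", "procedure_codes", "setting"],
    ).assign(service_date=lambda d: pd.to_datetime(d.service_date))


DEFN = IndicatorDefinition(
    indicator_id=1,
    name="toy imaging indicator",
    min_age=66,
    eligibility_dx_codes=("R51",),
    event_codes=("B030",),
    eligibility_window_days=30,
)

LINKAGE = pd.DataFrame(
    {
        "ccn": ["010001", "010002"],
        "hospital_name": ["General Medical Center", "Lakeside Hospital"],
        "system_id": ["S1", "S2"],
        "vintage": [2016, 2016],
    }
)


class TestSpecialtyExclusion:
    @pytest.mark.parametrize(
        "name,excluded",
        [
            ("St. Mary Children's Hospital", True),
            ("Lakeside Rehabilitation Hospital", True),
            ("Summit Behavioral Health Center", True),
            ("Northern Psychiatric Institute", True),
            ("General Medical Center", False),
        ],
    )
    def test_keyword_exclusion(self, name, excluded):
        link = pd.DataFrame(
            {"ccn": ["1"], "hospital_name": [name], "system_id": ["S"], "vintage": [2016]}
        )
        log = EngineLog()
        out = exclude_specialty_hospitals(link, log=log)
        assert (len(out) == 0) == excluded
        assert log.total("specialty_hospital_excluded") == int(excluded)


class TestEligibilityAndEvents:
    def test_episode_attributed_to_qualifying_claim_ccn(self, toy_beneficiaries):
        claims = claims_frame(
            [["A", "2016-02-01", "010001", "R51", "", "outpatient"]]
        )
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        assert len(eps) == 1 and eps.ccn.iloc[0] == "010001"
        assert eps.end_date.iloc[0] - eps.start_date.iloc[0] == pd.Timedelta(days=30)

    def test_age_predicate_blocks_episode(self, toy_beneficiaries):
        # beneficiary C is 66 only from 2016-01-01 birth 1950 => age 66 at 2016-02-01? no: 66.08 -> eligible
        claims = claims_frame([["C", "2016-02-01", "010001", "R51", "", "outpatient"]])
        young = toy_beneficiaries.assign(birth_date=pd.to_datetime(["1946-03-01", "1936-06-15", "1960-01-01"]))
        assert len(find_eligible(claims, young, DEFN)) == 0

    def test_demographic_only_attribution_deferred_to_event_claim(self, toy_beneficiaries):
        defn = IndicatorDefinition(
            indicator_id=12,
            name="screening in women over 85",
            min_age=85,
            sex="F",
            event_codes=("0UDB",),
            attribution="event_claim",
        )
        bene = toy_beneficiaries.assign(
            birth_date=pd.to_datetime(["1925-01-01", "1925-01-01", "1950-01-01"])
        )
        claims = claims_frame(
            [
                ["A", "2016-02-01", "010001", "", "", "outpatient"],   # contact only
                ["A", "2016-03-01", "010002", "", "0UDB", "outpatient"],  # event elsewhere
                ["B", "2016-02-01", "010001", "", "0UDB", "outpatient"],  # male: ineligible
            ]
        )
        eps = find_eligible(claims, bene, defn)
        assert set(eps.ccn) == {"010001", "010002"} and eps.demographic_only.all()
        ev = detect_events(claims, eps, defn)
        assert len(ev) == 1 and ev.ccn.iloc[0] == "010002"

    def test_event_window_boundaries(self, toy_beneficiaries):
        claims = claims_frame(
            [
                ["A", "2016-02-01", "010001", "R51", "", "outpatient"],
                ["A", "2016-02-04", "010001", "", "B030", "outpatient"],  # day 3: event
                ["B", "2016-02-01", "010001", "R51", "", "outpatient"],
                ["B", "2016-03-03", "010001", "", "B030", "outpatient"],  # day 31: outside
            ]
        )
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        log = EngineLog()
        ev = detect_events(claims, eps, DEFN, log=log)
        assert list(ev.beneficiary_id) == ["A"]
        assert log.total("event_outside_window") == 1

    def test_overlapping_windows_attribute_to_earliest_start(self, toy_beneficiaries):
        claims = claims_frame(
            [
                ["A", "2016-02-10", "010002", "R51", "", "outpatient"],
                ["A", "2016-02-01", "010001", "R51", "", "outpatient"],
                ["A", "2016-02-15", "010001", "", "B030", "outpatient"],
            ]
        )
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        ev = detect_events(claims, eps, DEFN)
        # brute force over the toy: both windows cover 02-15; earliest start is 02-01 at 010001
        covering = eps[(eps.start_date <= "2016-02-15") & (eps.end_date >= "2016-02-15")]
        assert len(covering) == 2
        assert len(ev) == 1 and ev.ccn.iloc[0] == "010001"

    def test_lookback_claims_establish_eligibility_but_never_events(self, toy_beneficiaries):
        claims = claims_frame(
            [
                ["A", "2015-12-20", "010001", "R51", "", "outpatient"],
                ["A", "2016-01-05", "010001", "", "B030", "outpatient"],  # in window, Q1
                ["B", "2015-08-01", "010001", "R51", "", "outpatient"],
                ["B", "2015-08-10", "010001", "", "B030", "outpatient"],  # pre-study event
            ]
        )
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        ev = detect_events(claims, eps, DEFN)
        assert list(ev.beneficiary_id) == ["A"] and list(ev.quarter_index) == [1]


class TestDedup:
    def base_events(self):
        return pd.DataFrame(
            {
                "beneficiary_id": ["A", "A", "A", "A", "A"],
                "indicator_id": [1, 1, 2, 1, 1],
                "ccn": ["010001"] * 5,
                "event_date": pd.to_datetime(
                    ["2016-02-10", "2016-02-20", "2016-02-11", "2016-05-01", "2016-02-05"]
                ),
                "quarter_index": [1, 1, 1, 2, 1],
            }
        )

    def test_first_occurrence_per_quarter_hospital(self):
        out = deduplicate_first_occurrence(self.base_events())
        # indicator 1 Q1: earliest (02-05) survives; indicator 2 Q1 kept; indicator 1 Q2 kept
        assert len(out) == 3
        kept = out[(out.indicator_id == 1) & (out.quarter_index == 1)]
        assert kept.event_date.iloc[0] == pd.Timestamp("2016-02-05")

    def test_distinct_indicators_same_quarter_all_retained(self):
        out = deduplicate_first_occurrence(self.base_events())
        assert set(out.indicator_id[out.quarter_index == 1]) == {1, 2}

    def test_idempotent(self):
        once = deduplicate_first_occurrence(self.base_events())
        twice = deduplicate_first_occurrence(once)
        pd.testing.assert_frame_equal(once, twice)


class TestAggregation:
    def test_cell_covariate_arithmetic(self, toy_beneficiaries):
        # eligible {A: 70F, B: 80M} at one hospital-quarter
        bene = toy_beneficiaries.assign(
            birth_date=pd.to_datetime(["1946-01-01", "1936-01-01", "1950-01-01"])
        )
        claims = claims_frame(
            [
                ["A", "2016-01-15", "010001", "R51", "", "outpatient"],
                ["B", "2016-01-20", "010001", "R51", "", "outpatient"],
            ]
        )
        eps = find_eligible(claims, bene, DEFN)
        cells = aggregate_cells(eps, pd.DataFrame(columns=["beneficiary_id", "indicator_id", "ccn", "event_date", "quarter_index"]), bene, LINKAGE)
        assert len(cells) == 1
        row = cells.iloc[0]
        assert row.eligible_count == 2 and row.event_count == 0
        assert row.mean_age == pytest.approx(75.0, abs=0.01)
        assert row.proportion_women == pytest.approx(0.5)
        assert row.median_chronic_conditions == 7.0

    def test_unknown_ccn_cells_dropped_and_logged(self, toy_beneficiaries):
        claims = claims_frame([["A", "2016-02-01", "999999", "R51", "", "outpatient"]])
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        log = EngineLog()
        cells = aggregate_cells(eps, pd.DataFrame(columns=["beneficiary_id", "indicator_id", "ccn", "event_date", "quarter_index"]), toy_beneficiaries, LINKAGE, log=log)
        assert len(cells) == 0 and log.total("unknown_ccn_cell_dropped") == 1

    def test_vintage_switching_moves_system_in_2018(self, toy_beneficiaries):
        link = pd.concat(
            [
                LINKAGE,
                LINKAGE.assign(vintage=2018, system_id=["S9", "S2"]),
            ],
            ignore_index=True,
        )
        claims = claims_frame(
            [
                ["A", "2016-02-01", "010001", "R51", "", "outpatient"],
                ["B", "2018-02-01", "010001", "R51", "", "outpatient"],
            ]
        )
        eps = find_eligible(claims, toy_beneficiaries, DEFN)
        cells = aggregate_cells(eps, pd.DataFrame(columns=["beneficiary_id", "indicator_id", "ccn", "event_date", "quarter_index"]), toy_beneficiaries, link)
        by_q = cells.set_index("quarter_index")["system_id"]
        assert by_q.loc[1] == "S1" and by_q.loc[9] == "S9"

    def test_round_trip_matches_generator_cells(self, small_structure, small_bundle):
        cells = count_cells(
            small_bundle.claims,
            small_bundle.beneficiaries,
            small_bundle.linkage,
            small_structure.config.resolved_defs(),
        )
        truth = small_bundle.cells.sort_values(["ccn", "quarter_index", "indicator_id"]).reset_index(drop=True)
        got = cells.sort_values(["ccn", "quarter_index", "indicator_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got[CELL_COLUMNS], truth[CELL_COLUMNS])

    def test_conservation_of_deduplicated_events(self, small_structure, small_bundle):
        cells = count_cells(
            small_bundle.claims,
            small_bundle.beneficiaries,
            small_bundle.linkage,
            small_structure.config.resolved_defs(),
        )
        assert cells.event_count.sum() == small_bundle.cells.event_count.sum()

    def test_duplicate_injection_removed_by_dedup(self, small_structure):
        noisy = oi.generate_cells_and_claims(
            oi.generate_structure(
                n_systems=3, hospitals_per_system=("fixed", 2), seed=7,
                eligible_mean=8.0, duplicate_injection=0.5,
            ),
            seed=8,
        )
        assert len(noisy.claims) > noisy.cells.eligible_count.sum() + noisy.cells.event_count.sum()
        cells = count_cells(noisy.claims, noisy.beneficiaries, noisy.linkage,
                            oi.default_indicator_definitions())
        assert cells.event_count.sum() == noisy.cells.event_count.sum()


class TestMinEligibleFilter:
    def make_cells(self, eligibles):
        return pd.DataFrame(
            {
                "ccn": ["1"] * len(eligibles),
                "system_id": ["S"] * len(eligibles),
                "quarter_index": range(1, len(eligibles) + 1),
                "indicator_id": [1] * len(eligibles),
                "eligible_count": eligibles,
                "event_count": [0] * len(eligibles),
                "mean_age": 75.0,
                "proportion_women": 0.5,
                "median_chronic_conditions": 7,
            }
        )

    @pytest.mark.parametrize("eligible,kept", [(19, 0), (20, 1)])
    def test_boundary_at_twenty(self, eligible, kept):
        cells = self.make_cells([eligible])
        assert len(apply_min_eligible_filter(cells, 20)) == kept
        assert len(apply_min_eligible_filter(cells, 20, per_quarter=True)) == kept

    def test_pair_rule_pools_quarters(self):
        cells = self.make_cells([12, 12])  # pair total 24 >= 20
        assert len(apply_min_eligible_filter(cells, 20)) == 2
        assert len(apply_min_eligible_filter(cells, 20, per_quarter=True)) == 0

    def test_threshold_one_is_identity(self, small_cells):
        out = apply_min_eligible_filter(small_cells, 1)
        pd.testing.assert_frame_equal(out, small_cells.reset_index(drop=True))
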