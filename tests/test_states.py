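import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmr.states import (
    EncounterHistory,
    HistorySet,
    apply_exclusion_filters,
    build_encounter_histories,
    classify_annual_state,
    ground_reader_breeder_rule,
)


def _days(year, offsets):
    return [dt.date(year, 4, 1) + dt.timedelta(days=o) for o in offsets]


class TestGroundReaderRule:
    def test_six_days_span_twelve(self):
        assert ground_reader_breeder_rule(_days(2015, [0, 3, 5, 8, 10, 12]), 2015)

    def test_five_days_false(self):
        assert not ground_reader_breeder_rule(_days(2015, [0, 20, 40, 60, 80]), 2015)

    def test_span_over_120_false(self):
        assert not ground_reader_breeder_rule(
            _days(2015, [0, 20, 40, 60, 80, 100, 121]), 2015
        )

    def test_out_of_season_pings_discarded(self):
        in_season = _days(2015, [0, 10, 20, 30])
        out_season = [dt.date(2015, 1, 5), dt.date(2015, 2, 1),
                      dt.date(2015, 11, 20), dt.date(2015, 12, 1)]
        assert not ground_reader_breeder_rule(in_season + out_season, 2015)

    def test_empty_false(self):
        assert not ground_reader_breeder_rule([], 2015)

    def test_duplicate_days_count_once(self):
        days = _days(2015, [0, 0, 0, 3, 5, 8, 10, 12])
        assert len(set(days)) == 6
        assert ground_reader_breeder_rule(days, 2015)
        assert not ground_reader_breeder_rule(_days(2015, [0, 0, 0, 0, 0, 13]), 2015)

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 120), min_size=6, max_size=30))
    def test_monotone_within_span(self, offsets):
        """Adding detection days inside the existing span never drops a
        breeder classification."""
        base = sorted(offsets)
        if not ground_reader_breeder_rule(_days(2016, base), 2016):
            return
        extra = base + [(base[0] + base[-1]) // 2]
        assert ground_reader_breeder_rule(_days(2016, extra), 2016)


def _records(rows):
    df = pd.DataFrame(rows, columns=["individual_id", "colony", "date", "method",
                                     "breeding_evidence"])
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestClassify:
    def test_nest_with_eggs_is_breeder(self):
        r = _records([("a", "RobbenIsland", "2015-05-01", "nest", 1)])
        assert classify_annual_state(r, prior_history=False, season_year=2015) == 1

    def test_few_reader_days_prior_breeder_is_nonbreeder(self):
        r = _records([("a", "RobbenIsland", f"2015-05-{d:02d}", "reader", 0)
                      for d in (1, 10, 20)])
        assert classify_annual_state(r, prior_history=True, season_year=2015) == 2

    def test_few_reader_days_never_bred_is_prebreeder(self):
        r = _records([("a", "RobbenIsland", f"2015-05-{d:02d}", "reader", 0)
                      for d in (1, 10, 20)])
        assert classify_annual_state(r, prior_history=False, season_year=2015) == 3

    def test_reader_rule_pass_is_breeder(self):
        r = _records([("a", "RobbenIsland", f"2015-05-{d:02d}", "reader", 0)
                      for d in (1, 4, 7, 10, 13, 16)])
        assert classify_annual_state(r, prior_history=False, season_year=2015) == 1

    def test_no_records_is_zero(self):
        assert classify_annual_state(_records([]), prior_history=True) == 0

    def test_multi_colony_raises(self):
        r = _records([("a", "RobbenIsland", "2015-05-01", "reader", 0),
                      ("a", "StonyPoint", "2015-06-01", "reader", 0)])
        with pytest.raises(ValueError, match="colonies"):
            classify_annual_state(r, prior_history=False, season_year=2015)

    def test_nest_evidence_beats_day_count(self):
        """Monotonicity: extra evidence can only move towards breeder."""
        base = [("a", "RobbenIsland", f"2015-05-{d:02d}", "reader", 0)
                for d in (1, 10, 20)]
        assert classify_annual_state(_records(base), False, 2015) == 3
        more = base + [("a", "RobbenIsland", "2015-06-01", "nest", 1)]
        assert classify_annual_state(_records(more), False, 2015) == 1


class TestExclusions:
    def _toy(self):
        rows = []
        for i in range(10):
            rows.append((f"id{i}", "RobbenIsland", "2014-05-01", "nest", 1))
        return _records(rows)

    def test_double_marked_removed(self):
        filtered, report = apply_exclusion_filters(self._toy(), {"id3"})
        assert filtered["individual_id"].nunique() == 9
        assert report["individual_id"].tolist() == ["id3"]
        assert report["reason"].tolist() == ["double-marked"]

    def test_multi_colony_breeder_removed(self):
        rows = [("a", "RobbenIsland", "2014-05-01", "nest", 1),
                ("a", "StonyPoint", "2015-05-01", "nest", 1),
                ("b", "StonyPoint", "2015-05-01", "nest", 1)]
        filtered, report = apply_exclusion_filters(_records(rows))
        assert set(filtered["individual_id"]) == {"b"}
        assert report.iloc[0]["reason"] == "multi-colony breeder"

    def test_nonbreeding_visit_elsewhere_kept(self):
        rows = [("a", "RobbenIsland", "2014-05-01", "nest", 1),
                ("a", "StonyPoint", "2015-05-01", "reader", 0)]
        filtered, report = apply_exclusion_filters(_records(rows))
        assert len(report) == 0
        assert filtered["individual_id"].nunique() == 1

    def test_remove_any_policy(self):
        rows = [("a", "RobbenIsland", "2014-05-01", "nest", 1),
                ("a", "StonyPoint", "2015-05-01", "reader", 0)]
        filtered, report = apply_exclusion_filters(
            _records(rows), multi_colony="remove-any"
        )
        assert len(filtered) == 0
        with pytest.raises(ValueError):
            apply_exclusion_filters(_records(rows), multi_colony="bogus")


class TestBuildHistories:
    def test_breeder_resighted_pattern(self):
        rows = [("a", "RobbenIsland", "2013-05-01", "nest", 1),
                ("a", "RobbenIsland", "2015-05-01", "nest", 1)]
        hset, tally = build_encounter_histories(_records(rows))
        assert hset[0].codes == (1, 0, 1, 0, 0, 0, 0, 0)
        assert tally.iloc[0].to_dict() == {
            "season": 2013, "colony": "RobbenIsland", "state": "B", "n_marked": 1}

    def test_prebreeder_stays_prebreeder(self):
        rows = [("a", "StonyPoint", "2016-05-01", "reader", 0),
                ("a", "StonyPoint", "2018-05-01", "reader", 0)]
        hset, _ = build_encounter_histories(_records(rows))
        assert hset[0].codes == (0, 0, 0, 3, 0, 3, 0, 0)

    def test_prebreeder_flips_to_nonbreeder_after_breeding(self):
        rows = [("a", "StonyPoint", "2014-05-01", "reader", 0),
                ("a", "StonyPoint", "2015-05-01", "nest", 1),
                ("a", "StonyPoint", "2017-05-01", "reader", 0)]
        hset, _ = build_encounter_histories(_records(rows))
        assert hset[0].codes == (0, 3, 1, 0, 2, 0, 0, 0)

    def test_out_of_range_record_rejected_with_id(self):
        rows = [("late", "StonyPoint", "2021-05-01", "nest", 1)]
        with pytest.raises(ValueError, match="late"):
            build_encounter_histories(_records(rows))
        rows = [("early", "StonyPoint", "2012-05-01", "nest", 1)]
        with pytest.raises(ValueError, match="early"):
            build_encounter_histories(_records(rows))

    def test_impute_switch(self):
        rows = [("a", "StonyPoint", "2014-05-01", "nest", 1),
                ("a", "StonyPoint", "2017-05-01", "nest", 1)]
        hset, _ = build_encounter_histories(_records(rows), impute_unobserved=True)
        assert hset[0].codes == (0, 1, 2, 2, 1, 0, 0, 0)

    def test_idempotent_and_deterministic(self):
        rows = [("a", "RobbenIsland", "2013-05-01", "nest", 1),
                ("b", "RobbenIsland", "2014-05-02", "reader", 0),
                ("b", "RobbenIsland", "2016-05-02", "nest", 1)]
        h1, t1 = build_encounter_histories(_records(rows))
        h2, t2 = build_encounter_histories(_records(rows))
        assert [h.codes for h in h1] == [h.codes for h in h2]
        pd.testing.assert_frame_equal(t1, t2)

    def test_history_invariants(self, sim_histories):
        for h in sim_histories:
            assert len(h.codes) == 8
            assert h.codes[h.first_occasion] != 0
            assert all(c == 0 for c in h.codes[: h.first_occasion])


class TestHistoryValidation:
    def test_prebreeder_after_breeder_rejected(self):
        with pytest.raises(ValueError, match="prebreeder"):
            EncounterHistory("x", "RobbenIsland", (1, 3, 0, 0, 0, 0, 0, 0))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            EncounterHistory("x", "RobbenIsland", (0,) * 8)

    def test_unknown_colony_rejected(self):
        with pytest.raises(ValueError):
            EncounterHistory("x", "Atlantis", (1, 0, 0, 0, 0, 0, 0, 0))


class TestSerialization:
    def test_inp_round_trip(self, sim_histories, tmp_path):
        p = tmp_path / "h.inp"
        sim_histories.to_inp(p)
        back = HistorySet.from_inp(p)
        assert [(h.individual_id, h.colony, h.codes) for h in back] == [
            (h.individual_id, h.colony, h.codes) for h in sim_histories
        ]

    def test_inp_format_exact(self, tmp_path):
        h = HistorySet([EncounterHistory("bird1", "StonyPoint",
                                         (1, 0, 2, 0, 0, 0, 0, 0))])
        p = tmp_path / "h.inp"
        h.to_inp(p)
        assert p.read_text() == "/* bird1 */ 10200000 0 1 ;\n"

    def test_csv_round_trip(self, sim_histories, tmp_path):
        p = tmp_path / "h.csv"
        sim_histories.to_csv(p)
        back = HistorySet.from_csv(p)
        assert [h.codes for h in back] == [h.codes for h in sim_histories]
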