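"""Friday-anchored calendar arithmetic, cohort filters, weekly binning."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edseries import (
    EncounterRecord,
    FilterSpec,
    SeriesPair,
    WeeklySeries,
    bin_weekly,
    filter_encounters,
    frame_to_pair,
    frame_to_records,
    pair_to_frame,
    records_to_frame,
    span_weeks,
    week_index_of,
)

ANCHOR = date(2018, 1, 5)  # a Friday


def make_record(**kwargs) -> EncounterRecord:
    base = dict(
        visit_date=date(2018, 1, 10),
        ethnicity="latino",
        age_years=40,
        sex="female",
        payer="restricted_medical",
        disposition="treat_release",
    )
    base.update(kwargs)
    return EncounterRecord(**base)


class TestWeekIndex:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (date(2018, 1, 5), 1),    # the anchor opens week 1
            (date(2018, 1, 11), 1),   # the following Thursday closes it
            (date(2018, 1, 12), 2),
            (date(2020, 5, 15), 124),  # week of the lifted restrictions
            (date(2019, 7, 19), 81),
            (date(2019, 7, 25), 81),
            (date(2020, 3, 13), 115),  # national-emergency declaration
        ],
    )
    def test_known_weeks(self, d, expected):
        assert week_index_of(d, ANCHOR) == expected

    def test_date_before_anchor_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            week_index_of(date(2017, 12, 31), ANCHOR)

    def test_non_friday_anchor_rejected(self):
        with pytest.raises(ValueError, match="not a Friday"):
            week_index_of(date(2018, 1, 10), date(2018, 1, 6))

    @settings(max_examples=200, deadline=None)
    @given(offset=st.integers(min_value=0, max_value=2000))
    def test_increments_by_one_every_seven_days(self, offset):
        d = ANCHOR + timedelta(days=offset)
        w = week_index_of(d, ANCHOR)
        assert w == 1 + offset // 7
        assert week_index_of(d + timedelta(days=7), ANCHOR) == w + 1
        assert week_index_of(d + timedelta(days=1), ANCHOR) >= w


class TestSpanWeeks:
    def test_single_week(self):
        assert span_weeks(date(2018, 1, 5), date(2018, 1, 11)) == 1

    def test_study_span_is_142_weeks(self):
        assert span_weeks(date(2018, 1, 5), date(2020, 9, 24)) == 142

    def test_pulse_window_span(self):
        # 2020-03-13 through the Thursday nine weeks later
        assert span_weeks(date(2020, 3, 13), date(2020, 5, 14)) == 9

    def test_partial_week_rejected(self):
        with pytest.raises(ValueError, match="not a Thursday"):
            span_weeks(date(2018, 1, 5), date(2018, 1, 10))

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            span_weeks(date(2018, 1, 5), date(2017, 1, 4))


class TestFilterEncounters:
    def test_boundary_age_excluded(self):
        kept, removed = filter_encounters(
            [make_record(age_years=17), make_record(age_years=18)], FilterSpec()
        )
        assert len(kept) == 1 and kept[0].age_years == 18
        assert removed["age"] == 1

    def test_other_payer_excluded(self):
        kept, removed = filter_encounters([make_record(payer="other")], FilterSpec())
        assert kept == [] and removed["payer"] == 1

    def test_matches_brute_force_oracle_on_generated_fixture(self):
        rng = np.random.default_rng(42)
        records = []
        for _ in range(1000):
            records.append(
                make_record(
                    visit_date=ANCHOR + timedelta(days=int(rng.integers(0, 400))),
                    ethnicity=str(rng.choice(["latino", "non_latino", "unknown"], p=[0.7, 0.2, 0.1])),
                    age_years=int(rng.integers(0, 95)),
                    payer=str(rng.choice(["restricted_medical", "full_medical", "other"])),
                    disposition=str(rng.choice(["treat_release", "inpatient"], p=[0.8, 0.2])),
                )
            )
        spec = FilterSpec()
        expected = [
            r
            for r in records
            if r.age_years >= 18
            and r.ethnicity == "latino"
            and r.payer in ("restricted_medical", "full_medical")
            and r.disposition == "treat_release"
        ]
        kept, removed = filter_encounters(records, spec)
        assert kept == expected
        assert len(kept) + sum(removed.values()) == 1000

    def test_order_preserved(self):
        records = [make_record(age_years=a) for a in (30, 20, 50, 25)]
        kept, _ = filter_encounters(records, FilterSpec())
        assert [r.age_years for r in kept] == [30, 20, 50, 25]

    def test_inpatient_kept_by_sensitivity_filter(self):
        rec = make_record(disposition="inpatient")
        kept, _ = filter_encounters([rec], FilterSpec().with_inpatient())
        assert kept == [rec]


class TestBinWeekly:
    def test_no_records_gives_zeros(self):
        series = bin_weekly([], ANCHOR, 5)
        assert series.counts == (0, 0, 0, 0, 0)

    def test_thursday_closes_week_one(self):
        recs = [make_record(visit_date=date(2018, 1, 11))] * 3
        series = bin_weekly(recs, ANCHOR, 2)
        assert series.counts == (3, 0)

    def test_conservation_and_independent_tally(self):
        rng = np.random.default_rng(7)
        n_weeks = 12
        offsets = rng.integers(0, 7 * n_weeks, size=300)
        recs = [make_record(visit_date=ANCHOR + timedelta(days=int(o))) for o in offsets]
        series = bin_weekly(recs, ANCHOR, n_weeks)
        assert sum(series.counts) == len(recs)
        # independent tally by plain day arithmetic
        tally = np.zeros(n_weeks, dtype=int)
        for o in offsets:
            tally[o // 7] += 1
        assert series.counts == tuple(tally)

    def test_out_of_span_record_names_its_date(self):
        stray = make_record(visit_date=date(2019, 6, 1))
        with pytest.raises(ValueError, match="2019-06-01"):
            bin_weekly([stray], ANCHOR, 4)


class TestDomainTypes:
    def test_weekly_series_requires_friday_anchor(self):
        with pytest.raises(ValueError, match="not a Friday"):
            WeeklySeries(date(2018, 1, 6), (1, 2, 3))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            WeeklySeries(ANCHOR, (1, -2))

    def test_pair_requires_alignment(self):
        a = WeeklySeries(ANCHOR, (1, 2, 3))
        b = WeeklySeries(ANCHOR, (1, 2))
        with pytest.raises(ValueError, match="equal length"):
            SeriesPair(dependent=a, control=b)

    def test_invalid_categories_rejected(self):
        with pytest.raises(ValueError):
            make_record(ethnicity="hispanic")
        with pytest.raises(ValueError):
            make_record(age_years=-1)


class TestCsvDialects:
    def test_encounter_frame_round_trip(self):
        records = [make_record(), make_record(age_years=72, sex="male")]
        assert frame_to_records(records_to_frame(records)) == records

    def test_pair_frame_round_trip(self):
        pair = SeriesPair(
            dependent=WeeklySeries(ANCHOR, (5, 6, 7), "dep"),
            control=WeeklySeries(ANCHOR, (8, 9, 10), "ctl"),
        )
        frame = pair_to_frame(pair)
        assert list(frame.columns) == [
            "week_index",
            "week_start_date",
            "count_dependent",
            "count_control",
        ]
        back = frame_to_pair(frame)
        assert back.dependent.counts == pair.dependent.counts
        assert back.control.counts == pair.control.counts
        assert back.anchor_date == ANCHOR

    def test_gapped_week_index_rejected(self):
        frame = pd.DataFrame(
            {
                "week_index": [1, 3],
                "week_start_date": ["2018-01-05", "2018-01-19"],
                "count_dependent": [1, 2],
                "count_control": [3, 4],
            }
        )
        with pytest.raises(ValueError, match="without gaps"):
            frame_to_pair(frame)
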