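import datetime as dt

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddisignal.case_extraction import (
    ExtractionConfig,
    build_analysis_cases,
    deduplicate_cases,
    exclude_injectable_cases,
    filter_concomitant_drugs,
    resolve_onset_date,
    select_cases_with_drug,
)
from ddisignal.srs_io import DrugRecord, EventRecord, dataset_from_frames

CONFIG = ExtractionConfig(index_drug_names=frozenset({"pitavastatin"}))


def _dataset(demo, drug, reac):
    return dataset_from_frames(
        pd.DataFrame(demo, columns=["case_id", "sex", "age"]),
        pd.DataFrame(drug, columns=["case_id", "drug_name", "route", "start_date", "end_date"]),
        pd.DataFrame(reac, columns=["case_id", "pt_code", "pt_name", "onset_date"]),
    )


def _drug(name="x", start=None, end=None, case="A", route="oral", order=0):
    return DrugRecord(
        case_id=case,
        drug_name=name,
        route=route,
        start_date=start,
        end_date=end,
        record_order=order,
    )


def _event(onset, case="A", pt="10039020", order=0):
    return EventRecord(
        case_id=case, pt_code=pt, pt_name="", onset_date=onset, record_order=order
    )


class TestSelectCases:
    def setup_method(self):
        self.ds = _dataset(
            [(c, "male", "60s") for c in "ABCDE"],
            [
                ("A", "pitavastatin", "oral", "", ""),
                ("B", "aspirin", "oral", "", ""),
                ("C", "pitavastatin", "oral", "", ""),
                ("C", "pravastatin", "oral", "", ""),
                ("D", "valsartan", "oral", "", ""),
                ("E", "metformin", "oral", "", ""),
            ],
            [],
        )

    def test_cases_with_index_drug(self):
        assert select_cases_with_drug(self.ds, {"pitavastatin"}) == {"A", "C"}

    def test_two_index_drugs_case_counted_once(self):
        assert select_cases_with_drug(self.ds, {"pitavastatin", "pravastatin"}) == {"A", "C"}

    def test_no_user_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert select_cases_with_drug(self.ds, {"cerivastatin"}) == set()


class TestInjectableExclusion:
    def test_whole_case_excluded_on_one_injectable_drug(self):
        ds = _dataset(
            [("A", "male", "60s")],
            [
                ("A", "pitavastatin", "oral", "", ""),
                ("A", "furosemide", "Intravenous drip", "", ""),
            ],
            [],
        )
        assert exclude_injectable_cases(ds, {"A"}, {"intravenous"}) == set()

    def test_all_oral_case_retained(self):
        ds = _dataset(
            [("A", "male", "60s")],
            [("A", "pitavastatin", "oral", "", "")],
            [],
        )
        assert exclude_injectable_cases(ds, {"A"}, {"intravenous"}) == {"A"}

    def test_empty_terms_is_identity(self):
        ds = _dataset(
            [("A", "male", "60s")],
            [("A", "x", "intravenous", "", "")],
            [],
        )
        assert exclude_injectable_cases(ds, {"A"}, set()) == {"A"}


class TestDeduplication:
    def _ds(self, extra_drug=False):
        drugs = [
            ("A", "pitavastatin", "oral", "", ""),
            ("A", "allopurinol", "oral", "", ""),
            ("B", "pitavastatin", "oral", "", ""),
            ("B", "allopurinol", "oral", "", ""),
        ]
        if extra_drug:
            drugs.append(("B", "valsartan", "oral", "", ""))
        return _dataset(
            [("A", "male", "60s"), ("B", "male", "60s")], drugs, []
        )

    def test_first_registered_kept(self):
        assert deduplicate_cases(self._ds(), {"A", "B"}) == {"A"}

    def test_drug_set_mismatch_keeps_both(self):
        assert deduplicate_cases(self._ds(extra_drug=True), {"A", "B"}) == {"A", "B"}

    def test_idempotent(self):
        ds = self._ds()
        once = deduplicate_cases(ds, {"A", "B"})
        assert deduplicate_cases(ds, once) == once


class TestResolveOnset:
    def test_earliest_non_missing(self):
        events = [_event(dt.date(2017, 5, 1)), _event(dt.date(2017, 3, 1))]
        assert resolve_onset_date(events) == dt.date(2017, 3, 1)

    def test_all_missing(self):
        assert resolve_onset_date([_event(None), _event(None)]) is None

    def test_single(self):
        assert resolve_onset_date([_event(dt.date(2017, 6, 1))]) == dt.date(2017, 6, 1)


ONSET = dt.date(2017, 6, 10)


class TestTimingFilter:
    @pytest.mark.parametrize(
        "start,end,kept",
        [
            (dt.date(2017, 6, 15), None, False),  # started after onset
            (dt.date(2017, 1, 1), dt.date(2017, 6, 5), True),  # stopped 5 d before
            (dt.date(2017, 1, 1), dt.date(2017, 5, 20), False),  # stopped 21 d before
            (dt.date(2016, 5, 1), None, False),  # open-ended, 405 d before onset
            (dt.date(2017, 1, 1), None, True),  # open-ended, within a year
            (dt.date(2017, 1, 1), dt.date(2017, 7, 1), True),  # spans onset
            (None, None, True),  # undated drug kept
            (None, dt.date(2017, 6, 8), True),  # end-only, within window
            (None, dt.date(2017, 5, 1), False),  # end-only, outside window
            (dt.date(2017, 6, 3), None, True),  # boundary: exactly 7 d... within 365
            (dt.date(2017, 1, 1), dt.date(2017, 6, 3), True),  # exactly 7 d inclusive
        ],
    )
    def test_rules(self, start, end, kept):
        records = [_drug(start=start, end=end)]
        out = filter_concomitant_drugs(records, ONSET, CONFIG)
        assert (len(out) == 1) is kept

    def test_missing_onset_keeps_everything(self):
        records = [
            _drug("a", dt.date(2018, 1, 1), None),
            _drug("b", None, dt.date(2000, 1, 1)),
        ]
        assert len(filter_concomitant_drugs(records, None, CONFIG)) == 2

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=1, max_value=30),
        st.lists(st.integers(min_value=0, max_value=40), max_size=8),
    )
    def test_widening_discontinuation_window_is_monotone(self, w, extra, gaps):
        """A larger discontinuation window never drops a retained drug."""
        records = [
            _drug(f"d{i}", dt.date(2017, 1, 1), ONSET - dt.timedelta(days=g))
            for i, g in enumerate(gaps)
        ]
        narrow = ExtractionConfig(
            index_drug_names=frozenset({"pitavastatin"}),
            discontinuation_window_days=w + 1,
        )
        wide = ExtractionConfig(
            index_drug_names=frozenset({"pitavastatin"}),
            discontinuation_window_days=w + 1 + extra,
        )
        kept_narrow = {r.drug_name for r in filter_concomitant_drugs(records, ONSET, narrow)}
        kept_wide = {r.drug_name for r in filter_concomitant_drugs(records, ONSET, wide)}
        assert kept_narrow <= kept_wide


class TestFullCascade:
    def test_worked_fixture_survivors(self, worked_fixture):
        dataset, expected = worked_fixture
        result = build_analysis_cases(dataset, CONFIG)
        assert [c.case_id for c in result.cases] == expected["surviving_case_ids"]
        for case in result.cases:
            assert set(case.concomitant_drugs) == expected["concomitant_sets"][case.case_id]

    def test_exclusions_accounted(self, worked_fixture):
        dataset, expected = worked_fixture
        result = build_analysis_cases(dataset, CONFIG)
        case_stage_exclusions = [
            e for e in result.exclusions if e.stage in ("injectable", "duplicate", "index_timing")
        ]
        assert result.n_selected == len(result.cases) + len(case_stage_exclusions)
        dup_excluded = {e.case_id for e in result.exclusions if e.stage == "duplicate"}
        assert dup_excluded == set(expected["duplicates_removed"])
        inj = [e.case_id for e in result.exclusions if e.stage == "injectable"]
        assert inj == expected["injectable_removed"]

    def test_event_flag_tracks_target_pt(self, worked_fixture):
        dataset, expected = worked_fixture
        result = build_analysis_cases(dataset, CONFIG)
        flagged = {c.case_id for c in result.cases if c.event_flag}
        assert flagged == {"C01", "C05", "C10"}

    def test_case_dropped_when_index_drug_starts_after_onset(self):
        ds = _dataset(
            [("A", "male", "60s")],
            [
                ("A", "pitavastatin", "oral", "20170615", ""),
                ("A", "allopurinol", "oral", "20170101", ""),
            ],
            [("A", "10039020", "Rhabdomyolysis", "20170610")],
        )
        with pytest.raises(Exception):
            build_analysis_cases(ds, CONFIG)

    def test_rerun_on_survivors_is_idempotent(self, worked_fixture):
        dataset, _ = worked_fixture
        first = build_analysis_cases(dataset, CONFIG)
        # restricting the dataset to survivors and re-running changes nothing
        ids = {c.case_id for c in first.cases}
        sub = _dataset(
            [(d.case_id, d.sex, d.age_band) for d in dataset.demographics if d.case_id in ids],
            [
                (r.case_id, r.drug_name, r.route, r.start_date_raw, r.end_date_raw)
                for r in dataset.drugs
                if r.case_id in ids
            ],
            [
                (e.case_id, e.pt_code, e.pt_name, e.onset_date_raw)
                for e in dataset.events
                if e.case_id in ids
            ],
        )
        second = build_analysis_cases(sub, CONFIG)
        assert [(c.case_id, c.concomitant_drugs, c.event_flag) for c in second.cases] == [
            (c.case_id, c.concomitant_drugs, c.event_flag) for c in first.cases
        ]
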