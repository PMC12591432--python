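"""Severity classification, eligibility filtering, exact matching and the
descriptive cohort summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from comorbits.cohort import (
    SEVERITY_ORDER,
    InjuryRecord,
    apply_eligibility,
    assign_control_index,
    classify_severity,
    exact_match,
    summarize_cohort,
)

_RANK = {s: i for i, s in enumerate(SEVERITY_ORDER)}


def _subject(sid, group="exposed", sex="M", race="White", eth="Non-Hispanic",
             age=30, index="2010-06", engagement=5.0,
             obs=("2002-01", "2023-12"), severity="mild"):
    return {
        "subject_id": sid, "group": group,
        "severity": severity if group == "exposed" else "none",
        "sex": sex, "race": race, "ethnicity": eth, "age_at_index": age,
        "index_month": index if group == "exposed" else "",
        "engagement_years": engagement,
        "observation_start": obs[0], "observation_end": obs[1],
    }


class TestClassifySeverity:
    @pytest.mark.parametrize(
        "records, expected",
        [
            ([InjuryRecord(loc_minutes=10, aoc_pta_days=0.5)], "mild"),
            ([InjuryRecord(loc_minutes=30)], "mild"),       # boundary: 0-30 min
            ([InjuryRecord(loc_minutes=45)], "moderate_severe"),
            ([InjuryRecord(aoc_pta_days=3)], "moderate_severe"),
            ([InjuryRecord()], "unclassified"),
            (
                [InjuryRecord(loc_minutes=10),
                 InjuryRecord(loc_minutes=45, penetrating=True)],
                "penetrating",
            ),
            (
                [InjuryRecord(loc_minutes=10), InjuryRecord(loc_minutes=45)],
                "moderate_severe",  # highest severity wins
            ),
        ],
    )
    def test_examples(self, records, expected):
        assert classify_severity(records) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_severity([])
        with pytest.raises(ValueError):
            InjuryRecord(loc_minutes=-1)

    @given(
        records=st.lists(
            st.builds(
                InjuryRecord,
                loc_minutes=st.one_of(st.none(), st.floats(0, 500)),
                aoc_pta_days=st.one_of(st.none(), st.floats(0, 30)),
                penetrating=st.booleans(),
            ),
            min_size=1, max_size=5,
        ),
        extra=st.builds(
            InjuryRecord,
            loc_minutes=st.one_of(st.none(), st.floats(0, 500)),
            penetrating=st.booleans(),
        ),
    )
    def test_monotone_in_records(self, records, extra):
        """Adding an injury record never lowers the classified severity."""
        before = classify_severity(records)
        after = classify_severity(records + [extra])
        assert _RANK[after] >= _RANK[before]


class TestEligibility:
    def test_exclusion_reasons(self):
        subjects = pd.DataFrame([
            _subject("a", index="2007-06"),
            _subject("b", engagement=1.5),
            _subject("c", obs=("2009-01", "2023-12"), index="2010-06"),
            _subject("d"),
            _subject("p1", group="control"),
        ])
        kept, log = apply_eligibility(subjects)
        assert set(kept["subject_id"]) == {"d", "p1"}
        assert dict(zip(log["subject_id"], log["reason"])) == {
            "a": "index_window", "b": "engagement", "c": "coverage",
        }

    def test_all_eligible_is_identity(self):
        subjects = pd.DataFrame([_subject("a"), _subject("b", index="2017-12")])
        kept, log = apply_eligibility(subjects)
        pd.testing.assert_frame_equal(kept, subjects)
        assert log.empty

    def test_missing_fields_raise(self):
        with pytest.raises(ValueError, match="missing fields"):
            apply_eligibility(pd.DataFrame({"subject_id": ["a"], "group": ["exposed"]}))


class TestExactMatch:
    def test_single_pair_inherits_index(self):
        cases = pd.DataFrame([_subject("t1", age=30)])
        pool = pd.DataFrame([_subject("c1", group="control", age=30)])
        pairs, unmatched = exact_match(cases, pool)
        assert len(pairs) == 1 and not unmatched
        assert pairs.iloc[0]["control_id"] == "c1"
        assert pairs.iloc[0]["index_month"] == "2010-06"

    def test_empty_pool_all_unmatched(self):
        cases = pd.DataFrame([_subject("t1"), _subject("t2")])
        pairs, unmatched = exact_match(cases, cases.iloc[:0])
        assert pairs.empty and unmatched == ["t1", "t2"]

    def test_controls_are_unique(self):
        cases = pd.DataFrame([_subject("t1"), _subject("t2")])
        pool = pd.DataFrame([_subject("c1", group="control")])
        pairs, unmatched = exact_match(cases, pool)
        assert len(pairs) == 1 and len(unmatched) == 1

    def test_overlapping_ids_raise(self):
        cases = pd.DataFrame([_subject("x")])
        with pytest.raises(ValueError, match="overlap"):
            exact_match(cases, cases)

    def test_bijection_and_covariate_equality(self):
        """Pairing is injective into the pool and matched covariates are
        exactly equal across groups."""
        rng = np.random.default_rng(5)
        cases = pd.DataFrame([
            _subject(f"t{i}", age=int(rng.integers(25, 35)),
                     sex=rng.choice(["M", "F"]), index=f"20{rng.integers(10, 16)}-03")
            for i in range(60)
        ])
        pool = pd.DataFrame([
            _subject(f"c{i}", group="control", age=int(rng.integers(25, 35)),
                     sex=rng.choice(["M", "F"]))
            for i in range(120)
        ])
        pairs, unmatched = exact_match(cases, pool, seed=1)
        assert pairs["control_id"].is_unique
        assert pairs["case_id"].is_unique
        assert len(pairs) + len(unmatched) == len(cases)
        merged = (
            pairs.merge(cases, left_on="case_id", right_on="subject_id")
            .merge(pool, left_on="control_id", right_on="subject_id",
                   suffixes=("_case", "_ctl"))
        )
        for cov in ["age_at_index", "sex", "race", "ethnicity"]:
            assert (merged[f"{cov}_case"] == merged[f"{cov}_ctl"]).all()

    def test_deterministic_given_seed(self):
        cases = pd.DataFrame([_subject(f"t{i}", age=30) for i in range(10)])
        pool = pd.DataFrame(
            [_subject(f"c{i}", group="control", age=30) for i in range(20)]
        )
        p1, _ = exact_match(cases, pool, seed=9)
        p2, _ = exact_match(cases, pool, seed=9)
        pd.testing.assert_frame_equal(p1, p2)


class TestSummary:
    def _matched(self):
        cases = pd.DataFrame([
            _subject("t1", sex="F"), _subject("t2"), _subject("t3"),
        ])
        pool = pd.DataFrame([
            _subject("c1", group="control", sex="F"),
            _subject("c2", group="control"), _subject("c3", group="control"),
        ])
        subjects = pd.concat([cases, pool], ignore_index=True)
        pairs, _ = exact_match(cases, pool)
        return subjects, pairs

    def test_matched_percentages_identical(self):
        subjects, pairs = self._matched()
        summary = summarize_cohort(subjects, pairs)
        sex = summary[(summary["covariate"] == "sex")]
        by_group = sex.pivot(index="level", columns="group", values="percent")
        assert np.allclose(by_group["exposed"], by_group["control"])

    def test_control_index_assignment(self):
        subjects, pairs = self._matched()
        cohort = assign_control_index(subjects, pairs)
        controls = cohort[cohort["group"] == "control"]
        assert (controls["index_month"] == "2010-06").all()

    def test_single_subject_cohort(self):
        subjects = pd.DataFrame([
            _subject("t1"), _subject("c1", group="control"),
        ])
        pairs, _ = exact_match(subjects.iloc[:1], subjects.iloc[1:])
        summary = summarize_cohort(subjects, pairs)
        assert (summary[summary["covariate"] == "n"]["count"] == 1).all()

    def test_empty_cohort_raises(self):
        subjects = pd.DataFrame([_subject("t1")])
        pairs = pd.DataFrame(columns=["case_id", "control_id", "index_month"])
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort(subjects, pairs)
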