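"""Cohort ingestion, history normalization, strata and patient filters."""

import datetime as dt

import numpy as np
import pytest

from trajmine.cohort import (
    SEX_FEMALE,
    SEX_MALE,
    CohortError,
    apply_patient_filters,
    assign_age_groups,
    read_event_table,
    read_patient_table,
)
from conftest import DAY0, make_cohort, make_patient


def _patient_csv(tmp_path, rows, header="PID,SEX,BIRTH_YEAR,TAGS"):
    p = tmp_path / "patients.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def _event_csv(tmp_path, rows):
    p = tmp_path / "events.csv"
    p.write_text("PID,CODE,DATE\n" + "\n".join(rows) + "\n")
    return p


class TestPatientTable:
    def test_reads_rows(self, tmp_path):
        src = _patient_csv(tmp_path, ["p1,F,1950,", "p2,M,1960,NMIBC", "p3,2,1970,NMIBC;MIBC"])
        pats = read_patient_table(src)
        assert len(pats) == 3
        assert pats[0].sex == SEX_FEMALE
        assert pats[2].sex == SEX_FEMALE  # numeric dialect: 2 = female
        assert pats[2].tags == {"NMIBC", "MIBC"}

    def test_duplicate_pid_rejected(self, tmp_path):
        src = _patient_csv(tmp_path, ["p1,F,1950,", "p1,M,1960,"])
        with pytest.raises(CohortError, match="p1"):
            read_patient_table(src)

    def test_bad_birth_year_skipped_with_warning(self, tmp_path):
        src = _patient_csv(tmp_path, ["p1,F,19xx,", "p2,M,1950,"])
        with pytest.warns(UserWarning, match="birth year"):
            pats = read_patient_table(src)
        assert [p.pid for p in pats] == ["p2"]

    def test_empty_birth_year_is_unknown(self, tmp_path):
        src = _patient_csv(tmp_path, ["p1,F,,"])
        assert read_patient_table(src)[0].birth_year is None


class TestEventTable:
    def test_level_map_dedup_first_occurrence(self, tmp_path, vocab):
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,M,1950,"]))
        src = _event_csv(tmp_path, ["p1,C67.2,2010-06-01", "p1,C67.9,2010-01-01"])
        cohort = read_event_table(src, vocab, 2, pats, anchor_codes=("C67",))
        assert [(e.code, e.date.isoformat()) for e in cohort.patients[0].events] == [
            ("C67", "2010-01-01")
        ]

    def test_histories_sorted(self, tmp_path, vocab):
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,M,1950,"]))
        src = _event_csv(tmp_path, ["p1,J44,2015-01-01", "p1,I10,2010-01-01"])
        cohort = read_event_table(src, vocab, 2, pats)
        assert [e.code for e in cohort.patients[0].events] == ["I10", "J44"]

    def test_unknown_pid_dropped_and_counted(self, tmp_path, vocab):
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,M,1950,"] * 1))
        rows = ["p1,J44,2010-01-01"] * 19 + ["ghost,J44,2010-01-01"]
        cohort = read_event_table(_event_csv(tmp_path, rows), vocab, 2, pats)
        assert cohort.dropped_event_rows == 1

    def test_excessive_bad_rows_abort(self, tmp_path, vocab):
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,M,1950,"]))
        rows = ["p1,J44,2010-01-01", "p1,I10,not-a-date"]
        with pytest.raises(CohortError, match="10%"):
            read_event_table(_event_csv(tmp_path, rows), vocab, 2, pats)

    def test_excluded_chapter_dropped(self, tmp_path, vocab):
        vocab.configure_exclusions(["XV"])
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,F,1950,"]))
        src = _event_csv(tmp_path, ["p1,O10,2010-01-01", "p1,J44,2011-01-01"])
        cohort = read_event_table(src, vocab, 2, pats)
        assert [e.code for e in cohort.patients[0].events] == ["J44"]

    def test_anchor_from_raw_history(self, tmp_path, vocab):
        pats = read_patient_table(_patient_csv(tmp_path, ["p1,M,1950,"]))
        src = _event_csv(tmp_path, ["p1,C67.9,2012-05-01", "p1,C67.2,2011-03-01"])
        cohort = read_event_table(src, vocab, 2, pats, anchor_codes=("C67.2",))
        assert cohort.patients[0].anchor_date == dt.date(2011, 3, 1)


class TestAgeGroups:
    def test_equal_width_bins(self):
        specs = [(f"p{y}", 1, y, []) for y in range(1920, 2020)]
        cohort = make_cohort(specs, n_age_groups=10)
        i_1955 = cohort.pid_index["p1955"]
        assert cohort.age_bin[i_1955] == 3  # floor((1955-1920)/10)

    def test_boundary_clamped_into_last_group(self):
        cohort = make_cohort([("a", 1, 1920, []), ("b", 1, 2019, [])], n_age_groups=10)
        assert cohort.age_bin[cohort.pid_index["b"]] == 9

    def test_single_group(self):
        cohort = make_cohort([("a", 1, 1940, []), ("b", 2, 1980, [])], n_age_groups=1)
        assert set(cohort.age_bin) == {0}

    def test_all_birth_years_missing_rejected(self, tmp_path):
        cohort = make_cohort([("a", 1, 1940, [])])
        cohort.patients[0].birth_year = None
        cohort._rebuild_arrays()
        with pytest.raises(CohortError):
            assign_age_groups(cohort, 5)

    def test_strata_partition_stratifiable_patients(self):
        rng = np.random.default_rng(1)
        specs = [
            (f"p{i}", int(rng.integers(1, 3)), 1930 + int(rng.integers(0, 60)), [])
            for i in range(50)
        ]
        cohort = make_cohort(specs, n_age_groups=4)
        sizes = sum(len(v) for v in cohort.stratum_members().values())
        assert sizes == 50


class TestPatientFilters:
    def _mixed(self):
        return make_cohort(
            [
                ("m1", 1, 1940, [("C67", 0)]),
                ("m2", 1, 1980, [("C67", 0)]),
                ("f1", 2, 1935, [("C67", 0)]),
            ]
        )

    def test_sex_filter(self):
        sub = apply_patient_filters(self._mixed(), ["male"])
        assert sorted(p.pid for p in sub.patients) == ["m1", "m2"]

    def test_age_filter_year_arithmetic(self):
        # born 1940, anchor 2009 -> whole-year age 69: excluded from age70+
        p_69 = make_patient("a", [("C67", 0)], birth_year=1940, anchor_day=-dt.date(2010, 1, 1).toordinal() + dt.date(2009, 5, 1).toordinal())
        p_70 = make_patient("b", [("C67", 0)], birth_year=1939, anchor_day=0)
        from trajmine.cohort import Cohort

        cohort = Cohort([p_69, p_70])
        assign_age_groups(cohort, 1)
        sub = apply_patient_filters(cohort, ["age70+"])
        assert [p.pid for p in sub.patients] == ["b"]

    def test_empty_filter_list_is_identity(self):
        cohort = self._mixed()
        assert apply_patient_filters(cohort, []) is cohort

    def test_unknown_filter_rejected(self):
        with pytest.raises(CohortError, match="registered"):
            apply_patient_filters(self._mixed(), ["age80+"])

    def test_filter_composition(self):
        cohort = make_cohort(
            [
                ("a", 1, 1940, []),
                ("b", 1, 1950, []),
                ("c", 2, 1940, []),
            ]
        )
        both = apply_patient_filters(cohort, ["male", "tag:X"])
        seq = apply_patient_filters(apply_patient_filters(cohort, ["male"]), ["tag:X"])
        assert [p.pid for p in both.patients] == [p.pid for p in seq.patients]

    def test_tag_filter(self):
        cohort = make_cohort([("a", 1, 1940, [])])
        cohort.patients[0].tags = frozenset({"NMIBC"})
        assert len(apply_patient_filters(cohort, ["NMIBC"]).patients) == 1
        assert len(apply_patient_filters(cohort, ["MIBC"]).patients) == 0


def test_dedup_means_one_event_per_code():
    cohort = make_cohort([("a", 1, 1950, [("J44", 0), ("I10", 10)])])
    codes = [e.code for p in cohort.patients for e in p.events]
    assert len(codes) == len(set(codes))
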