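"""Event-record I/O, domain-type invariants, and the baseline cohort table."""

import pytest

import remipk as rp
from remipk.cohort import summarize_cohort, table1_fixture
from remipk.data import (DatasetFormatError, DatasetValidationError,
                         read_dataset, write_dataset)


def _two_subject_dataset():
    cov = rp.CovariateRecord(sex=0, pump_speed=2300.0, age=55.0, weight=60.0)
    s1 = rp.SubjectRecord(
        id="A", covariates=cov,
        doses=(rp.InfusionEvent(0.0, 0.35, 48.0),),
        observations=(rp.Observation(10.0, 1.2), rp.Observation(24.0, 0.9)))
    s2 = rp.SubjectRecord(
        id="B", covariates=rp.CovariateRecord(sex=1, pump_speed=2500.0),
        doses=(rp.InfusionEvent(0.0, 0.5, 24.0), rp.InfusionEvent(24.0, 0.25, 24.0)),
        observations=(rp.Observation(8.0, 2.0), rp.Observation(40.0, 1.0),
                      rp.Observation(48.5, 0.03)))
    return rp.StudyDataset(subjects=(s1, s2))


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        ds = _two_subject_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.subjects == ds.subjects

    def test_generated_study_round_trips(self, tmp_path, small_study):
        path = tmp_path / "study.csv"
        write_dataset(small_study, path)
        assert read_dataset(path).subjects == small_study.subjects

    def test_repeated_writes_byte_stable(self, tmp_path):
        ds = _two_subject_dataset()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(ds, p1)
        write_dataset(ds, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_blq_flag_set_on_read(self, tmp_path):
        ds = _two_subject_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        last = back.subjects[1].observations[-1]
        assert last.concentration == 0.03 and last.blq_flag
        assert all(o.blq_flag == (o.concentration < rp.LLOQ)
                   for s in back for o in s.observations)


class TestValidation:
    def test_decreasing_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "ID,TIME,DV,RATE,EVID,MDV,SEX,PUMP\n"
            "X,0,.,0.35,1,1,0,2300\n"
            "X,24,1.0,.,0,0,0,2300\n"
            "X,10,1.2,.,0,0,0,2300\n")
        with pytest.raises(DatasetValidationError, match="X"):
            read_dataset(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,DV,RATE,MDV\nX,0,.,0.35,1\n")
        with pytest.raises(DatasetFormatError, match="EVID"):
            read_dataset(path)

    def test_write_refuses_non_dataset(self, tmp_path):
        with pytest.raises(DatasetValidationError):
            write_dataset([], tmp_path / "x.csv")

    def test_empty_dataset_rejected(self):
        with pytest.raises(DatasetValidationError):
            rp.StudyDataset(subjects=())

    @pytest.mark.parametrize("kwargs", [
        dict(sex=2, pump_speed=2300.0),
        dict(sex=0, pump_speed=0.0),
        dict(sex=0, pump_speed=2300.0, weight=-1.0),
        dict(sex=0, pump_speed=2300.0, crrt=3),
    ])
    def test_covariate_invariants(self, kwargs):
        with pytest.raises(DatasetValidationError):
            rp.CovariateRecord(**kwargs)

    def test_blq_flag_consistency_enforced(self):
        with pytest.raises(DatasetValidationError):
            rp.Observation(time=1.0, concentration=0.5, blq_flag=True)

    def test_subject_needs_a_dose(self):
        with pytest.raises(DatasetValidationError):
            rp.SubjectRecord(id="Z", covariates=rp.CovariateRecord(0, 2300.0),
                             doses=(), observations=())


class TestCohortTable:
    def test_fixture_shape_and_spot_values(self):
        t1 = table1_fixture()
        assert len(t1) == 15
        assert t1.loc[4, "weight"] == 40.8
        assert t1.loc[13, "rate"] == 1.0
        assert t1.attrs["pump_speed_median"] == 2350.0
        assert t1.attrs["pump_speed_iqr"] == (2302.0, 2532.0)

    def test_published_medians_reproduced(self):
        s = summarize_cohort(table1_fixture())
        assert s.loc["age", "median"] == 57
        assert s.loc["weight", "median"] == 65.4
        assert s.loc["bmi", "median"] == 23.8
        assert s.loc["total_protein", "median"] == 4.7
        assert s.loc["rate", "median"] == 0.35
        assert s.loc["ecmo_duration", "median"] == 143

    def test_published_iqrs_reproduced(self):
        s = summarize_cohort(table1_fixture())
        assert (s.loc["age", "q25"], s.loc["age", "q75"]) == (45, 69)
        assert (s.loc["weight", "q25"], s.loc["weight", "q75"]) == (54.5, 70.0)
        assert (s.loc["rate", "q25"], s.loc["rate", "q75"]) == (0.25, 0.35)
        assert (s.loc["ecmo_duration", "q25"], s.loc["ecmo_duration", "q75"]) == (96, 250)

    def test_categorical_counts(self):
        s = summarize_cohort(table1_fixture())
        assert s.loc["sex", "count"] == 10
        assert s.loc["sex", "fraction"] == pytest.approx(10 / 15)
        # the individual-level table lists 9 CRRT recipients
        assert s.loc["crrt", "count"] == 9

    def test_single_subject_cohort(self):
        one = table1_fixture().iloc[[0]]
        s = summarize_cohort(one)
        assert s.loc["age", "median"] == s.loc["age", "q25"] == s.loc["age", "q75"] == 69

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(table1_fixture().iloc[:0])
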