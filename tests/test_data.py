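import math

import numpy as np
import pandas as pd
import pytest

from lcsem import (
    derive_analysis_dataset,
    ks_normality,
    load_records,
    sample_covariance,
)
from lcsem.data import ANALYSIS_VARIABLES, AnalysisDataset, RecordTable

HEADER = (
    "subject_id,sex,age0,pbf_0,bmi_0,skinfold_0,waist_0,crs_0,"
    "pbf_1,bmi_1,skinfold_1,waist_1,crs_1"
)

ROWS = [
    "a,male,44,23.0,25.7,58.6,91.6,21.8,21.9,25.9,61.5,91.5,26.9",
    "b,female,42,33.2,24.7,75.0,79.4,39.6,31.9,25.0,78.2,79.6,40.4",
    "c,male,40,20.0,24.0,50.0,90.0,10.0,21.0,24.5,52.0,91.0,12.0",
]


def write(tmp_path, rows, header=HEADER):
    p = tmp_path / "records.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


class TestLoadRecords:
    def test_well_formed_passthrough(self, tmp_path):
        table = load_records(write(tmp_path, ROWS))
        assert len(table) == 3
        assert table.n_dropped == 0
        assert list(table.frame["sex"]) == ["male", "female", "male"]

    def test_listwise_deletion_counted(self, tmp_path):
        rows = ROWS + ["d,male,41,22,25,55,90,15,21,25,54,89,"]  # missing crs_1
        table = load_records(write(tmp_path, rows))
        assert len(table) == 3
        assert table.n_dropped == 1

    def test_unknown_sex_names_row(self, tmp_path):
        rows = [ROWS[0], ROWS[1].replace("female", "X")]
        with pytest.raises(ValueError, match="unknown sex code 'X'.*\\bb\\b"):
            load_records(write(tmp_path, rows))

    def test_non_numeric_measurement_is_hard_error(self, tmp_path):
        rows = [ROWS[0].replace("25.7", "abc")]
        with pytest.raises(ValueError, match="non-numeric"):
            load_records(write(tmp_path, rows))

    def test_empty_usable_set_is_hard_error(self, tmp_path):
        rows = ["a,male,44,,25.7,58.6,91.6,21.8,21.9,25.9,61.5,91.5,26.9"]
        with pytest.raises(ValueError, match="no usable rows"):
            load_records(write(tmp_path, rows))

    def test_column_mapping_binds_arbitrary_headers(self, tmp_path):
        header = HEADER.replace("bmi_0", "BMI_baseline")
        rows = [r for r in ROWS]
        p = write(tmp_path, rows, header=header)
        table = load_records(p, column_map={"bmi_0": "BMI_baseline"})
        assert table.frame["bmi_0"].iloc[0] == 25.7

    def test_tab_separated_input(self, tmp_path):
        p = tmp_path / "records.tsv"
        p.write_text(
            "\n".join([HEADER.replace(",", "\t")] + [r.replace(",", "\t") for r in ROWS])
        )
        assert len(load_records(p, sep="\t")) == 3


class TestDeriveAnalysisDataset:
    def test_log_transform_value(self, tmp_path):
        table = load_records(write(tmp_path, ROWS))
        ds = derive_analysis_dataset(table, "male", min_n=2)
        j = ds.variable_names.index("log_bmi0")
        recovered = ds.data_matrix[0, j] + ds.centering_means["log_bmi0"]
        assert recovered == pytest.approx(math.log(25.7), abs=5e-5)
        assert recovered == pytest.approx(3.2465, abs=1e-4)

    def test_change_is_delta_on_log_scale(self, tmp_path):
        table = load_records(write(tmp_path, ROWS))
        ds = derive_analysis_dataset(table, "male", min_n=2)
        j = ds.variable_names.index("d_log_bmi")
        val = ds.data_matrix[0, j] + ds.centering_means["d_log_bmi"]
        assert val == pytest.approx(math.log(25.9) - math.log(25.7), rel=1e-9)
        assert val == pytest.approx(0.007752, abs=1e-6)

    def test_all_columns_centered(self, male_cohort):
        ds = derive_analysis_dataset(male_cohort, "male")
        assert np.all(np.abs(ds.data_matrix.mean(axis=0)) < 1e-10)
        assert ds.variable_names == ANALYSIS_VARIABLES

    def test_nonpositive_value_names_subject_and_variable(self, tmp_path):
        rows = [ROWS[0].replace("58.6", "-1")]
        table = load_records(write(tmp_path, rows))
        with pytest.raises(ValueError, match="skinfold.*'a'"):
            derive_analysis_dataset(table, "male", min_n=1)

    def test_too_few_records(self, tmp_path):
        table = load_records(write(tmp_path, ROWS))
        with pytest.raises(ValueError, match="at least 12"):
            derive_analysis_dataset(table, "male")

    def test_sexes_partition_usable_records(self, both_sexes_cohort):
        m = derive_analysis_dataset(both_sexes_cohort, "male")
        f = derive_analysis_dataset(both_sexes_cohort, "female")
        assert m.n + f.n == len(both_sexes_cohort)

    def test_round_trip_uncentering_recovers_measurements(self, male_cohort):
        """Un-centering plus exponentiation reproduces the raw records."""
        ds = derive_analysis_dataset(male_cohort, "male")
        raw = male_cohort.frame
        mu = ds.centering_means
        bmi0 = np.exp(ds.column("log_bmi0") + mu["log_bmi0"])
        np.testing.assert_allclose(bmi0, raw["bmi_0"], rtol=1e-10)
        pbf1 = (ds.column("pbf0") + mu["pbf0"]) + (ds.column("d_pbf") + mu["d_pbf"])
        np.testing.assert_allclose(pbf1, raw["pbf_1"], rtol=1e-10)
        waist1 = np.exp(
            ds.column("log_waist0") + mu["log_waist0"] + ds.column("d_log_waist") + mu["d_log_waist"]
        )
        np.testing.assert_allclose(waist1, raw["waist_1"], rtol=1e-10)


class TestSampleCovariance:
    def test_unbiased_divisor_hand_example(self):
        # 3 subjects, 2 perfectly collinear variables -> S = [[1,2],[2,4]], singular
        ds = AnalysisDataset(
            sex="male",
            variable_names=["u", "v"],
            data_matrix=np.array([[-1.0, -2.0], [0.0, 0.0], [1.0, 2.0]]),
            centering_means={"u": 0.0, "v": 0.0},
            n=3,
        )
        with pytest.raises(ValueError, match="singular covariance"):
            sample_covariance(ds)
        S = np.cov(ds.data_matrix, rowvar=False, ddof=1)
        np.testing.assert_allclose(S, [[1, 2], [2, 4]])

    def test_duplicate_column_is_singular(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        mat = np.column_stack([x, x]) - np.column_stack([x, x]).mean(axis=0)
        ds = AnalysisDataset("male", ["a", "b"], mat, {"a": 0, "b": 0}, 30)
        with pytest.raises(ValueError, match="singular covariance"):
            sample_covariance(ds)

    def test_standardized_columns_give_unit_diagonal(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(50, 3))
        mat -= mat.mean(axis=0)
        mat /= mat.std(axis=0, ddof=1)
        ds = AnalysisDataset("male", ["a", "b", "c"], mat, {}, 50)
        S = sample_covariance(ds).S
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)

    def test_self_concatenation_preserves_covariance_shape(self, male_cohort):
        ds = derive_analysis_dataset(male_cohort, "male")
        S1 = sample_covariance(ds).S
        mat2 = np.vstack([ds.data_matrix, ds.data_matrix])
        ds2 = AnalysisDataset("male", ds.variable_names, mat2, ds.centering_means, 2 * ds.n)
        S2 = sample_covariance(ds2).S
        # matching divisor arithmetic: (2n-1) S2 = 2 (n-1) S1
        np.testing.assert_allclose((2 * ds.n - 1) * S2, 2 * (ds.n - 1) * S1, rtol=1e-10)


class TestKSNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(123).normal(3.0, 2.0, size=5000)
        rep = ks_normality(x, variable="x")
        assert rep.p_value > 0.05
        assert rep.ks_statistic >= 0

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(123).uniform(0, 1, size=5000)
        assert ks_normality(x).p_value < 0.001

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(100))

    def test_plain_ks_available_behind_flag(self):
        x = np.random.default_rng(5).normal(size=500)
        rep = ks_normality(x, lilliefors=False)
        assert 0 <= rep.p_value <= 1


def test_analysis_dataset_serialization_round_trip(tmp_path, male_cohort):
    ds = derive_analysis_dataset(male_cohort, "male")
    ds.save(tmp_path / "ds.csv")
    frame = pd.read_csv(tmp_path / "ds.csv")
    assert list(frame.columns) == ds.variable_names
    import json

    sidecar = json.loads((tmp_path / "ds.csv.json").read_text())
    assert sidecar["n"] == ds.n
    assert sidecar["centering_means"].keys() == ds.centering_means.keys()
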