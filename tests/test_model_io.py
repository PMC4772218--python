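import numpy as np
import pandas as pd
import pytest

from shs_hia import model_io
from shs_hia.model_io import (DiseaseInputSet, DomainError, PopulationPyramid,
                              SchemaError, SimulationConfig)


def _write_rr_csv(path, rows):
    pd.DataFrame(rows, columns=["sex", "disease", "rr"]).to_csv(path, index=False)


class TestRelativeRiskTable:
    def test_reads_published_point_estimates(self, tmp_path):
        path = tmp_path / "rr.csv"
        _write_rr_csv(path, [
            ("male", "ihd", 1.06), ("female", "ihd", 1.50),
            ("male", "copd", 1.50), ("female", "copd", 2.17),
            ("male", "stroke", 1.40), ("female", "stroke", 1.43)])
        table = model_io.read_rr_table(path)
        assert table.rr("female", "copd") == 2.17
        assert table.rr("male", "ihd") == 1.06

    def test_missing_cell_is_schema_error_naming_the_cell(self, tmp_path):
        path = tmp_path / "rr.csv"
        _write_rr_csv(path, [
            ("male", "ihd", 1.06), ("female", "ihd", 1.50),
            ("male", "copd", 1.50), ("female", "copd", 2.17),
            ("male", "stroke", 1.40)])
        with pytest.raises(SchemaError, match="female.*stroke"):
            model_io.read_rr_table(path)

    def test_nonpositive_rr_is_domain_error(self, tmp_path):
        path = tmp_path / "rr.csv"
        _write_rr_csv(path, [
            ("male", "ihd", -1.0), ("female", "ihd", 1.50),
            ("male", "copd", 1.50), ("female", "copd", 2.17),
            ("male", "stroke", 1.40), ("female", "stroke", 1.43)])
        with pytest.raises(DomainError):
            model_io.read_rr_table(path)


class TestExposureGroupTable:
    def _csv(self, tmp_path, rows):
        path = tmp_path / "exposure.csv"
        pd.DataFrame(rows, columns=["sex", "age_lo", "age_hi",
                                    "percent_exposed_pct"]).to_csv(path, index=False)
        return path

    FULL = [("men", 18, 29, 72.0), ("men", 30, 39, 49.0),
            ("men", 40, 49, 46.4), ("men", 50, 59, 42.5),
            ("men", 60, 69, 27.0), ("men", 70, None, 16.2),
            ("women", 18, 29, 61.6), ("women", 30, 39, 27.0),
            ("women", 40, 49, 28.1), ("women", 50, 59, 24.8),
            ("women", 60, 69, 17.0), ("women", 70, None, 8.9)]

    def test_percent_to_proportion_and_open_top_group(self, tmp_path):
        table = model_io.read_exposure_table(self._csv(tmp_path, self.FULL))
        assert table.fraction("male", 25) == pytest.approx(0.720)
        assert table.fraction("female", 95) == pytest.approx(0.089)
        assert table.fraction("male", 10) == 0.0

    def test_percent_above_100_is_domain_error(self, tmp_path):
        rows = [("men", 18, 29, 120.0)] + self.FULL[1:]
        with pytest.raises(DomainError):
            model_io.read_exposure_table(self._csv(tmp_path, rows))

    def test_overlapping_groups_are_schema_error(self, tmp_path):
        rows = self.FULL + [("men", 25, 35, 50.0)]
        with pytest.raises(SchemaError, match="overlap"):
            model_io.read_exposure_table(self._csv(tmp_path, rows))

    def test_coverage_gap_is_schema_error(self, tmp_path):
        rows = [r for r in self.FULL if r[:2] != ("men", 30)]
        with pytest.raises(SchemaError):
            model_io.read_exposure_table(self._csv(tmp_path, rows))


class TestDiseaseInputs:
    def test_out_of_range_values_raise_before_any_simulation(self):
        shape = (2, model_io.N_AGES, 3)
        good = np.zeros(shape)
        with pytest.raises(DomainError):
            DiseaseInputSet(prevalence=good + 1.5, incidence=good,
                            excess_mortality=good)
        with pytest.raises(DomainError):
            DiseaseInputSet(prevalence=good, incidence=good - 0.1,
                            excess_mortality=good)

    def test_csv_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        shape = (2, model_io.N_AGES, 3)
        inputs = DiseaseInputSet(prevalence=rng.uniform(0, 0.3, shape),
                                 incidence=rng.uniform(0, 0.05, shape),
                                 excess_mortality=rng.uniform(0, 0.1, shape))
        path = tmp_path / "disease.csv"
        inputs.to_csv(path)
        back = DiseaseInputSet.from_csv(path)
        np.testing.assert_allclose(back.prevalence, inputs.prevalence, atol=1e-9)
        np.testing.assert_allclose(back.incidence, inputs.incidence, atol=1e-9)


class TestPopulationPyramid:
    def test_newborn_split_follows_sex_ratio(self):
        pyr = PopulationPyramid(counts=np.ones((2, model_io.N_AGES)),
                                all_cause_mortality=np.zeros((2, model_io.N_AGES)),
                                newborns_per_year=1000.0, newborn_sex_ratio=1.05)
        male, female = pyr.newborns_by_sex
        assert male == pytest.approx(1000 * 1.05 / 2.05)
        assert female == pytest.approx(1000 / 2.05)

    def test_mortality_must_be_probability(self):
        with pytest.raises(DomainError):
            PopulationPyramid(counts=np.ones((2, model_io.N_AGES)),
                              all_cause_mortality=np.full((2, model_io.N_AGES), 1.2))


class TestResultsRoundTrip:
    def _frame(self):
        return pd.DataFrame([{
            "year": 2014, "scenario": "reference", "sex": "male", "age": 69,
            "disease": "ihd", "total_cases": 250.0,
            "counterfactual_cases": 150.0, "attributable_cases": 100.0,
            "population": 10_000.0,
            "population_prevalence_pct": 100.0 * 100.0 / 10_000.0}])

    def test_write_read_identity_and_prevalence_definition(self, tmp_path):
        path = tmp_path / "results.csv"
        frame = self._frame()
        model_io.write_results_csv(frame, path)
        back = model_io.read_results_csv(path)
        assert back.loc[0, "population_prevalence_pct"] == pytest.approx(1.0, abs=1e-9)
        pd.testing.assert_frame_equal(back, frame[model_io.RESULT_COLUMNS],
                                      check_exact=False, atol=1e-9)

    def test_empty_result_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        model_io.write_results_csv(self._frame().iloc[:0], path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1
        assert text[0].split(",") == model_io.RESULT_COLUMNS


class TestConfig:
    def test_invalid_horizon_and_mode_rejected(self):
        with pytest.raises(DomainError):
            SimulationConfig(start_year=2020, end_year=2014)
        with pytest.raises(DomainError):
            SimulationConfig(engine_mode="quantum")

    def test_default_scenario_is_reference(self):
        cfg = SimulationConfig()
        assert cfg.scenarios[0].success_rate == 0.0
        assert cfg.n_years == 27
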