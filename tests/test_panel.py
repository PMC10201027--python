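import numpy as np
import pandas as pd
import pytest

from spotrisk import (AreaYearPanel, compute_expected, read_covariates,
                      read_panel, write_panel)

# Printed yearly totals for the five-year study panel, used as a one-area
# panel to exercise the standardization arithmetic
YEAR_CRIMES = [27411, 28063, 28399, 24428, 24702]
YEAR_POPS = [996011, 993036, 990069, 986506, 982626]


def _write_long(path, rows):
    pd.DataFrame(rows, columns=["area_id", "year", "value"]).to_csv(
        path, index=False)


class TestReadPanel:
    def test_dense_ordered_matrix(self, tmp_path):
        _write_long(tmp_path / "c.csv", [("a", 2015, 3), ("a", 2016, 4),
                                         ("b", 2015, 0), ("b", 2016, 1)])
        _write_long(tmp_path / "p.csv", [("a", 2015, 10), ("a", 2016, 10),
                                         ("b", 2015, 5), ("b", 2016, 5)])
        panel = read_panel(tmp_path / "c.csv", tmp_path / "p.csv")
        assert panel.area_ids == ["a", "b"]
        assert panel.years == [2015, 2016]
        assert panel.counts.tolist() == [[3, 4], [0, 1]]

    def test_year_gap_rejected(self, tmp_path):
        _write_long(tmp_path / "c.csv", [("a", 2015, 3), ("a", 2017, 4)])
        _write_long(tmp_path / "p.csv", [("a", 2015, 10), ("a", 2017, 10)])
        with pytest.raises(ValueError, match="gap in year sequence"):
            read_panel(tmp_path / "c.csv", tmp_path / "p.csv")

    def test_key_mismatch_names_offender(self, tmp_path):
        _write_long(tmp_path / "c.csv", [("a", 2015, 3), ("b", 2015, 1)])
        _write_long(tmp_path / "p.csv", [("a", 2015, 10)])
        with pytest.raises(ValueError, match="b"):
            read_panel(tmp_path / "c.csv", tmp_path / "p.csv")

    def test_non_integer_count_rejected(self, tmp_path):
        _write_long(tmp_path / "c.csv", [("a", 2015, 3.5)])
        _write_long(tmp_path / "p.csv", [("a", 2015, 10)])
        with pytest.raises(TypeError):
            read_panel(tmp_path / "c.csv", tmp_path / "p.csv")

    def test_duplicate_key_rejected(self, tmp_path):
        _write_long(tmp_path / "c.csv", [("a", 2015, 3), ("a", 2015, 4)])
        _write_long(tmp_path / "p.csv", [("a", 2015, 10)])
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(tmp_path / "c.csv", tmp_path / "p.csv")

    def test_roundtrip_exact(self, tmp_path, small_panel):
        write_panel(small_panel, tmp_path / "c.csv", tmp_path / "p.csv")
        back = read_panel(tmp_path / "c.csv", tmp_path / "p.csv")
        assert np.array_equal(back.counts, small_panel.counts)
        assert np.array_equal(back.populations, small_panel.populations)
        assert back.area_ids == small_panel.area_ids
        assert back.years == small_panel.years


class TestComputeExpected:
    def test_uniform_rates(self):
        panel = AreaYearPanel(["a", "b"], [2015, 2016],
                              np.full((2, 2), 10), np.full((2, 2), 100.0))
        out = compute_expected(panel)
        assert np.allclose(out.expected, 10.0)

    def test_single_area_two_years(self):
        panel = AreaYearPanel(["a"], [2015, 2016],
                              np.array([[4, 0]]), np.array([[2.0, 2.0]]))
        out = compute_expected(panel)
        assert np.allclose(out.expected, [[2.0, 2.0]])

    def test_study_totals_rate(self):
        # one pseudo-area holding the printed yearly totals: the overall
        # standardization rate is sum(y)/sum(n)
        panel = AreaYearPanel(["province"], list(range(2015, 2020)),
                              np.array([YEAR_CRIMES]),
                              np.array([YEAR_POPS], dtype=float))
        out = compute_expected(panel)
        assert sum(YEAR_CRIMES) == 133_003
        assert sum(YEAR_POPS) == 4_948_248
        rate = out.expected[0, 0] / out.populations[0, 0]
        assert rate == pytest.approx(133_003 / 4_948_248, rel=1e-12)

    def test_totals_match_to_tolerance(self, small_panel):
        assert small_panel.expected.sum() == pytest.approx(
            small_panel.counts.sum(), rel=1e-9)

    def test_scale_equivariance(self, small_panel):
        scaled = AreaYearPanel(small_panel.area_ids, small_panel.years,
                               small_panel.counts,
                               small_panel.populations * 7.5)
        out = compute_expected(scaled)
        assert np.allclose(out.expected, small_panel.expected)

    def test_idempotent(self, small_panel):
        again = compute_expected(small_panel)
        assert np.allclose(again.expected, small_panel.expected)

    def test_per_year_option_balances_each_year(self):
        panel = AreaYearPanel(["a", "b"], [2015, 2016],
                              np.array([[10, 2], [6, 2]]),
                              np.array([[100.0, 100.0], [300.0, 100.0]]))
        out = compute_expected(panel, per_year=True)
        assert np.allclose(out.expected.sum(axis=0), panel.counts.sum(axis=0))

    def test_nonpositive_population_rejected(self):
        panel = AreaYearPanel(["a"], [2015], np.array([[1]]),
                              np.array([[-1.0]]))
        with pytest.raises(ValueError):
            compute_expected(panel)


class TestReadCovariates:
    def test_per_area_constant_broadcast(self, tmp_path, small_panel):
        pd.DataFrame({"area_id": ["a", "b"], "density": [5.0, 5.0]}).to_csv(
            tmp_path / "cov.csv", index=False)
        covs = read_covariates(tmp_path / "cov.csv", small_panel)
        assert len(covs) == 1
        assert covs[0].values.shape == (2, 2)
        assert np.all(covs[0].values == 5.0)

    def test_long_format_many_covariates(self, tmp_path, small_panel):
        rows = [(a, y, name, float(i)) for i, (name, a, y) in enumerate(
            (n, a, y) for n in ("u", "v") for a in ("a", "b")
            for y in (2015, 2016))]
        pd.DataFrame(rows, columns=["area_id", "year", "covariate",
                                    "value"]).to_csv(tmp_path / "cov.csv",
                                                     index=False)
        covs = read_covariates(tmp_path / "cov.csv", small_panel)
        assert [c.name for c in covs] == ["u", "v"]
        assert all(c.values.shape == (2, 2) for c in covs)

    def test_partial_area_coverage_rejected(self, tmp_path, small_panel):
        pd.DataFrame({"area_id": ["a"], "density": [5.0]}).to_csv(
            tmp_path / "cov.csv", index=False)
        with pytest.raises(ValueError, match="missing areas"):
            read_covariates(tmp_path / "cov.csv", small_panel)

    def test_empty_file_gives_empty_list(self, tmp_path, small_panel):
        (tmp_path / "cov.csv").write_text("area_id\n")
        assert read_covariates(tmp_path / "cov.csv", small_panel) == []
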