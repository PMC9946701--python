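import numpy as np
import pandas as pd
import pytest

import equipanel as eq
from equipanel.model import _trend_direction
from equipanel.panel import PanelValidationError


@pytest.fixture(scope="module")
def results(western_panel):
    panel = western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))
    return eq.EquityModel(panel).fit()


class TestGrid:
    def test_grid_cardinality(self, results):
        assert len(results.gini_table) == 2 * 3 * 5
        assert len(results.theil_table) == 2 * 3 * 5

    def test_population_dimension_is_most_fair(self, results):
        pop = results.gini_table[results.gini_table.dimension == "population"]
        assert (pop["grade"] == "most_fair").all()

    def test_geographic_dimension_is_less_fair(self, results):
        g = results.gini_table.pivot_table(
            index=["indicator", "year"], columns="dimension", values="gini"
        )
        assert (g["geographic"] > g["population"]).all()
        geo = results.gini_table[results.gini_table.dimension == "geographic"]
        assert geo["grade"].isin(["warning", "danger"]).all()

    def test_cell_access_consistent_with_tables(self, results):
        cell = results.gini("beds", 2018, "geographic")
        row = results.gini_table.query(
            "dimension == 'geographic' and indicator == 'beds' and year == 2018"
        ).iloc[0]
        assert cell.value == row["gini"]
        assert cell.grade.value == row["grade"]

    def test_theil_components_sum_to_total(self, results):
        t = results.theil_table
        np.testing.assert_allclose(
            t["theil_total"], t["theil_between"] + t["theil_within"], atol=1e-12
        )

    def test_ratio_rows_sum_to_hundred(self, results):
        t = results.theil_table
        np.testing.assert_allclose(t["between_pct"] + t["within_pct"], 100.0, atol=1e-9)

    def test_lorenz_cells_exist(self, results):
        curve = results.lorenz("nurses", 2016, "geographic")
        assert curve.x[0] == 0.0 and curve.x[-1] == 1.0
        assert len(curve.region_order) == 12

    def test_requires_attributes(self, western_panel):
        with pytest.raises(PanelValidationError, match="attributes"):
            eq.EquityModel(western_panel)

    def test_requires_two_groups_for_default_partition(self):
        spec = eq.ScenarioSpec(group_sizes=(0, 12), seed=0)
        panel = eq.generate_panel(spec)
        with pytest.raises(PanelValidationError, match="group"):
            eq.EquityModel(panel)

    def test_explicit_single_group_partition_allowed(self):
        panel = eq.generate_panel(eq.ScenarioSpec(seed=0, years=(2014,)))
        part = eq.GroupPartition({r: "all" for r in panel.region_ids})
        res = eq.EquityModel(panel, partition=part, dimensions=("population",)).fit()
        assert (res.theil_table["theil_between"].abs() < 1e-12).all()

    def test_missing_year_rejected_with_context(self, western_panel):
        panel = western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))
        with pytest.raises(PanelValidationError, match="1999"):
            eq.EquityModel(panel, years=(2014, 1999))

    def test_equal_density_panel_flags_perfect_equality(self):
        panel = eq.generate_panel(
            eq.ScenarioSpec(weight_model="equal", density_sigma=0.0, seed=0)
        )
        res = eq.EquityModel(panel).fit()
        assert (res.gini_table["gini"] == 0.0).all()
        assert res.theil_table["perfect_equality"].all()
        assert res.theil_table["between_pct"].isna().all()

    def test_run_grid_convenience(self, western_panel):
        panel = western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))
        res = eq.run_grid(panel, years=(2018,), indicators=("beds",))
        assert len(res.gini_table) == 2

    def test_from_csv_constructor(self, tmp_path, western_panel):
        panel = western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))
        dp, ap = tmp_path / "d.csv", tmp_path / "a.csv"
        panel.to_csv(dp, ap)
        model = eq.EquityModel.from_csv(dp, ap, years=(2018,))
        assert model.years == (2018,)


class TestTrend:
    def test_published_series_directions(self):
        pub = eq.published_gini()

        def series(dim, ind):
            sel = pub[(pub.dimension == dim) & (pub.indicator == ind)].sort_values("year")
            return sel["gini"].to_numpy()

        assert _trend_direction(series("population", "physicians"))[1] == "down"
        assert _trend_direction(series("geographic", "nurses"))[1] == "up"

    def test_flat_and_mixed(self):
        assert _trend_direction(np.array([0.1, 0.1, 0.1])) == ("00", "flat")
        signs, direction = _trend_direction(np.array([0.1, 0.3, 0.2]))
        assert signs == "+-" and direction == "mixed"

    def test_trend_table_shape(self, results):
        trend = results.trend()
        assert len(trend) == 6
        assert set(trend["direction"]) <= {"up", "down", "mixed", "flat"}
        assert (trend["delta"] == trend["last"] - trend["first"]).all()

    def test_trend_needs_two_years(self, western_panel):
        panel = western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))
        res = eq.EquityModel(panel, years=(2018,)).fit()
        with pytest.raises(PanelValidationError, match="two years"):
            res.trend()


class TestBenchmark:
    def test_physicians_2018_pass_set(self, western_panel):
        res = eq.benchmark_check(western_panel, 2018)
        assert res.passing("physicians") == (
            "Inner Mongolia", "Ningxia", "Qinghai", "Shaanxi", "Xinjiang",
        )

    def test_nurses_2018_pass_set(self, western_panel):
        res = eq.benchmark_check(western_panel, 2018)
        assert res.passing("nurses") == ("Ningxia", "Shaanxi")

    def test_counts(self, western_panel):
        counts = eq.benchmark_check(western_panel, 2018).counts()
        assert counts["physicians"] == 5
        assert counts["nurses"] == 2
        # beds >= 6: Shaanxi 6.57, Gansu 6.17, Qinghai 6.49, Xinjiang 7.19,
        # Sichuan 7.18, Chongqing 7.10, Yunnan 6.03, Guizhou 6.82, Inner Mongolia 6.27
        assert counts["beds"] == 9

    def test_zero_target_passes_everyone(self, western_panel):
        spec = eq.BenchmarkSpec(targets={"beds": 0.0})
        res = eq.benchmark_check(western_panel, 2018, spec)
        assert res.counts()["beds"] == 12

    def test_negative_target_rejected(self):
        with pytest.raises(PanelValidationError):
            eq.BenchmarkSpec(targets={"beds": -1.0})

    def test_strict_threshold(self, western_panel):
        # Ningxia 2018 beds 5.96 sits just under the target of 6 and fails
        res = eq.benchmark_check(western_panel, 2018)
        t = res.table
        row = t[(t.region_id == "Ningxia") & (t.indicator == "beds")].iloc[0]
        assert row["density"] == 5.96 and not row["passed"]


class TestExportAndSummary:
    def test_export_manifest(self, results, tmp_path):
        written = results.export(tmp_path)
        names = sorted(p.name for p in written)
        assert names == [
            "contribution_ratios.csv",
            "gini_coefficients.csv",
            "lorenz_geographic.csv",
            "lorenz_population.csv",
            "run_log.txt",
            "theil_decomposition.csv",
            "trend_geographic.csv",
            "trend_population.csv",
        ]

    def test_export_deterministic(self, results, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        results.export(a)
        results.export(b)
        for pa in sorted(a.iterdir()):
            assert pa.read_bytes() == (b / pa.name).read_bytes()

    def test_published_precision_rounding(self, results, tmp_path):
        results.export(tmp_path, published_precision=True)
        gini = pd.read_csv(tmp_path / "gini_coefficients.csv")
        assert (gini["gini"].round(4) == gini["gini"]).all()
        theil = pd.read_csv(tmp_path / "theil_decomposition.csv")
        assert (theil["theil_total"].round(3) == theil["theil_total"]).all()

    def test_ratio_export_carries_both_conventions(self, results, tmp_path):
        results.export(tmp_path)
        ratios = pd.read_csv(tmp_path / "contribution_ratios.csv")
        assert (ratios["swapped_label_T_inter_pct"] == ratios["within_pct"]).all()
        assert (ratios["swapped_label_T_intra_pct"] == ratios["between_pct"]).all()

    def test_empty_results_cannot_export(self, results, tmp_path):
        empty = eq.EquityResults(results.model, {}, {}, {})
        with pytest.raises(PanelValidationError, match="empty"):
            empty.export(tmp_path)

    def test_summary_mentions_key_sections(self, results):
        text = results.summary()
        assert "Gini coefficients" in text
        assert "Theil-L index" in text
        assert "trends" in text.lower()
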