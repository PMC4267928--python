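"""Orchestration: pairing, determinism, deviation statistics, reports."""

import numpy as np
import pandas as pd
import pytest

from gpaccuracy.config import ScenarioConfig, make_scenario_configs
from gpaccuracy.evaluation import (ACCURACY_METHODS, DatasetResult,
                                   MethodEstimates, compare_methods,
                                   count_flags, mean_deviation,
                                   read_results_table, results_to_frame,
                                   run_scenario, summarize, write_report)


def make_result(scenario=1, j=0, acc_clean=None, acc_cont=None,
                flags_clean=None, flags_cont=None, true_acc=0.8,
                true_h2=0.6):
    def est(acc, flags):
        acc = acc or {m: 0.5 for m in ACCURACY_METHODS}
        flags = flags or {}
        return MethodEstimates(
            H2={m: 0.5 for m in range(1, 6)},
            acc=dict(acc),
            r_gp=0.4,
            flags={m: frozenset(flags.get(m, ())) for m in ACCURACY_METHODS})
    return DatasetResult(scenario_id=scenario, dataset_index=j,
                         true_accuracy=true_acc, true_heritability=true_h2,
                         clean=est(acc_clean, flags_clean),
                         contaminated=est(acc_cont, flags_cont))


class TestScenarioConfigs:
    def test_ten_presets_match_study_grid(self):
        cfgs = make_scenario_configs()
        assert len(cfgs) == 10
        c1 = cfgs[0]
        assert (c1.n_genotypes, c1.n_markers) == (177, 275)
        assert c1.marker_variance == pytest.approx(0.2019)
        assert c1.error_sd == pytest.approx(6.977)
        assert c1.outlier_multiplier == 5
        c4 = cfgs[3]
        assert c4.marker_variance == pytest.approx(0.02019)
        c10 = cfgs[9]
        assert (c10.n_genotypes, c10.n_markers) == (698, 11646)
        assert c10.marker_variance == pytest.approx(0.005892 / 10)
        assert c10.error_sd == pytest.approx(7.340)
        assert c10.outlier_multiplier == 10
        assert c10.outlier_shift == pytest.approx(73.40)
        # outlier magnitudes across the grid
        assert [c.outlier_multiplier for c in cfgs] == [5, 8, 10, 5, 8, 10,
                                                        5, 10, 5, 10]

    def test_error_sd_consistency_enforced(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario_id=1, n_genotypes=10, n_markers=5,
                           marker_variance=0.1, error_variance=48.6728,
                           error_sd=9.0, block_variance=1.0)

    def test_shared_base_data_groups(self):
        cfgs = make_scenario_configs()
        assert cfgs[0].group_id == cfgs[1].group_id == cfgs[2].group_id
        assert cfgs[3].group_id != cfgs[0].group_id
        assert cfgs[6].group_id == cfgs[7].group_id

    def test_config_yaml_round_trip(self, tmp_path, small_config):
        from gpaccuracy.config import load_config, save_config
        path = tmp_path / "cfg.yaml"
        save_config(small_config, path)
        assert load_config(path) == small_config
        assert load_config(path, seed=9).seed == 9


class TestRunScenario:
    def test_bit_identical_reruns(self, small_config):
        a = results_to_frame(run_scenario(small_config, n_datasets=2))
        b = results_to_frame(run_scenario(small_config, n_datasets=2))
        pd.testing.assert_frame_equal(a, b)

    def test_scenarios_sharing_group_have_identical_clean_results(
            self, small_config):
        other = small_config.with_overrides(scenario_id=3,
                                            outlier_multiplier=10)
        res_a = run_scenario(small_config, n_datasets=2)
        res_b = run_scenario(other, n_datasets=2)
        fa = results_to_frame(res_a)
        fb = results_to_frame(res_b)
        ca = fa[fa.condition == "clean"].drop(columns=["scenario",
                                                       "outlier_shift"])
        cb = fb[fb.condition == "clean"].drop(columns=["scenario",
                                                       "outlier_shift"])
        pd.testing.assert_frame_equal(ca.reset_index(drop=True),
                                      cb.reset_index(drop=True))
        # same contaminated plot, different shift
        assert res_a[0].outlier_plot == res_b[0].outlier_plot
        assert res_b[0].outlier_shift == pytest.approx(
            2 * res_a[0].outlier_shift)

    def test_uncontaminated_scenario_pairs_with_itself(self, small_config):
        cfg = small_config.with_overrides(outlier_multiplier=0)
        res = run_scenario(cfg, n_datasets=1)
        assert res[0].contaminated is res[0].clean
        assert res[0].outlier_plot == -1

    def test_every_dataset_carries_all_methods_and_conditions(
            self, small_config):
        frame = results_to_frame(run_scenario(small_config, n_datasets=2))
        assert len(frame) == 2 * 2 * 7
        assert set(frame.method) == set(ACCURACY_METHODS)
        assert set(frame.condition) == {"clean", "contaminated"}


class TestMeanDeviation:
    def test_exact_estimates_give_zero(self):
        md, se, n = mean_deviation([0.5, 0.7], [0.5, 0.7])
        assert md == 0.0 and n == 2

    def test_single_pair(self):
        md, se, n = mean_deviation([0.8], [0.6])
        assert md == pytest.approx(0.2)
        assert np.isnan(se)

    def test_symmetric_deviations(self):
        md, se, n = mean_deviation([0.1, -0.1], [0.0, 0.0])
        assert md == pytest.approx(0.0)
        assert se == pytest.approx(0.1)

    def test_nan_pairs_excluded(self):
        md, se, n = mean_deviation([0.5, np.nan, 0.9], [0.4, 0.4, 0.4])
        assert n == 2
        assert md == pytest.approx(0.3)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            mean_deviation([np.nan], [0.1])


class TestCountFlags:
    def test_mixed_flag_counting(self):
        results = [
            make_result(acc_cont={**{m: 0.5 for m in ACCURACY_METHODS},
                                  1: -0.1},
                        flags_cont={1: ("undershoot",)}),
            make_result(j=1,
                        acc_cont={**{m: 0.5 for m in ACCURACY_METHODS},
                                  1: 1.2},
                        flags_cont={1: ("overshoot",)}),
            make_result(j=2, flags_cont={1: ("nonconverged",
                                             "not_computable")}),
        ]
        counts = count_flags(results, method=1, condition="contaminated")
        assert counts["undershoot"] == 1
        assert counts["overshoot"] == 1
        assert counts["nonconverged"] == 1
        assert counts["delta_undershoot"] == 1

    def test_clean_run_with_no_flags(self):
        counts = count_flags([make_result()], method=5, condition="clean")
        assert all(v == 0 for v in counts.values())

    def test_contaminated_minus_clean_differences(self):
        res = [make_result(flags_clean={2: ("undershoot",)},
                           flags_cont={2: ("undershoot",)}),
               make_result(j=1, flags_cont={2: ("undershoot",)})]
        counts = count_flags(res, method=2, condition="contaminated")
        assert counts["undershoot"] == 2
        assert counts["delta_undershoot"] == 1


class TestCompareMethods:
    def test_method_compared_with_itself(self):
        results = [make_result(j=j) for j in range(5)]
        table = compare_methods(results)
        self_rows = table[table.method_a == table.method_b]
        assert (self_rows.pearson_r == 1.0).all()
        assert (self_rows.t_stat == 0.0).all()

    def test_constant_offset_between_methods(self):
        rng = np.random.default_rng(0)
        results = []
        for j in range(50):
            base = {m: 0.5 for m in ACCURACY_METHODS}
            base[1] = 0.5 + rng.normal(0, 0.05)
            base[2] = base[1] + 0.1
            results.append(make_result(j=j, acc_cont=base))
        table = compare_methods(results)
        row = table[(table.method_a == 1) & (table.method_b == 2)].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        # A's deviations are 0.1 below B's
        assert row.t_stat < 0

    def test_independent_deviations_nearly_uncorrelated(self):
        rng = np.random.default_rng(1)
        results = []
        for j in range(1000):
            acc = {m: 0.5 for m in ACCURACY_METHODS}
            acc[3] = rng.normal(0.5, 0.1)
            acc[4] = rng.normal(0.5, 0.1)
            results.append(make_result(j=j, acc_cont=acc))
        table = compare_methods(results)
        row = table[(table.method_a == 3) & (table.method_b == 4)].iloc[0]
        assert abs(row.pearson_r) < 0.1

    def test_insufficient_common_datasets_raises(self):
        results = [make_result(j=j, flags_cont={1: ("not_computable",)},
                               acc_cont={**{m: 0.5 for m in
                                            ACCURACY_METHODS}, 1: np.nan})
                   for j in range(4)]
        with pytest.raises(ValueError):
            compare_methods(results)


class TestReports:
    def test_round_trip_preserves_summaries(self, small_config, tmp_path):
        results = run_scenario(small_config, n_datasets=2)
        paths = write_report(results, tmp_path)
        frame = read_results_table(paths["per_dataset"])
        original = results_to_frame(results)
        md_a = frame.groupby("method").accuracy.mean()
        md_b = original.groupby("method").accuracy.mean()
        pd.testing.assert_series_equal(md_a, md_b)

    def test_summary_covers_all_cells(self, small_config, tmp_path):
        results = run_scenario(small_config, n_datasets=2)
        summary = summarize(results)
        assert len(summary) == (5 + 7) * 2  # metrics x methods x conditions

    def test_empty_run_writes_headers_only(self, tmp_path):
        paths = write_report([], tmp_path)
        frame = read_results_table(paths["per_dataset"])
        assert frame.empty
        assert "accuracy" in frame.columns
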