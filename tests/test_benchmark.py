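"""Best-epoch protocol, multi-run averaging, the grid and its report."""

import json

import numpy as np
import pytest

import qsardnn as q
from qsardnn.benchmark import (
    BenchmarkReport,
    RunResult,
    SettingResult,
    best_of_trace,
    builtin_settings,
    run_grid,
    run_setting,
    run_single,
    scaled_setting,
    write_run_log,
)
from qsardnn.dnn import DNNSetting, TrainConfig


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = q.SyntheticSpec(n_train=120, n_test=60, n_descriptors=40, seed=11)
    ds, _ = q.generate_aligned(spec)
    return ds


MINI = DNNSetting("mini", (16,), (10,), 32)


class TestRunResult:
    def test_best_is_max_and_first_index(self):
        r = RunResult(r2_trace=[0.1, 0.5, 0.3], train_mse_trace=[1, 1, 1], seed=0)
        assert r.best_r2 == 0.5 and r.best_epoch == 2

    def test_tie_breaks_to_first_maximizer(self):
        assert best_of_trace([0.2, 0.7, 0.7, 0.1]) == (0.7, 2)
        r = RunResult(r2_trace=[0.7, 0.2, 0.7], train_mse_trace=[0, 0, 0], seed=0)
        assert r.best_epoch == 1

    def test_trace_length_mismatch(self):
        with pytest.raises(ValueError):
            RunResult(r2_trace=[0.1], train_mse_trace=[], seed=0)


class TestRunSingle:
    def test_one_epoch_trace(self, tiny_dataset):
        res = run_single(tiny_dataset, MINI, TrainConfig(epochs=1, n_runs=1), seed=0)
        assert res.n_epochs == 1 and res.best_epoch == 1
        assert res.best_r2 == res.final_r2

    def test_reproducible_bit_for_bit(self, tiny_dataset):
        cfg = TrainConfig(epochs=3, n_runs=1)
        a = run_single(tiny_dataset, MINI, cfg, seed=5)
        b = run_single(tiny_dataset, MINI, cfg, seed=5)
        assert a.r2_trace == b.r2_trace
        assert a.best_r2 == b.best_r2 and a.best_epoch == b.best_epoch

    def test_log_transform_setting_changes_training(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, n_runs=1)
        plain = run_single(tiny_dataset, MINI, cfg, seed=0)
        logged = run_single(
            tiny_dataset,
            DNNSetting("mini-log", (16,), (10,), 32, log_transform=True),
            cfg,
            seed=0,
        )
        assert plain.r2_trace != logged.r2_trace


class TestRunSetting:
    def test_single_run_mean_is_that_run(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, n_runs=1, base_seed=3)
        result = run_setting(tiny_dataset, MINI, cfg)
        assert result.mean_best_r2 == result.runs[0].best_r2
        assert result.runs[0].seed == 3

    def test_seeds_are_consecutive_and_result_deterministic(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, n_runs=3, base_seed=10)
        a = run_setting(tiny_dataset, MINI, cfg)
        assert [r.seed for r in a.runs] == [10, 11, 12]
        b = run_setting(tiny_dataset, MINI, cfg)
        assert [r.best_r2 for r in a.runs] == [r.best_r2 for r in b.runs]

    def test_mean_of_constructed_bests(self):
        runs = [
            RunResult(r2_trace=[0.2], train_mse_trace=[0.0], seed=0),
            RunResult(r2_trace=[0.4], train_mse_trace=[0.0], seed=1),
        ]
        assert SettingResult(setting=MINI, runs=runs).mean_best_r2 == pytest.approx(0.3)


class TestGridAndReport:
    def test_single_cell_grid_matches_run_setting(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, n_runs=1)
        report = run_grid({"T1": tiny_dataset}, [MINI], cfg)
        expected = run_setting(tiny_dataset, MINI, cfg).mean_best_r2
        assert report.cells[("T1", "mini")] == expected
        assert report.setting_average("mini") == expected

    def test_aggregates_recompute_from_cells(self):
        cells = {
            ("A", "s1"): 0.4, ("B", "s1"): 0.6,
            ("A", "s2"): 0.5, ("B", "s2"): 0.5,
        }
        report = BenchmarkReport(["A", "B"], ["s1", "s2"], cells, dict(cells))
        assert report.setting_average("s1") == pytest.approx(0.5)
        assert report.setting_average("s2") == pytest.approx(0.5)
        assert report.target_std("A") == pytest.approx(np.std([0.4, 0.5], ddof=1))
        assert report.target_std("B") == pytest.approx(np.std([0.6, 0.5], ddof=1))

    def test_identical_cells_give_zero_std(self):
        cells = {("A", "s1"): 0.4, ("A", "s2"): 0.4}
        report = BenchmarkReport(["A"], ["s1", "s2"], cells, dict(cells))
        assert report.target_std("A") == 0.0

    def test_incomplete_report_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            BenchmarkReport(["A"], ["s1"], {})

    def test_missing_dataset_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="T2"):
            run_grid({"T1": tiny_dataset, "T2": None}, [MINI], TrainConfig(1, 1))

    def test_serializations_carry_all_rows(self):
        cells = {("A", "s1"): 0.4, ("A", "s2"): 0.6}
        report = BenchmarkReport(["A"], ["s1", "s2"], cells, dict(cells))
        tsv = report.to_tsv()
        assert tsv.splitlines()[0] == "Setting\tA\tAverage"
        assert "Std. Dev." in tsv and "0.4000" in tsv
        md = report.to_markdown()
        assert md.count("|") > 8 and "s2" in md

    def test_run_logs_are_auditable(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(epochs=2, n_runs=2, base_seed=1)
        result = run_setting(tiny_dataset, MINI, cfg)
        for run in result.runs:
            write_run_log(tmp_path, "T1", MINI, run)
        files = sorted(tmp_path.glob("*.json"))
        assert len(files) == 2
        payload = json.loads(files[0].read_text())
        assert payload["best_r2"] == max(payload["r2_trace"])
        assert len(payload["r2_trace"]) == 2


class TestBuiltinSettings:
    def test_thirteen_rows(self):
        assert len(builtin_settings()) == 13

    def test_unique_names(self):
        names = [s.name for s in builtin_settings()]
        assert len(set(names)) == 13

    @pytest.mark.parametrize(
        "name, hidden, dropout, batch, log",
        [
            ("HL4", (4000, 2000, 1000, 1000), (25, 25, 25, 10), 100, False),
            ("HL3", (4000, 2500, 1500), (25, 25, 10), 100, False),
            ("HL2", (6000, 2000), (25, 10), 100, False),
            ("HL1", (8000,), (10,), 100, False),
            ("HL1/16", (500,), (10,), 100, False),
            ("HL4//4", (4000, 2000, 1000, 1000), (25, 25, 25, 10), 25, False),
            ("LOG HL4//4", (4000, 2000, 1000, 1000), (25, 25, 25, 10), 25, True),
        ],
    )
    def test_row_contents(self, name, hidden, dropout, batch, log):
        s = next(s for s in builtin_settings() if s.name == name)
        assert s.hidden_sizes == hidden
        assert s.dropout_percents == dropout
        assert s.minibatch_size == batch
        assert s.log_transform is log

    def test_batch_variants_quarter_batch_quadruple_updates(self):
        by_name = {s.name: s for s in builtin_settings()}
        n = 1000
        u100 = q.updates_per_epoch(n, by_name["HL4"].minibatch_size)
        u25 = q.updates_per_epoch(n, by_name["HL4//4"].minibatch_size)
        assert u25 == 4 * u100

    def test_scaled_setting_keeps_tail_dropout(self):
        hl4 = next(s for s in builtin_settings() if s.name == "HL4")
        s = scaled_setting(hl4, (64, 32), name="HL4-mini")
        assert s.hidden_sizes == (64, 32)
        assert s.dropout_percents == (25, 10)
        assert s.minibatch_size == hl4.minibatch_size
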