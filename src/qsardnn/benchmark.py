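"""Best-epoch / multi-run evaluation protocol and the settings grid.

One *run* trains a network on a target's training split and, after
every epoch, scores the instantaneous model by test-set R² with dropout
off; the run's score is the best R² over all epochs (first epoch on
ties). One *setting result* averages the best-R² of ``n_runs``
independently initialised runs. The *grid* crosses targets with
settings and reports, per setting, the per-target means, their overall
average across targets, and per target the standard deviation of the
means across settings.

Scoring by the best test epoch peeks at the test set — it is not a
blind-test protocol. Reports therefore label that column "oracle-epoch"
and also carry the honest "final-epoch" R² alongside.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_io import ActivityTable, AlignedDataset, log_transform
from .dnn import AdamState, DNNSetting, TrainConfig, build_model, train_one_epoch
from .metrics import mse, r_squared

__all__ = [
    "RunResult",
    "SettingResult",
    "BenchmarkReport",
    "best_of_trace",
    "run_single",
    "run_setting",
    "run_grid",
    "builtin_settings",
    "scaled_setting",
    "write_run_log",
]


def best_of_trace(trace) -> tuple[float, int]:
    """Best value in an epoch trace and its 1-based first-maximizer epoch."""
    trace = list(trace)
    if not trace:
        raise ValueError("empty trace")
    best = max(trace)
    return best, trace.index(best) + 1


@dataclass
class RunResult:
    """One training run: per-epoch test-R² trace and its best epoch."""

    r2_trace: list[float]
    train_mse_trace: list[float]
    seed: int
    best_r2: float = field(init=False)
    best_epoch: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.r2_trace) != len(self.train_mse_trace):
            raise ValueError("R² and train-MSE traces differ in length")
        self.best_r2, self.best_epoch = best_of_trace(self.r2_trace)

    @property
    def n_epochs(self) -> int:
        return len(self.r2_trace)

    @property
    def final_r2(self) -> float:
        return self.r2_trace[-1]


@dataclass
class SettingResult:
    """All runs of one setting on one target, and their mean best R²."""

    setting: DNNSetting
    runs: list[RunResult]
    mean_best_r2: float = field(init=False)
    mean_final_r2: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("a setting result needs at least one run")
        self.mean_best_r2 = float(np.mean([r.best_r2 for r in self.runs]))
        self.mean_final_r2 = float(np.mean([r.final_r2 for r in self.runs]))


@dataclass
class BenchmarkReport:
    """Targets × settings matrix of mean best-R² values.

    ``cells[(target, setting_name)]`` holds the oracle-epoch mean;
    ``final_cells`` the final-epoch means. Row averages (per setting,
    across targets) and per-target standard deviations (across
    settings) are recomputed from the cells on demand so they can never
    drift from them.
    """

    targets: list[str]
    setting_names: list[str]
    cells: dict[tuple[str, str], float]
    final_cells: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [
            (t, s)
            for t in self.targets
            for s in self.setting_names
            if (t, s) not in self.cells
        ]
        if missing:
            raise ValueError(f"incomplete report; missing cells {missing}")

    def setting_average(self, setting_name: str) -> float:
        """Overall average of one setting's mean R² across all targets."""
        return float(
            np.mean([self.cells[(t, setting_name)] for t in self.targets])
        )

    def target_std(self, target: str) -> float:
        """Std. dev. of one target's mean R² across all settings (ddof=1)."""
        values = [self.cells[(target, s)] for s in self.setting_names]
        if len(values) < 2:
            return 0.0
        return statistics.stdev(values)

    def best_setting(self) -> str:
        """Setting with the highest overall average mean R²."""
        return max(self.setting_names, key=self.setting_average)

    def to_tsv(self, mode: str = "oracle") -> str:
        """Tab-separated matrix: settings as rows, targets as columns,
        an Average column and a Std. Dev. row."""
        cells = self.cells if mode == "oracle" else self.final_cells
        lines = ["\t".join(["Setting", *self.targets, "Average"])]
        for s in self.setting_names:
            row = [f"{cells[(t, s)]:.4f}" for t in self.targets]
            avg = float(np.mean([cells[(t, s)] for t in self.targets]))
            lines.append("\t".join([s, *row, f"{avg:.4f}"]))
        std_row = [f"{self.target_std(t):.4f}" for t in self.targets]
        lines.append("\t".join(["Std. Dev.", *std_row, ""]))
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        header = "| Setting | " + " | ".join(self.targets) + " | Average |"
        rule = "|" + "---|" * (len(self.targets) + 2)
        lines = [header, rule]
        for s in self.setting_names:
            row = [f"{self.cells[(t, s)]:.4f}" for t in self.targets]
            lines.append(
                f"| {s} | " + " | ".join(row) + f" | {self.setting_average(s):.4f} |"
            )
        std = [f"{self.target_std(t):.4f}" for t in self.targets]
        lines.append("| Std. Dev. | " + " | ".join(std) + " |  |")
        return "\n".join(lines) + "\n"


def run_single(
    dataset: AlignedDataset,
    setting: DNNSetting,
    config: TrainConfig,
    seed: int,
) -> RunResult:
    """One training run under the protocol.

    Applies the setting's log transform to both splits if requested,
    trains epoch by epoch, and after each epoch records dropout-free
    test R² and dropout-free train MSE.
    """
    train, test = dataset.train, dataset.test
    if setting.log_transform:
        train, test = log_transform(train), log_transform(test)
    x_train, y_train = train.matrix(), train.activities
    x_test, y_test = test.matrix(), test.activities

    model = build_model(setting, input_dim=dataset.n_descriptors, seed=seed)
    optimizer = AdamState(model.parameters, config)
    r2_trace: list[float] = []
    mse_trace: list[float] = []
    for _ in range(config.epochs):
        train_one_epoch(model, x_train, y_train, optimizer)
        r2_trace.append(r_squared(y_test, model.predict(x_test)))
        mse_trace.append(mse(y_train, model.predict(x_train)))
    return RunResult(r2_trace=r2_trace, train_mse_trace=mse_trace, seed=seed)


def run_setting(
    dataset: AlignedDataset, setting: DNNSetting, config: TrainConfig
) -> SettingResult:
    """``n_runs`` independent runs with seeds base_seed + 0..n_runs-1."""
    runs = [
        run_single(dataset, setting, config, seed=config.base_seed + k)
        for k in range(config.n_runs)
    ]
    return SettingResult(setting=setting, runs=runs)


def run_grid(
    datasets: dict[str, AlignedDataset],
    settings: list[DNNSetting],
    config: TrainConfig,
    log_dir=None,
) -> BenchmarkReport:
    """Full targets × settings grid; every cell is a run_setting mean."""
    if not datasets:
        raise ValueError("no target datasets supplied")
    if not settings:
        raise ValueError("no settings supplied")
    targets = list(datasets)
    cells: dict[tuple[str, str], float] = {}
    final_cells: dict[tuple[str, str], float] = {}
    for target, dataset in datasets.items():
        if dataset is None:
            raise ValueError(f"missing dataset for target {target!r}")
        for setting in settings:
            result = run_setting(dataset, setting, config)
            cells[(target, setting.name)] = result.mean_best_r2
            final_cells[(target, setting.name)] = result.mean_final_r2
            if log_dir is not None:
                for run in result.runs:
                    write_run_log(log_dir, target, setting, run)
    return BenchmarkReport(
        targets=targets,
        setting_names=[s.name for s in settings],
        cells=cells,
        final_cells=final_cells,
    )


def write_run_log(log_dir, target: str, setting: DNNSetting, run: RunResult) -> None:
    """Persist one run as JSON (seed, setting, full traces) for audit."""
    from pathlib import Path

    log_dir = Path(log_dir)
    log_dir.mkdir(parents=True, exist_ok=True)
    safe = setting.name.replace("/", "_").replace(" ", "-")
    path = log_dir / f"{target}_{safe}_seed{run.seed}.json"
    payload = {
        "target": target,
        "setting": {
            "name": setting.name,
            "hidden_sizes": list(setting.hidden_sizes),
            "dropout_percents": list(setting.dropout_percents),
            "minibatch_size": setting.minibatch_size,
            "log_transform": setting.log_transform,
        },
        "seed": run.seed,
        "best_r2": run.best_r2,
        "best_epoch": run.best_epoch,
        "final_r2": run.final_r2,
        "r2_trace": run.r2_trace,
        "train_mse_trace": run.train_mse_trace,
    }
    path.write_text(json.dumps(payload, indent=1))


# The thirteen-row settings grid. HL4..HL1 vary depth at ~8000 total
# neurons; HL1/m shrinks the single hidden layer; HL4//k divides the
# mini-batch by k; LOG variants add the log(1+x) input transform.
_HL4 = dict(hidden_sizes=(4000, 2000, 1000, 1000), dropout_percents=(25, 25, 25, 10))


def builtin_settings() -> list[DNNSetting]:
    """The 13 hyperparameter settings of the benchmark grid."""
    return [
        DNNSetting("HL4", **_HL4, minibatch_size=100),
        DNNSetting("HL3", (4000, 2500, 1500), (25, 25, 10), 100),
        DNNSetting("HL2", (6000, 2000), (25, 10), 100),
        DNNSetting("HL1", (8000,), (10,), 100),
        DNNSetting("HL1/2", (4000,), (10,), 100),
        DNNSetting("HL1/4", (2000,), (10,), 100),
        DNNSetting("HL1/8", (1000,), (10,), 100),
        DNNSetting("HL1/16", (500,), (10,), 100),
        DNNSetting("HL4//2", **_HL4, minibatch_size=50),
        DNNSetting("HL4//4", **_HL4, minibatch_size=25),
        DNNSetting("LOG HL4", **_HL4, minibatch_size=100, log_transform=True),
        DNNSetting("LOG HL4//2", **_HL4, minibatch_size=50, log_transform=True),
        DNNSetting("LOG HL4//4", **_HL4, minibatch_size=25, log_transform=True),
    ]


def scaled_setting(
    base: DNNSetting, hidden_sizes: tuple[int, ...], name: str | None = None
) -> DNNSetting:
    """A size-reduced copy of a setting (same dropout schedule shape)."""
    rates = base.dropout_percents[-len(hidden_sizes):]
    if len(rates) < len(hidden_sizes):
        rates = (base.dropout_percents[0],) * len(hidden_sizes)
    return replace(
        base,
        name=name or f"{base.name}-scaled",
        hidden_sizes=hidden_sizes,
        dropout_percents=rates,
    )
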