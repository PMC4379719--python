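"""Experiment configuration, the full pipeline, and results output.

``run_experiment`` ties the stages together: load genotypes and phenotypes,
quality control, -1/0/1 coding, construction of the requested covariate
structure (X, G or UD), then — for every hidden-layer size in the grid — a
repeated k-fold cross-validation, always accompanied by the quasi-GBLUP
benchmark arm (one identity neuron on G). Results land in a long-format
table (one row per CV run) and a summary table (mean r with the variance of
runs), both derivable from each other exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import CVSummary, make_folds, quasi_gblup_config, run_cv
from .exceptions import ValidationError
from .genotypes import INPUT_KINDS, build_input, code_genotypes, qc_filter
from .io import load_genotypes, load_phenotypes
from .network import Architecture, TrainingConfig, select_learning_rate
from .simulate import SimulatedDataset

__all__ = ["ExperimentConfig", "ResultsTable", "run_experiment", "run_experiment_arrays", "write_results"]

BENCHMARK_LABEL = "benchmark"


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    Defaults follow the reference protocol: hidden-layer grid 1..20 with tanh
    activation, 1000-iteration cap, aMSE tolerance 1e-3, initialization in
    [-0.1, 0.1], 20x5-fold cross-validation, MAF < 0.05 and missing fraction
    > 0.95 marker exclusion.
    """

    genotype_path: str
    phenotype_path: str
    input_kind: str = "G"
    hidden_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    hidden_activation: str = "tanh"
    genotype_dialect: str = "tsv_counts"
    # training
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.01
    max_iterations: int = 1000
    amse_tolerance: float = 1e-3
    init_range: tuple[float, float] = (-0.1, 0.1)
    tune_learning_rate: bool = False
    # cross-validation
    k: int = 5
    repeats: int = 20
    seed: int = 0
    # quality control
    maf_min: float = 0.05
    missing_max: float = 0.95
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.input_kind not in INPUT_KINDS:
            raise ValidationError(f"input_kind must be one of {INPUT_KINDS}")
        if any(h < 1 for h in self.hidden_grid):
            raise ValidationError("hidden_grid entries must be >= 1")

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            max_iterations=self.max_iterations,
            amse_tolerance=self.amse_tolerance,
            init_range=tuple(self.init_range),
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for p in (cfg.genotype_path, cfg.phenotype_path):
            if not Path(p).exists():
                raise ValidationError(f"path not found: {p}")
        return cfg


@dataclass
class ResultsTable:
    """Long-format per-run records plus the per-arm summary."""

    long: pd.DataFrame  # input_kind, n_hidden, arm, repeat, fold, r
    summary: pd.DataFrame  # input_kind, n_hidden, arm, mean_r, var_r
    log: dict = field(default_factory=dict)


def _collect(label: str, kind: str, n_hidden: int, summary: CVSummary) -> list[dict]:
    return [
        {
            "arm": label,
            "input_kind": kind,
            "n_hidden": n_hidden,
            "repeat": run.repeat_index,
            "fold": run.fold_index,
            "r": run.r,
            "n_test": run.n_test,
            "failure": run.failure,
        }
        for run in summary.runs
    ]


def _tune_on_first_fold(
    arch: Architecture,
    training: TrainingConfig,
    inputs: np.ndarray,
    y: np.ndarray,
    plan,
) -> float:
    """Select a learning rate on the first repeat's first training fold only.

    The fold is split 4:1 into a probe-train and probe-validation part, so
    the selection criterion is generalization, not training fit; held-out
    test folds of that repeat are never touched.
    """
    idx = plan.train_indices(0, 0)
    rng = np.random.default_rng(np.random.SeedSequence([training.seed, 0x7E]))
    idx = rng.permutation(idx)
    cut = max(1, len(idx) // 5)
    val_idx, tr_idx = idx[:cut], idx[cut:]
    y_tr = y[tr_idx]
    mu, mx = y_tr.mean(), y_tr.max()
    return select_learning_rate(
        arch,
        training,
        inputs[tr_idx],
        (y_tr - mu) / mx,
        X_val=inputs[val_idx],
        y_val=(y[val_idx] - mu) / mx,
    )


def run_experiment_arrays(
    dataset_inputs: dict[str, np.ndarray],
    y: np.ndarray,
    config: ExperimentConfig,
) -> ResultsTable:
    """Core experiment loop on pre-built covariate structures.

    ``dataset_inputs`` maps input kinds to (n, p) matrices; it must contain
    ``config.input_kind`` and "G" (for the benchmark arm).
    """
    n = len(y)
    plan = make_folds(n, config.k, config.repeats, config.seed)
    base_training = config.training_config()
    records: list[dict] = []
    log: dict = {"seed": config.seed, "n": n, "k": config.k, "repeats": config.repeats}

    inputs = dataset_inputs[config.input_kind]
    training = base_training
    if config.tune_learning_rate:
        probe_arch = Architecture(
            inputs.shape[1], config.hidden_grid[0], config.hidden_activation
        )
        lr = _tune_on_first_fold(probe_arch, base_training, inputs, y, plan)
        training = replace(base_training, learning_rate=lr)
        log["tuned_learning_rate"] = lr

    for n_hidden in config.hidden_grid:
        arch = Architecture(inputs.shape[1], n_hidden, config.hidden_activation)
        summary = run_cv(inputs, y, arch, training, plan)
        records.extend(_collect("grid", config.input_kind, n_hidden, summary))

    g_inputs = dataset_inputs["G"]
    bench_arch, _ = quasi_gblup_config(g_inputs.shape[1])
    bench_training = base_training
    if config.tune_learning_rate:
        lr = _tune_on_first_fold(bench_arch, base_training, g_inputs, y, plan)
        bench_training = replace(base_training, learning_rate=lr)
        log["benchmark_tuned_learning_rate"] = lr
    summary = run_cv(g_inputs, y, bench_arch, bench_training, plan)
    records.extend(_collect(BENCHMARK_LABEL, "G", 1, summary))

    long = pd.DataFrame.from_records(records)
    ok = long[long["failure"].isna()]
    summary_df = (
        ok.groupby(["arm", "input_kind", "n_hidden"], as_index=False)["r"]
        .agg(mean_r="mean", var_r=lambda s: float(np.var(s)))
        .sort_values(["arm", "input_kind", "n_hidden"], ignore_index=True)
    )
    return ResultsTable(long=long, summary=summary_df, log=log)


def run_experiment(config: ExperimentConfig) -> ResultsTable:
    """Full pipeline from files: QC -> coding -> inputs -> CV grid + benchmark."""
    table = load_genotypes(config.genotype_path, config.genotype_dialect)
    phenotypes, dropped = load_phenotypes(config.phenotype_path, table.sample_ids)
    if dropped:
        keep = [i for i, s in enumerate(table.sample_ids) if s in set(phenotypes.sample_ids)]
        table = type(table)(
            sample_ids=[table.sample_ids[i] for i in keep],
            marker_ids=table.marker_ids,
            counts=table.counts[keep],
        )
    filtered, removals = qc_filter(table, config.maf_min, config.missing_max)
    coded = code_genotypes(filtered)
    needed = {config.input_kind, "G"}
    inputs = {kind: build_input(coded, kind).values for kind in needed}
    result = run_experiment_arrays(inputs, phenotypes.y, config)
    result.log.update(
        {
            "dropped_sample_ids": dropped,
            "markers_removed": int(len(removals)),
            "markers_retained": coded.m,
            "missing_imputed": int(np.isnan(filtered.counts).sum()),
        }
    )
    return result


def run_simulated_experiment(dataset: SimulatedDataset, config: ExperimentConfig) -> ResultsTable:
    """Experiment on an in-memory simulated dataset (no files involved)."""
    filtered, _ = qc_filter(dataset.genotypes, config.maf_min, config.missing_max)
    coded = code_genotypes(filtered)
    needed = {config.input_kind, "G"}
    inputs = {kind: build_input(coded, kind).values for kind in needed}
    return run_experiment_arrays(inputs, dataset.phenotype, config)


def write_results(table: ResultsTable, output_dir: str | Path, config: ExperimentConfig | None = None) -> dict[str, Path]:
    """Write long-format and summary CSVs plus a run manifest (JSON)."""
    if table.long.empty:
        raise ValidationError("results table is empty; nothing to write")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "long": out / "cv_runs.csv",
        "summary": out / "summary.csv",
        "manifest": out / "manifest.json",
    }
    table.long.to_csv(paths["long"], index=False)
    table.summary.to_csv(paths["summary"], index=False)
    manifest = {
        "netgp_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "log": table.log,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return paths
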