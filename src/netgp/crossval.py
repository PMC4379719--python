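"""Repeated k-fold cross-validation, Pearson scoring, the quasi-GBLUP
benchmark arm and a closed-form ridge oracle.

The validation protocol: each repeat cuts a fresh random permutation of the
samples into k near-equal folds; every fold serves as the test set once, so
k folds x R repeats yields k*R train/test evaluations (100 for the default
20x5 scheme). Each run re-normalizes the phenotype on its training folds
only, trains from a run-specific weight initialization, predicts the held-out
fold and scores with Pearson's r. The summary reports the mean and the
population variance of r over all runs.

The benchmark arm is a one-hidden-neuron network with identity activations
fed the genomic relationship matrix: an iteratively trained multiple linear
regression on relationships, approximately GBLUP, and hence comparable to a
closed-form ridge regression at matched shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .exceptions import NetgpError, UndefinedCorrelationError, ValidationError
from .network import (
    Architecture,
    NetworkWeights,
    TrainingConfig,
    predict,
    train,
)
from .phenotypes import invert_normalization

__all__ = [
    "CVPlan",
    "CVRunResult",
    "CVSummary",
    "RidgeSolution",
    "make_folds",
    "pearson_r",
    "ridge_oracle",
    "quasi_gblup_config",
    "derive_run_seed",
    "fit_fold",
    "run_cv",
]


@dataclass
class CVPlan:
    """Fold assignments for repeated k-fold cross-validation.

    ``assignments[r, i]`` is the fold label of sample i in repeat r; within
    each repeat the labels partition all n samples into folds whose sizes
    differ by at most one.
    """

    n: int
    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # (repeats, n) int fold labels in [0, k)

    @property
    def n_runs(self) -> int:
        return self.k * self.repeats

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


@dataclass
class CVRunResult:
    repeat_index: int
    fold_index: int
    r: float  # NaN when the run failed
    n_test: int
    failure: str | None = None


@dataclass
class CVSummary:
    mean_r: float
    var_r: float  # population variance over runs
    runs: list[CVRunResult] = field(default_factory=list)


@dataclass
class RidgeSolution:
    coefficients: np.ndarray
    intercept: float
    lam: float


def make_folds(n: int, k: int = 5, repeats: int = 20, seed: int = 0) -> CVPlan:
    """Cut a fresh uniform permutation into k near-equal folds, per repeat.

    When k does not divide n the remainder is spread one sample per fold
    starting from the first fold.
    """
    if k < 2:
        raise ValidationError("need k >= 2 folds")
    if n < k:
        raise ValidationError(f"cannot cut n={n} samples into k={k} folds")
    if repeats < 1:
        raise ValidationError("need at least one repeat")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC5]))
    base, extra = divmod(n, k)
    sizes = [base + (1 if f < extra else 0) for f in range(k)]
    labels_template = np.repeat(np.arange(k), sizes)
    assignments = np.empty((repeats, n), dtype=np.int64)
    for r in range(repeats):
        perm = rng.permutation(n)
        assignments[r, perm] = labels_template
    return CVPlan(n=n, k=k, repeats=repeats, seed=seed, assignments=assignments)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; constant input is an error, never a silent 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("pearson_r needs two equal-length vectors with n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def ridge_oracle(
    X_train: np.ndarray,
    y_train: np.ndarray,
    lam: float,
    X_test: np.ndarray,
) -> tuple[np.ndarray, RidgeSolution]:
    """Closed-form penalized least squares with an unpenalized intercept.

    Solves (Xc'Xc + lam I) beta = Xc'yc on train-centred covariates and
    responses; at lam = 0 a rank-deficient system is refused with advice to
    use lam > 0.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    Xt = np.asarray(X_test, dtype=float)
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    if X.ndim != 2 or y.shape != (X.shape[0],) or Xt.shape[1] != X.shape[1]:
        raise ValidationError("ridge_oracle shapes are inconsistent")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if lam == 0 and np.linalg.matrix_rank(Xc) < X.shape[1]:
        raise ValidationError(
            "centred design is rank-deficient at lam=0; use lam > 0 for a unique solution"
        )
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    beta = np.linalg.solve(A, Xc.T @ (y - y_mean))
    intercept = y_mean
    preds = (Xt - x_mean) @ beta + intercept
    return preds, RidgeSolution(coefficients=beta, intercept=intercept, lam=lam)


def quasi_gblup_config(n_individuals: int) -> tuple[Architecture, str]:
    """The benchmark arm: one hidden neuron, identity activations throughout,
    fed the genomic relationship matrix (input kind "G")."""
    arch = Architecture(
        n_inputs=n_individuals,
        n_hidden=1,
        hidden_activation="identity",
        output_activation="identity",
    )
    return arch, "G"


def derive_run_seed(master_seed: int, repeat: int, fold: int) -> int:
    """Stable per-run seed from (master seed, repeat, fold); below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(repeat), int(fold)])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_fold(
    inputs: np.ndarray,
    y_raw: np.ndarray,
    train_idx: np.ndarray,
    arch: Architecture,
    config: TrainingConfig,
) -> tuple[NetworkWeights, float, float, str]:
    """Train one CV run on its training rows only.

    Phenotype normalization statistics (mu_y, max_y) come from the training
    rows alone, so held-out phenotypes can never influence the fitted
    weights. Returns (weights, mu_y, max_y, stop_reason).
    """
    y_tr = y_raw[train_idx]
    mu = float(y_tr.mean())
    mx = float(y_tr.max())
    if mx == 0:
        raise ValidationError("training-fold phenotype maximum is zero; cannot normalize")
    y_star = (y_tr - mu) / mx
    trace = train(arch, config, inputs[train_idx], y_star)
    return trace.final_weights, mu, mx, trace.stop_reason


def run_cv(
    inputs: np.ndarray,
    y_raw: np.ndarray,
    arch: Architecture,
    training_config: TrainingConfig,
    plan: CVPlan,
    max_failure_fraction: float = 0.1,
) -> CVSummary:
    """Execute every (repeat, fold) run of the plan and summarize Pearson r.

    Per-run weight-initialization seeds derive from (plan.seed, repeat,
    fold), so the runs use distinct initializations but the whole summary is
    reproducible bit-for-bit from the master seed. Individual run failures
    (divergence, undefined correlation) are recorded; more than
    ``max_failure_fraction`` of failed runs aborts with a diagnostic.
    """
    inputs = np.asarray(inputs, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    if inputs.shape[0] != plan.n or y_raw.shape != (plan.n,):
        raise ValidationError("inputs/phenotype shapes do not match the CV plan")
    runs: list[CVRunResult] = []
    n_failed = 0
    for repeat in range(plan.repeats):
        for fold in range(plan.k):
            test_idx = plan.test_indices(repeat, fold)
            train_idx = plan.train_indices(repeat, fold)
            cfg = replace(training_config, seed=derive_run_seed(plan.seed, repeat, fold))
            try:
                weights, mu, mx, _ = fit_fold(inputs, y_raw, train_idx, arch, cfg)
                preds = invert_normalization(predict(weights, arch, inputs[test_idx]), mu, mx)
                r = pearson_r(y_raw[test_idx], preds)
                runs.append(CVRunResult(repeat, fold, r, len(test_idx)))
            except NetgpError as exc:
                n_failed += 1
                runs.append(
                    CVRunResult(repeat, fold, float("nan"), len(test_idx), failure=str(exc))
                )
    if n_failed >= max_failure_fraction * plan.n_runs and n_failed > 0:
        failures = [run.failure for run in runs if run.failure][:3]
        raise NetgpError(
            f"{n_failed}/{plan.n_runs} cross-validation runs failed; first failures: {failures}"
        )
    r_values = np.array([run.r for run in runs if run.failure is None])
    return CVSummary(
        mean_r=float(r_values.mean()),
        var_r=float(r_values.var()),  # population variance over runs
        runs=runs,
    )
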