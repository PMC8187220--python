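"""Multi-step workflows: delta-learning, self-correction, learning curves.

Delta-learning predicts a high-level (target) property as a cheap baseline
value plus an ML correction trained on target-minus-baseline differences.
Self-correction stacks KRR layers, each fitting the residual of the sum of
the previous layers.  The learning-curve task measures test error at a
sequence of training-set sizes with repeats and fits the power law

    eps(N) = eps_a + a / N^b        (eps_a, a >= 0, b > 0)
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .krr import KernelRidgeRegressor
from .stats import error_report

__all__ = [
    "DeltaRegressor",
    "SelfCorrectingRegressor",
    "PowerLawFit",
    "fit_power_law",
    "learning_curve",
    "LearningCurveResult",
]


class DeltaRegressor(BaseEstimator, RegressorMixin):
    """Baseline-plus-correction model: predict(X, baseline) = baseline + f_hat(X).

    The wrapped estimator is trained on ``y_target - baseline``; baseline
    values must be supplied for every training and query point (they come
    from the cheap reference method, not from this model).
    """

    def __init__(self, estimator: KernelRidgeRegressor | None = None):
        self.estimator = estimator

    def fit(self, X, y, baseline=None):
        if baseline is None:
            raise ValueError("delta-learning requires baseline values for the training points")
        y = np.asarray(y, dtype=float)
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != y.shape:
            raise ValueError("baseline and target lengths differ")
        self.correction_ = clone(self.estimator)
        self.correction_.fit(X, y - baseline)
        return self

    def predict(self, X, baseline=None) -> np.ndarray:
        if baseline is None:
            raise ValueError("delta-learning requires baseline values for every query point")
        baseline = np.asarray(baseline, dtype=float)
        if len(baseline) != len(X):
            raise ValueError("one baseline value per query geometry is required")
        if len(X) == 0:
            return np.zeros(0)
        return baseline + self.correction_.predict(X)


class SelfCorrectingRegressor(BaseEstimator, RegressorMixin):
    """Layered KRR where layer i fits the residual of layers 1..i-1; the
    prediction is the sum of all layers."""

    def __init__(self, estimator: KernelRidgeRegressor | None = None, n_layers: int = 1):
        self.estimator = estimator
        self.n_layers = n_layers

    def fit(self, X, y):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        y = np.asarray(y, dtype=float)
        self.layers_ = []
        self.layer_targets_ = []
        residual = y.copy()
        for i in range(self.n_layers):
            layer = clone(self.estimator)
            try:
                layer.fit(X, residual)
            except Exception as exc:
                raise RuntimeError(f"training failed in self-correction layer {i + 1}") from exc
            self.layers_.append(layer)
            self.layer_targets_.append(residual.copy())
            residual = residual - layer.predict(X)
        self.final_residual_ = residual
        return self

    def predict(self, X) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0)
        pred = self.layers_[0].predict(X)
        for layer in self.layers_[1:]:
            pred = pred + layer.predict(X)
        return pred


# ---------------------------------------------------------------------------
# Power-law learning-curve fit

@dataclass(frozen=True)
class PowerLawFit:
    eps_a: float
    a: float
    b: float
    converged: bool = True
    note: str = ""


def fit_power_law(sizes: Sequence[float], errors: Sequence[float]) -> PowerLawFit:
    """Constrained least-squares fit of eps(N) = eps_a + a / N^b.

    The initial guess comes from the log-log linear fit with eps_a = 0
    (log eps ~ log a - b log N); a trust-region least-squares refinement with
    10 deterministic multi-starts around that seed picks the lowest-residual
    solution.  Constant error curves give eps_a equal to that constant and
    a -> 0, with b flagged as unidentifiable.
    """
    n = np.asarray(sizes, dtype=float)
    e = np.asarray(errors, dtype=float)
    if len(np.unique(n)) < 3:
        raise ValueError("need at least 3 distinct sizes")
    if np.any(e <= 0):
        raise ValueError("errors must be positive")

    if np.ptp(e) == 0.0:
        return PowerLawFit(float(e[0]), 0.0, 1.0, converged=True,
                           note="constant errors: b unidentifiable")

    # log-log seed (eps_a = 0)
    slope, intercept = np.polyfit(np.log(n), np.log(e), 1)
    b0 = max(-slope, 1e-3)
    a0 = float(np.exp(intercept))

    def residuals(p):
        eps_a, a, b = p
        return eps_a + a / n**b - e

    lower = [0.0, 0.0, 1e-12]
    upper = [np.inf, np.inf, np.inf]
    starts = [(0.0, a0, b0)]
    for i in range(1, 10):
        f = 1.0 + 0.35 * ((i + 1) // 2) * (-1) ** i
        starts.append((0.1 * min(e) * (i % 3), a0 * f, max(b0 * f, 1e-3)))
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower, [1e12, 1e12, 50.0])
        try:
            sol = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                ftol=1e-15, xtol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        return PowerLawFit(0.0, a0, b0, converged=False,
                           note="nonlinear fit failed; log-log fallback")
    eps_a, a, b = best.x
    note = ""
    if a < 1e-10 * max(e):
        note = "amplitude ~ 0: b unidentifiable"
    return PowerLawFit(float(eps_a), float(a), float(b), converged=True, note=note)


# ---------------------------------------------------------------------------
# Learning curves

@dataclass
class LearningCurveResult:
    table: pd.DataFrame  # Ntrain, repeat, seed, RMSE_test, MAE_test, t_train_s, t_predict_s
    fit: PowerLawFit | None
    mean_rmse: pd.Series  # indexed by Ntrain

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def learning_curve(
    X,
    y,
    estimator_factory: Callable[[], BaseEstimator],
    sizes: Sequence[int],
    repeats: int = 5,
    test_size: int | None = None,
    seed: int = 0,
    fixed_test: bool = True,
    csv_path: str | Path | None = None,
) -> LearningCurveResult:
    """Test-set RMSE as a function of training-set size, with repeats.

    For every size x repeat a fresh seeded training sample is drawn and a
    fresh estimator from ``estimator_factory`` is trained and timed.  By
    default one fixed held-out test set is shared across all cells (paired
    comparisons); ``fixed_test=False`` redraws the test set per repeat.  The
    power law is fitted to the mean RMSE per size.  Identical seeds give an
    identical table.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if test_size is None:
        test_size = max(1, n // 5)
    if max(sizes) + test_size > n:
        usable = [s for s in sizes if s + test_size <= n]
        skipped = sorted(set(sizes) - set(usable))
        warnings.warn(f"sizes {skipped} skipped: not enough data", UserWarning, stacklevel=2)
        sizes = usable
        if not sizes:
            raise ValueError("no feasible training-set size")

    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    fixed_test_idx = rng.choice(n, size=test_size, replace=False) if fixed_test else None

    rows = []
    for size in sizes:
        for rep in range(repeats):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell_rng = np.random.default_rng(cell_seed)
            if fixed_test:
                test_idx = fixed_test_idx
            else:
                test_idx = cell_rng.choice(n, size=test_size, replace=False)
            pool = np.setdiff1d(all_idx, test_idx)
            train_idx = cell_rng.choice(pool, size=size, replace=False)
            X_tr = [X[i] for i in train_idx]
            X_te = [X[i] for i in test_idx]
            est = estimator_factory()
            t0 = time.perf_counter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est.fit(X_tr, y[train_idx])
            t_train = time.perf_counter() - t0
            t0 = time.perf_counter()
            pred = est.predict(X_te)
            t_predict = time.perf_counter() - t0
            rep_stats = error_report(pred, y[test_idx])
            rows.append(
                dict(
                    Ntrain=size,
                    repeat=rep,
                    seed=cell_seed,
                    RMSE_test=rep_stats.rmse,
                    MAE_test=rep_stats.mae,
                    t_train_s=t_train,
                    t_predict_s=t_predict,
                    fixed_test=fixed_test,
                )
            )
    table = pd.DataFrame(rows)
    mean_rmse = table.groupby("Ntrain")["RMSE_test"].mean()
    fit = None
    if len(mean_rmse) >= 3:
        try:
            fit = fit_power_law(mean_rmse.index.to_numpy(), mean_rmse.to_numpy())
        except ValueError:
            fit = None
    result = LearningCurveResult(table=table, fit=fit, mean_rmse=mean_rmse)
    if csv_path is not None:
        result.to_csv(csv_path)
    return result
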