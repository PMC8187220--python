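"""Loss combination and hyperparameter search on a nested logarithmic grid.

The search optimizes (sigma, lambda) by exhaustive evaluation of a log2 grid
against a validation split of the training set, re-centers the grid on the
best point (bracketing it one grid step on each side in log space) for each
refinement pass, and finally retrains on the whole training set —
sub-training plus validation — with the winning hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .data import MolecularDataset
from .sampling import random_split
from .stats import error_report, gradient_rmse
from .krr import KernelRidgeRegressor

__all__ = ["LossSpec", "GridSpec", "combined_loss", "GridSearchKRR", "evaluate_model"]


@dataclass(frozen=True)
class LossSpec:
    """How value and gradient errors combine into one scalar loss.

    * ``values_only``     L = L_val
    * ``sum_weighted``    L = L_val + w_grxyz * L_grxyz
    * ``geometric_mean``  L = sqrt(L_val * L_grxyz)
    """

    mode: str = "values_only"
    w_grxyz: float | None = None
    base_metric: str = "RMSE"

    def __post_init__(self) -> None:
        if self.mode not in ("values_only", "sum_weighted", "geometric_mean"):
            raise ValueError(f"unknown loss mode {self.mode!r}")
        if self.mode == "sum_weighted" and (self.w_grxyz is None or self.w_grxyz < 0):
            raise ValueError("sum_weighted mode requires nonnegative w_grxyz")
        if self.base_metric not in ("RMSE", "MAE"):
            raise ValueError("base_metric must be RMSE or MAE")

    @property
    def needs_gradients(self) -> bool:
        return self.mode != "values_only"


def combined_loss(spec: LossSpec, l_val: float, l_grxyz: float | None = None) -> float:
    if l_val < 0 or (l_grxyz is not None and l_grxyz < 0):
        raise ValueError("losses must be nonnegative")
    if spec.mode == "values_only":
        return float(l_val)
    if l_grxyz is None:
        raise ValueError(f"loss mode {spec.mode!r} requires a gradient loss")
    if spec.mode == "sum_weighted":
        return float(l_val + spec.w_grxyz * l_grxyz)
    return float(np.sqrt(l_val * l_grxyz))


@dataclass(frozen=True)
class GridSpec:
    """Nested logarithmic grid for (sigma, lambda); exponents are log-base powers."""

    log_base: float = 2.0
    sigma_min_exp: float = 2.0
    sigma_max_exp: float = 9.0
    lam_min_exp: float = -35.0
    lam_max_exp: float = -6.0
    points: int = 11
    n_passes: int = 3

    def __post_init__(self) -> None:
        if self.sigma_min_exp >= self.sigma_max_exp or self.lam_min_exp >= self.lam_max_exp:
            raise ValueError("min exponent must be below max exponent")
        if self.points < 2 or self.n_passes < 1:
            raise ValueError("need points >= 2 and n_passes >= 1")


class GridSearchKRR(BaseEstimator):
    """Nested-log-grid (sigma, lambda) optimization for a KRR estimator.

    Parameters
    ----------
    estimator : KernelRidgeRegressor
        Template; its sigma/lam are overwritten during the search.
    grid : GridSpec
    loss : LossSpec
    validation_fraction : float
        Sub-training:validation split of the training set (default 80:20).
    seed : int
        Seed for the validation split; the whole search is deterministic.

    Attributes
    ----------
    best_sigma_, best_lam_ : winning hyperparameters.
    best_loss_ : their validation loss.
    best_estimator_ : final model retrained on the full training set.
    log_ : DataFrame with one row per evaluated candidate
        (pass, sigma, lam, L_val, L_grxyz, L).
    """

    def __init__(
        self,
        estimator: KernelRidgeRegressor | None = None,
        grid: GridSpec = GridSpec(),
        loss: LossSpec = LossSpec(),
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.estimator = estimator
        self.grid = grid
        self.loss = loss
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y, gradients: Sequence[np.ndarray] | None = None):
        if self.estimator is None:
            raise ValueError("GridSearchKRR needs a template estimator")
        if self.loss.needs_gradients and gradients is None:
            raise ValueError(f"loss mode {self.loss.mode!r} requires gradients")
        y = np.asarray(y, dtype=float)
        n = len(y)
        split = random_split(
            n,
            fractions={"sub_training": 1 - self.validation_fraction,
                       "validation": self.validation_fraction},
            seed=self.seed,
        )
        sub, val = split["sub_training"], split["validation"]
        X_sub = [X[i] for i in sub]
        X_val = [X[i] for i in val]
        y_sub, y_val = y[sub], y[val]
        grads_val = None if gradients is None else [gradients[i] for i in val]

        g = self.grid
        sigma_lo, sigma_hi = g.sigma_min_exp, g.sigma_max_exp
        lam_lo, lam_hi = g.lam_min_exp, g.lam_max_exp
        rows = []
        best = None  # (loss, lam, sigma, sigma_exp, lam_exp)
        for p in range(g.n_passes):
            sigma_exps = np.linspace(sigma_lo, sigma_hi, g.points)
            lam_exps = np.linspace(lam_lo, lam_hi, g.points)
            pass_best = None
            for se in sigma_exps:
                for le in lam_exps:
                    sigma = float(g.log_base**se)
                    lam = float(g.log_base**le)
                    cand = clone(self.estimator)
                    cand.set_params(sigma=sigma, lam=lam)
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", RuntimeWarning)
                            cand.fit(X_sub, y_sub)
                    except Exception:
                        rows.append((p, sigma, lam, np.nan, np.nan, np.nan))
                        continue
                    pred = cand.predict(X_val)
                    rep = error_report(pred, y_val)
                    l_val = rep.rmse if self.loss.base_metric == "RMSE" else rep.mae
                    l_gr = None
                    if self.loss.needs_gradients:
                        l_gr = gradient_rmse(cand.predict_gradients(X_val), grads_val)
                    l = combined_loss(self.loss, l_val, l_gr)
                    rows.append((p, sigma, lam, l_val, l_gr if l_gr is not None else np.nan, l))
                    # ties: smaller lambda preferred, then smaller sigma
                    key = (l, lam, sigma)
                    if pass_best is None or key < pass_best[0]:
                        pass_best = (key, se, le)
            if pass_best is None:
                raise RuntimeError(
                    "every candidate training failed; see the attached log",
                ) from None
            (loss_key, se_best, le_best) = pass_best
            if best is None or loss_key < best[0]:
                best = (loss_key, se_best, le_best)
            # re-center: bracket the best point one grid step on each side in log space
            s_step = (sigma_hi - sigma_lo) / (g.points - 1)
            l_step = (lam_hi - lam_lo) / (g.points - 1)
            sigma_lo, sigma_hi = se_best - s_step, se_best + s_step
            lam_lo, lam_hi = le_best - l_step, le_best + l_step

        (best_loss, best_lam, best_sigma), _, _ = best
        self.best_sigma_ = best_sigma
        self.best_lam_ = best_lam
        self.best_loss_ = best_loss
        self.log_ = pd.DataFrame(
            rows, columns=["pass", "sigma", "lam", "L_val", "L_grxyz", "L"]
        )
        final = clone(self.estimator)
        final.set_params(sigma=self.best_sigma_, lam=self.best_lam_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            final.fit(X, y)  # retrain on sub-training + validation
        self.best_estimator_ = final
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)


def evaluate_model(
    model,
    X_test,
    y_test,
    gradients_test: Sequence[np.ndarray] | None = None,
    training_indices: Sequence[int] | None = None,
    test_indices: Sequence[int] | None = None,
):
    """Statistics report of a fitted model on an independent test set.

    Returns a dict with a ``values`` ErrorReport and, when reference
    gradients are supplied, a ``gradients`` block with the component RMSE.
    When both index sets are given their overlap is checked; a non-empty
    overlap triggers a warning (the test set should be independent).
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    if training_indices is not None and test_indices is not None:
        overlap = set(map(int, training_indices)) & set(map(int, test_indices))
        if overlap:
            warnings.warn(
                f"test set overlaps training set on {len(overlap)} indices; "
                "the reported errors are not generalization errors",
                UserWarning,
                stacklevel=2,
            )
    pred = model.predict(X_test)
    out = {"values": error_report(pred, np.asarray(y_test, dtype=float))}
    if gradients_test is not None:
        grad_pred = model.predict_gradients(X_test)
        out["gradients"] = {"rmse": gradient_rmse(grad_pred, gradients_test)}
    return out
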