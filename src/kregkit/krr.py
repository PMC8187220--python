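"""Kernel ridge regression on molecular descriptors.

The estimator solves the regularized linear system (K + lambda I) alpha = y by
matrix factorization (never by explicit inversion) and predicts

    f(x) = sum_j alpha_j k(x, x_j)

Cartesian first derivatives follow by the chain rule through the kernel
gradient and the descriptor Jacobian; with permutation groups declared, the
permutationally invariant kernel and its gradient are used instead.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.linalg import lapack
from sklearn.base import BaseEstimator, RegressorMixin

from .data import MolecularGeometry
from .descriptors import (
    CMDescriptor,
    IDDescriptor,
    PermutationGroups,
    REDescriptor,
    SortedREDescriptor,
)
from .kernels import (
    KernelSpec,
    NotDifferentiableError,
    kernel_gradient,
    kernel_matrix,
    kernel_matrix_vectors,
    perm_kernel_gradient,
)

__all__ = ["KernelRidgeRegressor", "SingularSystemError", "save_model", "load_model"]

MODEL_FORMAT_VERSION = "kregkit-krr-1"
_SOLVERS = ("cholesky", "bunch_kaufman", "lu")
_ILL_CONDITION_RESIDUAL = 1e-6


class SingularSystemError(np.linalg.LinAlgError):
    """No factorization produced a finite solution of (K + lambda I) alpha = y."""


def _solve_cholesky(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    c, low = scipy.linalg.cho_factor(a, lower=True)
    return scipy.linalg.cho_solve((c, low), y)


def _solve_bunch_kaufman(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, _, x, info = lapack.dsysv(a, y)
    if info != 0:
        raise np.linalg.LinAlgError(f"Bunch-Kaufman factorization failed (info={info})")
    return x


def _solve_lu(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
        lu, piv = scipy.linalg.lu_factor(a)
    return scipy.linalg.lu_solve((lu, piv), y)


_SOLVER_FUNCS = {
    "cholesky": _solve_cholesky,
    "bunch_kaufman": _solve_bunch_kaufman,
    "lu": _solve_lu,
}


def _is_geometry_input(X) -> bool:
    return len(X) > 0 and isinstance(X[0], MolecularGeometry)


class KernelRidgeRegressor(BaseEstimator, RegressorMixin):
    """KRR potential-energy-surface model with analytic Cartesian gradients.

    Parameters
    ----------
    descriptor :
        A descriptor transformer (REDescriptor, SortedREDescriptor,
        CMDescriptor, IDDescriptor) mapping geometries to input vectors, or
        None to fit on precomputed (user-supplied) descriptor matrices.
    kernel : {"gaussian", "laplacian", "exponential", "matern"}
    sigma : float
        Kernel length scale.
    matern_n : int
        Matern smoothness integer (matern family only).
    lam : float
        Regularization added to the kernel-matrix diagonal.  The default
        2**-35 is a small positive value that keeps the Cholesky
        factorization stable on clean data.
    solver : {"cholesky", "bunch_kaufman", "lu"}
        Factorization used for the linear solve; on failure the remaining
        solvers are tried in the order above, with a warning.
    permutation_groups : PermutationGroups, optional
        Activates the permutationally invariant kernel over these groups of
        equivalent atoms (requires geometry input).

    Attributes
    ----------
    alpha_ : regression coefficients, one per training point.
    X_train_ : training descriptor matrix.
    geometries_ : training geometries (geometry input only).
    residual_ : inf-norm of (K + lambda I) alpha - y after the solve.
    solver_used_ : the factorization that actually succeeded.
    """

    def __init__(
        self,
        descriptor=None,
        kernel: str = "gaussian",
        sigma: float = 1.0,
        matern_n: int = 2,
        lam: float = 2.0**-35,
        solver: str = "cholesky",
        permutation_groups: PermutationGroups | None = None,
    ):
        self.descriptor = descriptor
        self.kernel = kernel
        self.sigma = sigma
        self.matern_n = matern_n
        self.lam = lam
        self.solver = solver
        self.permutation_groups = permutation_groups

    # -- helpers -----------------------------------------------------------
    def _spec(self) -> KernelSpec:
        return KernelSpec(
            family=self.kernel,
            sigma=self.sigma,
            matern_n=self.matern_n,
            permutation_groups=self.permutation_groups,
        )

    def _check_lam(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.solver not in _SOLVERS:
            raise ValueError(f"unknown solver {self.solver!r}; choose from {_SOLVERS}")

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        self._check_lam()
        y = np.asarray(y, dtype=float)
        spec = self._spec()
        if _is_geometry_input(X):
            if self.descriptor is None:
                raise ValueError("geometry input requires a descriptor")
            if spec.permutation_groups is not None:
                spec.permutation_groups.validate_elements(X[0])
            self.geometries_ = list(X)
            self.X_train_ = self.descriptor.transform(X)
            K = kernel_matrix(spec, self.descriptor, self.geometries_)
        else:
            if spec.permutation_groups is not None:
                raise ValueError("the permutationally invariant kernel requires geometry input")
            self.geometries_ = None
            self.X_train_ = np.atleast_2d(np.asarray(X, dtype=float))
            K = kernel_matrix_vectors(spec, self.X_train_)
        if len(y) != K.shape[0]:
            raise ValueError("y length does not match number of training points")

        A = K + self.lam * np.eye(K.shape[0])
        order = [self.solver] + [s for s in _SOLVERS if s != self.solver]
        alpha = None
        for i, name in enumerate(order):
            try:
                cand = _SOLVER_FUNCS[name](A, y)
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgWarning):
                continue
            if not np.all(np.isfinite(cand)):
                continue
            if i > 0:
                warnings.warn(
                    f"{self.solver} factorization failed; fell back to {name}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            alpha = cand
            self.solver_used_ = name
            break
        if alpha is None:
            raise SingularSystemError(
                "K + lambda I is singular for every available factorization "
                "(duplicate training points with lam=0?)"
            )
        self.alpha_ = alpha
        self.residual_ = float(np.max(np.abs(A @ alpha - y))) if len(y) else 0.0
        if self.residual_ > _ILL_CONDITION_RESIDUAL * max(1.0, float(np.max(np.abs(y), initial=0.0))):
            warnings.warn(
                f"ill-conditioned kernel system: solve residual {self.residual_:.3e}",
                RuntimeWarning,
                stacklevel=2,
            )
        self.n_features_in_ = self.X_train_.shape[1]
        return self

    # -- prediction --------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        self._require_fitted()
        spec = self._spec()
        if _is_geometry_input(X):
            if self.descriptor is None:
                raise ValueError("model was fit on precomputed vectors; pass vectors to predict")
            if self.geometries_ is not None and X[0].elements != self.geometries_[0].elements:
                raise ValueError("query element sequence differs from the training molecules")
            K = kernel_matrix(spec, self.descriptor, list(X), self.geometries_) \
                if spec.permutation_groups is not None else \
                kernel_matrix_vectors(spec, self.descriptor.transform(X), self.X_train_)
            return K @ self.alpha_
        if len(X) == 0:
            return np.zeros(0)
        if spec.permutation_groups is not None:
            raise ValueError("permutationally invariant models require geometry input")
        Kc = kernel_matrix_vectors(spec, np.atleast_2d(np.asarray(X, dtype=float)), self.X_train_)
        return Kc @ self.alpha_

    def predict_gradients(self, geometries: Sequence[MolecularGeometry]) -> list[np.ndarray]:
        """Cartesian derivatives df/dM (value-units per Angstrom), one (n_atoms, 3)
        matrix per query geometry."""
        self._require_fitted()
        spec = self._spec()
        if not spec.differentiable:
            raise NotDifferentiableError(f"{self.kernel} kernel has no analytic derivative")
        if self.descriptor is None:
            raise ValueError(
                "user-supplied descriptor vectors carry no Jacobian; gradients unavailable"
            )
        out = []
        for geom in geometries:
            if spec.permutation_groups is not None:
                grad = np.zeros((geom.n_atoms, 3))
                for a_j, geom_j in zip(self.alpha_, self.geometries_):
                    grad += a_j * perm_kernel_gradient(spec, geom, geom_j, self.descriptor)
            else:
                x = self.descriptor.describe(geom)
                jac = self.descriptor.jacobian(geom)  # (N_x, 3 n_atoms)
                g_x = np.zeros(x.shape[0])
                for a_j, xj in zip(self.alpha_, self.X_train_):
                    g_x += a_j * kernel_gradient(spec, x, xj)
                grad = (g_x @ jac).reshape(geom.n_atoms, 3)
            out.append(grad)
        return out

    def _require_fitted(self) -> None:
        if not hasattr(self, "alpha_"):
            raise RuntimeError("estimator is not fitted")


# ---------------------------------------------------------------------------
# Serialization: versioned NPZ container with a JSON metadata member (.krr)

def _descriptor_to_meta(desc) -> tuple[dict, dict]:
    arrays: dict[str, np.ndarray] = {}
    if desc is None:
        return {"type": "none"}, arrays
    if isinstance(desc, (REDescriptor, SortedREDescriptor)):
        kind = "sorted_re" if isinstance(desc, SortedREDescriptor) else "re"
        arrays["ref_coordinates"] = desc.reference.coordinates
        return {"type": kind, "ref_elements": list(desc.reference.elements)}, arrays
    if isinstance(desc, CMDescriptor):
        return {"type": "cm", "max_atoms": desc.max_atoms, "variant": desc.variant}, arrays
    if isinstance(desc, IDDescriptor):
        return {"type": "id"}, arrays
    raise TypeError(f"cannot serialize descriptor of type {type(desc).__name__}")


def _descriptor_from_meta(meta: dict, arrays) -> object | None:
    kind = meta["type"]
    if kind == "none":
        return None
    if kind in ("re", "sorted_re"):
        ref = MolecularGeometry(tuple(meta["ref_elements"]), arrays["ref_coordinates"])
        return SortedREDescriptor(ref) if kind == "sorted_re" else REDescriptor(ref)
    if kind == "cm":
        return CMDescriptor(max_atoms=int(meta["max_atoms"]), variant=meta["variant"])
    if kind == "id":
        return IDDescriptor()
    raise ValueError(f"unknown descriptor type {kind!r} in model file")


def save_model(model: KernelRidgeRegressor, path) -> None:
    """Write a fitted model to a versioned NPZ container (extension .krr)."""
    model._require_fitted()
    desc_meta, arrays = _descriptor_to_meta(model.descriptor)
    meta = {
        "format": MODEL_FORMAT_VERSION,
        "kernel": model.kernel,
        "sigma": model.sigma,
        "matern_n": model.matern_n,
        "lam": model.lam,
        "solver": model.solver,
        "descriptor": desc_meta,
        "permutation_groups": (
            None
            if model.permutation_groups is None
            else [list(g) for g in model.permutation_groups.groups]
        ),
        "has_geometries": model.geometries_ is not None,
    }
    if model.geometries_ is not None:
        meta["train_elements"] = list(model.geometries_[0].elements)
        arrays["train_coordinates"] = np.array(
            [g.coordinates for g in model.geometries_]
        )
    with open(path, "wb") as fh:  # file handle: keeps the .krr extension as-is
        np.savez(
            fh,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            alpha=model.alpha_,
            X_train=model.X_train_,
            **arrays,
        )


def load_model(path) -> KernelRidgeRegressor:
    """Load a model written by :func:`save_model`; predictions round-trip bit-identically."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (ValueError, OSError, EOFError, zipfile.BadZipFile) as exc:
        raise ValueError(f"not a readable model container: {path}") from exc
    if "meta" not in data or "alpha" not in data:
        raise ValueError(f"truncated or foreign model file: {path}")
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {meta.get('format')!r} is incompatible with {MODEL_FORMAT_VERSION!r}"
        )
    model = KernelRidgeRegressor(
        descriptor=_descriptor_from_meta(meta["descriptor"], data),
        kernel=meta["kernel"],
        sigma=meta["sigma"],
        matern_n=meta["matern_n"],
        lam=meta["lam"],
        solver=meta["solver"],
        permutation_groups=(
            None
            if meta["permutation_groups"] is None
            else PermutationGroups(meta["permutation_groups"])
        ),
    )
    model.alpha_ = data["alpha"]
    model.X_train_ = data["X_train"]
    model.n_features_in_ = model.X_train_.shape[1]
    model.residual_ = 0.0
    model.solver_used_ = meta["solver"]
    if meta["has_geometries"]:
        elements = tuple(meta["train_elements"])
        model.geometries_ = [
            MolecularGeometry(elements, c) for c in data["train_coordinates"]
        ]
    else:
        model.geometries_ = None
    return model
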