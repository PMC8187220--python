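"""Kernel functions, analytic first derivatives, and the permutationally invariant kernel.

Supported families (all with length scale sigma > 0, d = ||x - x_j||_2):

* gaussian     k = exp(-d^2 / (2 sigma^2))
* laplacian    k = exp(-||x - x_j||_1 / sigma)
* exponential  k = exp(-d / sigma)
* matern       k = exp(-d / sigma) * sum_{k=0}^{n} (n+k)!/(2n)! C(n,k) (2d/sigma)^(n-k)

The Matern family carries an extra integer hyperparameter n; n = 0 collapses
to the exponential kernel.  Gaussian and Matern with n > 0 are differentiable;
laplacian, exponential and Matern n = 0 are not.

The permutationally invariant kernel symmetrizes a base kernel over the
permutations P of user-declared groups of equivalent atoms and normalizes so
that kbar(M, M) = 1:

    kbar(M, Mj) = sum_P k(x(M), x(P Mj))
                  / sqrt(sum_P k(x(M), x(P M)) * sum_P k(x(Mj), x(P Mj)))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import MolecularGeometry
from .descriptors import PermutationGroups

__all__ = [
    "KernelSpec",
    "kernel_value",
    "kernel_gradient",
    "perm_kernel_value",
    "perm_kernel_gradient",
    "kernel_matrix",
    "kernel_matrix_vectors",
    "cross_kernel_vectors",
    "NotDifferentiableError",
]

_FAMILIES = ("gaussian", "laplacian", "exponential", "matern")
_MATERN_N_MAX = 20


class NotDifferentiableError(ValueError):
    """The requested kernel family has no analytic first derivative."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters; optional permutation groups symmetrize it."""

    family: str = "gaussian"
    sigma: float = 1.0
    matern_n: int = 2
    permutation_groups: PermutationGroups | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.matern_n < 0:
            raise ValueError("matern_n must be nonnegative")
        if self.matern_n > _MATERN_N_MAX:
            raise ValueError(f"matern_n capped at {_MATERN_N_MAX} to keep coefficients finite")

    @property
    def differentiable(self) -> bool:
        return self.family == "gaussian" or (self.family == "matern" and self.matern_n > 0)


def _matern_coeff(n: int, k: int) -> float:
    # (n+k)! / (2n)! * C(n, k), in log space for large n to avoid overflow
    if n <= 10:
        return math.factorial(n + k) / math.factorial(2 * n) * math.comb(n, k)
    return math.exp(
        math.lgamma(n + k + 1) - math.lgamma(2 * n + 1)
    ) * math.comb(n, k)


def kernel_value(spec: KernelSpec, x: np.ndarray, xj: np.ndarray) -> float:
    """Evaluate the base kernel; value in (0, 1], equal to 1 iff x == xj."""
    x = np.asarray(x, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if x.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {xj.shape}")
    diff = x - xj
    if spec.family == "gaussian":
        return float(np.exp(-0.5 * diff @ diff / spec.sigma**2))
    if spec.family == "laplacian":
        return float(np.exp(-np.abs(diff).sum() / spec.sigma))
    d = float(np.linalg.norm(diff))
    if spec.family == "exponential":
        return float(np.exp(-d / spec.sigma))
    n = spec.matern_n
    s = sum(_matern_coeff(n, k) * (2.0 * d / spec.sigma) ** (n - k) for k in range(n + 1))
    return float(np.exp(-d / spec.sigma) * s)


def kernel_gradient(spec: KernelSpec, x: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """Analytic dk/dx_d per component.

    Gaussian: (x_j,d - x_d) k / sigma^2.  Matern n > 0:
    exp(-d/sigma) sum_{k=0}^{n-1} (n+k-1)!/(2n)! C(n,k) (n-k) (2/sigma^2)
    (2d/sigma)^(n-k-1) (x_j,d - x_d).
    """
    if not spec.differentiable:
        raise NotDifferentiableError(
            f"{spec.family} kernel"
            + (" with n=0" if spec.family == "matern" else "")
            + " is not differentiable"
        )
    x = np.asarray(x, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if x.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {xj.shape}")
    if spec.family == "gaussian":
        return (xj - x) / spec.sigma**2 * kernel_value(spec, x, xj)
    n = spec.matern_n
    d = float(np.linalg.norm(x - xj))
    s = 0.0
    for k in range(n):
        coeff = _matern_coeff(n, k) / (n + k)  # (n+k-1)!/(2n)! C(n,k)
        term = coeff * (n - k) * (2.0 / spec.sigma**2)
        if n - k - 1 == 0:
            term *= 1.0
        else:
            term *= (2.0 * d / spec.sigma) ** (n - k - 1)
        s += term
    return float(np.exp(-d / spec.sigma)) * s * (xj - x)


# ---------------------------------------------------------------------------
# Permutationally invariant kernel

def _perm_descriptors(descriptor, geom: MolecularGeometry, perms) -> list[np.ndarray]:
    return [descriptor.describe(geom.permuted(p)) for p in perms]


def _self_sum(spec: KernelSpec, descriptor, geom: MolecularGeometry, perms) -> float:
    x = descriptor.describe(geom)
    return sum(kernel_value(spec, x, xp) for xp in _perm_descriptors(descriptor, geom, perms))


def perm_kernel_value(
    spec: KernelSpec,
    geom_i: MolecularGeometry,
    geom_j: MolecularGeometry,
    descriptor,
) -> float:
    """Normalized symmetrized kernel kbar(M_i, M_j); equals 1 when the geometries coincide."""
    groups = spec.permutation_groups
    if groups is None:
        raise ValueError("KernelSpec carries no permutation groups; use the plain kernel")
    perms = groups.permutations(geom_i.n_atoms)
    xi = descriptor.describe(geom_i)
    cross = sum(
        kernel_value(spec, xi, xp) for xp in _perm_descriptors(descriptor, geom_j, perms)
    )
    s_ii = _self_sum(spec, descriptor, geom_i, perms)
    s_jj = _self_sum(spec, descriptor, geom_j, perms)
    return cross / math.sqrt(s_ii * s_jj)


def _permuted_jacobian(descriptor, geom: MolecularGeometry, perm: np.ndarray) -> np.ndarray:
    """d x(P M) / dM: Jacobian of the descriptor of the permuted geometry wrt the
    ORIGINAL coordinates.  Row i of P M is atom perm[i] of M, so the column
    block of original atom perm[i] receives the block of permuted position i."""
    pg = geom.permuted(perm)
    jac_p = descriptor.jacobian(pg)  # wrt coordinates of P M
    out = np.zeros_like(jac_p)
    for i, a in enumerate(perm):
        out[:, 3 * a : 3 * a + 3] = jac_p[:, 3 * i : 3 * i + 3]
    return out


def perm_kernel_gradient(
    spec: KernelSpec,
    geom_i: MolecularGeometry,
    geom_j: MolecularGeometry,
    descriptor,
) -> np.ndarray:
    """d kbar / dM of geom_i, shape (n_atoms, 3).

    Quotient rule on the normalized symmetrized kernel:

        d kbar = [sum_P d k(x(M), x(P Mj))] / sqrt(S_ii S_jj)
                 - (kbar / (2 S_ii)) sum_P d k(x(M), x(P M))

    where the self terms d k(x(M), x(P M)) pick up contributions through both
    kernel arguments (chain rule with the permuted-descriptor Jacobian).
    """
    groups = spec.permutation_groups
    if groups is None:
        raise ValueError("KernelSpec carries no permutation groups; use the plain kernel")
    if not spec.differentiable:
        raise NotDifferentiableError(f"{spec.family} base kernel is not differentiable")
    perms = groups.permutations(geom_i.n_atoms)
    n3 = geom_i.n_atoms * 3

    xi = descriptor.describe(geom_i)
    jac_i = descriptor.jacobian(geom_i)  # (N_x, n3)

    # cross sum and its gradient (geom_i enters only through x(M))
    cross = 0.0
    d_cross = np.zeros(n3)
    for xp in _perm_descriptors(descriptor, geom_j, perms):
        cross += kernel_value(spec, xi, xp)
        d_cross += kernel_gradient(spec, xi, xp) @ jac_i

    # self sums
    s_jj = _self_sum(spec, descriptor, geom_j, perms)
    s_ii = 0.0
    d_sii = np.zeros(n3)
    for p in perms:
        xp = descriptor.describe(geom_i.permuted(p))
        s_ii += kernel_value(spec, xi, xp)
        jac_p = _permuted_jacobian(descriptor, geom_i, p)
        # both arguments depend on M: dk/dx1 . dx(M)/dM + dk/dx2 . dx(PM)/dM
        d_sii += kernel_gradient(spec, xi, xp) @ jac_i
        d_sii += kernel_gradient(spec, xp, xi) @ jac_p

    kbar = cross / math.sqrt(s_ii * s_jj)
    grad = d_cross / math.sqrt(s_ii * s_jj) - 0.5 * kbar / s_ii * d_sii
    return grad.reshape(geom_i.n_atoms, 3)


# ---------------------------------------------------------------------------
# Kernel matrices

def kernel_matrix_vectors(spec: KernelSpec, x: np.ndarray, xj: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix between rows of descriptor matrices; symmetric when xj is None.

    The symmetric case is assembled from one triangle and mirrored so the
    result is exactly symmetric despite floating-point non-associativity.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if xj is None:
        n = x.shape[0]
        k = np.zeros((n, n))
        for i in range(n):
            k[i, i] = 1.0
            for j in range(i + 1, n):
                k[i, j] = kernel_value(spec, x[i], x[j])
                k[j, i] = k[i, j]
        return k
    xj = np.atleast_2d(np.asarray(xj, dtype=float))
    out = np.zeros((x.shape[0], xj.shape[0]))
    for i in range(x.shape[0]):
        for j in range(xj.shape[0]):
            out[i, j] = kernel_value(spec, x[i], xj[j])
    return out


def cross_kernel_vectors(spec: KernelSpec, x: np.ndarray, x_train: np.ndarray) -> np.ndarray:
    return kernel_matrix_vectors(spec, x, x_train)


def kernel_matrix(
    spec: KernelSpec,
    descriptor,
    geometries: Sequence[MolecularGeometry],
    geometries_j: Sequence[MolecularGeometry] | None = None,
) -> np.ndarray:
    """Kernel (or permutation-kernel) matrix over geometry pairs; exactly symmetric
    with unit diagonal in the square case."""
    if spec.permutation_groups is None:
        x = descriptor.transform(geometries)
        if geometries_j is None:
            return kernel_matrix_vectors(spec, x)
        return kernel_matrix_vectors(spec, x, descriptor.transform(geometries_j))
    if geometries_j is None:
        n = len(geometries)
        k = np.zeros((n, n))
        for i in range(n):
            k[i, i] = 1.0
            for j in range(i + 1, n):
                k[i, j] = perm_kernel_value(spec, geometries[i], geometries[j], descriptor)
                k[j, i] = k[i, j]
        return k
    out = np.zeros((len(geometries), len(geometries_j)))
    for i, gi in enumerate(geometries):
        for j, gj in enumerate(geometries_j):
            out[i, j] = perm_kernel_value(spec, gi, gj, descriptor)
    return out
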