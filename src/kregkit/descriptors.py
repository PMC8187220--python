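"""Molecular descriptors with analytic Jacobians.

Three descriptor families map an ``n_atoms x 3`` geometry ``M`` (Angstrom) to
an input vector ``x``:

* RE  — relative inverse distances ``x_d = r_ref[a,b] / r[a,b]`` over all
  unordered atom pairs ``a < b`` against a fixed reference geometry.
* CM  — the Coulomb matrix ``0.5 Z_a^2.4`` (diagonal), ``Z_a Z_b / r_ab``
  (off-diagonal, distances in Bohr), zero-padded to ``max_atoms`` and
  vectorized row-major including both symmetric halves.
* ID  — unnormalized inverse distances ``x_d = 1 / r[a,b]`` (1/Angstrom).

RE/ID pairs follow the canonical lexicographic order (a, b) with a < b.
Analytic Jacobians ``dx/dM`` (per Angstrom) are available for RE, ID and the
unsorted CM; sorting breaks differentiability.

Descriptors are scikit-learn transformers: ``transform`` maps a sequence of
geometries to a 2-D descriptor matrix, ``jacobian`` returns ``dx/dM`` for one
geometry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import BOHR_IN_ANGSTROM, MolecularGeometry

__all__ = [
    "PermutationGroups",
    "REDescriptor",
    "SortedREDescriptor",
    "CMDescriptor",
    "IDDescriptor",
    "pair_indices",
    "sort_homonuclear_re",
    "apply_permutation",
]


class SingularGeometryError(ValueError):
    """Two atoms coincide: inverse-distance descriptors are undefined."""


class UnsupportedDerivativeError(ValueError):
    """The requested descriptor variant has no analytic Jacobian."""


def pair_indices(n_atoms: int) -> list[tuple[int, int]]:
    """Canonical pair order for RE/ID descriptors: lexicographic (a, b), a < b."""
    return [(a, b) for a in range(n_atoms) for b in range(a + 1, n_atoms)]


def _pair_distances(geom: MolecularGeometry) -> np.ndarray:
    coords = geom.coordinates
    pairs = pair_indices(geom.n_atoms)
    diffs = np.array([coords[a] - coords[b] for a, b in pairs])
    r = np.linalg.norm(diffs, axis=1)
    if np.any(r == 0.0):
        raise SingularGeometryError("coincident atoms: zero internuclear distance")
    return r


@dataclass(frozen=True)
class PermutationGroups:
    """Disjoint groups of same-element atom indices whose permutations leave physics unchanged."""

    groups: tuple[tuple[int, ...], ...]

    def __init__(self, groups: Sequence[Sequence[int]]):
        object.__setattr__(self, "groups", tuple(tuple(int(i) for i in g) for g in groups))
        seen: set[int] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValueError("each permutation group needs at least 2 atoms")
            if seen & set(g):
                raise ValueError("permutation groups must be disjoint")
            seen |= set(g)

    def validate_elements(self, geom: MolecularGeometry) -> None:
        for g in self.groups:
            symbols = {geom.elements[i] for i in g}
            if len(symbols) > 1:
                raise ValueError(f"group {g} mixes elements {sorted(symbols)}")

    @property
    def n_perm(self) -> int:
        return math.prod(math.factorial(len(g)) for g in self.groups)

    def permutations(self, n_atoms: int) -> list[np.ndarray]:
        """All atom permutations: identity outside the groups, every arrangement inside.

        Groups are processed left to right, arrangements in lexicographic
        order; the first entry is always the identity.
        """
        if self.n_perm > math.factorial(10):
            raise ValueError("permutation group too large (N_perm > 10!)")
        per_group = [list(itertools.permutations(g)) for g in self.groups]
        perms = []
        for combo in itertools.product(*per_group):
            p = np.arange(n_atoms)
            for g, arrangement in zip(self.groups, combo):
                p[list(g)] = list(arrangement)
            perms.append(p)
        return perms


class _PairwiseDescriptor(BaseEstimator, TransformerMixin):
    """Shared machinery for inverse-distance descriptors (RE and ID)."""

    def _ref_distances(self, geom: MolecularGeometry) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[MolecularGeometry]) -> np.ndarray:
        return np.array([self.describe(g) for g in X])

    def describe(self, geom: MolecularGeometry) -> np.ndarray:
        return self._ref_distances(geom) / _pair_distances(geom)

    def jacobian(self, geom: MolecularGeometry) -> np.ndarray:
        """Analytic dx/dM, shape (n_pairs, n_atoms * 3), units 1/Angstrom x descriptor units.

        Row d for pair (a, b):  dx_d/dM_at = x_d (M_bt - M_at) / r_ab^2 and the
        opposite sign for atom b; all other columns vanish.
        """
        coords = geom.coordinates
        pairs = pair_indices(geom.n_atoms)
        r = _pair_distances(geom)
        x = self._ref_distances(geom) / r
        jac = np.zeros((len(pairs), geom.n_atoms * 3))
        for d, (a, b) in enumerate(pairs):
            g = x[d] * (coords[b] - coords[a]) / r[d] ** 2
            jac[d, 3 * a : 3 * a + 3] = g
            jac[d, 3 * b : 3 * b + 3] = -g
        return jac


class REDescriptor(_PairwiseDescriptor):
    """Relative-to-equilibrium inverse distances against a fixed reference geometry."""

    def __init__(self, reference: MolecularGeometry):
        self.reference = reference

    def _ref_distances(self, geom: MolecularGeometry) -> np.ndarray:
        if geom.elements != self.reference.elements:
            raise ValueError("geometry and reference have different element sequences")
        return _pair_distances(self.reference)


class SortedREDescriptor(REDescriptor):
    """RE descriptor on homonuclear-repulsion-sorted atom order.

    Query and reference are sorted consistently (the sort order is derived
    from the query geometry and applied to both).  Sorting makes the
    descriptor permutationally invariant at the price of discontinuities, so
    no analytic Jacobian is offered.
    """

    def describe(self, geom: MolecularGeometry) -> np.ndarray:
        if geom.elements != self.reference.elements:
            raise ValueError("geometry and reference have different element sequences")
        sorted_geom, sorted_ref = sort_homonuclear_re(geom, self.reference)
        return _pair_distances(sorted_ref) / _pair_distances(sorted_geom)

    def jacobian(self, geom: MolecularGeometry) -> np.ndarray:
        raise UnsupportedDerivativeError(
            "sorted RE descriptor is discontinuous; no analytic Jacobian"
        )


class IDDescriptor(_PairwiseDescriptor):
    """Unnormalized inverse internuclear distances, 1/Angstrom."""

    def _ref_distances(self, geom: MolecularGeometry) -> np.ndarray:
        return np.ones(geom.n_atoms * (geom.n_atoms - 1) // 2)


class CMDescriptor(BaseEstimator, TransformerMixin):
    """Coulomb matrix, vectorized row-major, zero-padded to ``max_atoms``.

    Diagonal ``0.5 Z^2.4``; off-diagonal ``Z_a Z_b / r_ab`` with distances in
    Bohr.  ``variant="sorted"`` reorders atoms by descending row norm before
    vectorization (permutationally invariant but non-differentiable); the
    analytic Jacobian is available for the unsorted variant only.
    """

    def __init__(self, max_atoms: int, variant: str = "unsorted"):
        self.max_atoms = max_atoms
        self.variant = variant

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[MolecularGeometry]) -> np.ndarray:
        return np.array([self.describe(g) for g in X])

    def _matrix(self, geom: MolecularGeometry) -> np.ndarray:
        n = geom.n_atoms
        if n > self.max_atoms:
            raise ValueError(f"geometry has {n} atoms > max_atoms={self.max_atoms}")
        z = geom.charges
        coords_bohr = geom.coordinates / BOHR_IN_ANGSTROM
        cm = np.zeros((n, n))
        for a in range(n):
            cm[a, a] = 0.5 * z[a] ** 2.4
            for b in range(a + 1, n):
                r = np.linalg.norm(coords_bohr[a] - coords_bohr[b])
                if r == 0.0:
                    raise SingularGeometryError("coincident atoms in Coulomb matrix")
                cm[a, b] = cm[b, a] = z[a] * z[b] / r
        return cm

    def describe(self, geom: MolecularGeometry) -> np.ndarray:
        cm = self._matrix(geom)
        if self.variant == "sorted":
            # descending row norm; ties broken by original atom index (stable)
            norms = np.linalg.norm(cm, axis=1)
            order = np.argsort(-norms, kind="stable")
            cm = cm[np.ix_(order, order)]
        elif self.variant != "unsorted":
            raise ValueError(f"unknown CM variant {self.variant!r}")
        padded = np.zeros((self.max_atoms, self.max_atoms))
        padded[: cm.shape[0], : cm.shape[0]] = cm
        return padded.ravel()

    def jacobian(self, geom: MolecularGeometry) -> np.ndarray:
        """Analytic dx/dM (per Angstrom) of the unsorted vectorized Coulomb matrix.

        For vector element (a, b), a != b:
        dx/dM_at = -Z_a Z_b a0 (M_at - M_bt) / r_ab^3 with r_ab in Angstrom and
        a0 the Bohr radius in Angstrom (the Bohr conversion folded in).
        Diagonal elements do not depend on the coordinates.
        """
        if self.variant != "unsorted":
            raise UnsupportedDerivativeError("sorted CM has no analytic Jacobian")
        n = geom.n_atoms
        z = geom.charges
        coords = geom.coordinates
        jac = np.zeros((self.max_atoms * self.max_atoms, n * 3))
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                diff = coords[a] - coords[b]
                r = np.linalg.norm(diff)
                if r == 0.0:
                    raise SingularGeometryError("coincident atoms in Coulomb matrix")
                g = -z[a] * z[b] * BOHR_IN_ANGSTROM * diff / r**3
                row = a * self.max_atoms + b
                jac[row, 3 * a : 3 * a + 3] = g
                jac[row, 3 * b : 3 * b + 3] = -g
        return jac


def sort_homonuclear_re(
    geom: MolecularGeometry, ref: MolecularGeometry | None = None
) -> tuple[MolecularGeometry, MolecularGeometry | None]:
    """Reorder same-element atoms by descending total nuclear repulsion to other atoms.

    Within each maximal set of same-element atoms, atoms are sorted by
    descending ``sum_{b != a} Z_a Z_b / r_ab`` (ties broken by original atom
    index).  Heteronuclear ordering is untouched.  The same reordering is
    applied to the reference geometry when one is given, so that reference
    pair distances stay matched to the sorted query.
    """
    z = geom.charges
    coords = geom.coordinates
    n = geom.n_atoms
    repulsion = np.zeros(n)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            r = np.linalg.norm(coords[a] - coords[b])
            if r == 0.0:
                raise SingularGeometryError("coincident atoms")
            repulsion[a] += z[a] * z[b] / r
    order = np.arange(n)
    for sym in dict.fromkeys(geom.elements):  # preserves first-appearance order
        members = [i for i in range(n) if geom.elements[i] == sym]
        ranked = sorted(members, key=lambda i: (-repulsion[i], i))
        order[members] = ranked
    sorted_geom = MolecularGeometry(
        tuple(geom.elements[i] for i in order), coords[order], geom.comment
    )
    sorted_ref = None
    if ref is not None:
        sorted_ref = MolecularGeometry(
            tuple(ref.elements[i] for i in order), ref.coordinates[order], ref.comment
        )
    return sorted_geom, sorted_ref


def apply_permutation(geom: MolecularGeometry, perm: Sequence[int]) -> MolecularGeometry:
    """Reorder atom rows: row i of the result is atom perm[i] of the input."""
    return geom.permuted(perm)
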