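"""Deterministic synthetic molecular datasets with exact analytic gradients.

Three generators cover the scenarios the rest of the library is exercised
on, without any external data:

* a Morse-potential diatomic (smooth anharmonic 1-D PES),
* a harmonic polyatomic built from pair springs,
* a permutation-symmetric XH3 system whose energy is built from symmetric
  functions of the three X-H distances (and the H-H distances), so it is
  exactly invariant under the 3! hydrogen permutations.

Every generated gradient is the exact analytic derivative of the generated
energy; optional Gaussian noise is applied to energies (labels) only, never
to geometries, so descriptor-level tests stay exact.  All randomness flows
through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MolecularDataset, MolecularGeometry
from .nea import SpectrumEnsemble

__all__ = [
    "MorseSpec",
    "morse_reference_geometry",
    "generate_morse_dataset",
    "xh3_reference_geometry",
    "generate_xh3_dataset",
    "generate_harmonic_dataset",
    "generate_labeled_ensemble",
]


# ---------------------------------------------------------------------------
# Morse diatomic

@dataclass(frozen=True)
class MorseSpec:
    """Morse potential V(r) = D (1 - exp(-a (r - r_eq)))^2 - D.

    Defaults are H2-like: well depth 4.75 eV, r_eq 0.741 Angstrom, a chosen
    to give a realistic curvature.  Energies come out in the well-depth unit
    (eV here); gradients in eV/Angstrom.
    """

    well_depth: float = 4.75
    r_eq: float = 0.741
    a: float = 1.95
    elements: tuple[str, str] = ("H", "H")
    r_min: float = 0.5
    r_max: float = 2.2
    noise_sigma: float = 0.0

    def energy(self, r: np.ndarray) -> np.ndarray:
        u = 1.0 - np.exp(-self.a * (np.asarray(r, dtype=float) - self.r_eq))
        return self.well_depth * u**2 - self.well_depth

    def denergy_dr(self, r: np.ndarray) -> np.ndarray:
        e = np.exp(-self.a * (np.asarray(r, dtype=float) - self.r_eq))
        return 2.0 * self.well_depth * (1.0 - e) * self.a * e


def morse_reference_geometry(spec: MorseSpec = MorseSpec()) -> MolecularGeometry:
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, spec.r_eq]])
    return MolecularGeometry(spec.elements, coords, comment="morse equilibrium")


def generate_morse_dataset(
    n_points: int, spec: MorseSpec = MorseSpec(), seed: int = 0
) -> MolecularDataset:
    """Diatomic geometries with r uniform in [r_min, r_max], Morse energies and
    exact gradients (optionally noisy energies)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not 0 < spec.r_min < spec.r_max:
        raise ValueError("need 0 < r_min < r_max")
    rng = np.random.default_rng(seed)
    r = rng.uniform(spec.r_min, spec.r_max, size=n_points)
    geometries = [
        MolecularGeometry(spec.elements, np.array([[0.0, 0.0, 0.0], [0.0, 0.0, ri]]))
        for ri in r
    ]
    energies = spec.energy(r)
    dE = spec.denergy_dr(r)
    gradients = [
        np.array([[0.0, 0.0, -d], [0.0, 0.0, d]]) for d in dE
    ]
    if spec.noise_sigma > 0:
        energies = energies + rng.normal(0.0, spec.noise_sigma, size=n_points)
    return MolecularDataset(
        geometries=geometries,
        values=energies,
        gradients=gradients,
        metadata={"generator": "morse_diatomic", "seed": seed},
    )


# ---------------------------------------------------------------------------
# Harmonic polyatomic (pair springs)

def generate_harmonic_dataset(
    n_points: int,
    reference: MolecularGeometry,
    force_constant: float = 20.0,
    displacement: float = 0.1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MolecularDataset:
    """Polyatomic PES from pair springs: E = 1/2 k sum_{a<b} (r_ab - r_ab^eq)^2.

    Geometries are the reference plus seeded Gaussian displacements of width
    ``displacement`` (Angstrom); gradients are exact.
    """
    rng = np.random.default_rng(seed)
    n_at = reference.n_atoms
    ref_coords = reference.coordinates
    pairs = [(a, b) for a in range(n_at) for b in range(a + 1, n_at)]
    r_eq = {p: np.linalg.norm(ref_coords[p[0]] - ref_coords[p[1]]) for p in pairs}
    geometries, energies, gradients = [], [], []
    for _ in range(n_points):
        coords = ref_coords + rng.normal(0.0, displacement, size=(n_at, 3))
        e = 0.0
        grad = np.zeros((n_at, 3))
        for a, b in pairs:
            diff = coords[a] - coords[b]
            r = np.linalg.norm(diff)
            stretch = r - r_eq[(a, b)]
            e += 0.5 * force_constant * stretch**2
            g = force_constant * stretch * diff / r
            grad[a] += g
            grad[b] -= g
        geometries.append(MolecularGeometry(reference.elements, coords))
        energies.append(e)
        gradients.append(grad)
    energies = np.array(energies)
    if noise_sigma > 0:
        energies = energies + rng.normal(0.0, noise_sigma, size=n_points)
    return MolecularDataset(
        geometries=geometries,
        values=energies,
        gradients=gradients,
        metadata={"generator": "harmonic_polyatomic", "seed": seed},
    )


# ---------------------------------------------------------------------------
# Permutation-symmetric XH3

def xh3_reference_geometry() -> MolecularGeometry:
    """CH3-like fragment with three equivalent hydrogens.

    The hydrogens sit at (d,0,0), (0,d,0), (0,0,d) and the heavy atom on the
    threefold axis at (t,t,t): permuting the hydrogens permutes coordinate
    axes, so all X-H and all H-H reference distances are *bitwise* equal.
    Exact permutational invariance of the permuted-RE kernel requires
    a reference that is exactly symmetric under the declared groups.
    """
    d, t = 1.2, 0.35
    coords = np.array(
        [[t, t, t], [d, 0.0, 0.0], [0.0, d, 0.0], [0.0, 0.0, d]]
    )
    return MolecularGeometry(("C", "H", "H", "H"), coords, comment="XH3 equilibrium")


def _morse_pair(r: np.ndarray, d: float, a: float, r_eq: float):
    e = np.exp(-a * (r - r_eq))
    v = d * (1.0 - e) ** 2 - d
    dv = 2.0 * d * (1.0 - e) * a * e
    return v, dv


def generate_xh3_dataset(
    n_points: int,
    displacement: float = 0.12,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MolecularDataset:
    """Permutation-symmetric XH3 PES with exact gradients.

    The energy sums a Morse term over the three X-H distances and a softer
    Morse term over the three H-H distances; both sums are symmetric
    functions of same-element pair distances, so the energy is exactly
    invariant under the 3! hydrogen permutations by construction.
    """
    ref = xh3_reference_geometry()
    rng = np.random.default_rng(seed)
    ref_coords = ref.coordinates
    r_xh_eq = float(np.linalg.norm(ref_coords[1] - ref_coords[0]))
    r_hh_eq = float(np.linalg.norm(ref_coords[1] - ref_coords[2]))
    xh_params = (4.5, 1.9, r_xh_eq)
    hh_params = (0.8, 1.2, r_hh_eq)
    geometries, energies, gradients = [], [], []
    for _ in range(n_points):
        coords = ref_coords + rng.normal(0.0, displacement, size=(4, 3))
        e = 0.0
        grad = np.zeros((4, 3))
        for (a, b), params in [
            ((0, 1), xh_params), ((0, 2), xh_params), ((0, 3), xh_params),
            ((1, 2), hh_params), ((1, 3), hh_params), ((2, 3), hh_params),
        ]:
            diff = coords[a] - coords[b]
            r = np.linalg.norm(diff)
            v, dv = _morse_pair(r, *params)
            e += v
            g = dv * diff / r
            grad[a] += g
            grad[b] -= g
        geometries.append(MolecularGeometry(ref.elements, coords))
        energies.append(e)
        gradients.append(grad)
    energies = np.array(energies)
    if noise_sigma > 0:
        energies = energies + rng.normal(0.0, noise_sigma, size=n_points)
    return MolecularDataset(
        geometries=geometries,
        values=energies,
        gradients=gradients,
        metadata={"generator": "perm_symmetric_xh3", "seed": seed},
    )


# ---------------------------------------------------------------------------
# Labeled nuclear ensembles

def generate_labeled_ensemble(
    n_points: int,
    n_states: int = 1,
    displacement: float = 0.05,
    label_noise: float = 0.0,
    negative_f_fraction: float = 0.02,
    seed: int = 0,
) -> SpectrumEnsemble:
    """Nuclear ensemble with smooth excitation-energy / oscillator-strength labels.

    Geometries are a water-like equilibrium plus seeded Gaussian
    displacements (a stand-in for a Wigner distribution).  For state n,
    dE_0n is an affine function of the O-H bond stretches around a base
    energy of (4 + n) eV and f_0n a smooth positive function of geometry,
    shifted down so roughly ``negative_f_fraction`` of the values come out
    negative — exercising the clipping rule downstream.  All points are
    labeled.
    """
    ref = MolecularGeometry(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399872, 0.9266272, 0.0]]),
        comment="water equilibrium",
    )
    rng = np.random.default_rng(seed)
    coords = ref.coordinates[None] + rng.normal(0.0, displacement, size=(n_points, 3, 3))
    geometries = [MolecularGeometry(ref.elements, c) for c in coords]
    r1 = np.linalg.norm(coords[:, 1] - coords[:, 0], axis=1)
    r2 = np.linalg.norm(coords[:, 2] - coords[:, 0], axis=1)
    r1_eq = np.linalg.norm(ref.coordinates[1] - ref.coordinates[0])
    r2_eq = np.linalg.norm(ref.coordinates[2] - ref.coordinates[0])
    s1, s2 = r1 - r1_eq, r2 - r2_eq
    delta_e = np.empty((n_points, n_states))
    f = np.empty((n_points, n_states))
    for n in range(n_states):
        delta_e[:, n] = (4.0 + n) - 1.5 * (s1 + s2) + 0.8 * (s1**2 + s2**2)
        raw_f = 0.05 + 0.01 * n + 0.12 * (s1 + s2)
        if negative_f_fraction > 0:
            # shift so the stated fraction of strengths lands below zero
            raw_f = raw_f - np.quantile(raw_f, negative_f_fraction)
        f[:, n] = raw_f
    if label_noise > 0:
        delta_e += rng.normal(0.0, label_noise, size=delta_e.shape)
        f += rng.normal(0.0, label_noise, size=f.shape)
    delta_e = np.maximum(delta_e, 0.1)  # labeled excitation energies stay positive
    return SpectrumEnsemble(
        geometries=geometries,
        n_states=n_states,
        labeled_indices=np.arange(n_points),
        delta_e=delta_e,
        f=f,
    )
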