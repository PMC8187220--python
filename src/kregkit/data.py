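"""Molecular geometries, datasets, and plain-text file formats.

Coordinates are stored in Angstrom throughout the package; the Coulomb-matrix
descriptor converts to Bohr internally.  Reference values (energies,
excitation energies, ...) are unit-agnostic: the library never converts
them, and gradients are expected in value-units per Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ELEMENTS",
    "MolecularGeometry",
    "MolecularDataset",
    "SplitIndices",
    "read_xyz",
    "write_xyz",
    "read_values",
    "write_values",
    "read_xyz_gradients",
    "write_xyz_gradients",
    "read_split_indices",
    "write_split_indices",
]

# Symbol -> nuclear charge Z for the first 86 elements.
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn"
).split()
ELEMENTS: Mapping[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}

#: 1 Angstrom in Bohr (CODATA 2014 value of the Bohr radius in Angstrom).
BOHR_IN_ANGSTROM = 0.52917721067


class XYZParseError(ValueError):
    """Raised when an XYZ-format file cannot be parsed."""


@dataclass(frozen=True)
class MolecularGeometry:
    """A single molecular structure: element symbols plus Cartesian coordinates (Angstrom)."""

    elements: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n_atoms, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("element count does not match coordinate rows")
        if coords.shape[0] < 1:
            raise ValueError("a geometry needs at least one atom")
        for sym in self.elements:
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol {sym!r}")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def charges(self) -> np.ndarray:
        """Per-atom nuclear charges Z (a.u.), derived from the symbols."""
        return np.array([ELEMENTS[s] for s in self.elements], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "MolecularGeometry":
        return MolecularGeometry(self.elements, coords, self.comment)

    def permuted(self, perm: Sequence[int]) -> "MolecularGeometry":
        """Return the geometry with atom rows reordered: row i of the result is atom perm[i]."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_atoms)):
            raise ValueError("perm must be a permutation of all atom indices")
        new_elements = tuple(self.elements[p] for p in perm)
        # element sequence must be preserved: each target slot keeps its element
        if new_elements != self.elements:
            raise ValueError("permutation maps atoms across different elements")
        return MolecularGeometry(new_elements, self.coordinates[perm], self.comment)


@dataclass
class MolecularDataset:
    """Geometries with optional per-geometry values y and Cartesian gradients dy/dM."""

    geometries: list[MolecularGeometry]
    values: np.ndarray | None = None
    gradients: list[np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != len(self.geometries):
                raise ValueError("values length does not match geometry count")
        if self.gradients is not None:
            if len(self.gradients) != len(self.geometries):
                raise ValueError("gradients length does not match geometry count")
            self.gradients = [np.asarray(g, dtype=float) for g in self.gradients]

    def __len__(self) -> int:
        return len(self.geometries)

    def subset(self, indices: Iterable[int]) -> "MolecularDataset":
        """Slice the dataset, preserving per-index association of geometry/value/gradient."""
        idx = list(indices)
        return MolecularDataset(
            geometries=[self.geometries[i] for i in idx],
            values=None if self.values is None else self.values[idx],
            gradients=None if self.gradients is None else [self.gradients[i] for i in idx],
            metadata=dict(self.metadata),
        )


@dataclass
class SplitIndices:
    """Named, disjoint groups of 0-based dataset indices (training/test/sub-training/...)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        seen: set[int] = set()
        for name, idx in self.groups.items():
            s = set(idx.tolist())
            if len(s) != len(idx):
                raise ValueError(f"group {name!r} contains duplicate indices")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.groups[name]

    def validate_disjoint(self, names: Sequence[str] | None = None) -> None:
        names = list(names or self.groups)
        seen: set[int] = set()
        for name in names:
            s = set(self.groups[name].tolist())
            if seen & s:
                raise ValueError(f"group {name!r} overlaps a previous group")
            seen |= s


# ---------------------------------------------------------------------------
# XYZ geometries

def _parse_xyz_records(lines: list[str], path: str, parse_elements: bool):
    """Shared record walker for geometry and gradient XYZ files."""
    records = []
    i = 0
    nrec = 0
    # trailing blank lines are ignored
    while i < len(lines) and all(not ln.strip() for ln in lines[i:]):
        break
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nrec += 1
        try:
            n_at = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: record {nrec}: malformed atom-count line {lines[i].strip()!r}"
            ) from None
        if i + 1 >= len(lines):
            raise XYZParseError(f"{path}: record {nrec}: missing comment line")
        comment = lines[i + 1].rstrip("\n")
        body = lines[i + 2 : i + 2 + n_at]
        if len(body) < n_at:
            raise XYZParseError(
                f"{path}: record {nrec}: declares {n_at} atoms but only {len(body)} lines follow"
            )
        elements: list[str] = []
        rows = np.empty((n_at, 3), dtype=float)
        for j, line in enumerate(body):
            tokens = line.split()
            if parse_elements:
                if len(tokens) < 4:
                    raise XYZParseError(f"{path}: record {nrec}, atom {j + 1}: expected 'El x y z'")
                elements.append(tokens[0].capitalize())
                vals = tokens[1:4]
            else:
                if len(tokens) not in (3, 4):
                    raise XYZParseError(
                        f"{path}: record {nrec}, atom {j + 1}: expected 3 numbers "
                        "(optionally preceded by an element symbol)"
                    )
                vals = tokens[-3:]
            try:
                rows[j] = [float(v) for v in vals]
            except ValueError:
                raise XYZParseError(
                    f"{path}: record {nrec}, atom {j + 1}: non-numeric coordinate"
                ) from None
        records.append((elements, rows, comment))
        i += 2 + n_at
    return records


def read_xyz(path: str | Path) -> MolecularDataset:
    """Read a multi-record XYZ file into a dataset (symbols capitalized, order preserved)."""
    lines = Path(path).read_text().splitlines()
    records = _parse_xyz_records(lines, str(path), parse_elements=True)
    geometries = [MolecularGeometry(tuple(el), rows, comment) for el, rows, comment in records]
    return MolecularDataset(geometries=geometries)


def write_xyz(path: str | Path, dataset: MolecularDataset | Sequence[MolecularGeometry]) -> None:
    geometries = dataset.geometries if isinstance(dataset, MolecularDataset) else dataset
    with open(path, "w") as fh:
        for geom in geometries:
            fh.write(f"{geom.n_atoms}\n{geom.comment}\n")
            for sym, (x, y, z) in zip(geom.elements, geom.coordinates):
                fh.write(f"{sym} {x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# One-column value files

def read_values(path: str | Path) -> np.ndarray:
    """Read a one-number-per-line file; order preserved."""
    out: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            out.append(float(line.strip()))
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric value {line.strip()!r}") from None
    return np.array(out, dtype=float)


def write_values(path: str | Path, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(values, dtype=float):
            fh.write(f"{v:.17g}\n")


# ---------------------------------------------------------------------------
# XYZ-shaped gradient blocks

def read_xyz_gradients(path: str | Path) -> list[np.ndarray]:
    """Read gradient blocks in XYZ record structure (element column optional)."""
    lines = Path(path).read_text().splitlines()
    records = _parse_xyz_records(lines, str(path), parse_elements=False)
    return [rows for _el, rows, _c in records]


def write_xyz_gradients(path: str | Path, gradients: Sequence[np.ndarray]) -> None:
    with open(path, "w") as fh:
        for grad in gradients:
            grad = np.asarray(grad, dtype=float)
            fh.write(f"{grad.shape[0]}\n\n")
            for x, y, z in grad:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# Split-index files (1-based on disk, 0-based in memory)

def read_split_indices(path: str | Path) -> np.ndarray:
    """Read a one-index-per-line file; file indices are 1-based, returned 0-based."""
    idx = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            v = int(line.strip())
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-integer index") from None
        if v < 1:
            raise ValueError(f"{path}: line {lineno}: indices on disk are 1-based, got {v}")
        idx.append(v - 1)
    return np.array(idx, dtype=int)


def write_split_indices(path: str | Path, indices: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i in np.asarray(indices, dtype=int):
            fh.write(f"{i + 1}\n")
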