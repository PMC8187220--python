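import numpy as np
import pytest

from kregkit.data import MolecularGeometry
from kregkit.synthetic import (
    MorseSpec,
    generate_morse_dataset,
    generate_xh3_dataset,
    morse_reference_geometry,
    xh3_reference_geometry,
)


@pytest.fixture(scope="session")
def morse_spec():
    return MorseSpec()


@pytest.fixture(scope="session")
def morse_train(morse_spec):
    return generate_morse_dataset(50, morse_spec, seed=1)


@pytest.fixture(scope="session")
def morse_test(morse_spec):
    return generate_morse_dataset(200, morse_spec, seed=2)


@pytest.fixture(scope="session")
def morse_ref(morse_spec):
    return morse_reference_geometry(morse_spec)


@pytest.fixture(scope="session")
def xh3_train():
    return generate_xh3_dataset(30, seed=3)


@pytest.fixture(scope="session")
def xh3_ref():
    return xh3_reference_geometry()


@pytest.fixture
def water():
    return MolecularGeometry(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.24, 0.927, 0.0]]),
    )


def random_geometry(rng, elements=("C", "H", "H", "O"), scale=1.5, min_sep=0.5):
    """Well-separated random geometry for derivative tests."""
    n = len(elements)
    while True:
        coords = rng.uniform(-scale, scale, size=(n, 3))
        ok = True
        for a in range(n):
            for b in range(a + 1, n):
                if np.linalg.norm(coords[a] - coords[b]) < min_sep:
                    ok = False
        if ok:
            return MolecularGeometry(elements, coords)


def fd_jacobian(func, geom, h=1e-5):
    """Central finite differences of a vector-valued function of a geometry."""
    x0 = np.asarray(func(geom), dtype=float)
    n = geom.n_atoms
    out = np.zeros((x0.size, n * 3))
    for a in range(n):
        for t in range(3):
            cp = geom.coordinates.copy()
            cp[a, t] += h
            cm = geom.coordinates.copy()
            cm[a, t] -= h
            out[:, 3 * a + t] = (
                np.asarray(func(geom.with_coordinates(cp))) - np.asarray(func(geom.with_coordinates(cm)))
            ) / (2 * h)
    return out
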