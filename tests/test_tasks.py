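import warnings

import numpy as np
import pandas as pd
import pytest

from kregkit.descriptors import REDescriptor
from kregkit.krr import KernelRidgeRegressor
from kregkit.synthetic import MorseSpec, generate_morse_dataset, morse_reference_geometry
from kregkit.tasks import (
    DeltaRegressor,
    SelfCorrectingRegressor,
    fit_power_law,
    learning_curve,
)


def morse_estimator(ref, sigma=0.5, lam=2.0**-35):
    return KernelRidgeRegressor(descriptor=REDescriptor(ref), sigma=sigma, lam=lam)


@pytest.fixture(scope="module")
def delta_fixture(morse_spec, morse_ref):
    """Baseline and target share a rugged high-frequency component (the hard
    part of both surfaces); the target adds only a smooth slowly-varying
    correction.  The delta model has to learn only the smooth difference,
    while a direct model must capture the rugged part from scratch."""
    data = generate_morse_dataset(300, morse_spec, seed=60)
    r = np.array([np.linalg.norm(g.coordinates[1] - g.coordinates[0]) for g in data.geometries])
    baseline = data.values + 0.5 * np.sin(12.0 * r)
    target = baseline + 0.3 * np.sin(2.0 * r)
    return data.geometries, baseline, target


class TestDeltaLearning:
    def test_identical_baseline_gives_baseline_back(self, delta_fixture, morse_ref):
        geoms, baseline, _ = delta_fixture
        m = DeltaRegressor(estimator=morse_estimator(morse_ref))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(geoms[:50], baseline[:50], baseline=baseline[:50])
        pred = m.predict(geoms[:50], baseline=baseline[:50])
        assert np.max(np.abs(pred - baseline[:50])) <= 1e-8

    def test_composition_is_exact(self, delta_fixture, morse_ref):
        geoms, baseline, target = delta_fixture
        m = DeltaRegressor(estimator=morse_estimator(morse_ref))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(geoms[:50], target[:50], baseline=baseline[:50])
        q = geoms[50:80]
        qb = baseline[50:80]
        pred = m.predict(q, baseline=qb)
        manual = qb + m.correction_.predict(q)
        np.testing.assert_array_equal(pred, manual)  # bitwise composition

    def test_beats_direct_model(self, delta_fixture, morse_ref):
        geoms, baseline, target = delta_fixture
        tr = slice(0, 50)
        te = slice(50, 300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dm = DeltaRegressor(estimator=morse_estimator(morse_ref))
            dm.fit(geoms[tr], target[tr], baseline=baseline[tr])
            direct = morse_estimator(morse_ref)
            direct.fit(geoms[tr], target[tr])
        rmse_delta = np.sqrt(np.mean((dm.predict(geoms[te], baseline=baseline[te]) - target[te]) ** 2))
        rmse_direct = np.sqrt(np.mean((direct.predict(geoms[te]) - target[te]) ** 2))
        assert rmse_delta * 2.0 <= rmse_direct

    def test_empty_query(self, delta_fixture, morse_ref):
        geoms, baseline, target = delta_fixture
        m = DeltaRegressor(estimator=morse_estimator(morse_ref))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(geoms[:20], target[:20], baseline=baseline[:20])
        assert m.predict([], baseline=[]).size == 0

    def test_missing_baseline_raises(self, delta_fixture, morse_ref):
        geoms, baseline, target = delta_fixture
        m = DeltaRegressor(estimator=morse_estimator(morse_ref))
        with pytest.raises(ValueError, match="baseline"):
            m.fit(geoms[:10], target[:10])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(geoms[:10], target[:10], baseline=baseline[:10])
        with pytest.raises(ValueError, match="baseline"):
            m.predict(geoms[:5])


class TestSelfCorrection:
    def test_one_layer_equals_plain_krr(self, morse_spec, morse_ref):
        data = generate_morse_dataset(30, morse_spec, seed=61)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sc = SelfCorrectingRegressor(estimator=morse_estimator(morse_ref), n_layers=1)
            sc.fit(data.geometries, data.values)
            plain = morse_estimator(morse_ref)
            plain.fit(data.geometries, data.values)
        q = generate_morse_dataset(10, morse_spec, seed=62).geometries
        np.testing.assert_array_equal(sc.predict(q), plain.predict(q))

    def test_layer_two_targets_near_zero_for_interpolating_layers(self, morse_spec, morse_ref):
        data = generate_morse_dataset(30, morse_spec, seed=63)
        sc = SelfCorrectingRegressor(
            estimator=morse_estimator(morse_ref, sigma=0.05, lam=1e-16), n_layers=2
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sc.fit(data.geometries, data.values)
        scale = np.max(np.abs(data.values))
        assert np.max(np.abs(sc.layer_targets_[1])) / scale <= 1e-8

    def test_training_rmse_nonincreasing_over_layers(self, morse_spec, morse_ref):
        noisy = MorseSpec(noise_sigma=0.05)
        data = generate_morse_dataset(60, noisy, seed=64)
        rmses = []
        for n_layers in (1, 2, 3, 4):
            sc = SelfCorrectingRegressor(
                estimator=morse_estimator(morse_ref, sigma=0.8, lam=1e-4), n_layers=n_layers
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sc.fit(data.geometries, data.values)
            pred = sc.predict(data.geometries)
            rmses.append(float(np.sqrt(np.mean((pred - data.values) ** 2))))
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_telescoping_residual(self, morse_spec, morse_ref):
        data = generate_morse_dataset(25, morse_spec, seed=65)
        sc = SelfCorrectingRegressor(estimator=morse_estimator(morse_ref, lam=1e-6), n_layers=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sc.fit(data.geometries, data.values)
        total = sc.predict(data.geometries)
        np.testing.assert_allclose(total + sc.final_residual_, data.values, atol=1e-9)


class TestPowerLaw:
    def test_noiseless_recovery(self):
        n = np.array([100, 200, 400, 800, 1600], dtype=float)
        e = 0.1 + 10.0 / n**0.5
        fit = fit_power_law(n, e)
        assert fit.eps_a == pytest.approx(0.1, abs=1e-6)
        assert fit.a == pytest.approx(10.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)

    def test_noisy_recovery_degrades_gracefully(self):
        # multiplicative curve noise propagates into the parameters through
        # the near-collinear (a, b) direction, amplified roughly tenfold;
        # recovery tightens proportionally as the noise shrinks
        n = np.array([50, 100, 200, 400, 800, 1600, 3200], dtype=float)
        true = np.array([0.05, 4.0, 0.6])
        for noise, tol in [(0.05, 0.30), (0.005, 0.05)]:
            rng = np.random.default_rng(0)
            curves = [
                (true[0] + true[1] / n ** true[2]) * (1 + rng.normal(0, noise, size=n.size))
                for _ in range(10)
            ]
            fit = fit_power_law(n, np.mean(curves, axis=0))
            got = np.array([fit.eps_a, fit.a, fit.b])
            assert np.max(np.abs((got - true) / true)) <= tol

    def test_constant_errors_flagged(self):
        fit = fit_power_law([10, 20, 40], [0.3, 0.3, 0.3])
        assert fit.eps_a == pytest.approx(0.3)
        assert fit.a == 0.0
        assert "unidentifiable" in fit.note

    def test_loglog_slope_identity_for_zero_asymptote(self):
        n = np.array([10, 30, 100, 300, 1000], dtype=float)
        e = 5.0 / n**0.75
        slope = np.polyfit(np.log(n), np.log(e), 1)[0]
        fit = fit_power_law(n, e)
        assert fit.b == pytest.approx(-slope, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_power_law([10, 10, 10], [1, 1, 1])
        with pytest.raises(ValueError, match="positive"):
            fit_power_law([10, 20, 40], [1.0, -1.0, 0.5])


class TestLearningCurve:
    @pytest.fixture(scope="class")
    def morse_pool(self, morse_spec):
        return generate_morse_dataset(260, morse_spec, seed=67)

    def test_single_cell_table(self, morse_pool, morse_ref):
        res = learning_curve(
            morse_pool.geometries, morse_pool.values,
            lambda: morse_estimator(morse_ref), sizes=[10], repeats=1, seed=0,
        )
        assert len(res.table) == 1
        assert res.table.loc[0, "Ntrain"] == 10

    def test_rmse_decreases_with_size(self, morse_pool, morse_ref):
        res = learning_curve(
            morse_pool.geometries, morse_pool.values,
            lambda: morse_estimator(morse_ref, sigma=0.3, lam=1e-10),
            sizes=[10, 20, 40, 80, 160], repeats=5, test_size=50, seed=1,
        )
        means = res.mean_rmse.to_numpy()
        assert np.all(np.diff(means) < 0)  # strictly decreasing on this fixture

    def test_csv_roundtrip(self, tmp_path, morse_pool, morse_ref):
        path = tmp_path / "lc.csv"
        res = learning_curve(
            morse_pool.geometries, morse_pool.values,
            lambda: morse_estimator(morse_ref), sizes=[10, 20, 40], repeats=2,
            seed=2, csv_path=path,
        )
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back[["Ntrain", "repeat", "RMSE_test"]],
            res.table[["Ntrain", "repeat", "RMSE_test"]],
        )

    def test_deterministic_under_seed(self, morse_pool, morse_ref):
        kw = dict(sizes=[10, 20], repeats=2, seed=3)
        a = learning_curve(morse_pool.geometries, morse_pool.values,
                           lambda: morse_estimator(morse_ref), **kw)
        b = learning_curve(morse_pool.geometries, morse_pool.values,
                           lambda: morse_estimator(morse_ref), **kw)
        pd.testing.assert_frame_equal(
            a.table.drop(columns=["t_train_s", "t_predict_s"]),
            b.table.drop(columns=["t_train_s", "t_predict_s"]),
        )

    def test_infeasible_sizes_skipped_with_warning(self, morse_pool, morse_ref):
        with pytest.warns(UserWarning, match="skipped"):
            res = learning_curve(
                morse_pool.geometries, morse_pool.values,
                lambda: morse_estimator(morse_ref), sizes=[10, 10_000],
                repeats=1, seed=4,
            )
        assert set(res.table["Ntrain"]) == {10}
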