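"""Concentration scaler, network forward/backward, PLSR, and evaluation."""

import numpy as np
import pytest

from sersquant import (
    PYRENE,
    ConcentrationScaler,
    NetworkArchitecture,
    ResponseModel,
    SpectralWindow,
    TrainConfig,
    evaluate,
    fit_plsr,
    forward_pass,
    generate_dataset,
    layer_output_shapes,
    loss_and_grad,
    train_pca_bp,
)
from sersquant.features import window_matrix
from sersquant.models import init_params


class TestConcentrationScaler:
    def test_boundaries_map_to_margin(self):
        s = ConcentrationScaler(0.01, 70.0, margin=0.05)
        assert s.forward(0.01) == pytest.approx(0.05)
        assert s.forward(70.0) == pytest.approx(0.95)

    def test_log_midpoint_maps_to_half(self):
        s = ConcentrationScaler(0.01, 70.0)
        assert s.forward(np.sqrt(0.01 * 70.0)) == pytest.approx(0.5)

    def test_bijection_on_random_concentrations(self):
        s = ConcentrationScaler(0.01, 70.0)
        c = np.random.default_rng(0).uniform(0.01, 70.0, size=100)
        assert np.allclose(s.inverse(s.forward(c)), c, rtol=1e-12)

    def test_nonpositive_concentration_rejected(self):
        s = ConcentrationScaler(0.01, 70.0)
        with pytest.raises(ValueError):
            s.forward(0.0)

    def test_out_of_range_clipped_with_warning(self):
        s = ConcentrationScaler(0.01, 70.0)
        with pytest.warns(RuntimeWarning, match="clipping"):
            assert s.forward(100.0) == pytest.approx(0.95)


class TestNetwork:
    def test_layer_shape_traversal(self):
        shapes = layer_output_shapes(NetworkArchitecture(), 16)
        assert shapes == [(32, 13), (64, 10), (128, 9), (256, 9), 2304, 400, 200, 100, 50, 1]

    def test_zero_weights_output_half(self):
        params = init_params(NetworkArchitecture(), 16, np.random.default_rng(0))
        for layer in params:
            layer["W"][:] = 0.0
            layer["b"][:] = 0.0
        out = forward_pass(params, np.random.default_rng(1).normal(size=(5, 16)))
        assert np.allclose(out, 0.5)
        # mid-range output maps back to the geometric-mean concentration
        s = ConcentrationScaler(0.01, 70.0)
        assert s.inverse(0.5) == pytest.approx(np.sqrt(0.01 * 70.0))

    def test_output_strictly_in_unit_interval(self):
        params = init_params(NetworkArchitecture(), 16, np.random.default_rng(2))
        out = forward_pass(params, np.random.default_rng(3).normal(size=(20, 16)) * 10)
        assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch_names_sizes(self):
        params = init_params(NetworkArchitecture(), 16, np.random.default_rng(0))
        with pytest.raises(ValueError, match="expected 16, got 12"):
            forward_pass(params, np.zeros((3, 12)))

    def test_analytic_gradient_matches_finite_differences(self):
        # central finite differences on randomly sampled parameter coordinates
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 16))
        y = rng.uniform(0.1, 0.9, 9)
        params = init_params(NetworkArchitecture(), 16, rng)
        _, grads = loss_and_grad(params, X, y, l2_lambda=1e-4)
        coord_rng = np.random.default_rng(1)
        for _ in range(30):
            li = coord_rng.integers(len(params))
            key = "W" if coord_rng.random() < 0.8 else "b"
            arr = params[li][key]
            idx = tuple(coord_rng.integers(s) for s in arr.shape)
            h = 1e-6 * max(1.0, abs(arr[idx]))
            orig = arr[idx]
            arr[idx] = orig + h
            lp, _ = loss_and_grad(params, X, y, 1e-4)
            arr[idx] = orig - h
            lm, _ = loss_and_grad(params, X, y, 1e-4)
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            an = grads[li][key][idx]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-10)


@pytest.fixture(scope="module")
def noiseless_dataset(grid):
    resp = ResponseModel(replicate_cv=0.0, noise_sd=0.0, baseline_coeffs=(0.0,))
    return generate_dataset(PYRENE, resp, grid, replicates=6, seed=0)


class TestTraining:
    def test_recovers_noiseless_mapping(self, noiseless_dataset):
        # without noise the peak height determines concentration exactly;
        # with the L2 penalty off (it floors the loss and biases weights
        # away from exact interpolation) the network learns the inverse map
        # essentially perfectly
        cfg = TrainConfig(
            epochs=2500, patience=2500, learning_rate=5e-3, seed=0,
            precision="float64", val_fraction=0.2,
            architecture=NetworkArchitecture(l2_lambda=0.0),
        )
        with pytest.warns(RuntimeWarning):  # rank-limited PCA on 9 levels
            model = train_pca_bp(noiseless_dataset, SpectralWindow(500, 600), cfg)
        report = evaluate(model, noiseless_dataset)
        assert report.r_squared >= 0.999

    def test_reproducible_given_seed(self, default_dataset):
        cfg = TrainConfig(epochs=30, patience=30, seed=5)
        window = SpectralWindow(500, 600)
        m1 = train_pca_bp(default_dataset[:60], window, cfg)
        m2 = train_pca_bp(default_dataset[:60], window, cfg)
        for l1, l2 in zip(m1.params, m2.params):
            assert np.array_equal(l1["W"], l2["W"])
        r1 = evaluate(m1, default_dataset[60:90])
        r2 = evaluate(m2, default_dataset[60:90])
        assert r1.r_squared == r2.r_squared

    def test_huge_l2_collapses_to_mid_range(self, default_dataset):
        cfg = TrainConfig(
            epochs=300, patience=300, seed=0,
            architecture=NetworkArchitecture(l2_lambda=10.0),
        )
        model = train_pca_bp(default_dataset, SpectralWindow(500, 600), cfg)
        scaled = model.predict_scaled(default_dataset)
        assert np.ptp(scaled) < 0.05  # near-constant prediction
        assert abs(float(np.mean(scaled)) - 0.5) < 0.2  # near mid-range

    def test_single_level_rejected(self, grid, clean_response, single_peak_library):
        ds = generate_dataset(
            single_peak_library, clean_response, grid, levels=[5.0], replicates=4, seed=0
        )
        with pytest.raises(ValueError, match="levels"):
            train_pca_bp(ds, SpectralWindow(500, 600), TrainConfig(epochs=5))


class TestPlsr:
    def test_exact_linear_relation_one_component(self, small_grid=None):
        # y (scaled) exactly linear in one spectral direction -> R^2 = 1
        from sersquant import AcquisitionGrid, Spectrum

        grid = AcquisitionGrid(500.0, 600.0, 2.0)
        direction = np.exp(-((grid.wavenumbers() - 550.0) ** 2) / 200.0)
        scaler = ConcentrationScaler(1.0, 100.0, margin=0.05)
        concs = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0])
        spectra = [
            Spectrum(grid, float(scaler.forward(c)) * direction, concentration=float(c))
            for c in concs
        ]
        model = fit_plsr(spectra, SpectralWindow(500, 600), n_components=1)
        report = evaluate(model, spectra)
        assert report.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_coefficients_match_nipals_oracle(self, default_dataset):
        # independent oracle: hand-written NIPALS PLS1 on centered data
        window = SpectralWindow(500, 600)
        train = default_dataset[:60]
        model = fit_plsr(train, window, n_components=4)

        X = window_matrix(train, window)
        y = np.asarray(model.scaler.forward(
            np.array([sp.concentration for sp in train])
        ))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        W_list, P_list, q_list = [], [], []
        Xd, yd = Xc.copy(), yc.copy()
        for _ in range(4):
            w = Xd.T @ yd
            w /= np.linalg.norm(w)
            t = Xd @ w
            tt = float(t @ t)
            p = Xd.T @ t / tt
            q = float(yd @ t / tt)
            Xd = Xd - np.outer(t, p)
            yd = yd - q * t
            W_list.append(w); P_list.append(p); q_list.append(q)
        Wm, Pm, qv = np.column_stack(W_list), np.column_stack(P_list), np.array(q_list)
        coef_oracle = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
        assert np.allclose(model.coef, coef_oracle, atol=1e-6)

    def test_too_many_components_rejected(self, default_dataset):
        # first 30 spectra span two levels (20 replicates per level)
        with pytest.raises(ValueError, match="n_components"):
            fit_plsr(default_dataset[:30], SpectralWindow(500, 600), n_components=40)


class TestEvaluate:
    class _Fixed:
        def __init__(self, pred):
            self.pred = np.asarray(pred, dtype=float)

        def predict_ppm(self, spectra):
            return self.pred

    @staticmethod
    def _spectra_with_levels(levels):
        from sersquant import AcquisitionGrid, Spectrum

        grid = AcquisitionGrid(0.0, 10.0, 1.0)
        return [
            Spectrum(grid, np.zeros(len(grid)), concentration=float(c)) for c in levels
        ]

    def test_perfect_prediction(self):
        sp = self._spectra_with_levels([1, 2, 3])
        rep = evaluate(self._Fixed([1, 2, 3]), sp)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.fit_line_slope == pytest.approx(1.0)
        assert rep.fit_line_intercept == pytest.approx(0.0, abs=1e-12)

    def test_mean_prediction_gives_zero(self):
        sp = self._spectra_with_levels([1, 2, 3])
        rep = evaluate(self._Fixed([2, 2, 2]), sp)
        assert rep.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_case(self):
        sp = self._spectra_with_levels([1, 2, 3])
        rep = evaluate(self._Fixed([1, 2, 4]), sp)
        assert rep.r_squared == pytest.approx(0.5)

    def test_constant_truth_rejected(self):
        sp = self._spectra_with_levels([2, 2, 2])
        with pytest.raises(ValueError, match="constant"):
            evaluate(self._Fixed([1, 2, 3]), sp)
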