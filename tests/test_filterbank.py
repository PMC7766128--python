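import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exobci import filterbank as fb

FS = 500.0


class TestFilterBank:
    def test_default_bands_exact(self):
        assert fb.FilterBank().bands == (
            (7.0, 9.0), (10.0, 12.0), (13.0, 15.0),
            (16.0, 20.0), (21.0, 25.0), (26.0, 34.0))

    def test_default_counts(self):
        bank = fb.FilterBank()
        assert bank.n_bands == 6
        assert bank.n_features == 24

    def test_reversed_band_rejected(self):
        with pytest.raises(ValueError, match="low edge"):
            fb.FilterBank(bands=((12.0, 10.0),))

    def test_band_outside_envelope_rejected(self):
        with pytest.raises(ValueError, match="envelope"):
            fb.FilterBank(bands=((2.0, 15.0),))


class TestBandpass:
    def test_passband_sinusoid_preserved_zero_lag(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 11.0 * t)
        y = fb.bandpass(x, (10, 12), FS)
        core = slice(int(2 * FS), int(8 * FS))
        amp = np.max(np.abs(y[core]))
        assert abs(amp - 1.0) < 0.05
        # zero-phase: cross-correlation peak at lag 0
        xc, yc = x[core], y[core]
        lags = range(-10, 11)
        corr = [np.dot(xc, np.roll(yc, l)) for l in lags]
        assert list(lags)[int(np.argmax(corr))] == 0

    def test_60hz_attenuated_20db(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 60.0 * t)
        y = fb.bandpass(x, (7, 34), FS)
        core = slice(int(2 * FS), int(8 * FS))
        ratio = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert 20 * np.log10(1 / ratio) >= 20.0

    def test_dc_removed(self):
        x = np.full(5000, 7.3)
        y = fb.bandpass(x, (10, 12), FS)
        assert abs(np.mean(y)) < 1e-6

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fb.bandpass(np.zeros(5000), (10, 250.0), FS)


def _toy_epochs(rng, n_epochs, scales):
    """Independent-channel epochs with per-channel std given by scales."""
    return [rng.standard_normal((len(scales), 1000)) * np.asarray(scales)[:, None]
            for _ in range(n_epochs)]


class TestCSP:
    def test_identical_covariance_ratios_half(self, rng):
        a = _toy_epochs(rng, 20, [1.0, 1.0, 1.0])
        b = _toy_epochs(rng, 20, [1.0, 1.0, 1.0])
        model = fb.fit_csp(a, b)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.05)

    def test_two_channel_toy_concentrates_weight(self, rng):
        a = _toy_epochs(rng, 30, [3.0, 0.5])
        b = _toy_epochs(rng, 30, [0.5, 3.0])
        model = fb.fit_csp(a, b)
        w1 = model.W[0]
        assert abs(w1[0]) > 10 * abs(w1[1])

    def test_brute_force_oracle_matches_eigensolution(self, rng):
        # Oracle: exhaustive search over random unit projections for the
        # maximal class-A variance ratio.
        a = _toy_epochs(rng, 30, [2.0, 0.7, 1.0])
        b = _toy_epochs(rng, 30, [0.7, 2.0, 1.0])
        ca = np.mean([e @ e.T / np.trace(e @ e.T) for e in a], axis=0)
        cb = np.mean([e @ e.T / np.trace(e @ e.T) for e in b], axis=0)
        dirs = rng.standard_normal((10_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ratios = np.einsum("ij,jk,ik->i", dirs, ca, dirs) / \
            np.einsum("ij,jk,ik->i", dirs, ca + cb, dirs)
        best_brute = ratios.max()
        model = fb.fit_csp(a, b)
        assert model.eigenvalues[0] == pytest.approx(best_brute, abs=1e-3)

    def test_eigenvalues_non_increasing(self, rng):
        a = _toy_epochs(rng, 10, [1.0, 2.0, 0.5, 1.5])
        b = _toy_epochs(rng, 10, [1.5, 0.5, 2.0, 1.0])
        model = fb.fit_csp(a, b)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_31_channel_shapes(self, rng):
        a = _toy_epochs(rng, 4, np.ones(31))
        b = _toy_epochs(rng, 4, np.ones(31))
        model = fb.fit_csp(a, b)
        assert model.W.shape == (31, 31)
        assert model.selected_rows == (0, 1, 29, 30)

    def test_too_few_epochs_rejected(self, rng):
        a = _toy_epochs(rng, 1, [1.0, 1.0])
        b = _toy_epochs(rng, 5, [1.0, 1.0])
        with pytest.raises(ValueError, match="2 epochs"):
            fb.fit_csp(a, b)

    def test_mismatched_channels_rejected(self, rng):
        a = _toy_epochs(rng, 3, [1.0, 1.0])
        b = _toy_epochs(rng, 3, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="channel"):
            fb.fit_csp(a, b)


class TestApplyCSP:
    def test_identity_returns_selected_channels(self, rng):
        e = rng.standard_normal((4, 100))
        model = fb.CSPModel(W=np.eye(4), eigenvalues=np.full(4, 0.5),
                            selected_rows=(0, 1, 2, 3))
        assert np.array_equal(fb.apply_csp(e, model), e)

    def test_linearity(self, rng):
        e = rng.standard_normal((3, 200))
        w = rng.standard_normal((3, 3))
        model = fb.CSPModel(W=w, eigenvalues=np.full(3, 0.5),
                            selected_rows=(0, 1, 2))
        assert np.allclose(fb.apply_csp(3.7 * e, model), 3.7 * fb.apply_csp(e, model))

    def test_explicit_dot_product_oracle(self, rng):
        e = rng.standard_normal((5, 50))
        w = rng.standard_normal((5, 5))
        model = fb.CSPModel(W=w, eigenvalues=np.full(5, 0.5),
                            selected_rows=(0, 1, 3, 4))
        z = fb.apply_csp(e, model)
        for out_row, w_row in zip(z, [w[0], w[1], w[3], w[4]]):
            expected = np.array([np.dot(w_row, e[:, j]) for j in range(e.shape[1])])
            assert np.allclose(out_row, expected)

    def test_channel_mismatch_rejected(self, rng):
        model = fb.CSPModel(W=np.eye(4), eigenvalues=np.full(4, 0.5),
                            selected_rows=(0, 1, 2, 3))
        with pytest.raises(ValueError, match="channels"):
            fb.apply_csp(rng.standard_normal((5, 100)), model)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    epochs = [rng.standard_normal((31, 1000)) for _ in range(12)]
    labels = np.array(["A"] * 6 + ["B"] * 6)
    model = fb.fit_fbcsp(epochs, labels, ("A", "B"))
    return model, epochs


class TestFBCSPFeatures:

    def test_six_csp_models_24_features(self, fitted):
        model, epochs = fitted
        assert len(model.csp_models) == 6
        feats = fb.extract_features(epochs[0], model)
        assert feats.shape == (24,)
        assert np.all(np.isfinite(feats))

    def test_within_band_normalization_identity(self, fitted):
        model, epochs = fitted
        feats = fb.extract_features(epochs[0], model)
        for b in range(6):
            assert np.exp(feats[4 * b:4 * b + 4]).sum() == pytest.approx(1.0)

    def test_scale_invariance(self, fitted):
        model, epochs = fitted
        f1 = fb.extract_features(epochs[0], model)
        f2 = fb.extract_features(np.float64(217.0) * epochs[0], model)
        assert np.allclose(f1, f2, atol=1e-9)

    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_property(self, fitted, scale):
        model, epochs = fitted
        f1 = fb.extract_features(epochs[1], model)
        f2 = fb.extract_features(scale * epochs[1], model)
        assert np.allclose(f1, f2, atol=1e-9)

    def test_single_band_dim_4(self):
        rng = np.random.default_rng(3)
        epochs = [rng.standard_normal((4, 1000)) for _ in range(8)]
        labels = np.array(["A", "B"] * 4)
        bank = fb.FilterBank(bands=((10.0, 12.0),))
        model = fb.fit_fbcsp(epochs, labels, ("A", "B"), bank=bank)
        assert fb.extract_features(epochs[0], model).shape == (4,)

    def test_missing_class_rejected(self, rng):
        epochs = [rng.standard_normal((4, 1000)) for _ in range(4)]
        with pytest.raises(ValueError, match="2 epochs"):
            fb.fit_fbcsp(epochs, ["A"] * 4, ("A", "B"))

    def test_fisher_separation_on_synthetic_session(self, small_windows):
        from exobci.filterbank import FilterBank, band_covariances, \
            features_from_covariances, fit_fbcsp_from_covariances
        windows, labels, _ = small_windows["gvn"]
        bank = FilterBank()
        covs = band_covariances(windows[:100], bank, 500.0)
        lab = labels[:100]
        model = fit_fbcsp_from_covariances(covs, lab, ("GAIT_MI", "NOTHING"),
                                           bank, 500.0)
        feats = fb.features_from_covariances(covs, model)
        a, b = feats[lab == "GAIT_MI"], feats[lab == "NOTHING"]
        fisher = (a.mean(0) - b.mean(0)) ** 2 / (a.var(0) + b.var(0))
        assert fisher.max() > 1.0


class TestZeroPhaseProperty:
    def test_cross_correlation_peak_at_zero_lag(self, rng):
        x = rng.standard_normal(10_000)
        y = fb.bandpass(x, (13, 15), FS)
        xb = fb.bandpass(x, (13, 15), FS)  # band-limited reference
        core = slice(2000, 8000)
        lags = range(-20, 21)
        corr = [np.dot(xb[core], np.roll(y, l)[core]) for l in lags]
        assert list(lags)[int(np.argmax(corr))] == 0
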