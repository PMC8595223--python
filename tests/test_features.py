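"""Fourier featurisation: projection exactness, reconstruction, feature
assembly widths/ordering, and Z-score standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsescreen import (
    FourierFeaturizer,
    MeasurementCombination,
    ZScoreScaler,
    all_combinations,
    assemble_features,
    fourier_coefficients,
    reconstruct,
)
from pulsescreen.features import coefficient_names

from conftest import make_twin_pools


def grid(m=64, period=0.8):
    return np.arange(m) / m * period


class TestFourierCoefficients:
    def test_constant_signal(self):
        f = fourier_coefficients(np.full(64, 3.0), period=0.8)
        assert f.coefficients[0] == pytest.approx(3.0)
        np.testing.assert_allclose(f.coefficients[1:], 0.0, atol=1e-12)

    def test_pure_cosine(self):
        t = grid()
        f = fourier_coefficients(np.cos(2 * np.pi * t / 0.8), period=0.8)
        names = coefficient_names()
        got = dict(zip(names, f.coefficients))
        assert got["b1"] == pytest.approx(1.0)
        for k, v in got.items():
            if k != "b1":
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_compound_bandlimited_signal(self):
        # u = 2 + sin(2wt) - 0.5 cos(5wt): b0=2, a2=1, b5=-0.5 exactly
        t = grid()
        w = 2 * np.pi / 0.8
        u = 2.0 + np.sin(2 * w * t) - 0.5 * np.cos(5 * w * t)
        f = fourier_coefficients(u, period=0.8)
        got = dict(zip(coefficient_names(), f.coefficients))
        assert got["b0"] == pytest.approx(2.0, abs=1e-12)
        assert got["a2"] == pytest.approx(1.0, abs=1e-12)
        assert got["b5"] == pytest.approx(-0.5, abs=1e-12)
        others = [v for k, v in got.items() if k not in ("b0", "a2", "b5")]
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fourier_coefficients(np.ones(20), period=0.8, order=5)

    def test_coefficient_count_is_2n_plus_1(self):
        for order in (1, 3, 5, 8):
            f = fourier_coefficients(np.ones(64), period=1.0, order=order)
            assert f.coefficients.shape == (2 * order + 1,)


class TestReconstruct:
    @settings(deadline=None, max_examples=50)
    @given(coefs=st.lists(st.floats(-2, 2), min_size=11, max_size=11))
    def test_roundtrip_exact_for_bandlimited(self, coefs):
        """projection(reconstruction) is the identity on the truncated basis."""
        t = grid()
        from pulsescreen.features import FourierFeatures
        f = FourierFeatures(np.array(coefs), order=5, omega=2 * np.pi / 0.8)
        u = reconstruct(f, t)
        f2 = fourier_coefficients(u, period=0.8)
        np.testing.assert_allclose(f2.coefficients, f.coefficients, atol=1e-10)

    def test_periodicity(self):
        f = fourier_coefficients(np.sin(2 * np.pi * grid() / 0.8) + 2, period=0.8)
        assert reconstruct(f, 0.13) == pytest.approx(reconstruct(f, 0.13 + 0.8))

    def test_out_of_band_content_becomes_tail_error(self):
        """Content above 5w is invisible to the projection; the mean-square
        reconstruction error equals the tail energy (Parseval: 1/2 for a
        unit-amplitude harmonic)."""
        t = grid()
        w = 2 * np.pi / 0.8
        u = np.cos(7 * w * t)
        f = fourier_coefficients(u, period=0.8)
        np.testing.assert_allclose(f.coefficients, 0.0, atol=1e-12)
        err = u - reconstruct(f, t)
        assert np.mean(err**2) == pytest.approx(0.5, abs=1e-12)

    def test_error_nonincreasing_in_order(self):
        rng = np.random.default_rng(5)
        t = grid(128)
        u = sum(rng.normal() * np.cos(2 * np.pi * k * t / 0.8 + rng.uniform(0, 6))
                for k in range(12))
        errs = []
        for order in range(1, 9):
            f = fourier_coefficients(u, period=0.8, order=order)
            errs.append(np.mean((u - reconstruct(f, t))**2))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestAssembleFeatures:
    def test_bilateral_width_22_per_measurement(self):
        h, d = make_twin_pools(4, np.random.default_rng(0))
        X, y, ids, cols = assemble_features(h + d, MeasurementCombination(("Q1",)))
        assert X.shape == (8, 22)
        assert list(y) == [0] * 4 + [1] * 4

    def test_unilateral_width_11(self):
        h, _ = make_twin_pools(3, np.random.default_rng(0))
        X, _, _, cols = assemble_features(h, MeasurementCombination(("P3",), "right"))
        assert X.shape == (3, 11)
        assert all(c.startswith("P3_R_") for c in cols)

    def test_all_six_bilateral_width_132(self):
        h, _ = make_twin_pools(2, np.random.default_rng(0))
        combo = MeasurementCombination(("Q1", "Q2", "Q3", "P1", "P2", "P3"))
        X, _, _, cols = assemble_features(h, combo)
        assert X.shape == (2, 132)

    def test_column_order_documented_and_stable(self):
        combo = MeasurementCombination(("P1", "Q1"))  # canonical: Q before P
        cols = combo.column_names()
        assert cols[0] == "Q1_R_b0"
        assert cols[11] == "Q1_L_b0"
        assert cols[22] == "P1_R_b0"
        assert cols[1:6] == [f"Q1_R_a{n}" for n in range(1, 6)]
        assert cols[6:11] == [f"Q1_R_b{n}" for n in range(1, 6)]

    def test_width_formula(self):
        for combo in all_combinations(("Q1", "Q2", "P1")):
            assert combo.width == 22 * len(combo.measurements)
        for combo in all_combinations(("Q1", "P3"), laterality="left"):
            assert combo.width == 11 * len(combo.measurements)

    def test_missing_site_raises(self):
        h, _ = make_twin_pools(1, np.random.default_rng(0))
        del h[0].waveforms.series["Q1_R"]
        with pytest.raises(KeyError, match="Q1_R"):
            assemble_features(h, MeasurementCombination(("Q1",)))

    def test_combination_enumeration(self):
        assert len(all_combinations()) == 63
        assert len(all_combinations(("Q1", "Q2", "P1"))) == 7


class TestZScore:
    def test_closed_form_example(self):
        sc = ZScoreScaler().fit(np.array([[1.0], [2.0], [3.0]]))
        out = sc.transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_train_moments_zero_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 7, size=(200, 5))
        Z = ZScoreScaler().fit(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_transform_not_refit_on_test(self):
        rng = np.random.default_rng(1)
        sc = ZScoreScaler().fit(rng.normal(0, 1, size=(100, 3)))
        X_test = rng.normal(5, 2, size=(50, 3))
        Z = sc.transform(X_test)
        assert abs(Z.mean()) > 1.0  # shifted distribution stays shifted

    def test_zero_variance_column_dropped_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = ZScoreScaler().fit(X)
        assert sc.transform(X).shape == (5, 1)
        assert sc.n_dropped_ == 1

    def test_affine_and_invertible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2, 3, size=(50, 4))
        sc = ZScoreScaler().fit(X)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X,
                                   atol=1e-10)


class TestFourierFeaturizerTransformer:
    def test_matches_single_waveform_path(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(5, 64))
        out = FourierFeaturizer(order=5).fit(W).transform(W)
        for i in range(5):
            ref = fourier_coefficients(W[i], period=1.0)
            np.testing.assert_allclose(out[i], ref.coefficients, atol=1e-12)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = clone(FourierFeaturizer(order=3))
        assert est.order == 3
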