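"""Chemometrics: MSC/D1 preprocessing, CARS, regression, evaluation."""

import numpy as np
import pytest
from sklearn.metrics import r2_score

from needlespec.chemometrics import (
    CARSConfig,
    cars_select,
    d1,
    default_grid,
    evaluate,
    fit_predict,
    make_split,
    msc_apply,
    msc_fit,
    preprocess,
    rpd_from_r2,
)


@pytest.fixture()
def wavelengths():
    return np.linspace(450, 950, 146)


class TestMSC:
    def test_exactly_inverts_affine_distortion_of_reference(self, rng):
        base = rng.random(100) * 0.5 + 0.2
        train = np.vstack([a * base + b for a, b in
                           [(1.1, 0.01), (0.9, -0.02), (1.0, 0.0)]])
        model = msc_fit(train)
        distorted = 1.7 * model.reference + 0.33
        np.testing.assert_allclose(msc_apply(model, distorted)[0],
                                   model.reference, atol=1e-12)

    def test_reference_is_fixed_point(self, rng):
        model = msc_fit(rng.random((5, 50)) + 0.1)
        np.testing.assert_allclose(
            msc_apply(model, model.reference.copy())[0], model.reference,
            atol=1e-12)

    def test_reduces_scatter_variance(self, rng):
        base = rng.random(80) * 0.5 + 0.2
        spectra = np.vstack([
            rng.uniform(0.8, 1.2) * base + rng.uniform(-0.02, 0.02)
            for _ in range(30)
        ])
        model = msc_fit(spectra)
        corrected = msc_apply(model, spectra)
        assert corrected.var(axis=0).mean() < spectra.var(axis=0).mean()

    def test_flat_spectrum_rejected(self, rng):
        model = msc_fit(rng.random((3, 20)) + 0.5)
        with pytest.raises(ValueError):
            msc_apply(model, np.full(20, 0.4))

    def test_needs_two_training_spectra(self, rng):
        with pytest.raises(ValueError):
            msc_fit(rng.random((1, 20)))


class TestD1:
    def test_constant_spectrum_gives_zero(self, wavelengths):
        out = d1(np.full((2, wavelengths.size), 0.7), wavelengths)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_linear_spectrum_gives_slope(self, wavelengths):
        c = 0.003
        out = d1((c * wavelengths)[None, :], wavelengths)
        np.testing.assert_allclose(out, c, atol=1e-12)

    def test_offset_invariance(self, wavelengths, rng):
        s = rng.random(wavelengths.size)[None, :]
        np.testing.assert_allclose(
            d1(s, wavelengths), d1(s + 0.25, wavelengths), atol=1e-12)

    def test_savgol_option_matches_slope_on_linear(self, wavelengths):
        out = d1((0.002 * wavelengths)[None, :], wavelengths, method="savgol")
        np.testing.assert_allclose(out, 0.002, atol=1e-10)


class TestPreprocess:
    def test_raw_is_identity(self, wavelengths, rng):
        tr, te = rng.random((10, 146)), rng.random((4, 146))
        out_tr, out_te = preprocess(tr, te, "raw", wavelengths)
        np.testing.assert_array_equal(out_tr, tr)
        np.testing.assert_array_equal(out_te, te)

    @pytest.mark.parametrize("method", ["raw", "msc", "d1", "d1_msc"])
    def test_shapes_preserved_for_all_methods(self, wavelengths, rng, method):
        tr = rng.random((10, 146)) + 0.1
        te = rng.random((4, 146)) + 0.1
        out_tr, out_te = preprocess(tr, te, method, wavelengths)
        assert out_tr.shape == tr.shape and out_te.shape == te.shape

    def test_unknown_method_rejected(self, wavelengths, rng):
        with pytest.raises(ValueError):
            preprocess(rng.random((5, 146)), rng.random((2, 146)),
                       "snv", wavelengths)


class TestCARS:
    def test_planted_bands_recovered_single_seed(self, rng):
        n, p = 120, 80
        X = rng.normal(0.5, 0.1, (n, p))
        planted = [5, 20, 41, 60, 77]
        y = X[:, planted] @ np.array([1.5, -2.0, 1.0, 2.5, -1.2])
        y += rng.normal(0, 0.05 * y.std(), n)
        res = cars_select(X, y, CARSConfig(n_mc_runs=30, seed=0))
        assert set(planted) <= set(res.selected)

    def test_retained_counts_non_increasing_to_two(self, rng):
        X = rng.normal(0, 1, (40, 30))
        y = rng.normal(0, 1, 40)
        res = cars_select(X, y, CARSConfig(n_mc_runs=15, seed=2))
        counts = [len(s) for s in res.retained_sets]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 2

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(0, 1, (30, 20))
        y = X[:, 3] + rng.normal(0, 0.1, 30)
        r1 = cars_select(X, y, CARSConfig(n_mc_runs=10, seed=9))
        r2 = cars_select(X, y, CARSConfig(n_mc_runs=10, seed=9))
        assert r1 == r2

    def test_selected_is_argmin_rmsecv_run(self, rng):
        X = rng.normal(0, 1, (30, 20))
        y = X[:, [2, 7]] @ np.array([1.0, -1.0]) + rng.normal(0, 0.05, 30)
        res = cars_select(X, y, CARSConfig(n_mc_runs=10, seed=4))
        assert res.best_run == int(np.argmin(res.rmsecv))
        assert res.selected == res.retained_sets[res.best_run]

    @pytest.mark.parametrize("n,p", [(10, 50), (30, 3)])
    def test_input_validation(self, rng, n, p):
        with pytest.raises(ValueError):
            cars_select(rng.normal(0, 1, (n, p)), rng.normal(0, 1, n))


class TestSplit:
    def test_disjoint_and_exhaustive(self):
        s = make_split(120, 0.2, seed=5)
        assert len(s.test_idx) == 24
        assert set(s.train_idx) | set(s.test_idx) == set(range(120))
        assert not set(s.train_idx) & set(s.test_idx)

    def test_seeded(self):
        assert make_split(50, 0.2, 3) == make_split(50, 0.2, 3)
        assert make_split(50, 0.2, 3) != make_split(50, 0.2, 4)


class TestFitPredict:
    def test_noiseless_linear_map_recovered(self, rng):
        X = rng.normal(0.5, 0.2, (60, 30))
        beta = rng.normal(0, 1, 30)
        y = X @ beta + 3.0
        s = make_split(60, 0.2, 0)
        tr, te = np.array(s.train_idx), np.array(s.test_idx)
        fit = fit_predict(default_grid("plsr", 30), X[tr], y[tr], X[te],
                          cv_folds=10, seed=0)
        assert evaluate(y[te], fit.predictions).r2p >= 0.999

    def test_single_candidate_equals_direct_fit(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(0, 1, (40, 10))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        spec = default_grid("plsr", 10)
        single = spec.__class__("plsr", ({"n_components": 3},))
        fit = fit_predict(single, X[:30], y[:30], X[30:], seed=0)
        mu, sd = y[:30].mean(), y[:30].std()
        direct = PLSRegression(n_components=3, scale=False)
        direct.fit(X[:30], (y[:30] - mu) / sd)
        np.testing.assert_allclose(
            fit.predictions, np.ravel(direct.predict(X[30:])) * sd + mu,
            atol=1e-10)

    def test_rf_deterministic_under_seed(self, rng):
        X = rng.normal(0, 1, (40, 8))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        grids = default_grid("rf", 8, seed=1)
        small = grids.__class__("rf", grids.grid[:1])
        p1 = fit_predict(small, X[:30], y[:30], X[30:], seed=1).predictions
        p2 = fit_predict(small, X[:30], y[:30], X[30:], seed=1).predictions
        np.testing.assert_array_equal(p1, p2)

    def test_svr_grid_runs(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        spec = default_grid("svr", 5)
        small = spec.__class__("svr", spec.grid[:4])
        fit = fit_predict(small, X[:24], y[:24], X[24:], cv_folds=5, seed=0)
        assert fit.predictions.shape == (6,)


class TestEvaluate:
    def test_matches_brute_force_formulas(self, rng):
        y = rng.normal(10, 2, 50)
        p = y + rng.normal(0, 0.5, 50)
        res = evaluate(y, p)
        ss_res = sum((a - b) ** 2 for a, b in zip(p, y))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert res.r2p == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert res.rmsep == pytest.approx(np.sqrt(ss_res / 50), abs=1e-12)

    def test_agrees_with_sklearn_r2(self, rng):
        y = rng.normal(0, 1, 30)
        p = y + rng.normal(0, 0.3, 30)
        assert evaluate(y, p).r2p == pytest.approx(r2_score(y, p), abs=1e-12)

    def test_perfect_predictions(self, rng):
        y = rng.normal(0, 1, 10)
        res = evaluate(y, y.copy())
        assert res.r2p == 1.0 and res.rmsep == 0.0
        assert res.rpd == float("inf")

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.full(5, 2.0), np.arange(5.0))

    def test_rpd_consistency_with_r2(self, rng):
        y = rng.normal(5, 1, 40)
        p = y + rng.normal(0, 0.4, 40)
        res = evaluate(y, p)
        assert res.rpd == pytest.approx(1 / np.sqrt(1 - res.r2p), abs=1e-9)


class TestRPD:
    # the self-consistent printed (R², RPD) pairs from the reference tables
    PRINTED = [
        (0.9038, 3.2246), (0.8523, 2.6024), (0.7022, 1.8326),
        (0.8087, 2.2866), (0.8370, 2.4767), (0.6950, 1.810),
        (0.5040, 1.4199), (0.8159, 2.3308),
    ]

    @pytest.mark.parametrize("r2,expected", PRINTED)
    def test_printed_pairs_reproduced(self, r2, expected):
        assert rpd_from_r2(r2) == pytest.approx(expected, abs=1e-3)

    def test_closed_form_values(self):
        assert rpd_from_r2(0.0) == pytest.approx(1.0)
        assert rpd_from_r2(0.75) == pytest.approx(2.0)
        assert rpd_from_r2(1.0) == float("inf")
        assert rpd_from_r2(-0.5) < 1.0
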