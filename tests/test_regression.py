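"""PLS/MPLS/PCR fitters, cross-validation and outlier elimination."""

import numpy as np
import pytest

import grainspec as gs
from grainspec.regression import fit_method

from conftest import toy_spectra


def _random_problem(rng, n=10, p=3, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y


def _ols(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef  # [intercept, b...]


class TestPLS:
    def test_full_rank_equals_ols(self, rng):
        X, y = _random_problem(rng, n=10, p=3, noise=0.1)
        model = gs.fit_pls(X, y, n_pcs=3)
        ols = _ols(X, y)
        np.testing.assert_allclose(model.coefficients, ols[1:], atol=1e-8)
        np.testing.assert_allclose(model.intercept, ols[0], atol=1e-8)

    def test_one_component_structure_recovered_exactly(self, rng):
        t = rng.normal(size=20)
        load = rng.normal(size=6)
        X = np.outer(t, load)
        y = 2.0 * t + 3.0
        model = gs.fit_pls(X, y, n_pcs=1)
        assert model.stats["rsq"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_nipals(self, rng):
        """Dual route: coefficients agree with scikit-learn's PLSRegression
        (NIPALS, unscaled) on a noisy multicollinear problem."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 12))
        X[:, 6:] = X[:, :6] + 0.1 * rng.normal(size=(40, 6))
        y = X[:, 0] - X[:, 7] + 0.05 * rng.normal(size=40)
        ours = gs.fit_pls(X, y, n_pcs=4)
        ref = sklearn_pls.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.coefficients, ref.coef_.ravel(), atol=1e-8
        )

    def test_zero_variance_y_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="variance"):
            gs.fit_pls(X, np.ones(8), n_pcs=2)


class TestMPLS:
    def test_rank_one_noiseless_equals_pls(self, rng):
        t = rng.normal(size=15)
        X = np.outer(t, rng.normal(size=5))
        y = -1.3 * t + 0.4
        pls = gs.fit_pls(X, y, n_pcs=1)
        mpls = gs.fit_mpls(X, y, n_pcs=1)
        np.testing.assert_allclose(pls.predict(X), mpls.predict(X), atol=1e-8)

    def test_secv_within_20pct_of_pls_on_fixture(self, study_fixture):
        spectra, ref = study_fixture
        treated, _ = gs.preprocess(spectra, "snv_dt", "4,8,8,1")
        y = ref.values_for("protein_pct")
        a = gs.cross_validate(treated.absorbance, y, method="pls", n_pcs_max=5)
        b = gs.cross_validate(treated.absorbance, y, method="mpls", n_pcs_max=5)
        assert abs(a.secv - b.secv) / a.secv < 0.20

    def test_residual_scaling_spreads_coefficient_mass(self, rng):
        """Pre-scaling one column x1000 concentrates PLS weight there; MPLS's
        residual standardisation reduces that concentration."""
        X = rng.normal(size=(60, 10))
        beta = np.ones(10)
        y = X @ beta + 0.1 * rng.normal(size=60)
        Xs = X.copy()
        Xs[:, 0] *= 1000.0
        pls = gs.fit_pls(Xs, y, n_pcs=2)
        mpls = gs.fit_mpls(Xs, y, n_pcs=2)

        def share(model):
            w = np.abs(model.coefficients * Xs.std(axis=0))
            return w[0] / w.sum()

        assert share(mpls) < share(pls)


class TestPCR:
    def test_full_rank_equals_ols(self, rng):
        X, y = _random_problem(rng, n=12, p=4, noise=0.2)
        model = gs.fit_pcr(X, y, n_pcs=4)
        ols = _ols(X, y)
        np.testing.assert_allclose(model.coefficients, ols[1:], atol=1e-8)

    def test_y_on_second_pc_needs_two_components(self, rng):
        # X with dominant PC1 and a weaker PC2; y depends only on PC2
        n = 100
        t1 = 10.0 * rng.normal(size=n)
        t2 = rng.normal(size=n)
        v1 = np.array([1.0, 0, 0, 0])
        v2 = np.array([0, 1.0, 0, 0])
        X = np.outer(t1, v1) + np.outer(t2, v2)
        y = t2 + 5.0
        one = gs.fit_pcr(X, y, n_pcs=1)
        two = gs.fit_pcr(X, y, n_pcs=2)
        assert one.stats["rsq"] < 0.05
        assert two.stats["rsq"] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, rng):
        X, y = _random_problem(rng, n=30, p=8, noise=0.5)
        model = gs.fit_pcr(X, y, n_pcs=5)
        G = model.scores_.T @ model.scores_
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-10)


class TestMonotoneFit:
    @pytest.mark.parametrize("method", ["pls", "mpls", "pcr"])
    def test_training_sec_never_increases_with_components(self, method, rng):
        X = rng.normal(size=(40, 15))
        y = X[:, :5] @ rng.normal(size=5) + 0.3 * rng.normal(size=40)
        rss = []
        for k in range(1, 7):
            m = fit_method(X, y, k, method)
            resid = y - m.predict(X)
            rss.append(resid @ resid)
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))


class TestCrossValidate:
    def test_noiseless_two_component_data(self, rng):
        n = 24
        T = rng.normal(size=(n, 2))
        X = T @ rng.normal(size=(2, 10))
        y = T @ np.array([1.0, -2.0])
        cv = gs.cross_validate(X, y, method="pls", n_pcs_max=5, n_groups=4)
        assert cv.chosen_n_pcs == 2
        assert cv.secv < 1e-8

    def test_chosen_never_exceeds_cap(self, small_fixture):
        spectra, ref = small_fixture
        treated, _ = gs.preprocess(spectra, "snv_dt", "2,4,4,1")
        for method in ("pls", "mpls", "pcr"):
            cv = gs.cross_validate(
                treated.absorbance, ref.values_for("protein_pct"),
                method=method, n_pcs_max=5,
            )
            assert 1 <= cv.chosen_n_pcs <= 5

    @pytest.mark.parametrize("method", ["pls", "pcr"])
    def test_matches_literal_loop_reimplementation(self, method, rng):
        """SECV equals an explicit per-fold, per-k refit loop on 30 samples."""
        X = rng.normal(size=(30, 12))
        y = X[:, :4] @ rng.normal(size=4) + 0.2 * rng.normal(size=30)
        kmax, groups = 4, 3
        cv = gs.cross_validate(X, y, method=method, n_pcs_max=kmax, n_groups=groups)
        bounds = np.linspace(0, 30, groups + 1).astype(int)
        for k in range(1, kmax + 1):
            press = 0.0
            for g in range(groups):
                held = np.zeros(30, dtype=bool)
                held[bounds[g]:bounds[g + 1]] = True
                m = fit_method(X[~held], y[~held], k, method)
                press += float(((y[held] - m.predict(X[held])) ** 2).sum())
            np.testing.assert_allclose(
                cv.secv_by_pcs[k], np.sqrt(press / 30), atol=1e-10
            )

    def test_small_group_rejected(self, rng):
        X, y = _random_problem(rng, n=5, p=2)
        with pytest.raises(ValueError, match="group"):
            gs.cross_validate(X, y, n_groups=4)


class TestRemoveOutliers:
    def test_clean_noiseless_data_removes_nothing(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 2.0
        model, removed = gs.remove_outliers(X, y, method="pls", n_pcs=5)
        assert removed == []

    def test_single_corrupted_sample_flagged_by_t_rule(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=40)
        y = y.copy()
        y[17] += 10.0 * y.std()
        ids = [f"S{i}" for i in range(40)]
        model, removed = gs.remove_outliers(
            X, y, method="pls", n_pcs=5, sample_ids=ids
        )
        assert [r[0] for r in removed] == ["S17"]
        assert removed[0][1].startswith("t=")

    def test_eight_corrupted_samples_stay_under_default_cap(self, rng):
        X = rng.normal(size=(120, 6))
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=120)
        bad = rng.choice(120, size=8, replace=False)
        y[bad] += 12.0 * y.std()
        ids = [f"S{i}" for i in range(120)]
        _, removed = gs.remove_outliers(
            X, y, method="pls", n_pcs=5, sample_ids=ids
        )
        assert len(removed) <= 12  # default cap: 10% of n
        assert {r[0] for r in removed} >= {f"S{i}" for i in bad}

    def test_removal_capped_with_warning(self, rng):
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=80)
        y[:4] += 12.0 * y.std()
        with pytest.warns(UserWarning, match="cap"):
            _, removed = gs.remove_outliers(
                X, y, method="pls", n_pcs=5, max_remove_fraction=0.025
            )
        assert len(removed) <= 2  # cap: 2.5% of 80

    def test_never_errors_at_cap(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)  # pure noise: many large residuals
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, removed = gs.remove_outliers(X, y, method="pcr", n_pcs=3)
        assert len(removed) <= 3


class TestModelSerialization:
    def test_round_trip_bit_identical_predictions(self, tmp_path, small_fixture):
        spectra, ref = small_fixture
        treated, _ = gs.preprocess(spectra, "snv_dt", "4,8,8,1")
        model = gs.fit_mpls(treated, ref.values_for("oil_pct"), n_pcs=4)
        model.trait, model.scatter, model.treatment = "oil_pct", "snv_dt", "4,8,8,1"
        path = tmp_path / "model.json"
        model.save(path)
        back = gs.CalibrationModel.load(path)
        pred_a = model.predict(treated)
        pred_b = back.predict(treated)
        np.testing.assert_array_equal(pred_a, pred_b)
        assert back.method == "mpls" and back.n_pcs == model.n_pcs

    def test_prediction_invariant_to_sample_order(self, rng, small_fixture):
        spectra, ref = small_fixture
        treated, _ = gs.preprocess(spectra, "none", "2,4,4,1")
        model = gs.fit_pls(treated, ref.values_for("starch_pct"), n_pcs=3)
        perm = rng.permutation(treated.n_samples)
        shuffled = treated.subset([treated.sample_ids[i] for i in perm])
        np.testing.assert_allclose(
            model.predict(shuffled), model.predict(treated)[perm], atol=1e-12
        )
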