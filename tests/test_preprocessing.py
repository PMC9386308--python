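"""Scatter corrections and math treatments, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grainspec as gs
from grainspec.preprocessing import apply_scatter

from conftest import toy_spectra


# ---------------------------------------------------------------------------
# brute-force oracle: literal nested-loop implementation of the treatment
# ---------------------------------------------------------------------------

def brute_force_treatment(x: np.ndarray, d: int, g: int, s1: int, s2: int) -> np.ndarray:
    """Literal definition: boxcar(s1) -> d centred gap differences -> boxcar(s2)."""

    def boxcar(v, w):
        if w == 1:
            return v
        left = w // 2
        out = []
        for i in range(left, len(v) - (w - left - 1)):
            out.append(sum(v[i - left : i - left + w]) / w)
        return np.array(out)

    def gap_diff(v, gap):
        h = gap // 2
        return np.array([v[i + h] - v[i - h] for i in range(h, len(v) - h)])

    v = boxcar(np.asarray(x, float), s1)
    for _ in range(d):
        v = gap_diff(v, g)
    return boxcar(v, s2)


class TestApplyTreatment:
    @pytest.mark.parametrize(
        "code", ["0,0,1,1", "1,2,1,1", "2,4,3,2", "4,8,8,1", "3,16,8,2", "2,8,8,1", "1,4,4,4"]
    )
    def test_matches_brute_force_on_random_spectra(self, code, rng):
        X = rng.normal(size=(4, 60))
        t = gs.parse_treatment(code)
        out = gs.apply_treatment(toy_spectra(X), t)
        for i in range(4):
            expected = brute_force_treatment(
                X[i], t.derivative, t.gap, t.smooth1, t.smooth2
            )
            np.testing.assert_allclose(out.absorbance[i], expected, atol=1e-10)

    def test_identity_treatment(self, rng):
        s = toy_spectra(rng.normal(size=(3, 20)))
        out = gs.apply_treatment(s, gs.parse_treatment("0,0,1,1"))
        np.testing.assert_array_equal(out.absorbance, s.absorbance)
        np.testing.assert_array_equal(out.wavelengths_nm, s.wavelengths_nm)

    def test_linear_spectrum_first_gap_derivative_constant(self):
        c = 0.7
        x = c * np.arange(30.0)
        out = gs.apply_treatment(toy_spectra(x[None, :]), gs.parse_treatment("1,4,1,1"))
        np.testing.assert_allclose(out.absorbance[0], 4 * c, atol=1e-12)
        # edge trim recorded in the grid: 2 points lost each side
        assert out.n_wavelengths == 30 - 4

    def test_quadratic_spectrum_second_and_third_derivatives(self):
        x = np.arange(40.0) ** 2
        second = gs.apply_treatment(toy_spectra(x[None, :]), gs.parse_treatment("2,2,1,1"))
        np.testing.assert_allclose(second.absorbance[0], 8.0, atol=1e-9)
        third = gs.apply_treatment(toy_spectra(x[None, :]), gs.parse_treatment("3,2,1,1"))
        np.testing.assert_allclose(third.absorbance[0], 0.0, atol=1e-9)

    def test_too_short_grid_errors(self):
        s = toy_spectra(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="grid"):
            gs.apply_treatment(s, gs.parse_treatment("4,16,8,2"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(-3, 3, allow_nan=False),
        beta=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_gap_derivative_is_linear_operator(self, alpha, beta, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=50), r.normal(size=50)
        t = gs.parse_treatment("2,4,3,1")
        tx = gs.apply_treatment(toy_spectra(x[None, :]), t).absorbance[0]
        ty = gs.apply_treatment(toy_spectra(y[None, :]), t).absorbance[0]
        tz = gs.apply_treatment(
            toy_spectra((alpha * x + beta * y)[None, :]), t
        ).absorbance[0]
        np.testing.assert_allclose(tz, alpha * tx + beta * ty, atol=1e-9)

    def test_row_local_operators_commute_with_permutation(self, rng):
        X = rng.normal(size=(6, 40))
        perm = rng.permutation(6)
        t = gs.parse_treatment("2,4,4,1")
        a = gs.apply_treatment(toy_spectra(X), t).absorbance[perm]
        b = gs.apply_treatment(toy_spectra(X[perm]), t).absorbance
        np.testing.assert_array_equal(a, b)


class TestMSC:
    def test_spectrum_equal_to_reference_unchanged(self):
        m = np.sin(np.linspace(0, 3, 30)) + 2
        s = toy_spectra(np.vstack([m, m * 1.5 + 0.2]))
        out, corr = gs.msc_fit_apply(s, reference=m)
        np.testing.assert_allclose(out.absorbance[0], m, atol=1e-10)
        np.testing.assert_allclose(corr.reference, m)

    def test_affine_distortion_removed(self):
        m = np.cos(np.linspace(0, 4, 25)) + 3
        x = 2 * m + 1
        s = toy_spectra(np.vstack([x, m]))
        out, _ = gs.msc_fit_apply(s, reference=m)
        np.testing.assert_allclose(out.absorbance[0], m, atol=1e-10)

    def test_zero_slope_sample_errors_with_name(self):
        m = np.linspace(1, 2, 20)
        flat = np.full(20, 5.0)
        s = toy_spectra(np.vstack([m, flat]), ids=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            gs.msc_fit_apply(s, reference=m)

    def test_scatter_variance_collapse_on_fixture(self, study_fixture):
        """Post-MSC between-sample variance at a pure-baseline wavelength
        drops by >= 90% relative to the raw scattered spectra."""
        spectra, _ = study_fixture
        corrected, _ = gs.msc_fit_apply(spectra)
        j = int(np.argmin(np.abs(spectra.wavelengths_nm - 700.0)))  # no bands there
        raw_var = spectra.absorbance[:, j].var()
        cor_var = corrected.absorbance[:, j].var()
        assert cor_var <= 0.10 * raw_var

    def test_stored_reference_reused_out_of_set(self, small_fixture):
        spectra, _ = small_fixture
        cal = spectra.subset(spectra.sample_ids[:40])
        val = spectra.subset(spectra.sample_ids[40:])
        _, corr = gs.msc_fit_apply(cal)
        out_val = apply_scatter(val, corr)
        # applying with the calibration mean, not the validation mean
        direct, _ = gs.msc_fit_apply(val, reference=corr.reference)
        np.testing.assert_array_equal(out_val.absorbance, direct.absorbance)


class TestSnvDetrend:
    def test_affine_spectrum_maps_to_zero(self):
        wl = 400.0 + 2.0 * np.arange(50)
        x = 0.5 + 0.01 * wl
        out = gs.snv_detrend(toy_spectra(np.vstack([x, x**2])))
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-8)

    def test_pure_quadratic_maps_to_zero(self):
        wl = 400.0 + 2.0 * np.arange(50)
        x = 1 + 0.001 * (wl - 1000) ** 2
        out = gs.snv_detrend(toy_spectra(np.vstack([x, np.sin(wl)])))
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-8)

    def test_output_orthogonal_to_quadratic_basis(self, rng):
        X = rng.normal(size=(5, 60))
        out = gs.snv_detrend(toy_spectra(X))
        wl = out.wavelengths_nm
        basis = np.vander((wl - wl.mean()) / wl.std(), 3, increasing=True)
        coefs, *_ = np.linalg.lstsq(basis, out.absorbance.T, rcond=None)
        np.testing.assert_allclose(coefs, 0.0, atol=1e-8)

    def test_snv_stage_statistics(self, rng):
        """Before detrend the SNV rows are mean-0, SD-1; after quadratic
        detrend the row mean stays ~0."""
        X = rng.normal(size=(4, 80))
        s = toy_spectra(X)
        snv = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        np.testing.assert_allclose(snv.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(snv.std(axis=1), 1.0, atol=1e-12)
        out = gs.snv_detrend(s)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-9)

    def test_constant_spectrum_errors(self):
        s = toy_spectra(np.vstack([np.ones(10), np.arange(10.0)]), ids=["c", "v"])
        with pytest.raises(ValueError, match="c"):
            gs.snv_detrend(s)


class TestPreprocessComposition:
    def test_msc_with_identity_treatment_equals_msc(self, small_fixture):
        spectra, _ = small_fixture
        via_pipeline, _ = gs.preprocess(spectra, "msc", "0,0,1,1")
        direct, _ = gs.msc_fit_apply(spectra)
        np.testing.assert_array_equal(via_pipeline.absorbance, direct.absorbance)

    def test_none_scatter_equals_treatment_alone(self, small_fixture):
        spectra, _ = small_fixture
        via_pipeline, _ = gs.preprocess(spectra, "none", "4,8,8,1")
        direct = gs.apply_treatment(spectra, gs.parse_treatment("4,8,8,1"))
        np.testing.assert_array_equal(via_pipeline.absorbance, direct.absorbance)

    def test_full_fixture_snv_dt_heavy_treatment(self, study_fixture):
        spectra, _ = study_fixture
        out, _ = gs.preprocess(spectra, "snv_dt", "3,16,8,2")
        assert np.all(np.isfinite(out.absorbance))
        assert out.n_wavelengths < spectra.n_wavelengths
        assert len(out.meta["history"]) == 2
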