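"""Spectral sensitivity derivation, replicate averaging, lambda-max fitting."""

import numpy as np
import pytest

from heliovis.photoresponse import NakaRushtonParams, nr_response
from heliovis.sensitivity import (
    FluxCalibration,
    LambdaMaxEstimator,
    SpectralFlashSeries,
    SpectralSensitivity,
    average_cells,
    derive_sensitivity,
    fit_lambda_max,
)
from heliovis.templates import PigmentTemplate

PARAMS = NakaRushtonParams(v_max=60.0, k=1.0 / 9.0, n=1.0)


def flashes_from_template(grid, lmax, params=PARAMS, calib=None, top=0.8):
    """Forward-simulate noiseless flash responses from a template."""
    s = PigmentTemplate(lmax)(grid)
    flux = np.ones_like(grid) if calib is None else calib.relative_flux
    i_top = params.k * (top / (1 - top)) ** (1 / params.n)
    v = nr_response(i_top / (flux * s).max() * flux * s, params)
    return SpectralFlashSeries(wavelengths=grid, responses=v)


def test_flat_responses_flat_calibration_give_flat_sensitivity(grid10):
    flashes = SpectralFlashSeries(wavelengths=grid10, responses=np.full_like(grid10, 30.0))
    sens = derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))
    np.testing.assert_allclose(sens.sensitivity, 1.0)


@pytest.mark.parametrize("lmax", [365.0, 470.0, 570.0])
def test_forward_inverse_self_consistency(grid10, lmax):
    """Noiseless flashes generated from a template invert back to it (up to
    the max-normalization on the measurement grid)."""
    flashes = flashes_from_template(grid10, lmax)
    sens = derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))
    expected = PigmentTemplate(lmax)(grid10)
    np.testing.assert_allclose(sens.sensitivity, expected / expected.max(), atol=1e-6)


def test_calibration_correction_algebra(grid10):
    """Doubling the delivered flux at one wavelength halves the recovered
    sensitivity there (n = 1)."""
    flux = np.ones_like(grid10)
    j = 12
    flux[j] = 2.0
    calib = FluxCalibration(wavelengths=grid10, relative_flux=flux)
    flashes = flashes_from_template(grid10, 470.0)  # generated under flat flux
    flat = derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))
    corrected = derive_sensitivity(flashes, PARAMS, calib)
    # calibration is max-normalized internally: compare sensitivity ratios
    ratio = corrected.sensitivity / corrected.sensitivity[j + 1]
    ratio_flat = flat.sensitivity / flat.sensitivity[j + 1]
    assert ratio[j] == pytest.approx(ratio_flat[j] / 2.0, rel=1e-9)


def test_flat_calibration_is_identity(grid10):
    flashes = flashes_from_template(grid10, 445.0)
    a = derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))
    b = derive_sensitivity(
        flashes, PARAMS, FluxCalibration(wavelengths=grid10, relative_flux=np.full_like(grid10, 0.25))
    )
    np.testing.assert_allclose(a.sensitivity, b.sensitivity, rtol=1e-12)


def test_saturating_response_error_names_wavelengths(grid10):
    v = np.full_like(grid10, 10.0)
    v[5] = 61.0  # above v_max
    flashes = SpectralFlashSeries(wavelengths=grid10, responses=v)
    with pytest.raises(ValueError, match="350"):
        derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))


def test_calibration_grid_mismatch_rejected(grid10):
    flashes = flashes_from_template(grid10, 470.0)
    calib = FluxCalibration.flat(grid10[:-1])
    with pytest.raises(ValueError, match="grid"):
        derive_sensitivity(flashes, PARAMS, calib)


def test_average_single_cell_is_identity(grid10):
    sens = SpectralSensitivity(wavelengths=grid10, sensitivity=PigmentTemplate(470.0)(grid10))
    avg = average_cells([sens])
    np.testing.assert_allclose(avg.sensitivity, sens.sensitivity)
    assert np.all(avg.se == 0) and avg.n_cells == 1


def test_average_mirror_noise_cancels(grid10):
    """Two replicates with antisymmetric noise average back to the template.

    The noise is proportional to base * (1 - base) so it vanishes at the
    peak, never drives a replicate negative or above 1, and per-replicate
    max-normalization preserves the exact mirror symmetry."""
    base = PigmentTemplate(470.0)(grid10)
    noise = 0.4 * base * (1.0 - base) * np.sin((grid10 - 470.0) / 30.0)
    up = SpectralSensitivity(wavelengths=grid10, sensitivity=np.clip(base + noise, 1e-9, None))
    down = SpectralSensitivity(wavelengths=grid10, sensitivity=np.clip(base - noise, 1e-9, None))
    avg = average_cells([up, down])
    np.testing.assert_allclose(avg.sensitivity, base / base.max(), atol=1e-9)
    assert np.all(avg.se[np.abs(noise) > 1e-12] > 0)


def test_average_replicates_have_positive_se_off_peak(grid10, rng):
    cells = []
    base = PigmentTemplate(445.0)(grid10)
    for _ in range(7):
        noisy = np.clip(base + rng.normal(0, 0.03, base.shape), 1e-9, None)
        cells.append(SpectralSensitivity(wavelengths=grid10, sensitivity=noisy))
    avg = average_cells(cells)
    assert avg.n_cells == 7
    off_peak = np.abs(grid10 - 445.0) > 60
    assert np.all(avg.se[off_peak] > 0)
    assert avg.sensitivity.max() == pytest.approx(1.0)


def test_average_mixed_grids_rejected(grid10):
    a = SpectralSensitivity(wavelengths=grid10, sensitivity=np.ones_like(grid10))
    b = SpectralSensitivity(wavelengths=grid10[:-1], sensitivity=np.ones_like(grid10[:-1]))
    with pytest.raises(ValueError, match="grids"):
        average_cells([a, b])


def test_lambda_max_self_fit_exact(grid10):
    sens = SpectralSensitivity(wavelengths=grid10, sensitivity=PigmentTemplate(445.0)(grid10))
    fit = fit_lambda_max(sens)
    assert fit.lambda_max_hat == pytest.approx(445.0, abs=0.1)
    assert fit.rss < 1e-12
    assert not fit.boundary_hit


def test_lambda_max_matches_dense_grid_oracle(grid10, rng):
    """Optimizer result equals a 0.1 nm brute-force grid search within 0.2 nm
    on noisy synthetic cells."""
    for _ in range(10):
        lmax = rng.uniform(360.0, 600.0)
        noisy = np.clip(PigmentTemplate(lmax)(grid10) + rng.normal(0, 0.03, grid10.shape), 1e-9, None)
        sens = SpectralSensitivity(wavelengths=grid10, sensitivity=noisy)
        fit = fit_lambda_max(sens)
        dense = np.arange(3000, 7001) / 10.0
        s = sens.sensitivity

        def rss_at(lm):
            t = PigmentTemplate(lm)(grid10)
            a = max(float(np.dot(s, t) / np.dot(t, t)), 0.0)
            return float(np.sum((s - a * t) ** 2))

        oracle = dense[int(np.argmin([rss_at(lm) for lm in dense]))]
        assert abs(fit.lambda_max_hat - oracle) <= 0.2


def test_lambda_max_boundary_warning(grid10):
    """A search window that excludes the true optimum flags a boundary hit."""
    sens = SpectralSensitivity(wavelengths=grid10, sensitivity=PigmentTemplate(570.0)(grid10))
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_lambda_max(sens, search_bounds=(300.0, 500.0))
    assert fit.boundary_hit


def test_lambda_max_estimator_sklearn_surface(grid10):
    est = LambdaMaxEstimator()
    est.fit(grid10.reshape(-1, 1), PigmentTemplate(470.0)(grid10))
    assert est.lambda_max_ == pytest.approx(470.0, abs=0.1)
    pred = est.predict(grid10.reshape(-1, 1))
    assert pred.max() == pytest.approx(1.0, abs=1e-4)
    assert est.get_params()["family"] == "govardovskii_a1"


def test_normalization_invariant_through_pipeline(grid10):
    """Every pipeline product is max-normalized to exactly 1."""
    flashes = flashes_from_template(grid10, 390.0)
    sens = derive_sensitivity(flashes, PARAMS, FluxCalibration.flat(grid10))
    assert sens.sensitivity.max() == 1.0
    avg = average_cells([sens, sens])
    assert avg.sensitivity.max() == 1.0
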