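"""Bead calibration: localization, sphere height mapping, exponential fits,
and the end-to-end sucrose-to-water chain on synthetic ground truth."""

import numpy as np
import pytest

from evanstim import (
    BeadSpec,
    LocalizationFailure,
    ValidationError,
    convert_penetration_depth,
    fit_bead_center,
    fit_penetration_depth,
    pixel_heights,
    run_bead_calibration,
)
from evanstim.exceptions import FitFailure
from evanstim.synthetic import ExcitationStripe, NoiseModel, generate_bead_image

NOISELESS = NoiseModel(shot_noise=False, read_noise_sd_counts=0.0, offset_counts=50.0, seed=0)


def medium_depth_for_water_target(d_p_water_nm: float, medium_index: float) -> float:
    """Depth the field has in the immersion medium when its water-frame depth
    is the given value — the inverse of the calibration's conversion step."""
    return convert_penetration_depth(d_p_water_nm, 1.340, medium_index, 491.0).d_p_nm


class TestFitBeadCenter:
    def test_noiseless_gaussian_blob_subpixel(self):
        yy, xx = np.mgrid[0:128, 0:128]
        frame = 500.0 * np.exp(-((xx - 50.25) ** 2 + (yy - 71.75) ** 2) / (2 * 9.0**2)) + 20.0
        c = fit_bead_center(frame)
        assert c.center_xy_px[0] == pytest.approx(50.25, abs=0.05)
        assert c.center_xy_px[1] == pytest.approx(71.75, abs=0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_bead_center_within_half_pixel(self, seed):
        image, truth = generate_bead_image(
            BeadSpec(), d_p_true_nm=80.0, peak_counts=2.5e3,
            center_px=(60.3, 67.8), noise=NoiseModel(seed=seed),
        )
        c = fit_bead_center(image)
        assert abs(c.center_xy_px[0] - 60.3) < 0.5
        assert abs(c.center_xy_px[1] - 67.8) < 0.5

    def test_blank_frame_fails_localization(self):
        rng = np.random.default_rng(0)
        with pytest.raises(LocalizationFailure):
            fit_bead_center(rng.normal(100.0, 2.0, (64, 64)).clip(0))


class TestPixelHeights:
    def test_sphere_geometry_closed_form(self):
        bead = BeadSpec(diameter_um=7.38)
        heights, valid = pixel_heights((50.0, 50.0), bead, 0.1, (101, 101))
        radius_nm = 3.69e3
        assert heights[50, 50] == 0.0  # contact point
        # r = 0.6 R => y = 0.2 R (3-4-5 triangle)
        r_px = 0.6 * 36.9
        y = np.interp(r_px, np.arange(51), heights[50, 50:])
        assert y == pytest.approx(0.2 * radius_nm, rel=0.01)
        # beyond the equator the sphere no longer covers the pixel
        assert not valid[50, 99]
        assert np.isnan(heights[50, 99])

    def test_rotational_symmetry_preserves_fit(self):
        image, _ = generate_bead_image(BeadSpec(), d_p_true_nm=57.0, noise=NOISELESS)
        frame = image.data[0]
        heights, valid = pixel_heights((63.5, 63.5), BeadSpec(), 0.11, frame.shape)
        h, c = heights[valid], frame[valid]
        fit = fit_penetration_depth(h, c)
        perm = np.random.default_rng(1).permutation(h.size)
        fit_perm = fit_penetration_depth(h[perm], c[perm])
        assert fit_perm.d_p_nm == pytest.approx(fit.d_p_nm, rel=1e-9)


class TestFitPenetrationDepth:
    def test_noiseless_exact_recovery(self):
        y = np.linspace(0.0, 400.0, 200)
        counts = 2500.0 * np.exp(-y / 57.0) + 30.0
        fit = fit_penetration_depth(y, counts)
        assert fit.d_p_nm == pytest.approx(57.0, rel=1e-6)
        assert fit.reliable

    def test_noisy_recovery_rate(self):
        # Poisson noise at the platform's ~2.5e3 peak counts: d_p within 10%
        # in at least 18 of 20 seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.linspace(0.0, 480.0, 400)
            counts = rng.poisson(2500.0 * np.exp(-y / 80.0) + 30.0)
            fit = fit_penetration_depth(y, counts.astype(float))
            hits += abs(fit.d_p_nm - 80.0) < 0.10 * 80.0
        assert hits >= 18

    def test_constant_counts_degenerate(self):
        y = np.linspace(0.0, 400.0, 100)
        counts = np.full(100, 500.0)
        try:
            fit = fit_penetration_depth(y, counts)
        except FitFailure:
            return  # acceptable outcome for a flat profile
        assert not fit.reliable

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValidationError):
            fit_penetration_depth(np.arange(10.0), np.arange(10.0))


class TestRunBeadCalibration:
    # the waveguide case is measured in index-matched sucrose and converted;
    # the objective-TIRF reference is measured in the aqueous chamber directly
    @pytest.mark.parametrize(
        "d_p_water, medium_index", [(57.0, 1.450), (80.0, 1.340)]
    )
    def test_noiseless_water_depth_recovery(self, d_p_water, medium_index):
        d_p_medium = medium_depth_for_water_target(d_p_water, medium_index)
        image, _ = generate_bead_image(BeadSpec(), d_p_true_nm=d_p_medium, noise=NOISELESS)
        fit = run_bead_calibration(
            image, BeadSpec(), medium_index=medium_index, wavelength_nm=491.0
        )
        assert fit.d_p_water_nm == pytest.approx(d_p_water, rel=0.05)
        assert fit.d_p_measured_nm == pytest.approx(d_p_medium, rel=0.05)
        assert fit.n_pixels_used >= 30

    def test_conversion_leaves_medium_fit_untouched(self):
        image, _ = generate_bead_image(BeadSpec(), d_p_true_nm=96.8, noise=NOISELESS)
        a = run_bead_calibration(image, BeadSpec(), medium_index=1.450, wavelength_nm=491.0)
        b = run_bead_calibration(
            image, BeadSpec(), medium_index=1.450, wavelength_nm=491.0, water_index=1.38
        )
        assert a.d_p_measured_nm == b.d_p_measured_nm
        assert a.d_p_water_nm != b.d_p_water_nm

    def test_stripe_restricted_fit_is_unbiased(self):
        # a bead on the waveguide edge is excited in an elliptical sector;
        # fitting only the stripe-covered pixels must not bias d_p beyond
        # its own standard error (noiseless: agreement is tight)
        stripe = ExcitationStripe(center_px=55.0, width_um=4.5)
        image, _ = generate_bead_image(
            BeadSpec(), d_p_true_nm=96.8, excitation_stripe=stripe, noise=NOISELESS
        )
        mask = stripe.mask(image.data[0].shape, image.pixel_size_um)
        # the excited region is elliptical: narrower across the stripe
        excited = image.data[0] > 100.0
        rows = np.ptp(np.nonzero(excited.any(axis=1))[0])
        cols = np.ptp(np.nonzero(excited.any(axis=0))[0])
        assert rows < cols
        fit = run_bead_calibration(
            image, BeadSpec(), medium_index=1.450, wavelength_nm=491.0,
            stripe_mask=mask, approximate_center_px=(63.5, 63.5),
        )
        assert fit.d_p_measured_nm == pytest.approx(96.8, rel=0.05)

    def test_bias_vanishes_with_noise(self):
        # estimator consistency: median |bias| shrinks as shot noise scales down
        biases = []
        for scale in (1.0, 10.0, 100.0):
            errs = []
            for seed in range(5):
                rng_noise = NoiseModel(seed=seed, read_noise_sd_counts=0.0, offset_counts=30.0)
                image, _ = generate_bead_image(
                    BeadSpec(), d_p_true_nm=96.8, peak_counts=2.5e3 * scale, noise=rng_noise
                )
                fit = run_bead_calibration(
                    image, BeadSpec(), medium_index=1.450, wavelength_nm=491.0
                )
                errs.append(abs(fit.d_p_measured_nm - 96.8))
            biases.append(np.median(errs))
        assert biases[2] < biases[0]

    def test_missing_pixel_size_names_field(self):
        image, _ = generate_bead_image(BeadSpec(), d_p_true_nm=80.0, noise=NOISELESS)
        image.pixel_size_um = None
        with pytest.raises(ValidationError, match="pixel_size_um"):
            run_bead_calibration(image, BeadSpec(), medium_index=1.45, wavelength_nm=491.0)

    def test_no_bead_raises_localization_failure(self):
        from evanstim import OpticalStack

        rng = np.random.default_rng(3)
        blank = OpticalStack(
            rng.normal(100, 2, (128, 128)).clip(0), frame_interval_s=None, pixel_size_um=0.11
        )
        with pytest.raises(LocalizationFailure):
            run_bead_calibration(blank, BeadSpec(), medium_index=1.45, wavelength_nm=491.0)
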