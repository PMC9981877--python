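"""Pupil/source construction, WOTF kernels and closed-form instrument formulas."""

import math

import numpy as np
import pytest

from uvqdpc.optics import (
    AcquisitionConfig,
    ConfigurationError,
    DegenerateSourceError,
    SourceDistribution,
    coherence_length,
    compute_wotf,
    depth_of_field,
    linepair_resolution,
    make_annular_pupil,
    make_halfring_source,
    power_budget,
    theoretical_resolution,
)


class TestAnnularPupil:
    def test_area_fraction_matches_analytic_annulus(self, config, pupil):
        """Pixel count of the annulus tracks 1 - (NA_obs/NA)^2 of the disc."""
        full = make_annular_pupil(config.with_(na_obs=1e-9))
        frac = np.abs(pupil.values).sum() / np.abs(full.values).sum()
        expected = 1.0 - (config.na_obs / config.na) ** 2
        assert frac == pytest.approx(expected, abs=0.01)

    def test_outer_edge_is_closed(self, config):
        """A frequency exactly at NA/lambda lies inside the support."""
        pup = make_annular_pupil(config)
        radius_px = (config.na / config.wavelength) / pup.frequency_step
        # pick the on-axis pixel closest to (but not beyond) the cutoff
        col = 128 + int(math.floor(radius_px))
        assert np.abs(pup.values[128, col]) == 1.0

    def test_zero_outside_and_inside(self, config, pupil):
        rho = pupil.radius_grid()
        assert not np.any(np.abs(pupil.values[rho > config.na / config.wavelength + 1e-12]))
        assert not np.any(np.abs(pupil.values[rho < config.na_obs / config.wavelength - 1e-12]))

    def test_obscuration_geq_na_rejected(self, config):
        with pytest.raises(ConfigurationError):
            make_annular_pupil(config.with_(na_obs=0.7))


class TestHalfRingSource:
    def test_opposite_halves_tile_the_annulus(self, small_pupil):
        s0 = make_halfring_source(small_pupil, 0.0)
        s180 = make_halfring_source(small_pupil, 180.0)
        union = (s0.values > 0) | (s180.values > 0)
        annulus = np.abs(small_pupil.values) > 0
        assert np.array_equal(union, annulus)
        # overlap only on the dividing line (both include boundary pixels)
        overlap = (s0.values > 0) & (s180.values > 0)
        cols = np.nonzero(overlap.any(axis=0))[0]
        assert set(cols) <= {32}

    def test_four_orientations_cover_annulus_twice(self, small_pupil):
        total = sum(
            make_halfring_source(small_pupil, a).values for a in (0, 90, 180, 270)
        )
        annulus = np.abs(small_pupil.values)
        interior = annulus.astype(bool) & (total > 0)
        # away from the dividing lines every annulus pixel is covered twice
        assert np.all(total[interior] >= 2 * annulus[interior] - 1e-12)

    def test_flat_weight_equals_masked_pupil(self, small_pupil):
        src = make_halfring_source(small_pupil, 30.0, radial_weight=None)
        masked = src.values > 0
        assert np.allclose(src.values[masked], np.abs(small_pupil.values)[masked])

    def test_source_energy_never_exceeds_pupil_energy(self, small_pupil):
        for angle in (0, 37, 90, 211):
            src = make_halfring_source(small_pupil, angle)
            assert src.values.sum() <= np.abs(small_pupil.values).sum() + 1e-9


class TestWOTF:
    def test_zero_frequency_values(self, small_pupil):
        """h_ph(0) = 0 and h_abs(0) = -2B for any source."""
        for angle in (0.0, 45.0, 270.0):
            tf = compute_wotf(make_halfring_source(small_pupil, angle), small_pupil)
            c = (32, 32)
            assert tf.h_ph[c] == pytest.approx(0.0, abs=1e-10 * tf.background)
            assert tf.h_abs[c].real == pytest.approx(-2 * tf.background, rel=1e-10)

    def test_symmetric_source_kills_phase_transfer(self, small_pupil):
        full = SourceDistribution(
            values=np.abs(small_pupil.values),
            orientation=np.array([1.0, 0.0]),
            frequency_step=small_pupil.frequency_step,
        )
        tf = compute_wotf(full, small_pupil)
        assert np.abs(tf.h_ph).max() <= 1e-10 * tf.background

    def test_kernel_symmetries(self, small_pupil):
        """For a real pupil/source: h_abs is real and even, h_ph imaginary
        and odd under u -> -u (both are spectra of real-valued kernels)."""
        tf = compute_wotf(make_halfring_source(small_pupil, 30.0), small_pupil)

        def flipped(a):
            # u -> -u about the centered origin (drop the unpaired edge row/col)
            return a[1:, 1:][::-1, ::-1]

        scale = tf.background
        assert np.abs(tf.h_abs.imag).max() < 1e-10 * scale
        assert np.abs(tf.h_ph.real).max() < 1e-10 * scale
        assert np.allclose(tf.h_abs[1:, 1:], np.conj(flipped(tf.h_abs)), atol=1e-9 * scale)
        assert np.allclose(tf.h_ph[1:, 1:], -flipped(tf.h_ph), atol=1e-9 * scale)

    def test_halfring_at_zero_h_ph_odd_along_x_even_along_y(self, small_pupil):
        tf = compute_wotf(make_halfring_source(small_pupil, 0.0), small_pupil)
        h = tf.h_ph[1:, 1:]  # symmetric index range about the center
        assert np.allclose(h, -h[:, ::-1], atol=1e-9)  # odd along u_x
        assert np.allclose(h, h[::-1, :], atol=1e-9)  # even along u_y

    def test_rotational_covariance_quarter_turn(self, small_pupil):
        """The 90-degree WOTF is the 0-degree one rotated by 90 degrees."""
        tf0 = compute_wotf(make_halfring_source(small_pupil, 0.0), small_pupil)
        tf90 = compute_wotf(make_halfring_source(small_pupil, 90.0), small_pupil)
        # +90 deg rotation in (x, y-up) maps arrays via rot90 on the
        # symmetric sub-grid
        r0 = tf0.h_abs[1:, 1:]
        r90 = tf90.h_abs[1:, 1:]
        assert np.allclose(np.rot90(r0, 1), r90, atol=1e-9 * tf0.background)

    def test_empty_source_rejected(self, small_pupil):
        src = SourceDistribution(
            values=np.zeros_like(np.abs(small_pupil.values)),
            orientation=np.array([1.0, 0.0]),
            frequency_step=small_pupil.frequency_step,
        )
        with pytest.raises(DegenerateSourceError):
            compute_wotf(src, small_pupil)


class TestClosedFormFormulas:
    def test_depth_of_field_printed_value(self):
        """Truncated Ewald sphere at the instrument parameters: 1.355 um."""
        cfg = AcquisitionConfig(wavelength=275.0, na=0.65, na_obs=0.27, n_medium=1.0)
        assert depth_of_field(cfg) == pytest.approx(1.355, abs=5e-4)

    def test_depth_of_field_low_na_asymptote(self):
        """NA_obs=0, small NA: Delta z -> 2 n lambda / NA^2 within 0.5%."""
        cfg = AcquisitionConfig(wavelength=275.0, na=0.05, na_obs=0.0)
        asymptote = 2 * 275.0 / 0.05**2 * 1e-3
        assert depth_of_field(cfg) == pytest.approx(asymptote, rel=5e-3)

    def test_depth_of_field_degenerate_and_domain_errors(self):
        with pytest.raises((ZeroDivisionError, ConfigurationError)):
            depth_of_field(AcquisitionConfig(na=0.65, na_obs=0.65))
        with pytest.raises(ConfigurationError):
            depth_of_field(AcquisitionConfig(na=1.2, n_medium=1.0))

    def test_depth_of_field_monotonicity(self):
        """Decreasing in NA; increasing in NA_obs."""
        dz_na = [
            depth_of_field(AcquisitionConfig(na=na, na_obs=0.1))
            for na in np.linspace(0.2, 0.9, 8)
        ]
        assert all(a > b for a, b in zip(dz_na, dz_na[1:]))
        dz_obs = [
            depth_of_field(AcquisitionConfig(na=0.65, na_obs=o))
            for o in np.linspace(0.0, 0.6, 7)
        ]
        assert all(a < b for a, b in zip(dz_obs, dz_obs[1:]))

    @pytest.mark.parametrize(
        "wavelength,na,expected",
        [(275.0, 0.65, 211.5), (550.0, 0.65, 423.1), (500.0, 1.0, 250.0)],
    )
    def test_theoretical_resolution(self, wavelength, na, expected):
        cfg = AcquisitionConfig(wavelength=wavelength, na=na, n_medium=1.5)
        assert theoretical_resolution(cfg) == pytest.approx(expected, abs=0.05)

    def test_resolution_rounds_to_printed_212(self):
        assert round(theoretical_resolution(AcquisitionConfig())) == 212

    @pytest.mark.parametrize("lp,period", [(3300, 303), (1000, 1000), (2000, 500)])
    def test_linepair_resolution(self, lp, period):
        assert linepair_resolution(lp) == period

    def test_coherence_length(self):
        assert coherence_length(
            AcquisitionConfig(bandwidth=11.1)
        ) == pytest.approx(6.81, abs=0.01)
        # the nominal 10 nm bandwidth gives a longer value under L = l^2/dl
        assert coherence_length(AcquisitionConfig(bandwidth=10.0)) == pytest.approx(
            7.56, abs=0.01
        )
        assert coherence_length(
            AcquisitionConfig(wavelength=275.0, bandwidth=275.0)
        ) == pytest.approx(0.275, abs=1e-9)

    def test_power_budget_printed_value(self):
        p = power_budget(80, 0.5, 0.5, 0.27, 0.65, 0.55, 2)
        assert p == pytest.approx(0.205, abs=0.005)

    def test_power_budget_identity_and_zero(self):
        assert power_budget(80, 1, 1, 0.65, 0.65, 2 / math.sqrt(math.pi), 1) == (
            pytest.approx(80.0)
        )
        assert power_budget(80, 0.0, 0.5, 0.27, 0.65, 0.55, 2) == 0.0

    def test_nyquist_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            AcquisitionConfig(pixel_size_sample=200.0)
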