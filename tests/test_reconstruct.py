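"""Flat-field correction, Tikhonov retrieval and extinction conversion."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from uvqdpc.forward import DPCStack, acquire_stack, forward_wotf
from uvqdpc.optics import (
    AcquisitionConfig,
    compute_wotf,
    make_annular_pupil,
    make_halfring_source,
)
from uvqdpc.phantom import EffectiveObject, make_lsec_phantom, phantom_to_effective_object
from uvqdpc.reconstruct import (
    RegularizationRequiredError,
    bandlimit,
    flatfield_correct,
    mu_to_k,
    reconstruct_stack,
    solve_qdpc,
)


def _hf_energy(k_map, config, frac=0.5):
    """Spectral energy above half the incoherent cutoff."""
    F = np.fft.fft2(k_map)
    fy = np.fft.fftfreq(k_map.shape[0], config.pixel_size_sample)
    fx = np.fft.fftfreq(k_map.shape[1], config.pixel_size_sample)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    mask = np.hypot(FY, FX) > frac * 2 * config.na / config.wavelength
    return float(np.sum(np.abs(F[mask]) ** 2))


class TestFlatfield:
    def test_image_equals_background_gives_zero(self, config):
        imgs = [np.full((16, 16), 2.0)] * 2
        stack = DPCStack(imgs, [i.copy() for i in imgs], [0.0, 90.0], config)
        for d in flatfield_correct(stack):
            assert np.allclose(d, 0.0)

    def test_ten_percent_excess_gives_constant(self, config):
        bg = np.full((16, 16), 2.0)
        stack = DPCStack([1.1 * bg] * 2, [bg] * 2, [0.0, 90.0], config)
        for d in flatfield_correct(stack):
            assert np.allclose(d, 0.1)

    def test_linear_in_image_for_fixed_background(self, config, rng):
        bg = np.full((16, 16), 2.0)
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        s = lambda img: DPCStack([img] * 2, [bg] * 2, [0.0, 90.0], config)
        d_sum = flatfield_correct(s(3 * i1 + 2 * i2))[0]
        d1 = flatfield_correct(s(i1))[0]
        d2 = flatfield_correct(s(i2))[0]
        # correct(aI1 + bI2) = a d1 + b d2 + (a + b - 1) since d = I/B - 1
        assert np.allclose(d_sum, 3 * d1 + 2 * d2 + 4.0)


@pytest.fixture(scope="module")
def known_fields(small_config):
    rng = np.random.default_rng(0)
    phi = bandlimit(gaussian_filter(rng.normal(size=(64, 64)), 3), small_config) * 0.2
    mu = np.abs(bandlimit(gaussian_filter(rng.normal(size=(64, 64)), 3), small_config)) * 0.1
    return EffectiveObject(phi=phi, mu=mu)


@pytest.fixture(scope="module")
def forward_diffs(known_fields, small_config, small_pupil):
    diffs, tfs = [], []
    for angle in (0.0, 90.0, 180.0, 270.0):
        src = make_halfring_source(small_pupil, angle)
        diffs.append(forward_wotf(known_fields, src, small_pupil, small_config) - 1.0)
        tfs.append(compute_wotf(src, small_pupil))
    return diffs, tfs


def _project_on_transfer_support(arr, tfs):
    """Keep only frequencies the discrete transfer functions actually carry."""
    sup = sum(np.abs(np.fft.ifftshift(t.h_abs)) ** 2 for t in tfs)
    sup = sup + sum(np.abs(np.fft.ifftshift(t.h_ph)) ** 2 for t in tfs)
    mask = sup > 1e-9 * sup.max()
    return np.fft.ifft2(np.fft.fft2(arr) * mask).real


class TestSolveQdpc:
    def test_round_trip_recovers_both_maps(
        self, known_fields, forward_diffs, small_config
    ):
        """Noise-free forward -> inverse with tiny tau: < 1% in-band error
        (phase compared after mean removal; its DC term has no transfer).
        In-band means the support of the discrete transfer functions."""
        diffs, tfs = forward_diffs
        phi_r, mu_r = solve_qdpc(diffs, tfs, 1e-6, 1e-6, config=small_config)
        mu_t = _project_on_transfer_support(known_fields.mu, tfs)
        phi_t = _project_on_transfer_support(known_fields.phi, tfs)
        mu_r = _project_on_transfer_support(mu_r, tfs)
        phi_r = _project_on_transfer_support(phi_r, tfs)
        err_mu = np.sqrt(np.mean((mu_r - mu_t) ** 2) / np.mean(mu_t**2))
        pr, pt = phi_r - phi_r.mean(), phi_t - phi_t.mean()
        err_phi = np.sqrt(np.mean((pr - pt) ** 2) / np.mean(pt**2))
        assert err_mu < 0.01
        assert err_phi < 0.01

    def test_zero_diffs_give_zero_maps(self, forward_diffs, small_config):
        _, tfs = forward_diffs
        zeros = [np.zeros((64, 64))] * 4
        phi, mu = solve_qdpc(zeros, tfs, 1.0, 1.0, config=small_config)
        assert not np.any(phi) and not np.any(mu)

    def test_infinite_regularization_suppresses_everything(
        self, forward_diffs, small_config
    ):
        diffs, tfs = forward_diffs
        phi, mu = solve_qdpc(diffs, tfs, 1e12, 1e12, config=small_config)
        assert np.abs(phi).max() < 1e-6
        assert np.abs(mu).max() < 1e-6

    def test_unregularized_solve_is_singular(self, forward_diffs):
        diffs, tfs = forward_diffs
        with pytest.raises(RegularizationRequiredError):
            solve_qdpc(diffs, tfs, 0.0, 0.0)

    def test_linearity_in_the_data(self, forward_diffs, small_config, rng):
        """Reconstruction of a sum of diffs equals sum of reconstructions."""
        diffs, tfs = forward_diffs
        other = [gaussian_filter(rng.normal(size=(64, 64)), 4) * 0.01 for _ in range(4)]
        both = [a + b for a, b in zip(diffs, other)]
        r_both = solve_qdpc(both, tfs, 300.0, 300.0, config=small_config)
        r_a = solve_qdpc(diffs, tfs, 300.0, 300.0, config=small_config)
        r_b = solve_qdpc(other, tfs, 300.0, 300.0, config=small_config)
        for i in range(2):
            assert np.allclose(r_both[i], r_a[i] + r_b[i], atol=1e-9)


class TestMuToK:
    def test_hand_value(self):
        """mu = 0.0210 over L = 1355 nm at 275 nm -> k = 3.4e-4."""
        k = mu_to_k(np.array([0.0210]), AcquisitionConfig(), path_length_nm=1355.0)
        assert k[0] == pytest.approx(3.4e-4, rel=0.01)

    def test_zero_and_inverse_proportionality(self):
        cfg = AcquisitionConfig()
        assert mu_to_k(np.zeros(3), cfg)[0] == 0.0
        mu = np.array([0.02])
        assert mu_to_k(mu, cfg, 500.0)[0] == pytest.approx(
            2 * mu_to_k(mu, cfg, 1000.0)[0]
        )

    def test_default_path_is_depth_of_field(self):
        cfg = AcquisitionConfig()
        assert mu_to_k(np.array([0.0210]), cfg)[0] == pytest.approx(
            mu_to_k(np.array([0.0210]), cfg, 1355.2)[0], rel=1e-3
        )


class TestReconstructStack:
    def test_recovered_extinction_correlates_with_truth(
        self, lsec_recon, lsec_phantom, config
    ):
        """Moderate tau = 300: recovered k map tracks the phantom's truth."""
        truth = bandlimit(lsec_phantom.k_map, config)
        r = np.corrcoef(lsec_recon.k_map.ravel(), truth.ravel())[0, 1]
        assert r > 0.9

    def test_background_only_stack_is_flat(self, config):
        ph = make_lsec_phantom(seed=0, n_clusters=0)
        ph.k_map[:] = 0
        ph.delta_n[:] = 0
        ph.thickness[:] = 0
        stack = acquire_stack(ph, config)
        rec = reconstruct_stack(stack, tau_abs=300.0, tau_ph=300.0)
        assert np.abs(rec.k_map).max() < 1e-6

    def test_tau_sweep_monotonically_smooths(self, lsec_stack, config):
        """Raising tau from 100 to 1000 strictly lowers high-frequency energy."""
        energies = [
            _hf_energy(
                reconstruct_stack(lsec_stack, tau_abs=t, tau_ph=t).k_map, config
            )
            for t in (100.0, 300.0, 600.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_median_extinction_ordering(self, lsec_recon, lsec_phantom):
        """Median recovered k: background < membrane < nucleus."""
        labels = lsec_phantom.truth_labels
        med = [float(np.median(lsec_recon.k_map[labels == i])) for i in (0, 1, 2)]
        assert med[0] < med[1] < med[2]

    def test_noise_degrades_gracefully(self, lsec_phantom, config):
        """Recovery error is non-decreasing in the noise level."""
        obj = phantom_to_effective_object(lsec_phantom, config)
        truth = bandlimit(obj.mu, config)
        errors = []
        for photons in (None, 1e6, 1e4):
            stack = acquire_stack(lsec_phantom, config, noise_photons=photons, seed=1)
            rec = reconstruct_stack(stack, tau_abs=300.0, tau_ph=300.0)
            errors.append(float(np.sqrt(np.mean((rec.mu - truth) ** 2))))
        assert errors[0] <= errors[1] <= errors[2]

    def test_parameters_recorded(self, lsec_recon):
        assert lsec_recon.tau_abs == 300.0
        assert lsec_recon.tau_ph == 300.0
        assert lsec_recon.path_length_nm > 0
        assert lsec_recon.orientations_deg == [0.0, 90.0, 180.0, 270.0]
        # invariant: k = mu * lambda / (4 pi L) pixelwise
        lam = lsec_recon.config.wavelength
        assert np.allclose(
            lsec_recon.k_map,
            lsec_recon.mu * lam / (4 * np.pi * lsec_recon.path_length_nm),
        )
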