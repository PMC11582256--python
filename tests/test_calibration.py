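"""Map estimation: CSMs, phase-sensitive combination, noise covariance."""

import numpy as np
import pytest
from scipy import ndimage

from synthraw import calibration, core_data, phantoms
from synthraw.calibration import (
    CoilSensitivityMaps,
    NoiseCovariance,
    decompose_scan,
    estimate_csm,
    estimate_noise_cov,
    find_background_region,
    normalize_csm_phase,
    phase_sensitive_combine,
)
from synthraw.core_data import MultiCoilKSpace, fft2c, ifft2c, rss_combine


def _interior_support(csm_est, magnitude):
    """Support interior: estimated support ∩ object, eroded to drop the
    partial-volume boundary ring."""
    sup = csm_est.support_mask & (magnitude > 0.05 * magnitude.max())
    return ndimage.binary_erosion(sup, iterations=2)


class TestEstimateCSM:
    def test_recovers_ground_truth_maps(self, noiseless_scan):
        scan, triplets = noiseless_scan
        est = estimate_csm(scan.kspace[0], calib_lines=26)
        m = triplets[0].magnitude.data
        sup = _interior_support(est, m)
        c_est = est.data[:, sup]
        c_true = triplets[0].csm.data[:, sup]
        g = np.vdot(c_est, c_true)
        g /= abs(g)  # one global phase is unconstrained
        rel = np.abs(c_est * g - c_true) / np.maximum(np.abs(c_true), 1e-9)
        assert rel.max() < 0.05

    def test_single_uniform_coil_gives_unit_map(self, spec64):
        m = phantoms.make_magnitude(spec64, 0)
        ks = MultiCoilKSpace(fft2c(m.data.astype(complex))[None])
        est = estimate_csm(ks, calib_lines=26)
        assert np.allclose(est.data[0][est.support_mask], 1.0, atol=1e-10)

    def test_unit_rss_inside_support(self, noiseless_scan):
        scan, _ = noiseless_scan
        est = estimate_csm(scan.kspace[1], calib_lines=26)
        rss = np.sqrt(np.sum(np.abs(est.data) ** 2, axis=0))
        assert np.allclose(rss[est.support_mask], 1.0, atol=1e-6)
        assert np.all(rss[~est.support_mask] == 0.0)

    def test_all_zero_kspace_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_csm(MultiCoilKSpace(np.zeros((2, 64, 64), dtype=complex)), 26)

    def test_calib_lines_bounds(self, noiseless_scan):
        scan, _ = noiseless_scan
        with pytest.raises(ValueError):
            estimate_csm(scan.kspace[0], calib_lines=4)
        with pytest.raises(ValueError):
            estimate_csm(scan.kspace[0], calib_lines=128)


class TestPhaseSensitiveCombine:
    def test_magnitude_matches_rss_with_exact_maps(self, noiseless_scan):
        scan, triplets = noiseless_scan
        coil_images = ifft2c(scan.kspace[0].data)
        combined = phase_sensitive_combine(coil_images, triplets[0].csm)
        rss = rss_combine(coil_images)
        sup = triplets[0].magnitude.data > 0.05
        assert np.allclose(np.abs(combined)[sup], rss[sup], rtol=1e-6)

    def test_phase_matches_object_phase(self, noiseless_scan):
        scan, triplets = noiseless_scan
        coil_images = ifft2c(scan.kspace[0].data)
        combined = phase_sensitive_combine(coil_images, triplets[0].csm)
        sup = triplets[0].magnitude.data > 0.05
        est = combined[sup] / np.abs(combined[sup])
        true = triplets[0].phase.data[sup]
        g = np.vdot(est, true)
        g /= abs(g)
        assert np.abs(np.angle(est * g * np.conj(true))).max() < 1e-3

    def test_identity_for_unit_single_coil(self):
        rng = np.random.default_rng(4)
        img = (rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16)))
        csm = CoilSensitivityMaps(np.ones((1, 16, 16), dtype=complex),
                                  np.ones((16, 16), dtype=bool))
        assert np.array_equal(phase_sensitive_combine(img, csm), img[0])

    def test_shape_mismatch_rejected(self, noiseless_scan):
        scan, triplets = noiseless_scan
        with pytest.raises(ValueError, match="shape"):
            phase_sensitive_combine(np.zeros((2, 8, 8), dtype=complex), triplets[0].csm)


class TestNormalizeCSMPhase:
    def test_idempotent(self, noiseless_scan):
        _, triplets = noiseless_scan
        once = normalize_csm_phase(triplets[0].csm)
        twice = normalize_csm_phase(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_phase_removed(self):
        maps = np.ones((2, 16, 16), dtype=complex) * np.exp(0.7j)
        csm = CoilSensitivityMaps(maps / np.sqrt(2), np.ones((16, 16), dtype=bool))
        out = normalize_csm_phase(csm)
        assert np.allclose(np.angle(out.data[0]), 0.0, atol=1e-12)

    def test_mean_phase_zero_after_call(self, spec64):
        csm = phantoms.make_csms(spec64, 9)
        rotated = CoilSensitivityMaps(csm.data * np.exp(1.3j), csm.support_mask)
        out = normalize_csm_phase(rotated)
        coil0 = out.data[0][out.support_mask]
        mean_dir = np.mean(coil0 / np.abs(coil0))
        assert abs(np.angle(mean_dir)) < 1e-6

    def test_preserves_magnitudes_exactly(self, spec64):
        csm = phantoms.make_csms(spec64, 2)
        out = normalize_csm_phase(csm)
        assert np.array_equal(np.abs(out.data), np.abs(csm.data))


class TestNoiseCovariance:
    def test_identity_covariance_recovered(self):
        # 400 complex samples of 4 i.i.d. unit-variance coils
        rng = np.random.default_rng(2024)
        noise = (rng.standard_normal((4, 20, 20))
                 + 1j * rng.standard_normal((4, 20, 20))) / np.sqrt(2)
        est = estimate_noise_cov(noise, region=(0, 0, 20, 20))
        assert np.linalg.norm(est.matrix - np.eye(4)) < 0.25

    def test_zero_region_gives_zero_matrix(self):
        est = estimate_noise_cov(np.zeros((3, 32, 32), dtype=complex),
                                 region=(0, 0, 20, 20))
        assert np.all(est.matrix == 0)

    def test_off_diagonal_correlation_recovered(self):
        rho, n_rep = 0.5, 50
        phi = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(phi)
        rng = np.random.default_rng(77)
        estimates = []
        for _ in range(n_rep):
            z = (rng.standard_normal((2, 400)) + 1j * rng.standard_normal((2, 400)))
            z /= np.sqrt(2)
            x = (chol @ z).reshape(2, 20, 20)
            estimates.append(estimate_noise_cov(x, region=(0, 0, 20, 20)).matrix[0, 1])
        mean_est = np.mean(np.real(estimates))
        se = np.std(np.real(estimates), ddof=1) / np.sqrt(n_rep)
        assert abs(mean_est - rho) < 3 * se + 1e-9

    def test_region_out_of_bounds(self):
        with pytest.raises(ValueError, match="out of bounds"):
            estimate_noise_cov(np.zeros((2, 32, 32), dtype=complex),
                               region=(20, 20, 20, 20))

    def test_error_decreases_with_region_size(self):
        # convergence of the sample covariance: 10x10 vs 40x40 patches
        rng = np.random.default_rng(5)
        errs = {10: [], 40: []}
        for _ in range(50):
            noise = (rng.standard_normal((2, 40, 40))
                     + 1j * rng.standard_normal((2, 40, 40))) / np.sqrt(2)
            for size in (10, 40):
                est = estimate_noise_cov(noise, region=(0, 0, size, size))
                errs[size].append(np.linalg.norm(est.matrix - np.eye(2)))
        assert np.mean(errs[40]) < np.mean(errs[10])

    def test_corner_search_picks_quietest_corner(self, spec64):
        scan, _ = phantoms.make_scan(spec64, 1, seed=3)
        coil_images = ifft2c(scan.kspace[0].data)
        y0, x0, h, w = find_background_region(coil_images)
        assert (h, w) == (20, 20)
        assert y0 in (0, 44) and x0 in (0, 44)

    def test_hermitian_psd_enforced(self):
        with pytest.raises(ValueError):
            NoiseCovariance(np.array([[1.0, 1.0j], [1.0j, 1.0]]))


class TestDecomposeScan:
    def test_deterministic(self, noiseless_scan):
        scan, _ = noiseless_scan
        a = decompose_scan(scan)
        b = decompose_scan(scan)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.magnitude.data, tb.magnitude.data)
            assert np.array_equal(ta.csm.data, tb.csm.data)

    def test_magnitude_non_negative(self, noiseless_scan):
        scan, _ = noiseless_scan
        for trip in decompose_scan(scan):
            assert np.all(trip.magnitude.data >= 0)

    def test_recomposition_preserves_rss(self, noiseless_scan):
        from synthraw.synthesis import synthesize_raw

        scan, _ = noiseless_scan
        trip = decompose_scan(scan)[0]
        zero_phi = NoiseCovariance(np.zeros((scan.n_coils, scan.n_coils)))
        resynth = synthesize_raw(trip.magnitude, trip.phase, trip.csm, zero_phi, 0)
        rss_orig = rss_combine(ifft2c(scan.kspace[0].data))
        rss_back = rss_combine(ifft2c(resynth.data))
        sup = trip.csm.support_mask & (rss_orig > 0.05 * rss_orig.max())
        rel = np.abs(rss_back[sup] - rss_orig[sup]) / rss_orig[sup]
        assert rel.max() < 0.02
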