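"""LCMV beamformer: covariance, weights, orientation, images, VEs."""

import numpy as np
import pytest

from opmpipe import beamform, forward, preprocess, synth
from opmpipe.data import Recording, TrialSet
from opmpipe.exceptions import EmptySetError, GeometryError

FS = 375.0


class TestCovariance:
    def test_white_noise_diagonal(self, small_array):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((small_array.n_channels, 100_000))
        cov = beamform.compute_covariance(X, band=None, sampling_rate=FS)
        C = cov.matrix
        assert np.abs(np.diag(C) - 1.0).max() < 0.05
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05

    def test_rank_one_data(self, small_array):
        rng = np.random.default_rng(1)
        g = rng.standard_normal(small_array.n_channels)
        X = np.outer(g, rng.standard_normal(5000))
        cov = beamform.compute_covariance(X, band=None, sampling_rate=FS)
        w = np.linalg.eigvalsh(cov.matrix)
        assert w[-1] / w.sum() > 0.99

    def test_duplicated_channel_rows_equal(self, small_array):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 2000))
        X[3] = X[0]
        cov = beamform.compute_covariance(X, band=None, sampling_rate=FS)
        C = cov.matrix
        assert np.allclose(C, C.T)
        assert np.allclose(C[0], C[3])


class TestRegularize:
    def test_identity_scaled(self):
        cov = beamform.Covariance(matrix=np.eye(5), band=(1, 150), n_samples=100,
                                  channel_mask=np.ones(5, bool))
        assert np.allclose(beamform.regularize(cov).matrix, 1.05 * np.eye(5))

    def test_spectrum_shifted_by_fraction_of_lambda_max(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((6, 6))
        C = A @ A.T
        cov = beamform.Covariance(matrix=C, band=None, n_samples=100,
                                  channel_mask=np.ones(6, bool))
        lam = np.linalg.eigvalsh(C)
        lam_reg = np.linalg.eigvalsh(beamform.regularize(cov).matrix)
        assert np.allclose(lam_reg, lam + 0.05 * lam[-1])

    def test_rank_one_condition_number_21(self):
        g = np.arange(1.0, 5.0)
        C = np.outer(g, g)
        cov = beamform.Covariance(matrix=C, band=None, n_samples=10,
                                  channel_mask=np.ones(4, bool))
        lam = np.linalg.eigvalsh(beamform.regularize(cov).matrix)
        assert lam[-1] / lam[0] == pytest.approx(21.0, rel=1e-10)


class TestWeightsAndOrientation:
    def test_unit_gain_constraint(self, small_array):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((small_array.n_channels, small_array.n_channels))
        C = A @ A.T + 10 * np.eye(small_array.n_channels)
        l = forward.leadfield(np.array([0.01, 0.02, 0.05]), small_array)[:, 0]
        w = beamform.lcmv_weights(C, l)
        assert abs(w @ l - 1.0) < 1e-12

    def test_identity_covariance_closed_form(self):
        l = np.array([3.0, 4.0])
        w = beamform.lcmv_weights(np.eye(2), l)
        assert np.allclose(w, l / 25.0)

    def test_zero_leadfield_rejected(self):
        with pytest.raises(GeometryError):
            beamform.lcmv_weights(np.eye(3), np.zeros(3))

    def test_isotropic_noise_orientation_is_leading_singular_vector(self, small_array):
        loc = np.array([-0.02, 0.015, 0.045])
        L = forward.leadfield(loc, small_array)
        t1, t2, _ = forward.tangential_basis(loc, small_array.sphere_origin)
        C = 2.0 * np.eye(small_array.n_channels)
        with pytest.warns(UserWarning):
            eta = beamform.optimal_orientation(C, L, (t1, t2))
        _, _, Vt = np.linalg.svd(L[:, :2], full_matrices=False)
        eta_svd = Vt[0, 0] * t1 + Vt[0, 1] * t2
        assert abs(abs(eta @ eta_svd) - 1.0) < 1e-10
        assert np.linalg.norm(eta) == pytest.approx(1.0, abs=1e-10)
        nz = np.nonzero(np.abs(eta) > 1e-12)[0]
        assert eta[nz[0]] > 0  # deterministic sign

    def test_known_source_orientation_recovered(self, small_array):
        rng = np.random.default_rng(5)
        loc = np.array([-0.025, 0.01, 0.045])
        t1, t2, _ = forward.tangential_basis(loc, small_array.sphere_origin)
        eta_true = (t1 + 0.7 * t2) / np.linalg.norm(t1 + 0.7 * t2)
        g = forward.dipole_field(loc, eta_true, small_array)
        n = 40_000
        X = np.outer(g / np.abs(g).max() * 10, rng.standard_normal(n))
        X += rng.standard_normal(X.shape)
        cov = beamform.regularize(
            beamform.compute_covariance(X, band=None, sampling_rate=FS))
        L = forward.leadfield(loc, small_array)
        eta = beamform.optimal_orientation(cov.matrix, L, (t1, t2))
        assert abs(eta @ eta_true) > 0.99

    def test_interfering_source_suppressed(self, small_array):
        """VE at source A suppresses an uncorrelated source B by >= 20 dB."""
        rng = np.random.default_rng(6)
        locA = np.array([-0.03, 0.0, 0.045])
        locB = np.array([0.03, 0.01, 0.04])
        tA = forward.tangential_basis(locA, small_array.sphere_origin)[0]
        tB = forward.tangential_basis(locB, small_array.sphere_origin)[0]
        gA = forward.dipole_field(locA, tA, small_array)
        gB = forward.dipole_field(locB, tB, small_array)
        gA *= 10 / np.abs(gA).max()
        gB *= 10 / np.abs(gB).max()
        n = 60_000
        sA = rng.standard_normal(n)
        sB = rng.standard_normal(n)
        X = np.outer(gA, sA) + np.outer(gB, sB) + rng.standard_normal((gA.size, n))
        rec = Recording(data=X, sampling_rate=FS, array=small_array)
        ve = beamform.extract_virtual_electrode(rec, locA, cov_band=None)
        ca = np.corrcoef(ve.data, sA)[0, 1]
        cb = np.corrcoef(ve.data, sB)[0, 1]
        assert (cb / ca) ** 2 < 10 ** (-20 / 10)


@pytest.fixture(scope="module")
def erd_trialset(small_array, truth):
    rec, motion = synth.simulate_visuomotor_dataset(
        small_array, truth, n_trials=40, seed=21, group="control", snr=5.0)
    rec = preprocess.bandpass_filter(rec, 1, 150)
    return preprocess.segment_trials(rec, motion.offset_times, (-1, 4))


@pytest.fixture(scope="module")
def erd_image(small_array, truth, erd_trialset):
    bounds = np.array([truth.motor_location - 0.014,
                       truth.motor_location + 0.014]).T
    grid = beamform.make_grid(small_array, spacing=0.004, bounds=bounds)
    return beamform.pseudo_t_image(erd_trialset, (13, 30), (-1, 0), (0.5, 1.5),
                                   grid=grid, spacing=0.004, mode="noise")


class TestPseudoTImage:
    def test_planted_erd_localized_within_one_step(self, truth, erd_image):
        peak = beamform.find_peak_location(erd_image, sign="min")
        assert np.abs(peak - truth.motor_location).max() <= 0.004 + 1e-9

    def test_window_swap_flips_sign_exactly(self, small_array, truth, erd_trialset):
        grid = beamform.make_grid(small_array, spacing=0.004,
                                  bounds=np.array([truth.motor_location - 0.006,
                                                   truth.motor_location + 0.006]).T)
        img1 = beamform.pseudo_t_image(erd_trialset, (13, 30), (-1, 0), (0.5, 1.5),
                                       grid=grid, spacing=0.004)
        img2 = beamform.pseudo_t_image(erd_trialset, (13, 30), (0.5, 1.5), (-1, 0),
                                       grid=grid, spacing=0.004)
        assert np.allclose(img1.values, -img2.values)

    def test_normalized_image_max_abs_is_one(self, erd_image):
        normed = erd_image.normalize()
        assert np.max(np.abs(normed.values)) == 1.0
        assert normed.normalized

    def test_stationary_noise_null_image(self, small_array):
        """Active and control windows statistically identical: contrast near 0."""
        rng = np.random.default_rng(8)
        n_trials = 30
        data = rng.standard_normal((n_trials, small_array.n_channels, 1875))
        ts = TrialSet(data=data, sampling_rate=FS, array=small_array,
                      window=(-1.0, 4.0))
        grid = beamform.make_grid(small_array, spacing=0.02)
        img = beamform.pseudo_t_image(ts, (13, 30), (-1, 0), (0.5, 1.5),
                                      grid=grid, spacing=0.02)
        # (Pa-Pc)/(Pa+Pc) on equal windows: SE ~ sqrt(2/(n_eff)); allow 3 SE
        n_eff = n_trials * 375 * (30 - 13) * 2 / FS
        assert np.abs(img.values).max() < 3 * np.sqrt(2 / n_eff) * 3

    def test_empty_window_rejected(self, erd_trialset):
        with pytest.raises((EmptySetError, ValueError)):
            beamform.pseudo_t_image(erd_trialset, (13, 30), (-1, -1), (0.5, 1.5),
                                    grid=np.array([[0.0, 0.0, 0.04]]))


class TestVirtualElectrode:
    def test_noiseless_source_recovered(self, small_array):
        rng = np.random.default_rng(9)
        loc = np.array([0.02, -0.01, 0.05])
        t1 = forward.tangential_basis(loc, small_array.sphere_origin)[0]
        g = forward.dipole_field(loc, t1, small_array)
        s = rng.standard_normal(40_000)
        X = np.outer(g, s) + 1e-6 * np.abs(g).max() * rng.standard_normal((g.size, 40_000))
        rec = Recording(data=X, sampling_rate=FS, array=small_array)
        ve = beamform.extract_virtual_electrode(rec, loc, cov_band=None)
        assert abs(np.corrcoef(ve.data, s)[0, 1]) > 0.999
        assert np.linalg.norm(ve.orientation) == pytest.approx(1.0, abs=1e-10)

    def test_scaling_linearity(self, small_array):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((small_array.n_channels, 20_000))
        rec = Recording(data=X, sampling_rate=FS, array=small_array)
        rec2 = Recording(data=3.0 * X, sampling_rate=FS, array=small_array)
        loc = np.array([0.0, 0.02, 0.05])
        v1 = beamform.extract_virtual_electrode(rec, loc, cov_band=None).data
        # weights recomputed from the scaled covariance are identical up to
        # the unit-gain constraint, so the VE scales exactly
        v2 = beamform.extract_virtual_electrode(rec2, loc, cov_band=None).data
        assert np.allclose(v2, 3.0 * v1, rtol=1e-8)

    def test_noise_floor_bound(self, small_array):
        """VE of pure white sensor noise stays at the projected noise floor
        w' Sigma w, with Sigma = sigma^2 I known."""
        rng = np.random.default_rng(11)
        sigma = 2.0
        loc = np.array([0.0, 0.02, 0.05])
        X = sigma * rng.standard_normal((small_array.n_channels, 100_000))
        rec = Recording(data=X, sampling_rate=FS, array=small_array)
        ve = beamform.extract_virtual_electrode(rec, loc, cov_band=None)
        # rebuild the unit-gain weights the extractor used
        cov = beamform.regularize(beamform.compute_covariance(rec, band=None))
        L = forward.leadfield(loc, small_array)
        t1, t2, _ = forward.tangential_basis(loc, small_array.sphere_origin)
        eta = beamform.optimal_orientation(cov.matrix, L, (t1, t2))
        w = beamform.lcmv_weights(cov.matrix, L[:, :2] @ np.array([t1 @ eta, t2 @ eta]))
        assert np.allclose(ve.data, w @ X)
        assert ve.data.var() <= 1.05 * sigma ** 2 * (w @ w)


class TestPeakFinding:
    def test_planted_extremum_and_ties(self):
        pts = np.array([[0, 0, 0.04], [0.004, 0, 0.04], [0.008, 0, 0.04]])
        img = beamform.PseudoTImage(points=pts, values=np.array([0.1, -0.9, 0.1]),
                                    spacing=0.004)
        assert np.allclose(beamform.find_peak_location(img, "min"), pts[1])
        tie = beamform.PseudoTImage(points=pts, values=np.array([0.5, 0.2, 0.5]),
                                    spacing=0.004)
        assert np.allclose(beamform.find_peak_location(tie, "max"), pts[0])

    def test_group_mean_peak(self):
        pts = np.array([[0, 0, 0.04], [0.004, 0, 0.04], [0.008, 0, 0.04]])
        imgs = [beamform.PseudoTImage(points=pts, values=v, spacing=0.004)
                for v in (np.array([0.1, 0.8, 0.3]), np.array([0.2, 0.9, 0.4]))]
        peak = beamform.group_peak_location(imgs, "max")
        assert np.allclose(peak, pts[1])
        # identical images: group peak equals the individual peak
        same = beamform.group_peak_location([imgs[0], imgs[0]], "max")
        assert np.allclose(same, beamform.find_peak_location(imgs[0], "max"))

    def test_adjacent_extrema_group_peak_in_bounding_box(self):
        pts = np.array([[0, 0, 0.04], [0.004, 0, 0.04], [0.008, 0, 0.04]])
        a = beamform.PseudoTImage(points=pts, values=np.array([0.2, 1.0, 0.1]),
                                  spacing=0.004)
        b = beamform.PseudoTImage(points=pts, values=np.array([0.1, 0.6, 1.0]),
                                  spacing=0.004)
        peak = beamform.group_peak_location([a, b], "max")
        assert 0.004 - 1e-12 <= peak[0] <= 0.008 + 1e-12
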