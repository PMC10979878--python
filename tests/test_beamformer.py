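"""LCMV beamformer tests: algebraic identities and localization oracles."""

import numpy as np
import pytest

import opmsim as om
import opmsim.beamformer as bf
import opmsim.preprocess as pp
import opmsim.spectral as sp
from opmsim.containers import Epochs
from opmsim.sensors import SensorModelParams
from opmsim.sessions import TRIGGER_CODES, amplitude_for_snr
from conftest import simulate_beta_erd

FS = 375.0
BETA = (13.0, 30.0)


def preprocess_to_epochs(rec, code, window):
    rec = pp.apply_filters(rec)
    rec = pp.homogeneous_field_correction(rec)
    return pp.segment_trials(rec, code, window)


@pytest.fixture(scope="module")
def erd_fit(helmet16, sphere, beta_scene):
    """One seeded beta-ERD session fitted end to end, reused across tests."""
    rec = simulate_beta_erd(helmet16, sphere, beta_scene["dipole"], seed=21)
    ep = preprocess_to_epochs(rec, TRIGGER_CODES["catch"], (-0.3, 1.7))
    model = bf.lcmv_weights(bf.compute_covariance(ep, BETA),
                            beta_scene["leadfields"], beta_scene["grid"])
    return {"rec": rec, "ep": ep, "model": model}


class TestCovariance:
    def test_white_noise_limit(self):
        rng = np.random.default_rng(0)
        sigma = 1e-13
        data = sigma * rng.standard_normal((1, 24, int(60 * FS)))
        ep = Epochs(data, FS, (0.0, 60.0))
        model = bf.compute_covariance(ep, (1.0, 150.0), reg_fraction=0.0)
        C = model.covariance
        # the 1-150 Hz band holds ~80% of the Nyquist bandwidth
        band_sigma2 = sigma**2 * (150.0 - 1.0) / (FS / 2)
        assert np.allclose(np.diag(C), band_sigma2, rtol=0.1)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05 * band_sigma2

    def test_regularisation_spectral_shift(self, erd_fit):
        model = erd_fit["model"]
        lam = np.linalg.eigvalsh(model.covariance)
        lam_reg = np.linalg.eigvalsh(model.reg_covariance)
        assert np.isclose(lam_reg[-1], 1.01 * lam[-1], rtol=1e-10)
        assert np.isclose(lam_reg[0] - lam[0], 0.01 * lam[-1], rtol=1e-8)

    def test_trial_duplication_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 8, 400)) * 1e-13
        ep = Epochs(data, FS, (0.0, 400 / FS))
        ep2 = Epochs(np.concatenate([data, data]), FS, (0.0, 400 / FS))
        C1 = bf.compute_covariance(ep, BETA).covariance
        C2 = bf.compute_covariance(ep2, BETA).covariance
        assert np.allclose(C1, C2, atol=1e-12 * np.abs(C1).max())


class TestWeights:
    def test_unit_gain_constraint(self, erd_fit):
        model = erd_fit["model"]
        gains = np.einsum("vc,cv->v", model.weights, model.leadfield_scalar)
        assert np.abs(gains - 1.0).max() < 1e-8

    def test_identity_covariance_gives_matched_filter(self, beta_scene):
        n_ch = beta_scene["leadfields"].shape[0]
        model = bf.BeamformerModel(np.eye(n_ch), 0.0, BETA, FS,
                                   reg_covariance=np.eye(n_ch))
        model = bf.lcmv_weights(model, beta_scene["leadfields"], beta_scene["grid"])
        for v in (0, beta_scene["voxel"], beta_scene["grid"].n_voxels - 1):
            w = model.weights[v]
            l = model.leadfield_scalar[:, v]
            cos = np.dot(w, l) / (np.linalg.norm(w) * np.linalg.norm(l))
            assert cos > 1 - 1e-10

    def test_output_power_identity(self):
        # output power at a voxel equals 1/(l^T C^-1 l): explicit inversion
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 6))
        C = A @ A.T + 6 * np.eye(6)
        L = rng.standard_normal((6, 3, 2))
        grid = om.SourceGrid(rng.standard_normal((3, 3)) * 0.01)
        model = bf.BeamformerModel(C, 0.0, BETA, FS, reg_covariance=C)
        model = bf.lcmv_weights(model, L, grid)
        Cinv = np.linalg.inv(C)
        for v in range(3):
            l = model.leadfield_scalar[:, v]
            w = model.weights[v]
            assert np.isclose(w @ C @ w, 1.0 / (l @ Cinv @ l), rtol=1e-10)

    def test_localises_seeded_dipole(self, erd_fit, beta_scene):
        # exhaustive scan: minimum of the ERD pseudo-T over the grid
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3),
                                (0.8, 1.4))
        err = np.linalg.norm(img.peak_position("min")
                             - beta_scene["dipole"].position)
        assert err <= 0.004 + 1e-12


class TestPseudoT:
    def test_null_contrast_near_zero(self, erd_fit):
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (0.8, 1.4),
                                (0.8, 1.4))
        assert np.abs(img.values).max() < 1e-12

    def test_antisymmetric_under_window_swap(self, erd_fit):
        a = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3), (0.8, 1.4))
        b = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (0.8, 1.4), (-0.3, 0.3))
        assert np.allclose(a.values, -b.values, atol=1e-12)

    def test_values_bounded(self, erd_fit):
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3), (0.8, 1.4))
        assert np.all(np.abs(img.values[~img.invalid]) <= 1.0 + 1e-12)

    def test_channel_permutation_invariance(self, helmet16, sphere, beta_scene):
        rec = simulate_beta_erd(helmet16, sphere, beta_scene["dipole"], seed=33,
                                n_trials=15)
        ep = preprocess_to_epochs(rec, TRIGGER_CODES["catch"], (-0.3, 1.7))
        L = beta_scene["leadfields"]
        model = bf.lcmv_weights(bf.compute_covariance(ep, BETA), L,
                                beta_scene["grid"])
        img = bf.pseudo_t_image(ep, model, (-0.3, 0.3), (0.8, 1.4))
        perm = np.random.default_rng(5).permutation(ep.n_channels)
        ep_p = Epochs(ep.data[:, perm], ep.sample_rate, ep.window)
        model_p = bf.lcmv_weights(bf.compute_covariance(ep_p, BETA), L[perm],
                                  beta_scene["grid"])
        img_p = bf.pseudo_t_image(ep_p, model_p, (-0.3, 0.3), (0.8, 1.4))
        assert np.allclose(img.values, img_p.values, atol=1e-8)


class TestPseudoZ:
    def evoked_session(self, helmet, sphere, dipole, seed, gain=1.0, n_trials=40):
        params = SensorModelParams(sample_rate=FS, loop_mode="closed")
        amp = amplitude_for_snr(helmet, sphere, dipole, (2.0, 40.0), params, 5.0)
        sch = om.make_visuomotor_schedule(seed, trial_counts={"faces": (n_trials, 0.5)},
                                          start=1.0)
        src = [om.SourceSpec(dipole, "evoked", (2.0, 40.0), "faces",
                             gain * 3 * amp, evoked_latency=0.17)]
        return om.simulate_visuomotor_session(helmet, sch, src, params,
                                              seed=seed, sphere=sphere)

    def test_localises_evoked_source(self, helmet16, sphere, beta_scene):
        rec = self.evoked_session(helmet16, sphere, beta_scene["dipole"], seed=8)
        ep = preprocess_to_epochs(rec, TRIGGER_CODES["faces"], (0.0, 1.5))
        model = bf.lcmv_weights(bf.compute_covariance(ep, (2.0, 40.0)),
                                beta_scene["leadfields"], beta_scene["grid"])
        img = bf.pseudo_z_image(ep, model, 0.17)
        err = np.linalg.norm(img.peak_position("max") - beta_scene["dipole"].position)
        assert err <= 0.004 * np.sqrt(2) + 1e-12  # within one grid step

    def test_null_distribution_stays_low(self, helmet16, sphere, beta_scene):
        # no evoked signal: 95th percentile of peak pseudo-Z below 3
        params = SensorModelParams(sample_rate=FS, loop_mode="closed")
        peaks = []
        for seed in range(20):
            sch = om.make_visuomotor_schedule(seed, trial_counts={"faces": (20, 0.5)},
                                              start=1.0)
            rec = om.simulate_visuomotor_session(helmet16, sch, [], params,
                                                 seed=seed, sphere=sphere)
            ep = pp.segment_trials(rec, TRIGGER_CODES["faces"], (0.0, 1.5))
            model = bf.lcmv_weights(bf.compute_covariance(ep, (2.0, 40.0)),
                                    beta_scene["leadfields"], beta_scene["grid"])
            img = bf.pseudo_z_image(ep, model, 0.17)
            peaks.append(img.values)
        assert np.quantile(np.concatenate(peaks), 0.95) < 3.0

    def test_amplitude_doubling_doubles_peak(self, helmet16, sphere, beta_scene):
        # linearity in the signal holds for a fixed set of weights
        rec1 = self.evoked_session(helmet16, sphere, beta_scene["dipole"], seed=9)
        rec2 = self.evoked_session(helmet16, sphere, beta_scene["dipole"], seed=9,
                                   gain=2.0)
        ep1 = preprocess_to_epochs(rec1, TRIGGER_CODES["faces"], (0.0, 1.5))
        ep2 = preprocess_to_epochs(rec2, TRIGGER_CODES["faces"], (0.0, 1.5))
        model = bf.lcmv_weights(bf.compute_covariance(ep1, (2.0, 40.0)),
                                beta_scene["leadfields"], beta_scene["grid"])
        z1 = bf.pseudo_z_image(ep1, model, 0.17).values.max()
        z2 = bf.pseudo_z_image(ep2, model, 0.17).values.max()
        assert abs(z2 / z1 - 2.0) < 0.1

    def test_latency_outside_window_rejected(self, erd_fit):
        with pytest.raises(bf.BeamformerError):
            bf.pseudo_z_image(erd_fit["ep"], erd_fit["model"], 5.0)


class TestVirtualElectrode:
    def test_noiseless_reconstruction_is_exact(self, helmet16, sphere, beta_scene):
        params = SensorModelParams(sample_rate=FS, loop_mode="closed",
                                   noise_density=0.0)
        sch = om.make_visuomotor_schedule(4, trial_counts={"catch": (8, 0.8)},
                                          start=1.0)
        src = [om.SourceSpec(beta_scene["dipole"], "erd", BETA, "catch",
                             30e-9, 0.5, (-0.3, 0.3))]
        rec = om.simulate_visuomotor_session(helmet16, sch, src, params, seed=6,
                                             sphere=sphere)
        ep = pp.segment_trials(rec, TRIGGER_CODES["catch"], (-0.3, 1.7))
        model = bf.lcmv_weights(bf.compute_covariance(ep, BETA),
                                beta_scene["leadfields"], beta_scene["grid"])
        ve = bf.virtual_electrode(ep, model, beta_scene["voxel"])
        truth = rec.ground_truth["sources"][0]["timecourse"]
        truth_ep = pp.segment_trials(
            om.Recording(truth[None, :], FS, triggers=rec.triggers),
            TRIGGER_CODES["catch"], (-0.3, 1.7))
        # apply the virtual electrode's band-pass to the truth as well
        truth_filt = bf.bandpass_epochs(truth_ep, BETA)
        r = np.corrcoef(ve.trials.ravel(), truth_filt.data[:, 0, :].ravel())[0, 1]
        assert abs(r) > 1 - 1e-6

    def test_envelope_tracks_truth_at_moderate_snr(self, helmet16, sphere,
                                                   beta_scene, erd_fit):
        rec, ep, model = erd_fit["rec"], erd_fit["ep"], erd_fit["model"]
        ve = bf.virtual_electrode(ep, model, beta_scene["voxel"])
        env = sp.hilbert_envelope(ve, BETA)
        truth = rec.ground_truth["sources"][0]["timecourse"]
        truth_ep = pp.segment_trials(
            om.Recording(truth[None, :], FS, triggers=rec.triggers),
            TRIGGER_CODES["catch"], (-0.3, 1.7))
        tv = bf.VirtualElectrode(truth_ep.data[:, 0, :], FS, (-0.3, 1.7),
                                 ve.voxel_position, BETA)
        truth_env = sp.hilbert_envelope(tv, BETA)
        r = np.corrcoef(env, truth_env)[0, 1]
        assert r >= 0.9

    def test_zero_data_gives_zero_timecourse(self, erd_fit, beta_scene):
        ep = erd_fit["ep"]
        zero = Epochs(np.zeros_like(ep.data), FS, ep.window)
        ve = bf.virtual_electrode(zero, erd_fit["model"], beta_scene["voxel"])
        assert np.allclose(ve.trials, 0.0)

    def test_unknown_voxel_rejected(self, erd_fit):
        with pytest.raises(bf.BeamformerError):
            bf.virtual_electrode(erd_fit["ep"], erd_fit["model"], 10**6)


class TestCompareLocalisations:
    def test_identity(self, erd_fit, beta_scene):
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3),
                                (0.8, 1.4))
        ve = bf.virtual_electrode(erd_fit["ep"], erd_fit["model"],
                                  beta_scene["voxel"])
        d, r = bf.compare_localisations(img, img, ve, ve, extremum="min")
        assert d == 0.0
        assert np.isclose(r, 1.0)

    def test_pearson_affine_invariance(self, erd_fit, beta_scene):
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3),
                                (0.8, 1.4))
        ve = bf.virtual_electrode(erd_fit["ep"], erd_fit["model"],
                                  beta_scene["voxel"])
        scaled = bf.VirtualElectrode(3.0 * ve.trials + 1e-9, FS, ve.window,
                                     ve.voxel_position, BETA)
        _, r = bf.compare_localisations(img, img, ve, scaled, extremum="min")
        assert np.isclose(r, 1.0, atol=1e-12)

    def test_grid_mismatch_rejected(self, erd_fit, sphere, beta_scene):
        img = bf.pseudo_t_image(erd_fit["ep"], erd_fit["model"], (-0.3, 0.3),
                                (0.8, 1.4))
        other = om.SourceGrid(beta_scene["grid"].voxel_positions[:5])
        img2 = bf.StatImage(img.values[:5], "pseudo_t", other, BETA)
        ve = bf.virtual_electrode(erd_fit["ep"], erd_fit["model"], 0)
        with pytest.raises(bf.BeamformerError):
            bf.compare_localisations(img, img2, ve, ve)
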