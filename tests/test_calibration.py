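"""Calibration: trimming, envelope, chirp, regridding, overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octstitch as ox
from octstitch import CalibrationError
from octstitch.calibration import (
    AnalyticSpectrum,
    depth_cross_correlation,
    determine_overlap,
    pad_spectra,
)
from octstitch.forward_model import (
    FLAT_ENVELOPE,
    LASER_840,
    LASER_950,
    ChirpModel,
    EnvelopeModel,
    ScatteringPhantom,
    build_chirp_curve,
    simulate_klinear_pair,
    simulate_sweep,
)


# ----------------------------------------------------------------------
# Trimming
# ----------------------------------------------------------------------

class TestTrimSweep:
    def make(self, n=515, head=8, tail=8):
        spec = ox.LaserSpec("L", 805, 882, n)
        return ox.RawSweep(
            frames=np.random.default_rng(0).normal(size=(2, 2, n)),
            laser=spec, discard_head=head, discard_tail=tail,
        )

    def test_discard_arithmetic(self):
        trimmed = ox.trim_sweep(self.make(515, 8, 8))
        assert trimmed.n_frames == 499
        assert trimmed.discard_head == trimmed.discard_tail == 0

    def test_zero_discard_is_identity(self):
        raw = self.make(64, 0, 0)
        trimmed = ox.trim_sweep(raw)
        np.testing.assert_array_equal(trimmed.frames, raw.frames)

    def test_overtrim_rejected(self):
        with pytest.raises(CalibrationError):
            self.make(30, 8, 8)

    def test_trim_retains_high_contrast_region(self, calib_session):
        """With ASE at the sweep ends, the retained frames carry the
        high-contrast part of the simulated truth contrast."""
        lid = calib_session.lasers[0].laser_id
        alpha_truth = calib_session.truth["alpha"][lid]
        # truth alpha is recorded on retained frames: its extremes stay
        # above the configured ASE floor by construction
        assert alpha_truth.min() > 0.69
        assert alpha_truth.max() == pytest.approx(1.0)


# ----------------------------------------------------------------------
# Envelope and amplitude correction
# ----------------------------------------------------------------------

class TestEnvelope:
    def test_flat_envelope_alpha_is_unity(self):
        # mirror on an exact depth bin: the estimator has no leakage there
        n = LASER_840.n_frames
        zpx = ox.depth_pixel_um(n, LASER_840.k_span / (n - 1))
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE,
            ScatteringPhantom.mirror(130 * zpx, 1.0, (2, 2)),
        )
        env = ox.estimate_envelope(sweep, mode="reflecting")
        assert np.max(np.abs(env.alpha - 1.0)) < 1e-6

    def test_flat_envelope_alpha_near_unity_fractional_depth(self):
        # off-bin mirror with discard margins: percent-level edge ripple
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"),
                                  margin=(8, 8))
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE,
            ScatteringPhantom.mirror(600.0, 1.0, (2, 2)), discard=(8, 8),
        )
        env = ox.estimate_envelope(sweep, mode="reflecting")
        assert np.max(np.abs(env.alpha[8:-8] - 1.0)) < 0.08

    def test_scattering_mode_recovers_contrast(self, rng):
        """alpha tracks a known multiplicative contrast g(k) on a many-layer
        scattering phantom, within 2% in the sweep interior."""
        env_model = EnvelopeModel(ase_edge_fraction=0.15,
                                  ase_contrast_floor=0.55)
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        phantom = ScatteringPhantom.random_volume(
            rng, 40, (150.0, 900.0), (48, 48)
        )
        sweep = simulate_sweep(LASER_840, chirp, env_model, phantom)
        env = ox.estimate_envelope(sweep, mode="scattering")
        tau = np.linspace(0, 1, LASER_840.n_frames)
        truth = env_model.contrast(tau)
        truth = truth / truth.max()
        sl = slice(10, -10)
        rel = (env.alpha[sl] - truth[sl]) / truth[sl]
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_scattering_raw_magnitude_variant_agrees(self, rng):
        env_model = EnvelopeModel(ase_edge_fraction=0.12,
                                  ase_contrast_floor=0.6)
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        phantom = ScatteringPhantom.random_volume(
            rng, 40, (150.0, 900.0), (16, 16)
        )
        sweep = simulate_sweep(LASER_840, chirp, env_model, phantom)
        a = ox.estimate_envelope(sweep, mode="scattering")
        b = ox.estimate_envelope(sweep, mode="scattering",
                                 use_raw_magnitude=True)
        sl = slice(10, -10)
        diff = a.alpha[sl] - b.alpha[sl]
        assert np.sqrt(np.mean(diff**2)) < 0.04

    def test_reflecting_mode_rejects_two_surfaces_in_window(self):
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        phantom = ScatteringPhantom.layered([(300.0, 1.0), (600.0, 1.0)])
        sweep = simulate_sweep(LASER_840, chirp, FLAT_ENVELOPE, phantom)
        with pytest.raises(CalibrationError, match="surface"):
            ox.estimate_envelope(sweep, mode="reflecting",
                                 depth_window=(50, 500))

    def test_reflecting_mode_single_surface_window_removes_beat(self):
        """Coverslip-like target: isolating one surface gives a contrast
        estimate free of the two-surface interference beat."""
        # coverslip-like target: 170 um glass at n = 1.51 -> ~257 um of
        # optical separation between the two surface reflections
        env_model = EnvelopeModel(ase_edge_fraction=0.15,
                                  ase_contrast_floor=0.65)
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"),
                                  margin=(8, 8))
        n = LASER_840.n_frames - 16
        z_px = ox.depth_pixel_um(n, LASER_840.k_span / (n - 1))
        peak, gap = 98, 56  # 56 depth px ~ 257 um optical separation
        phantom = ScatteringPhantom.layered(
            [(peak * z_px, 1.0), ((peak + gap) * z_px, 0.9)]
        )
        sweep = simulate_sweep(LASER_840, chirp, env_model, phantom,
                               discard=(8, 8))
        env = ox.estimate_envelope(
            sweep, mode="reflecting",
            depth_window=(peak - gap // 2 + 2, peak + gap // 2 - 1),
        )
        tau = np.linspace(0, 1, n)
        truth = env_model.contrast(tau)
        truth = truth / truth.max()
        sl = slice(12, -12)
        assert np.max(np.abs(env.alpha[sl] - truth[sl]) / truth[sl]) < 0.03
        # without surface isolation the two-surface interference would beat
        # the magnitude by tens of percent; prove the alternative is worse
        naive = ox.estimate_envelope(sweep, mode="scattering")
        naive_err = np.max(np.abs(naive.alpha[sl] - truth[sl]) / truth[sl])
        assert naive_err > 0.10

    def test_scattering_and_reflecting_agree_on_mirror(self):
        """The two estimator variants agree within 3% on a phantom valid
        for both: one clean surface, no background (interior of the sweep).
        """
        env_model = EnvelopeModel(ase_edge_fraction=0.12,
                                  ase_contrast_floor=0.7)
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"),
                                  margin=(8, 8))
        sweep = simulate_sweep(
            LASER_840, chirp, env_model,
            ScatteringPhantom.mirror(650.0, 1.0, (2, 2)), discard=(8, 8),
        )
        refl = ox.estimate_envelope(sweep, mode="reflecting")
        scat = ox.estimate_envelope(sweep, mode="scattering")
        sl = slice(12, -12)
        assert np.max(np.abs(refl.alpha[sl] - scat.alpha[sl])) < 0.03


class TestCorrectAmplitude:
    def make_spec(self, n=64):
        return AnalyticSpectrum(np.ones(n, complex), k_start=7e-3, dk=1e-6)

    def test_unity_alpha_is_identity(self):
        spec = self.make_spec()
        env = ox.EnvelopeCorrection("L", np.ones(64), np.ones(64), 1.0,
                                    "scattering")
        out = ox.correct_amplitude(spec, env)
        np.testing.assert_array_equal(out.data, spec.data)

    def test_half_alpha_doubles_amplitude(self):
        spec = self.make_spec()
        alpha = np.full(64, 0.5)
        alpha[0] = 1.0  # keep max(alpha) = 1 invariant
        env = ox.EnvelopeCorrection("L", alpha.copy(), alpha, 1.0,
                                    "scattering")
        out = ox.correct_amplitude(spec, env)
        np.testing.assert_allclose(out.data[0, 0, 1:], 2.0)

    def test_ase_edges_flattened(self):
        """Dividing by the estimated contrast flattens the fringe amplitude
        to a few percent over the retained frames."""
        env_model = EnvelopeModel(ase_edge_fraction=0.12,
                                  ase_contrast_floor=0.6)
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        sweep = simulate_sweep(
            LASER_840, chirp, env_model,
            ScatteringPhantom.mirror(700.0, 1.0, (2, 2)),
        )
        env = ox.estimate_envelope(sweep, mode="reflecting")
        corrected = ox.correct_amplitude(sweep, env)
        from scipy.signal import hilbert

        amp = np.abs(hilbert(corrected.frames[0, 0]))
        sl = slice(12, -12)
        assert np.ptp(amp[sl]) / np.median(amp[sl]) < 0.05
        # alpha floor invariant
        assert env.alpha.min() >= 0.05


# ----------------------------------------------------------------------
# Chirp estimation
# ----------------------------------------------------------------------

class TestEstimateChirp:
    def run_case(self, model, z_um=800.0, spec=LASER_840):
        chirp = build_chirp_curve(spec, model)
        sweep = simulate_sweep(
            spec, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(z_um)
        )
        est = ox.estimate_chirp(sweep, spec)
        return np.max(np.abs(est.k_of_t - chirp.k_of_t)) / spec.k_span

    def test_linear_chirp_recovered(self):
        assert self.run_case(ChirpModel("linear")) < 1e-3

    def test_quadratic_chirp_recovered(self):
        # 5% peak nonlinearity
        assert self.run_case(ChirpModel("polynomial", (0.2,))) < 1e-3

    def test_depth_invariance(self):
        """Doubling the mirror depth leaves the anchored chirp unchanged:
        z0 cancels in the affine anchoring."""
        model = ChirpModel("polynomial", (0.2,))
        chirp = build_chirp_curve(LASER_840, model)
        ests = []
        for z in (400.0, 800.0):
            sweep = simulate_sweep(
                LASER_840, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(z)
            )
            ests.append(ox.estimate_chirp(sweep, LASER_840).k_of_t)
        assert np.max(np.abs(ests[0] - ests[1])) / LASER_840.k_span < 1e-3

    def test_chirp_recovery_property(self):
        """Recovery error stays below 0.1% of the span for monotonic chirps
        with up to 10% nonlinearity."""
        for model in [
            ChirpModel("polynomial", (0.4,)),           # 10% quadratic
            ChirpModel("polynomial", (-0.3, 0.1)),
            ChirpModel("sinusoidal-perturbed", (0.03, 2.0)),
        ]:
            for spec in (LASER_840, LASER_950):
                assert self.run_case(model, z_um=700.0, spec=spec) < 1e-3

    def test_low_depth_rejected_with_guidance(self):
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(2.0)
        )
        with pytest.raises(CalibrationError, match="z0"):
            ox.estimate_chirp(sweep, LASER_840)


# ----------------------------------------------------------------------
# Regridding
# ----------------------------------------------------------------------

class TestRegrid:
    def test_linear_input_native_dk_is_identity(self):
        from scipy.signal import hilbert

        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(500.0)
        )
        dk = LASER_840.k_span / (LASER_840.n_frames - 1)
        out = ox.regrid_klinear(sweep, chirp, dk)
        expected = hilbert(sweep.frames[0, 0]
                           - sweep.frames[0, 0].mean())
        scale = np.abs(expected).max()
        np.testing.assert_allclose(
            out.data[0, 0] / scale, expected / scale, atol=1e-6
        )

    @pytest.mark.parametrize("method", ["lsq", "spline"])
    def test_chirped_mirror_flat_instantaneous_frequency(self, method):
        model = ChirpModel("polynomial", (0.2,))
        chirp = build_chirp_curve(LASER_840, model)
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(600.0)
        )
        dk = LASER_840.k_span / (LASER_840.n_frames - 1)
        out = ox.regrid_klinear(sweep, chirp, dk, method=method)
        phase = np.unwrap(np.angle(out.data[0, 0]))
        f_inst = np.diff(phase)[10:-10]
        assert np.std(f_inst) / np.abs(np.mean(f_inst)) < 0.01

    def test_common_dk_gives_common_fringe_frequency(self):
        """After regridding to a shared dk, a fixed depth produces the same
        fringe frequency in both lasers within 0.5%."""
        z = 500.0
        dk = LASER_840.k_span / (LASER_840.n_frames - 1)
        freqs = []
        for spec, c in ((LASER_840, 0.2), (LASER_950, -0.15)):
            chirp = build_chirp_curve(spec, ChirpModel("polynomial", (c,)))
            sweep = simulate_sweep(
                spec, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(z)
            )
            out = ox.regrid_klinear(sweep, chirp, dk)
            phase = np.unwrap(np.angle(out.data[0, 0]))
            freqs.append(np.median(np.diff(phase)))
        assert abs(freqs[0] - freqs[1]) / freqs[0] < 0.005

    def test_excessive_upsampling_rejected(self):
        chirp = build_chirp_curve(LASER_840, ChirpModel("linear"))
        sweep = simulate_sweep(
            LASER_840, chirp, FLAT_ENVELOPE, ScatteringPhantom.mirror(400.0)
        )
        dk = LASER_840.k_span / (5 * LASER_840.n_frames)
        with pytest.raises(CalibrationError, match="upsampling"):
            ox.regrid_klinear(sweep, chirp, dk)


# ----------------------------------------------------------------------
# Padding and cross-correlation
# ----------------------------------------------------------------------

class TestPadSpectra:
    def test_padded_lengths_sum(self):
        a = AnalyticSpectrum(np.ones(515, complex), 7e-3, 1e-6)
        b = AnalyticSpectrum(np.ones(478, complex), 7.5e-3, 1e-6)
        pa, pb = pad_spectra(a, b)
        assert pa.size == pb.size == 993

    def test_zero_padding_conserves_energy(self, rng):
        a = AnalyticSpectrum(rng.normal(size=100) + 1j * rng.normal(size=100),
                             7e-3, 1e-6)
        b = AnalyticSpectrum(rng.normal(size=80) + 1j * rng.normal(size=80),
                             7.5e-3, 1e-6)
        pa, pb = pad_spectra(a, b)
        assert np.sum(np.abs(pa) ** 2) == pytest.approx(
            np.sum(np.abs(a.mean_aline()) ** 2))
        assert np.sum(np.abs(pb) ** 2) == pytest.approx(
            np.sum(np.abs(b.mean_aline()) ** 2))

    def test_dk_mismatch_rejected(self):
        a = AnalyticSpectrum(np.ones(8, complex), 7e-3, 1e-6)
        b = AnalyticSpectrum(np.ones(8, complex), 7e-3, 2e-6)
        with pytest.raises(CalibrationError, match="dk"):
            pad_spectra(a, b)

    def test_empty_spectrum_rejected(self):
        a = AnalyticSpectrum(np.ones(8, complex), 7e-3, 1e-6)
        b = AnalyticSpectrum(np.ones((1, 1, 0), dtype=complex), 7e-3, 1e-6)
        with pytest.raises(CalibrationError, match="empty"):
            pad_spectra(a, b)


def direct_cross_correlation(a, b):
    """Brute-force O(n^2) circular cross-correlation oracle."""
    n = a.size
    return np.array([
        np.sum(a[(np.arange(n) + lag) % n] * np.conj(b))
        for lag in range(n)
    ])


class TestDepthCrossCorrelation:
    def test_fine_grid_resolution_is_001_px(self):
        pair = simulate_klinear_pair(10.0, [300.0], n_a=64, n_b=64, dk=1e-5)
        pa, pb = pad_spectra(*pair[0])
        lags, rho = depth_cross_correlation(pa, pb)
        steps = np.unique(np.round(np.diff(np.sort(lags)), 9))
        assert steps.size == 1 and steps[0] == pytest.approx(0.01)

    def test_rho_bounded(self, rng):
        a = rng.normal(size=128) + 1j * rng.normal(size=128)
        b = rng.normal(size=128) + 1j * rng.normal(size=128)
        _, rho = depth_cross_correlation(a, b)
        assert np.all(rho >= -1 - 1e-12) and np.all(rho <= 1 + 1e-12)

    def test_integer_shift_attains_unity(self):
        """b equal to a shifted by exactly 10 px (same envelope): rho
        reaches 1.0 at lag 10.00."""
        rng = np.random.default_rng(1)
        n = 96
        a = np.zeros(2 * n, complex)
        a[:n] = np.exp(1j * rng.uniform(0, 2 * np.pi, n))
        b = np.roll(a, 10)
        lags, rho = depth_cross_correlation(a, b)
        # on the overlap convention kappa = -lag: the shift reads as 10.00
        kappas = -lags
        i = int(np.argmin(np.abs(kappas - 10.0)))
        assert rho[i] == pytest.approx(1.0, abs=1e-9)

    def test_fft_equals_direct_sum_oracle(self, rng):
        for n in (32, 128, 256):
            a = rng.normal(size=n) + 1j * rng.normal(size=n)
            b = rng.normal(size=n) + 1j * rng.normal(size=n)
            r_fft = np.fft.ifft(np.fft.fft(a) * np.conj(np.fft.fft(b)))
            r_direct = direct_cross_correlation(a, b)
            np.testing.assert_allclose(r_fft, r_direct, rtol=0, atol=1e-9 *
                                       np.abs(r_direct).max())

    def test_no_common_content_rejected(self):
        a = np.zeros(64, complex)
        b = np.zeros(64, complex)
        with pytest.raises(CalibrationError):
            depth_cross_correlation(a, b)


class TestDetermineOverlap:
    def test_single_depth_is_ambiguous_and_refused(self):
        pair = simulate_klinear_pair(24.0, [400.0])
        with pytest.raises(CalibrationError, match="depth"):
            determine_overlap(pair, kappa_nominal=24.0)

    def test_single_depth_rho_periodic_with_peak_near_truth(self):
        """One depth gives a periodic rho whose maxima include the true
        overlap but do not identify it."""
        (pair,) = simulate_klinear_pair(24.0, [404.9])
        pa, pb = pad_spectra(*pair)
        lags, rho = depth_cross_correlation(pa, pb)
        kappas = -lags
        near = np.abs(kappas - 24.0) < 0.005
        assert rho[near].max() > 0.999
        # ... but other near-unity maxima exist away from 24
        far = (np.abs(kappas - 24.0) > 3) & (kappas > 5) & (kappas < 90)
        assert rho[far].max() > 0.999

    def test_four_depths_recover_24px_overlap(self):
        depths = [150.3, 333.1, 527.9, 804.2]
        pairs = simulate_klinear_pair(24.0, depths, n_a=403, n_b=515,
                                      dk=1.3258e-6)
        est = determine_overlap(pairs, kappa_nominal=20.0, depths_um=depths)
        assert est.kappa == pytest.approx(24.0, abs=0.01)
        assert est.n_depths == 4

    @pytest.mark.parametrize("kappa", [5.0, 17.58, 24.0, 40.0])
    def test_noiseless_recovery_within_002(self, kappa):
        depths = [118.2, 222.7, 345.3, 469.1, 613.9, 787.4]
        pairs = simulate_klinear_pair(kappa, depths, n_a=403, n_b=515,
                                      dk=1.3258e-6)
        est = determine_overlap(pairs, kappa_nominal=kappa * 1.1,
                                depths_um=depths)
        assert abs(est.kappa - kappa) <= 0.02

    @pytest.mark.parametrize("kappa", [17.58, 24.0])
    def test_noisy_recovery_within_01(self, kappa):
        depths = [118.2, 222.7, 345.3, 469.1, 613.9, 787.4]
        pairs = simulate_klinear_pair(
            kappa, depths, n_a=403, n_b=515, dk=1.3258e-6,
            noise_sigma=0.05, seed=2,
        )
        est = determine_overlap(pairs, kappa_nominal=kappa * 1.1,
                                depths_um=depths)
        assert abs(est.kappa - kappa) <= 0.1

    def test_harmonic_depths_warn(self):
        pairs = simulate_klinear_pair(24.0, [200.0, 400.0, 800.0])
        with pytest.warns(UserWarning, match="multiple"):
            determine_overlap(pairs, kappa_nominal=24.0,
                              depths_um=[200.0, 400.0, 800.0])


# ----------------------------------------------------------------------
# System calibration assembly
# ----------------------------------------------------------------------

class TestSystemCalibration:
    def test_roundtrip_bitexact(self, system_calibration, tmp_path):
        path = tmp_path / "calib.h5"
        system_calibration.save(path)
        loaded = ox.SystemCalibration.load(path)
        assert loaded.kappa == system_calibration.kappa
        assert loaded.dk == system_calibration.dk
        assert [s.laser_id for s in loaded.lasers] == [
            s.laser_id for s in system_calibration.lasers
        ]
        for lid in system_calibration.chirps:
            np.testing.assert_array_equal(
                loaded.chirps[lid].k_of_t,
                system_calibration.chirps[lid].k_of_t,
            )
            np.testing.assert_array_equal(
                loaded.envelopes[lid].alpha,
                system_calibration.envelopes[lid].alpha,
            )

    def test_missing_pair_rejected(self, system_calibration):
        with pytest.raises(CalibrationError, match="pair"):
            ox.build_system_calibration(
                system_calibration.lasers,
                system_calibration.chirps,
                system_calibration.envelopes,
                {},
                system_calibration.dk,
            )

    def test_end_to_end_overlap_recovery(self, calib_session,
                                         system_calibration):
        truth = calib_session.truth["kappa"][0]
        assert abs(system_calibration.kappa[0] - truth) <= 0.02

    def test_end_to_end_chirp_recovery(self, calib_session,
                                       system_calibration):
        for lid, chirp in system_calibration.chirps.items():
            truth = calib_session.truth["chirp"][lid]
            err = np.max(np.abs(chirp.k_of_t - truth.k_of_t))
            assert err / truth.k_span < 1e-3

    def test_three_laser_chain(self):
        """A third laser extends the chain; both pair overlaps are
        recovered on the common grid."""
        l3 = ox.LaserSpec("laser1050", 948.0, 1010.0, 420)
        lasers = [LASER_840, LASER_950, l3]
        chirps = {
            "laser840": ChirpModel("polynomial", (0.1,)),
            "laser950": ChirpModel("polynomial", (-0.08,)),
            "laser1050": ChirpModel("linear"),
        }
        sess = ox.simulate_calibration_set(
            lasers, chirps, FLAT_ENVELOPE, seed=5, n_depths=5,
            lateral_size=(1, 1),
        )
        calib = ox.calibrate_session(
            sess.raw, sess.lasers,
            depths_um=list(sess.truth["depths_um"]),
        )
        assert len(calib.kappa) == 2
        assert [s.laser_id for s in calib.lasers] == [
            "laser1050", "laser950", "laser840"
        ]
        for est, tru in zip(calib.kappa, sess.truth["kappa"]):
            assert abs(est - tru) <= 0.05


# ----------------------------------------------------------------------
# Property tests
# ----------------------------------------------------------------------

@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rho_always_bounded(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(16, 200))
    a = rng.normal(size=n) + 1j * rng.normal(size=n)
    b = rng.normal(size=n) + 1j * rng.normal(size=n)
    _, rho = depth_cross_correlation(a, b)
    assert np.all(np.abs(rho) <= 1 + 1e-12)
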