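"""Binary-amplitude holograms, interferometric demodulation, calibration."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import holofiber as hf
from holofiber.holography_calibration import (
    DEFAULT_CARRIER,
    MeasuredTM,
    make_interferograms,
    phase_only_enhancement,
)
from holofiber.optics_core import ComplexField
from holofiber.transport_model import random_unitary


def smooth_target(n, sigma, phase_std, amp_lo, seed):
    rng = np.random.default_rng(seed)
    phi = gaussian_filter(rng.standard_normal((n, n)), sigma)
    phi *= phase_std / phi.std()
    a = gaussian_filter(rng.uniform(size=(n, n)), sigma)
    a = amp_lo + (1 - amp_lo) * (a - a.min()) / (a.max() - a.min())
    return ComplexField(a * np.exp(1j * phi), 1.0, 488.0)


class TestEncodeHologram:
    def test_uniform_phase_gives_straight_grating_near_half_duty(self):
        u = ComplexField(np.ones((128, 128), complex), 1.0, 488.0)
        pat = hf.encode_hologram(u, carrier=(0.0, 1 / 8))
        # duty cycle 50 % up to one pixel-row quantization per period
        assert abs(pat.frame.mean() - 0.5) <= 1 / 8
        assert np.array_equal(pat.frame, np.tile(pat.frame[:1], (128, 1)))

    def test_zero_amplitude_region_all_off(self):
        t = np.ones((64, 64), complex)
        t[:, :32] = 0.0
        pat = hf.encode_hologram(ComplexField(t, 1.0, 488.0), (0.0, 1 / 8))
        assert not pat.frame[:, :32].any()
        assert pat.frame[:, 32:].any()

    def test_over_unit_amplitude_rejected(self):
        t = ComplexField(np.full((16, 16), 1.5 + 0j), 1.0, 488.0)
        with pytest.raises(ValueError):
            hf.encode_hologram(t)

    def test_nyquist_carrier_rejected(self):
        u = ComplexField(np.ones((16, 16), complex), 1.0, 488.0)
        with pytest.raises(ValueError):
            hf.encode_hologram(u, carrier=(0.4, 0.4))


class TestFirstOrder:
    def test_uniform_grating_gives_flat_phase(self):
        u = ComplexField(np.ones((128, 128), complex), 1.0, 488.0)
        pat = hf.encode_hologram(u, carrier=(0.0, 1 / 8))
        rec = hf.simulate_first_order(pat, 0.07)
        inner = rec.amplitude[20:-20, 20:-20]
        phase = np.angle(inner * np.exp(-1j * np.angle(inner.mean())))
        assert phase.std() < 1e-6

    def test_linear_in_the_frame(self):
        rng = np.random.default_rng(2)
        f1 = rng.uniform(size=(64, 64)) > 0.5
        f2 = rng.uniform(size=(64, 64)) > 0.5
        # disjoint supports: left half from f1, right half from f2
        a = np.zeros((64, 64), bool); a[:, :32] = f1[:, :32]
        b = np.zeros((64, 64), bool); b[:, 32:] = f2[:, 32:]
        c = a | b
        carrier = (0.0, 1 / 8)
        ra = hf.simulate_first_order(hf.BinaryPattern(a, carrier), 0.07)
        rb = hf.simulate_first_order(hf.BinaryPattern(b, carrier), 0.07)
        rc = hf.simulate_first_order(hf.BinaryPattern(c, carrier), 0.07)
        assert np.abs(rc.amplitude - (ra.amplitude + rb.amplitude)).max() < 1e-10

    def test_overlapping_orders_rejected(self):
        pat = hf.BinaryPattern(np.zeros((32, 32), bool), (0.0, 0.1))
        with pytest.raises(ValueError):
            hf.simulate_first_order(pat, 0.2)

    def test_round_trip_phase_error(self):
        # smooth random phase at the default 1/8-magnitude carrier
        target = smooth_target(256, sigma=24, phase_std=1.0, amp_lo=0.3, seed=0)
        pat = hf.encode_hologram(target, carrier=DEFAULT_CARRIER)
        rec = hf.simulate_first_order(pat, 0.45 / 8)
        sl = (slice(24, -24), slice(24, -24))
        r, t = rec.amplitude[sl], target.amplitude[sl]
        gp = np.angle(np.vdot(t, r))
        rms = np.angle(r * np.conj(t) * np.exp(-1j * gp)).std()
        assert rms < 0.1

    def test_round_trip_relative_phase_between_points(self):
        # relative phase carried between well-separated points, measured on
        # a local window so single-pixel binarization noise averages out
        target = smooth_target(256, sigma=48, phase_std=0.5, amp_lo=0.3, seed=1)
        pat = hf.encode_hologram(target, carrier=DEFAULT_CARRIER)
        rec = hf.simulate_first_order(pat, 0.45 / 8)

        def local_phase(field, i, j, h=3):
            win = field[i - h:i + h + 1, j - h:j + h + 1]
            ref = target.amplitude[i - h:i + h + 1, j - h:j + h + 1]
            return np.angle(np.vdot(np.abs(ref), win))

        pts = [(64, 64), (128, 190), (190, 80), (100, 128)]
        for (i1, j1), (i2, j2) in zip(pts, pts[1:]):
            d_true = (np.angle(target.amplitude[i1, j1])
                      - np.angle(target.amplitude[i2, j2]))
            d_rec = local_phase(rec.amplitude, i1, j1) - local_phase(
                rec.amplitude, i2, j2)
            err = np.angle(np.exp(1j * (d_rec - d_true)))
            assert abs(err) < 0.05

    def test_round_trip_amplitude_correlation(self):
        # very smooth seeded target, iris narrowed to the signal band
        target = smooth_target(384, sigma=40, phase_std=0.5, amp_lo=0.3, seed=0)
        pat = hf.encode_hologram(target, carrier=DEFAULT_CARRIER)
        rec = hf.simulate_first_order(pat, 0.2 / 8)
        sl = (slice(24, -24), slice(24, -24))
        r = np.abs(rec.amplitude[sl]).ravel()
        a = np.abs(target.amplitude[sl]).ravel()
        assert np.corrcoef(r, a)[0, 1] > 0.99


class TestPsiDemodulate:
    def test_algebraic_identity(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        r = 1.7 * np.exp(1j * 0.4) * np.ones((32, 32))
        c = hf.psi_demodulate(make_interferograms(s, r))
        assert np.abs(c / np.conj(r) - s).max() < 1e-10

    def test_zero_signal_gives_zero(self):
        r = np.ones((16, 16), complex)
        c = hf.psi_demodulate(make_interferograms(np.zeros((16, 16)), r))
        assert np.abs(c).max() < 1e-12

    def test_linearity_in_the_signal(self):
        rng = np.random.default_rng(1)
        s1 = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        s2 = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        r = np.ones((16, 16), complex) * 2.0
        c1 = hf.psi_demodulate(make_interferograms(s1, r))
        c2 = hf.psi_demodulate(make_interferograms(s2, r))
        c12 = hf.psi_demodulate(make_interferograms(s1 + s2, r))
        assert np.abs(c12 - (c1 + c2)).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        frames = (np.ones((8, 8)), np.ones((8, 8)), np.ones((8, 8)),
                  np.ones((8, 9)))
        with pytest.raises(ValueError):
            hf.InterferogramSet(intensities=frames)

    def test_poisson_noise_scales_as_inverse_sqrt_photons(self):
        rng0 = np.random.default_rng(123)
        s = rng0.standard_normal((48, 48)) + 1j * rng0.standard_normal((48, 48))
        r = 2.0 * np.ones((48, 48), complex)
        c_true = s * np.conj(r)
        rms = {}
        for n_ph in (1e2, 1e4):
            errs = []
            for seed in range(20):
                ig = make_interferograms(s, r, photons=n_ph,
                                         rng=np.random.default_rng(seed))
                errs.append(np.sqrt(np.mean(
                    np.abs(hf.psi_demodulate(ig) - c_true) ** 2)))
            rms[n_ph] = np.mean(errs)
        # two decades of photon number: rms ratio should be 10 within 20 %
        assert rms[1e2] / rms[1e4] == pytest.approx(10.0, rel=0.2)


class TestPruneInputs:
    def test_disk_indicator_keeps_disk_points(self):
        mask, count = hf.aperture_mask((41, 41), 1.0, 30.0)
        kept = hf.prune_inputs(mask.astype(float), 0.1)
        assert len(kept) == count

    def test_threshold_near_one_keeps_argmax_ties(self):
        v = np.array([0.2, 1.0, 0.5, 1.0])
        kept = hf.prune_inputs(v, 0.999)
        assert list(kept) == [1, 3]

    def test_all_zero_map_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            kept = hf.prune_inputs(np.zeros(10), 0.1)
        assert len(kept) == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            hf.prune_inputs(np.ones(4), 1.5)

    def test_full_scale_window_geometry(self):
        # 201×201 holograms scanned over a window 10 % wider than the core:
        # the kept fraction is the circle-to-window area ratio π/4·(d/w)²
        window = 1.1 * 232.0
        _, kept = hf.aperture_mask((201, 201), window / 201, 232.0)
        assert kept / 201**2 == pytest.approx(np.pi / 4 / 1.1**2, rel=0.01)
        # and lands on the instrument's reported order of magnitude
        assert abs(kept - 26_000) / 26_000 < 0.02


class TestAcquireTM:
    def test_noiseless_columns_match_ground_truth(self, scaled_measured_tm,
                                                  scaled_truth):
        num = np.abs(np.sum(np.conj(scaled_truth) * scaled_measured_tm.matrix,
                            axis=0))
        den = (np.linalg.norm(scaled_truth, axis=0)
               * np.linalg.norm(scaled_measured_tm.matrix, axis=0))
        assert (num / den).min() > 0.999

    def test_zero_transmission_gives_zero_tm(self, scaled_system, scaled_spec,
                                             scaled_modes):
        from dataclasses import replace
        dead = replace(scaled_system.tm,
                       matrix=np.zeros_like(scaled_system.tm.matrix))
        sys0 = hf.FiberSystem(scaled_modes, dead, scaled_spec.pulp_diameter,
                              scaled_spec.na_multimode, input_grid_n=6)
        mtm = hf.acquire_tm(sys0, prune_threshold=0.1)
        # the four-phase cancellation leaves only ~1e-16 float residue
        assert np.abs(mtm.matrix).max() < 1e-12

    def test_noisy_acquisition_deterministic(self, scaled_system):
        a = hf.acquire_tm(scaled_system, photons=1e3, noise_seed=5)
        b = hf.acquire_tm(scaled_system, photons=1e3, noise_seed=5)
        assert np.array_equal(a.matrix, b.matrix)

    def test_pruned_ratio_bounded_by_window_geometry(self, scaled_system,
                                                     scaled_measured_tm):
        # soft mode boundary at small V keeps slightly more than the
        # geometric circle fraction, never fewer
        ratio = len(scaled_measured_tm.kept_inputs) / len(scaled_system.input_points)
        geometric = np.pi / 4 / 1.1**2
        assert geometric <= ratio <= geometric + 0.3


class TestSynthesizeFocus:
    def test_measured_tm_focus_equals_ground_truth_focus(
            self, scaled_measured_tm, scaled_truth):
        t = scaled_measured_tm.matrix.shape[0] // 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, met_m, _ = hf.synthesize_focus(scaled_measured_tm, t,
                                              forward=scaled_truth)
            gt = MeasuredTM(matrix=scaled_truth,
                            kept_inputs=scaled_measured_tm.kept_inputs,
                            output_mask=scaled_measured_tm.output_mask,
                            pitch=scaled_measured_tm.pitch,
                            wavelength=scaled_measured_tm.wavelength,
                            na=scaled_measured_tm.na,
                            input_grid_shape=scaled_measured_tm.input_grid_shape)
            _, met_t, _ = hf.synthesize_focus(gt, t, forward=scaled_truth)
        assert met_m.power_ratio >= 0.95 * met_t.power_ratio
        assert met_m.power_ratio <= 1.0

    def test_unitary_tm_argmax_at_target(self):
        # abstract unitary transport: matched-filter optimality is exact
        u = random_unitary(80, 4)
        mask = np.zeros((9, 9), bool)
        mask.ravel()[:80] = True
        mtm = MeasuredTM(matrix=u, kept_inputs=np.arange(80),
                         output_mask=mask, pitch=1.0, wavelength=488.0,
                         na=0.1, input_grid_shape=(8, 10))
        for t in (0, 33, 79):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, intensity = hf.synthesize_focus(mtm, t)
            assert np.argmax(intensity) == mtm.masked_indices[t]

    def test_power_ratio_in_unit_interval(self, scaled_measured_tm,
                                          scaled_truth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, met, _ = hf.synthesize_focus(scaled_measured_tm, 10,
                                            forward=scaled_truth)
        assert 0.0 <= met.power_ratio <= 1.0

    def test_out_of_mask_target_rejected(self, scaled_measured_tm):
        with pytest.raises(ValueError):
            hf.synthesize_focus(scaled_measured_tm,
                                scaled_measured_tm.matrix.shape[0] + 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_phase_only_enhancement_follows_quarter_pi_law(self, seed):
        u = random_unitary(100, seed)
        enh = phase_only_enhancement(u, 37, seed=seed + 100)
        assert enh == pytest.approx(np.pi / 4 * 100, rel=0.15)


def test_measured_tm_roundtrip(tmp_path, scaled_measured_tm):
    from holofiber.holography_calibration import (load_measured_tm,
                                                  save_measured_tm)
    p = tmp_path / "tm.npz"
    save_measured_tm(p, scaled_measured_tm)
    back = load_measured_tm(p)
    assert np.array_equal(back.matrix, scaled_measured_tm.matrix)
    assert np.array_equal(back.kept_inputs, scaled_measured_tm.kept_inputs)
    assert np.array_equal(back.output_mask, scaled_measured_tm.output_mask)
    assert back.na == scaled_measured_tm.na
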