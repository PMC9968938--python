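import dataclasses
import warnings

import numpy as np
import pytest

import fptycho as fp
from fptycho.recon import ReconConfig, ap_iterate, dip_ratio


class TestInitializeGuess:
    def test_flat_mode_all_energy_at_dc(self, cfg):
        sel = fp.select_leds(cfg, 5)
        gt = fp.make_tissue_phantom(
            fp.PhantomSpec(shape_hr=(64, 64), pixel_size_um=0.25,
                           max_phase=1.0))
        stack = fp.simulate_stack(gt, cfg, sel, q=4)
        spec = fp.initialize_guess(stack, ReconConfig(q=4, init="flat"))
        assert spec.shape == (64, 64)
        off_dc = spec.copy()
        off_dc[32, 32] = 0
        assert np.abs(off_dc).max() == 0
        assert np.abs(spec[32, 32]) > 0

    def test_central_brightfield_flat_object_matches_flat_mode(self, cfg):
        sel = fp.select_leds(cfg, 5)
        gt = fp.make_tissue_phantom(
            fp.PhantomSpec(shape_hr=(64, 64), pixel_size_um=0.25,
                           max_phase=1.0))
        stack = fp.simulate_stack(gt, cfg, sel, q=4)
        a = fp.initialize_guess(stack, ReconConfig(q=4, init="flat"))
        b = fp.initialize_guess(stack, ReconConfig(q=4,
                                                   init="central_brightfield"))
        assert np.allclose(a, b, atol=1e-8 * np.abs(a).max())

    def test_output_shape_is_q_times_lr(self, inband_roundtrip):
        stack = inband_roundtrip["stack"]
        spec = fp.initialize_guess(stack, ReconConfig(q=4))
        assert spec.shape == (4 * 64, 4 * 64)

    def test_missing_on_axis_frame_raises(self, cfg):
        sel = fp.select_leds(cfg, 5)
        gt = fp.make_tissue_phantom(
            fp.PhantomSpec(shape_hr=(64, 64), pixel_size_um=0.25,
                           max_phase=1.0))
        stack = fp.simulate_stack(gt, cfg, sel, q=4)
        keep = [k for k, p in enumerate(stack.led_positions_mm)
                if p != (0.0, 0.0)]
        trimmed = fp.LRStack(frames=stack.frames[keep],
                             led_ids=[stack.led_ids[k] for k in keep],
                             led_positions_mm=[stack.led_positions_mm[k]
                                               for k in keep],
                             cfg=cfg, q=4, pixel_size_lr_um=1.0)
        with pytest.raises(ValueError, match="on-axis"):
            fp.initialize_guess(trimmed, ReconConfig(q=4))


class TestApIterate:
    def test_truth_is_fixed_point(self, inband_roundtrip):
        rt = inband_roundtrip
        truth_spec = np.fft.fftshift(np.fft.fft2(rt["gt"].field.data))
        res = ap_iterate(truth_spec.copy(), rt["stack"],
                         ReconConfig(n_iters=3, q=4))
        assert fp.field_rmse(res.field.data, rt["gt"].field.data) < 1e-12
        assert max(res.error_trace) < 1e-20

    def test_flat_stack_flat_reconstruction(self, cfg):
        sel = fp.select_leds(cfg, 5)
        gt = fp.make_tissue_phantom(
            fp.PhantomSpec(shape_hr=(64, 64), pixel_size_um=0.25,
                           max_phase=1.0))
        stack = fp.simulate_stack(gt, cfg, sel, q=4)
        res = fp.reconstruct_patch(stack, ReconConfig(n_iters=5, q=4))
        assert res.amplitude.std() / res.amplitude.mean() < 1e-6
        assert res.error_trace[0] < 1e-12

    def test_single_on_axis_led_no_resolution_gain(self, cfg):
        sel = fp.select_leds(cfg, 1)
        gt = fp.kidney_phantom(shape=(128, 128), pixel_size_um=0.25, seed=2)
        stack = fp.simulate_stack(gt, cfg, sel, q=4)
        res = fp.reconstruct_patch(stack, ReconConfig(n_iters=5, q=4), sel)
        # one projection: amplitude is the upsampled bright-field, phase flat
        lr_amp = np.sqrt(stack.frames[0])
        assert res.na_synthetic == pytest.approx(0.1)
        phases = res.phase[res.amplitude > 0.1 * res.amplitude.max()]
        spread = np.angle(np.exp(1j * (phases - phases.mean())))
        assert np.abs(spread).max() < 1e-4
        assert res.amplitude.mean() == pytest.approx(lr_amp.mean(), rel=1e-6)

    def test_error_trace_non_increasing(self, inband_roundtrip):
        rt = inband_roundtrip
        rc = ReconConfig(n_iters=20, q=4)
        res = ap_iterate(fp.initialize_guess(rt["stack"], rc), rt["stack"], rc)
        t = np.array(res.error_trace[1:])
        assert np.all(np.diff(t) <= 1e-6 * t[0])

    def test_determinism(self, inband_roundtrip):
        rt = inband_roundtrip
        rc = ReconConfig(n_iters=5, q=4)
        r1 = fp.reconstruct_patch(rt["stack"], rc)
        r2 = fp.reconstruct_patch(rt["stack"], rc)
        assert np.array_equal(r1.field.data, r2.field.data)

    def test_shifted_pupil_out_of_grid_names_led(self, cfg):
        # q=1 leaves no headroom for off-axis sub-apertures
        sel = fp.select_leds(cfg, 9)
        gt = fp.kidney_phantom(shape=(64, 64), pixel_size_um=1.058, seed=0)
        stack = fp.simulate_stack(gt, cfg, fp.select_leds(cfg, 1), q=1)
        big = dataclasses.replace(cfg, n_leds_active=9)
        bad = fp.LRStack(frames=np.tile(stack.frames, (9, 1, 1)),
                         led_ids=sel.indices, led_positions_mm=sel.positions_mm,
                         cfg=big, q=1, pixel_size_lr_um=1.058)
        with pytest.raises(ValueError, match="LED"):
            fp.reconstruct_patch(bad, ReconConfig(n_iters=1, q=1))

    def test_sparse_led_grid_warns_on_low_overlap(self, cfg):
        sparse = dataclasses.replace(cfg, led_pitch_mm=14.0, n_leds_active=5)
        sel = fp.select_leds(sparse)
        gt = fp.kidney_phantom(shape=(128, 128), pixel_size_um=0.25, seed=1)
        stack = fp.simulate_stack(gt, sparse, sel, q=4)
        with pytest.warns(UserWarning, match="overlap"):
            fp.reconstruct_patch(stack, ReconConfig(n_iters=1, q=4), sel)

    def test_paper_geometry_does_not_warn(self, inband_roundtrip):
        rt = inband_roundtrip
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fp.reconstruct_patch(rt["stack"], ReconConfig(n_iters=1, q=4))


class TestRoundTrip:
    def test_recovery_at_convergence(self, inband_roundtrip):
        """Noise-free in-band acquisition is inverted essentially exactly."""
        rt = inband_roundtrip
        res = fp.reconstruct_patch(rt["stack"], ReconConfig(n_iters=250, q=4),
                                   rt["sel"])
        assert fp.field_rmse(res.field.data, rt["gt"].field.data) < 0.02
        assert fp.phase_rmse(res.field.data, rt["gt"].field.data,
                             rt["support"]) < 0.05
        amp = np.abs(fp.global_phase_align(res.field.data,
                                           rt["gt"].field.data))
        ref = rt["gt"].true_amplitude
        assert np.sqrt(((amp - ref) ** 2).mean()) / ref.mean() < 0.05

    def test_resimulation_consistency(self, inband_roundtrip):
        rt = inband_roundtrip
        res = fp.reconstruct_patch(rt["stack"], ReconConfig(n_iters=60, q=4))
        assert fp.data_fidelity(res.spectrum, rt["stack"], 4) < 1e-3

    def test_patch_upsampling_contract(self, inband_roundtrip):
        rt = inband_roundtrip
        res = fp.reconstruct_patch(rt["stack"], ReconConfig(n_iters=1, q=4))
        assert res.field.shape == (256, 256)
        assert res.field.pixel_size_um == pytest.approx(
            rt["stack"].pixel_size_lr_um / 4)


class TestDataFidelity:
    def test_zero_at_exact_solution(self, inband_roundtrip):
        rt = inband_roundtrip
        truth_spec = np.fft.fftshift(np.fft.fft2(rt["gt"].field.data))
        assert fp.data_fidelity(truth_spec, rt["stack"], 4) < 1e-20

    def test_invariant_to_global_phase(self, inband_roundtrip):
        rt = inband_roundtrip
        truth_spec = np.fft.fftshift(np.fft.fft2(rt["gt"].field.data))
        rotated = truth_spec * np.exp(1j * 0.7)
        assert fp.data_fidelity(rotated, rt["stack"], 4) < 1e-20

    def test_positive_for_perturbed_solution(self, inband_roundtrip):
        rt = inband_roundtrip
        truth_spec = np.fft.fftshift(np.fft.fft2(rt["gt"].field.data))
        rng = np.random.default_rng(0)
        noisy = truth_spec * (1 + 0.05 * rng.normal(size=truth_spec.shape))
        assert fp.data_fidelity(noisy, rt["stack"], 4) > 1e-6


class TestResolutionGain:
    def test_two_points_resolved_beyond_coherent_sparrow(self, cfg, sel177):
        """FPM resolves a 1.8x-half-pitch pair the 0.1-NA image cannot.

        1.8 x lambda/(2 NA_syn) = 0.90 µm sits beyond the coherent
        two-point Sparrow distance of the synthetic aperture (so a true
        central dip exists) yet far below the 3.16 µm objective-only
        half-pitch: the pair lands on adjacent LR pixels and cannot even be
        sampled apart in the bright-field frame.
        """
        q, n_lr = 8, 64
        pix = cfg.pixel_size_lr_um / q
        n = q * n_lr
        sep = 1.8 * fp.theoretical_resolution(cfg, sel177)
        spec = fp.PhantomSpec(shape_hr=(n, n), pixel_size_um=pix,
                              max_phase=1.0)
        gt = fp.make_resolution_target(sep, spec)
        stack = fp.simulate_stack(gt, cfg, sel177, q=q)
        res = fp.reconstruct_patch(stack, ReconConfig(n_iters=60, q=q),
                                   sel177)
        cr, cc = n // 2, n // 2
        sep_px = round(sep / pix)
        left = cc - sep_px // 2
        right = left + sep_px
        ratio = dip_ratio(res.phase[cr], left, right)
        assert ratio is not None and ratio < 0.8
        # bright-field frame: pair collapses onto adjacent pixels
        lr = stack.frames[stack.central_index()]
        lr_sep = round(sep / stack.pixel_size_lr_um)
        lr_left = n_lr // 2 - lr_sep // 2
        assert dip_ratio(1 - lr[n_lr // 2], lr_left, lr_left + lr_sep) is None


def test_dip_ratio_basic():
    prof = np.array([0.1, 1.0, 0.5, 0.9, 0.1])
    assert dip_ratio(prof, 1, 3) == pytest.approx(0.5)
    assert dip_ratio(prof, 1, 2) is None


def test_global_phase_align_recovers_rotation():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
    est = 1.7 * ref * np.exp(1j * 1.1)
    aligned = fp.global_phase_align(est, ref)
    assert np.allclose(aligned, ref, atol=1e-10)
    assert fp.field_rmse(est, ref) < 1e-12
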