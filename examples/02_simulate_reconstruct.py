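"""Round trip: simulate an LED acquisition and recover the phase.

Builds a kidney-like phantom (glomerulus blob cluster, tubule rings, red
blood cells), band-limits it to the synthetic aperture, simulates the
49-LED low-resolution intensity stack at 64x64 pixels, reconstructs with
60 alternate-projection iterations at q=4, and prints recovery metrics.
"""

import dataclasses

import fptycho as fp
from fptycho.recon import ReconConfig

cfg = dataclasses.replace(fp.paper_setup(), n_leds_active=49)
sel = fp.select_leds(cfg)
q = 4
pixel_hr = cfg.pixel_size_lr_um / q

gt = fp.kidney_phantom(shape=(256, 256), pixel_size_um=pixel_hr,
                       max_phase=1.5, seed=3)
f_max = fp.synthetic_na(cfg, sel) / cfg.wavelength_um
gt = fp.bandlimit(gt, 0.9 * f_max)

stack = fp.simulate_stack(gt, cfg, sel, q=q)
print(f"simulated {len(stack)} LR frames of {stack.frame_shape} "
      f"({stack.pixel_size_lr_um:.3f} um pixels)")

result = fp.reconstruct_patch(stack, ReconConfig(n_iters=60, q=q), sel)
print(f"reconstructed {result.field.shape} field, "
      f"NA_syn = {result.na_synthetic:.3f}, "
      f"predicted resolution {result.resolution_um:.2f} um")

phase_err = fp.phase_rmse(result.field.data, gt.field.data)
field_err = fp.field_rmse(result.field.data, gt.field.data)
fidelity = fp.data_fidelity(result.spectrum, stack, q)
print(f"phase RMSE vs truth:    {phase_err:.4f} rad")
print(f"complex-field RMSE:     {field_err:.4f} (relative)")
print(f"re-simulation fidelity: {fidelity:.2e}")

# A noise-free in-band acquisition is inverted to a few-percent error in
# 60 iterations; the fidelity shows the recovered field reproduces every
# measured frame almost exactly.
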