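"""Patchwise tiling and feathered stitching of a wide field of view.

Cuts a smooth synthetic phase surface into overlapping tiles, stitches
them back with linear feathering (the raster-grid artifact suppression
used for full-frame mosaics), and verifies the blend is seamless.
"""

import numpy as np

import fptycho as fp

# full-frame bookkeeping with the default camera
cfg = fp.paper_setup()
plan_full = fp.plan_tiles((cfg.frame_rows, cfg.frame_cols), 100, 0)
print(f"full frame {cfg.frame_rows}x{cfg.frame_cols}: "
      f"{plan_full.n_tiles} patches of 100x100")
print(f"overlapped plan (40 px): "
      f"{fp.plan_tiles((cfg.frame_rows, cfg.frame_cols), 100, 40).n_tiles} "
      f"tiles, HR overlap {5 * 40} px at q=5")

# small demonstration: cut + stitch a smooth surface exactly
plan = fp.plan_tiles((120, 120), 60, 20)
q = 2
yy, xx = np.mgrid[0:240, 0:240] / 240.0
truth = np.sin(3 * yy) + np.cos(2 * xx)
patches = [truth[r * q:r * q + 120, c * q:c * q + 120]
           for r, c in plan.offsets]
mosaic = fp.stitch_patches(patches, plan, q=q)
print(f"\nstitched {plan.n_tiles} overlapping tiles -> {mosaic.shape}")
print(f"max seam error: {np.abs(mosaic - truth).max():.2e} "
      f"(feather weights form a partition of unity)")

scan = fp.plan_fov_scan((17.1, 9.8), cfg)
print(f"\nmotorized scan of a 17.1 x 9.8 mm slide: "
      f"{scan.n_fovs} FoVs ({scan.grid_rows} rows x {scan.grid_cols} cols)")
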