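import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import fptycho as fp

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    """Default instrument profile (32x32 LEDs, 0.1 NA, red channel)."""
    return fp.paper_setup()


@pytest.fixture(scope="session")
def sel177(cfg):
    return fp.select_leds(cfg)


@pytest.fixture(scope="session")
def reduced_cfg(cfg):
    """49-LED reduced profile used for fast round-trip experiments."""
    return dataclasses.replace(cfg, n_leds_active=49)


@pytest.fixture(scope="session")
def inband_roundtrip(reduced_cfg):
    """Noise-free acquisition of an in-band phantom at reduced scale.

    64x64 LR patch, 49 LEDs, q=4; the phantom is low-passed to 90% of the
    synthetic aperture so a noise-free stack determines it completely.
    """
    sel = fp.select_leds(reduced_cfg)
    q = 4
    pix_hr = reduced_cfg.pixel_size_lr_um / q
    gt = fp.kidney_phantom(shape=(256, 256), pixel_size_um=pix_hr,
                           max_phase=1.5, seed=3)
    f_max = fp.synthetic_na(reduced_cfg, sel) / reduced_cfg.wavelength_um
    gt_ib = fp.bandlimit(gt, 0.9 * f_max)
    stack = fp.simulate_stack(gt_ib, reduced_cfg, sel, q=q)
    support = gt.true_phase.values > 0.1
    return dict(cfg=reduced_cfg, sel=sel, q=q, gt=gt_ib, stack=stack,
                support=support)
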