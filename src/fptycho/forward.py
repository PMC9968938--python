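"""Coherent forward model: from a complex object to LED-wise LR intensities.

For the i-th LED the object is illuminated by a tilted plane wave, so the
transmitted field is ``t(r) = s(r) exp(j 2 pi f_i . r)``.  The objective
low-pass filters the field with the binary pupil H(f) and the camera records
``I_i = |t * h|^2``.  On the discrete grid this is implemented in the
Fourier domain: take the centred spectrum of s, extract the pupil-sized
block centred at the (nearest-pixel) illumination offset, apply the mask,
and inverse-transform at the low-resolution sampling — i.e. downsampling by
ideal spectral cropping, consistent with a band-limited coherent image.

Intensities are normalised so a flat unit-amplitude object under the
on-axis LED yields intensity 1 everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .config import InstrumentConfig
from .fields import ComplexField
from .geometry import (FrequencyVector, LEDSelection, Pupil,
                       illumination_frequency, make_pupil)
from .phantom import GroundTruth

__all__ = ["LRStack", "transmit", "simulate_lr_frame", "simulate_stack",
           "spectral_shift_px", "save_stack", "load_stack"]


@dataclass
class LRStack:
    """Ordered low-resolution intensity frames with their LED metadata."""
    frames: np.ndarray                      # (n_leds, n, n), intensities >= 0
    led_ids: list[tuple[int, int]]
    led_positions_mm: list[tuple[float, float]]
    cfg: InstrumentConfig
    q: int                                  # HR/LR upsampling factor
    pixel_size_lr_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_leds, rows, cols) array")
        if len(self.led_ids) != len(self.frames) or \
           len(self.led_positions_mm) != len(self.frames):
            raise ValueError("led metadata length mismatch")
        if (self.frames < 0).any():
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def central_index(self) -> int:
        """Index of the on-axis (smallest-radius) LED frame."""
        r = [x * x + y * y for x, y in self.led_positions_mm]
        k = int(np.argmin(r))
        if r[k] > (0.25 * self.cfg.led_pitch_mm) ** 2:
            raise ValueError("stack contains no on-axis LED frame")
        return k


def spectral_shift_px(freq: FrequencyVector, freq_step: float) -> tuple[int, int]:
    """Centred-grid pixel offset (rows, cols) of a LED's sub-aperture.

    An off-axis LED shifts the accessible object band to be centred at the
    illumination frequency; with the sign convention of
    :func:`fptycho.geometry.illumination_frequency` (f = -sin(angle)/lambda)
    the sub-aperture centre in the object's centred spectrum sits at
    ``-f_i / freq_step``, rounded to the nearest spectral pixel.
    """
    return (round(-freq.fy / freq_step), round(-freq.fx / freq_step))


def transmit(obj: ComplexField, freq: FrequencyVector) -> ComplexField:
    """Object field times the tilted-illumination factor exp(j 2 pi f.r)."""
    nr, nc = obj.shape
    p = obj.pixel_size_um
    y = (np.arange(nr) - nr // 2) * p
    x = (np.arange(nc) - nc // 2) * p
    ramp = np.exp(2j * np.pi * (freq.fy * y[:, None] + freq.fx * x[None, :]))
    return ComplexField(obj.data * ramp, p)


def _check_square(obj: ComplexField, q: int) -> tuple[int, int]:
    nr, nc = obj.shape
    if nr != nc:
        raise ValueError("object grid must be square")
    if nr % q:
        raise ValueError(f"grid side {nr} not divisible by q={q}")
    return nr, nr // q


def simulate_lr_frame(obj: ComplexField, freq: FrequencyVector,
                      pupil: Pupil, q: int) -> np.ndarray:
    """One low-resolution intensity frame for a single LED.

    ``pupil`` must be built on the LR grid with the LR pixel size
    (``q * obj.pixel_size_um``); its frequency step then equals the HR
    spectrum's step, so the pupil-masked crop is a plain block extraction.
    """
    n_hr, n_lr = _check_square(obj, q)
    if pupil.grid_shape != (n_lr, n_lr):
        raise ValueError("pupil grid does not match the LR frame size")
    spectrum = np.fft.fftshift(np.fft.fft2(obj.data))
    block = _extract_block(spectrum, freq, pupil, n_lr, label="LED")
    field_lr = np.fft.ifft2(np.fft.ifftshift(block * pupil.mask)) / q ** 2
    return np.abs(field_lr) ** 2


def _extract_block(spectrum: np.ndarray, freq: FrequencyVector,
                   pupil: Pupil, n_lr: int, label: str = "LED"):
    n_hr = spectrum.shape[0]
    dr, dc = spectral_shift_px(freq, pupil.freq_step)
    r0 = n_hr // 2 + dr - n_lr // 2
    c0 = n_hr // 2 + dc - n_lr // 2
    if r0 < 0 or c0 < 0 or r0 + n_lr > n_hr or c0 + n_lr > n_hr:
        raise ValueError(
            f"shifted pupil for {label} at offset ({dr}, {dc}) px exceeds "
            f"the {n_hr}x{n_hr} spectral grid; increase q or the grid size")
    return spectrum[r0:r0 + n_lr, c0:c0 + n_lr]


def simulate_stack(gt: GroundTruth, cfg: InstrumentConfig,
                   sel: LEDSelection, q: int,
                   noise: str | None = None, photons: float = 1e4,
                   quantize: bool = False, seed: int | None = None) -> LRStack:
    """Simulate the full acquisition: one LR frame per selected LED.

    Frames follow ``sel.radial_order`` (centre-outward).  ``noise="poisson"``
    applies shot noise at a mean of ``photons`` photons per unit intensity;
    ``quantize`` then maps the stack to integer digital numbers in
    [0, 2**bit_depth - 1] scaled by the stack maximum.
    """
    obj = gt.field
    n_hr, n_lr = _check_square(obj, q)
    pupil = make_pupil(cfg, n_lr, q * obj.pixel_size_um)
    spectrum = np.fft.fftshift(np.fft.fft2(obj.data))
    frames, ids, pos = [], [], []
    for k in sel.radial_order:
        p = sel.positions_mm[k]
        freq = illumination_frequency(p, cfg)
        block = _extract_block(spectrum, freq, pupil, n_lr,
                               label=f"LED {sel.indices[k]}")
        field_lr = np.fft.ifft2(np.fft.ifftshift(block * pupil.mask)) / q ** 2
        frames.append(np.abs(field_lr) ** 2)
        ids.append(sel.indices[k])
        pos.append(p)
    frames = np.asarray(frames)
    if noise not in (None, "none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if noise == "poisson":
        if photons <= 0:
            raise ValueError("photons must be > 0")
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames * photons).astype(float) / photons
    if quantize:
        levels = 2 ** cfg.bit_depth - 1
        peak = frames.max()
        if peak > 0:
            frames = np.round(frames * (levels / peak))
    return LRStack(frames=frames, led_ids=ids, led_positions_mm=pos,
                   cfg=cfg, q=q, pixel_size_lr_um=q * obj.pixel_size_um)


# ---------------------------------------------------------------------------
# I/O: multi-page float TIFF + JSON manifest
# ---------------------------------------------------------------------------

def save_stack(stack: LRStack, basepath: str | Path) -> None:
    """Write ``<base>.tif`` (one page per LED, radial order) + manifest."""
    import tifffile
    base = Path(basepath)
    tifffile.imwrite(base.with_suffix(".tif"),
                     stack.frames.astype(np.float32))
    manifest = {
        "config": stack.cfg.to_dict(),
        "led_ids": [list(i) for i in stack.led_ids],
        "led_positions_mm": [list(p) for p in stack.led_positions_mm],
        "q": stack.q,
        "pixel_size_lr_um": stack.pixel_size_lr_um,
        "page_order": "radial",
    }
    base.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_stack(basepath: str | Path) -> LRStack:
    import tifffile
    base = Path(basepath)
    if not base.with_suffix(".json").exists():
        raise FileNotFoundError(f"missing LED manifest {base.with_suffix('.json')}")
    manifest = json.loads(base.with_suffix(".json").read_text())
    frames = tifffile.imread(base.with_suffix(".tif")).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return LRStack(
        frames=frames,
        led_ids=[tuple(i) for i in manifest["led_ids"]],
        led_positions_mm=[tuple(p) for p in manifest["led_positions_mm"]],
        cfg=InstrumentConfig.from_dict(manifest["config"]),
        q=int(manifest["q"]),
        pixel_size_lr_um=float(manifest["pixel_size_lr_um"]),
    )
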