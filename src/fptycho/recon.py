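"""Alternate-projection Fourier-ptychographic phase retrieval.

The reconstruction maintains one high-resolution centred spectrum covering
the synthetic aperture and cycles through the LEDs, alternating between two
constraints:

* space domain — the low-resolution field estimate for LED i must have
  modulus ``sqrt(I_i)`` (the measurement), its phase is kept;
* Fourier domain — the update may only change the spectrum inside that
  LED's shifted pupil support.

Sequential hard replacement (no relaxation), centre-outward LED order, and
a fixed iteration count (default 60) are the defaults; all are
configurable.  The recovered field is known only up to a global phase (and
amplitude scale when frames are rescaled), so the comparison helpers align
those before computing errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import ComplexField
from .forward import LRStack, _extract_block, spectral_shift_px
from .geometry import (LEDSelection, illumination_frequency, make_pupil,
                       pupil_overlap_fraction, synthetic_na,
                       theoretical_resolution)

__all__ = ["ReconConfig", "ReconResult", "initialize_guess", "ap_iterate",
           "data_fidelity", "reconstruct_patch",
           "global_phase_align", "field_rmse", "phase_rmse", "dip_ratio"]

#: Adjacent sub-apertures sharing less area than this trigger a warning.
MIN_PUPIL_OVERLAP = 0.40


@dataclass
class ReconConfig:
    """Knobs of the alternate-projection solver."""
    n_iters: int = 60
    q: int = 5
    led_order: str = "radial"          # "radial" | "acquisition"
    init: str = "central_brightfield"  # "central_brightfield" | "flat"
    convergence_tol: float = 0.0       # relative spectrum change; 0 = run all
    track_error: bool = True

    def __post_init__(self) -> None:
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.led_order not in ("radial", "acquisition"):
            raise ValueError("led_order must be 'radial' or 'acquisition'")
        if self.init not in ("central_brightfield", "flat"):
            raise ValueError("init must be 'central_brightfield' or 'flat'")


@dataclass
class ReconResult:
    """Recovered complex field plus solver diagnostics."""
    field: ComplexField
    spectrum: np.ndarray
    error_trace: list[float] = dc_field(default_factory=list)
    na_synthetic: float = float("nan")
    resolution_um: float = float("nan")
    n_iters_run: int = 0

    @property
    def amplitude(self) -> np.ndarray:
        return self.field.amplitude

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]; unwrap explicitly via phase_tools."""
        return self.field.phase


def initialize_guess(stack: LRStack, rc: ReconConfig) -> np.ndarray:
    """Initial HR centred spectrum, shape ``q * LR shape``.

    ``central_brightfield``: the sqrt of the on-axis intensity frame,
    upsampled by zero-padding its spectrum (zero phase).  ``flat``: all
    energy at DC, scaled to the stack's mean amplitude.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    n_lr = stack.frame_shape[0]
    n_hr = rc.q * n_lr
    if rc.init == "flat":
        spec = np.zeros((n_hr, n_hr), dtype=complex)
        spec[n_hr // 2, n_hr // 2] = n_hr ** 2 * np.sqrt(stack.frames.mean())
        return spec
    k = stack.central_index()   # raises if no on-axis frame
    a0 = np.sqrt(stack.frames[k])
    spec_lr = np.fft.fftshift(np.fft.fft2(a0)) * rc.q ** 2
    spec = np.zeros((n_hr, n_hr), dtype=complex)
    lo = n_hr // 2 - n_lr // 2
    spec[lo:lo + n_lr, lo:lo + n_lr] = spec_lr
    return spec


def _led_frequencies(stack: LRStack):
    return [illumination_frequency(p, stack.cfg)
            for p in stack.led_positions_mm]


def _iteration_order(stack: LRStack, rc: ReconConfig) -> list[int]:
    if rc.led_order == "acquisition":
        return list(range(len(stack)))
    r = [x * x + y * y for x, y in stack.led_positions_mm]
    return sorted(range(len(stack)), key=lambda k: (r[k], stack.led_ids[k]))


def ap_iterate(spectrum: np.ndarray, stack: LRStack,
               rc: ReconConfig) -> ReconResult:
    """Run the alternate-projection loop on an initial HR spectrum."""
    n_lr = stack.frame_shape[0]
    n_hr = spectrum.shape[0]
    if n_hr != rc.q * n_lr:
        raise ValueError("spectrum shape inconsistent with q * LR shape")
    pupil = make_pupil(stack.cfg, n_lr, stack.pixel_size_lr_um)
    if pupil_overlap_fraction(stack.cfg) < MIN_PUPIL_OVERLAP:
        warnings.warn(
            "adjacent LED sub-apertures overlap by less than "
            f"{MIN_PUPIL_OVERLAP:.0%}; alternate projections may stagnate",
            stacklevel=2)
    freqs = _led_frequencies(stack)
    order = _iteration_order(stack, rc)
    mask = pupil.mask.astype(bool)
    q2 = rc.q ** 2
    centre = n_hr // 2
    # precompute block corners, validating every LED against the grid
    corners = []
    for k in range(len(stack)):
        dr, dc = spectral_shift_px(freqs[k], pupil.freq_step)
        r0, c0 = centre + dr - n_lr // 2, centre + dc - n_lr // 2
        if r0 < 0 or c0 < 0 or r0 + n_lr > n_hr or c0 + n_lr > n_hr:
            raise ValueError(
                f"shifted pupil of LED {stack.led_ids[k]} exceeds the "
                f"{n_hr}x{n_hr} spectral grid")
        corners.append((r0, c0))
    sqrt_meas = np.sqrt(stack.frames)
    norm = stack.frames.sum()
    spec = spectrum.astype(complex).copy()
    trace: list[float] = []
    n_run = 0
    for it in range(rc.n_iters):
        prev = spec.copy() if rc.convergence_tol > 0 else None
        err = 0.0
        for k in order:
            r0, c0 = corners[k]
            block = spec[r0:r0 + n_lr, c0:c0 + n_lr]
            psi = np.fft.ifft2(np.fft.ifftshift(block * mask)) / q2
            amp = np.abs(psi)
            if rc.track_error:
                err += ((amp - sqrt_meas[k]) ** 2).sum()
            # space-domain constraint: impose the measured modulus
            with np.errstate(invalid="ignore", divide="ignore"):
                psi_new = np.where(amp > 0, psi / amp, 1.0) * sqrt_meas[k]
            update = np.fft.fftshift(np.fft.fft2(psi_new)) * q2
            block[mask] = update[mask]
        if rc.track_error:
            trace.append(err / norm)
        n_run = it + 1
        if prev is not None:
            delta = np.linalg.norm(spec - prev) / max(np.linalg.norm(prev), 1e-30)
            if delta < rc.convergence_tol:
                break
    field = np.fft.ifft2(np.fft.ifftshift(spec))
    pixel_hr = stack.pixel_size_lr_um / rc.q
    return ReconResult(field=ComplexField(field, pixel_hr), spectrum=spec,
                       error_trace=trace, n_iters_run=n_run)


def data_fidelity(spectrum: np.ndarray, stack: LRStack, q: int) -> float:
    """Normalised intensity misfit sum_i ||sqrt(I_est,i) - sqrt(I_i)||² / sum I."""
    n_lr = stack.frame_shape[0]
    pupil = make_pupil(stack.cfg, n_lr, stack.pixel_size_lr_um)
    mask = pupil.mask
    total = 0.0
    for k, p in enumerate(stack.led_positions_mm):
        freq = illumination_frequency(p, stack.cfg)
        block = _extract_block(spectrum, freq, pupil, n_lr,
                               label=f"LED {stack.led_ids[k]}")
        psi = np.fft.ifft2(np.fft.ifftshift(block * mask)) / q ** 2
        total += ((np.abs(psi) - np.sqrt(stack.frames[k])) ** 2).sum()
    return total / stack.frames.sum()


def reconstruct_patch(stack: LRStack, rc: ReconConfig | None = None,
                      sel: LEDSelection | None = None) -> ReconResult:
    """End-to-end patch reconstruction: initial guess + AP iterations.

    A square ``n x n`` LR patch yields a ``q*n x q*n`` complex field (with
    the defaults, 100x100 in, 500x500 out).  The result records the
    synthetic NA and predicted half-pitch resolution of the LED set used.
    """
    rc = rc or ReconConfig()
    nr, nc = stack.frame_shape
    if nr != nc:
        raise ValueError("LR patches must be square")
    spec0 = initialize_guess(stack, rc)
    result = ap_iterate(spec0, stack, rc)
    if sel is None:
        sel = LEDSelection(indices=list(stack.led_ids),
                           positions_mm=list(stack.led_positions_mm))
    result.na_synthetic = synthetic_na(stack.cfg, sel)
    result.resolution_um = theoretical_resolution(stack.cfg, sel)
    return result


# ---------------------------------------------------------------------------
# ground-truth comparison helpers (phase retrieval is blind to a global
# phase, and to a global scale when intensities are rescaled)
# ---------------------------------------------------------------------------

def global_phase_align(est: np.ndarray, ref: np.ndarray,
                       scale: bool = True) -> np.ndarray:
    """Rotate (and optionally scale) ``est`` to best match ``ref`` globally."""
    inner = np.vdot(est, ref)
    if np.abs(inner) == 0:
        return est
    phase = inner / np.abs(inner)
    out = est * phase
    if scale:
        denom = np.vdot(out, out).real
        if denom > 0:
            out = out * (np.vdot(out, ref).real / denom)
    return out


def field_rmse(est: np.ndarray, ref: np.ndarray) -> float:
    """Relative complex-field RMSE after global phase/scale alignment."""
    aligned = global_phase_align(est, ref)
    return float(np.linalg.norm(aligned - ref) / np.linalg.norm(ref))


def dip_ratio(profile: np.ndarray, i: int, j: int) -> float | None:
    """Two-point (Rayleigh-style) dip statistic along a 1D profile.

    Returns ``min(profile[i+1:j]) / max(profile[i], profile[j])`` — below 1
    means a central dip separates the two peaks (resolved); ``None`` when
    the peaks have no interior samples (unresolvable on this grid).
    """
    if j <= i + 1:
        return None
    interior = profile[i + 1:j]
    peak = max(profile[i], profile[j])
    if peak <= 0:
        return None
    return float(interior.min() / peak)


def phase_rmse(est: np.ndarray, ref: np.ndarray,
               support: np.ndarray | None = None) -> float:
    """Phase RMSE (rad) after removing the global phase offset.

    ``support`` restricts the comparison to structure pixels; the offset is
    estimated circularly so wrapped values do not bias it.
    """
    est_p, ref_p = np.angle(est), np.angle(ref)
    diff = np.angle(np.exp(1j * (est_p - ref_p)))
    offset = np.angle(np.exp(1j * diff).mean())
    resid = np.angle(np.exp(1j * (diff - offset)))
    if support is not None:
        resid = resid[support]
    return float(np.sqrt((resid ** 2).mean()))
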