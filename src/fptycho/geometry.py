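"""Illumination and pupil geometry for the LED-array microscope.

A LED at position ``(x, y)`` (mm, relative to the optical axis) illuminates
the sample with a tilted plane wave whose spatial-frequency vector is

    f = -(1/lambda) * (sin(atan(x/d)), sin(atan(y/d)))      [cycles/µm]

where ``d`` is the LED-matrix-to-sample distance.  The objective acts as a
binary circular low-pass filter (coherent transfer function) of radius
``NA/lambda``.  Combining the off-axis illuminations synthesises an aperture

    NA_syn = NA_MO + max_i sin(atan(r_i/d)),

which sets the half-pitch resolution ``lambda / (2 NA_syn)``.

All discrete frequency grids in this package are *centred*: the DC component
sits at index ``n // 2`` (``fftshift`` layout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import InstrumentConfig

__all__ = [
    "LEDSelection", "FrequencyVector", "Pupil",
    "select_leds", "illumination_frequency", "make_pupil",
    "synthetic_na", "theoretical_resolution", "pupil_overlap_fraction",
]


@dataclass(frozen=True)
class FrequencyVector:
    """Spatial-frequency vector of one tilted illumination, cycles/µm."""
    fx: float
    fy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.fx, self.fy)


@dataclass
class LEDSelection:
    """Active LEDs sorted centre-outward.

    ``indices[k]`` is the (row, col) grid coordinate of the k-th LED and
    ``positions_mm[k]`` its (x, y) position relative to the optical axis,
    with x along columns and y along rows.  ``radial_order`` is the identity
    permutation when the lists are already sorted by radius (they are, as
    produced by :func:`select_leds`); it is kept explicit so stacks loaded
    from disk in acquisition order can still be iterated radially.
    """
    indices: list[tuple[int, int]]
    positions_mm: list[tuple[float, float]]
    radial_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.positions_mm):
            raise ValueError("indices and positions length mismatch")
        if not self.radial_order:
            r = [math.hypot(x, y) for x, y in self.positions_mm]
            self.radial_order = sorted(range(len(r)), key=lambda k: (r[k], self.indices[k]))

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def max_radius_mm(self) -> float:
        return max(math.hypot(x, y) for x, y in self.positions_mm)


def led_position(row: int, col: int, cfg: InstrumentConfig) -> tuple[float, float]:
    """(x, y) position in mm of grid LED (row, col) relative to the axis.

    The reference LED is the grid point ``(rows//2, cols//2)``; by default
    the optical axis coincides with it (``axis_offset_mm = (0, 0)``).
    """
    ox, oy = cfg.axis_offset_mm
    x = (col - cfg.led_cols // 2) * cfg.led_pitch_mm - ox
    y = (row - cfg.led_rows // 2) * cfg.led_pitch_mm - oy
    return (x, y)


def select_leds(cfg: InstrumentConfig, n: int | None = None) -> LEDSelection:
    """Select the ``n`` LEDs closest to the optical axis (circular subset).

    Ties in radial distance are broken by (row, col) lexicographic order,
    which makes the selection independent of grid enumeration order.
    """
    if n is None:
        n = cfg.n_leds_active
    if n > cfg.led_rows * cfg.led_cols:
        raise ValueError(f"requested {n} LEDs from a "
                         f"{cfg.led_rows}x{cfg.led_cols} grid")
    if n < 1:
        raise ValueError("need at least one LED")
    entries = []
    for row in range(cfg.led_rows):
        for col in range(cfg.led_cols):
            x, y = led_position(row, col, cfg)
            entries.append((x * x + y * y, row, col, x, y))
    entries.sort()
    chosen = entries[:n]
    return LEDSelection(
        indices=[(r, c) for _, r, c, _, _ in chosen],
        positions_mm=[(x, y) for _, _, _, x, y in chosen],
        radial_order=list(range(n)),
    )


def illumination_frequency(position_mm: tuple[float, float],
                           cfg: InstrumentConfig) -> FrequencyVector:
    """Spatial-frequency vector (cycles/µm) for a LED at ``position_mm``."""
    x, y = position_mm
    d = cfg.led_distance_mm
    lam = cfg.wavelength_um
    return FrequencyVector(
        fx=-math.sin(math.atan2(x, d)) / lam,
        fy=-math.sin(math.atan2(y, d)) / lam,
    )


@dataclass
class Pupil:
    """Binary circular coherent transfer function on a centred frequency grid."""
    radius_freq: float          # cycles/µm, = NA / lambda
    grid_shape: tuple[int, int]
    freq_step: float            # cycles/µm per pixel
    mask: np.ndarray            # float {0,1}, shape = grid_shape

    @property
    def radius_px(self) -> float:
        return self.radius_freq / self.freq_step


def make_pupil(cfg: InstrumentConfig,
               grid_shape: int | tuple[int, int],
               pixel_size_um: float) -> Pupil:
    """Pupil mask of radius ``NA/lambda`` for a grid of given pixel size.

    ``pixel_size_um`` is the *spatial* sampling of the grid the pupil will
    filter; the frequency step is ``1 / (n * pixel_size_um)``.  Rectangular
    grids are supported but must share one frequency step (square pixels and
    equal side lengths), which is the only case the reconstruction uses.
    """
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    nr, nc = grid_shape
    if nr != nc:
        raise ValueError("pupil grids must be square")
    step = 1.0 / (nr * pixel_size_um)
    radius = cfg.na_objective / cfg.wavelength_um
    nyquist = 1.0 / (2.0 * pixel_size_um)
    if radius >= nyquist:
        raise ValueError(
            f"pupil radius {radius:.4f} cycles/µm exceeds the grid Nyquist "
            f"frequency {nyquist:.4f}; decrease pixel_size_um")
    fr = np.fft.fftshift(np.fft.fftfreq(nr, d=pixel_size_um))
    fc = np.fft.fftshift(np.fft.fftfreq(nc, d=pixel_size_um))
    f2 = fr[:, None] ** 2 + fc[None, :] ** 2
    mask = (f2 <= radius * radius).astype(float)
    return Pupil(radius_freq=radius, grid_shape=grid_shape,
                 freq_step=step, mask=mask)


def synthetic_na(cfg: InstrumentConfig, sel: LEDSelection) -> float:
    """Synthetic numerical aperture NA_MO + max illumination NA.

    The largest illumination NA over the selected LEDs is
    ``sin(atan(r_max/d)) = r_max / sqrt(r_max² + d²)``.
    """
    if len(sel) == 0:
        raise ValueError("LED selection is empty")
    r = sel.max_radius_mm
    return cfg.na_objective + r / math.hypot(r, cfg.led_distance_mm)


def theoretical_resolution(cfg: InstrumentConfig, sel: LEDSelection) -> float:
    """Half-pitch lateral resolution lambda / (2 NA_syn), in µm."""
    return cfg.wavelength_um / (2.0 * synthetic_na(cfg, sel))


def pupil_overlap_fraction(cfg: InstrumentConfig) -> float:
    """Fractional area overlap of pupils of two adjacent LEDs near the axis.

    Alternate-projection recovery needs neighbouring sub-apertures to share
    spectral content; overlaps below ~40% are a documented warning heuristic
    in the reconstruction.  Uses the lens-area formula for two circles of
    radius ``NA/lambda`` whose centres differ by one LED pitch of
    illumination frequency.
    """
    r = cfg.na_objective / cfg.wavelength_um
    p, d = cfg.led_pitch_mm, cfg.led_distance_mm
    s = math.sin(math.atan2(p, d)) / cfg.wavelength_um  # adjacent shift
    if s >= 2 * r:
        return 0.0
    lens = 2 * r * r * math.acos(s / (2 * r)) - (s / 2) * math.sqrt(4 * r * r - s * s)
    return lens / (math.pi * r * r)
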