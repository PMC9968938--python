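"""Instrument configuration for the LED-array Fourier ptychographic microscope.

All geometry lives here: the LED matrix (grid size, pitch, distance to the
sample plane), the low-NA objective, and the camera.  Lengths use the units
most natural to each part of the instrument: LED geometry in millimetres,
wavelengths and pixel pitches in micrometres.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Nominal centre wavelengths (µm) of the RGB LED matrix channels.
LED_WAVELENGTHS_UM = {"red": 0.632, "green": 0.532, "blue": 0.472}


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of the LED-array microscope.

    Defaults describe a 32x32 LED matrix with 4 mm pitch placed 46.7 mm
    below the sample, a 0.1-NA objective with an effective magnification of
    4.29 onto a 4.54 µm-pitch, 12-bit, 1460x1940 camera, using the 177 red
    LEDs closest to the optical axis.
    """

    led_rows: int = 32
    led_cols: int = 32
    led_pitch_mm: float = 4.0
    led_distance_mm: float = 46.7
    wavelength_um: float = LED_WAVELENGTHS_UM["red"]
    na_objective: float = 0.1
    magnification: float = 4.29
    camera_pixel_um: float = 4.54
    frame_rows: int = 1460
    frame_cols: int = 1940
    bit_depth: int = 12
    n_leds_active: int = 177
    #: (x, y) offset of the optical axis from the reference LED, in mm.
    #: Zero means the axis coincides with a LED of the grid.
    axis_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("led_pitch_mm", "led_distance_mm", "wavelength_um",
                     "magnification", "camera_pixel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.na_objective < 1:
            raise ValueError("na_objective must lie in (0, 1)")
        if self.n_leds_active > self.led_rows * self.led_cols:
            raise ValueError(
                f"n_leds_active={self.n_leds_active} exceeds grid size "
                f"{self.led_rows}x{self.led_cols}")
        if min(self.led_rows, self.led_cols, self.frame_rows,
               self.frame_cols, self.bit_depth, self.n_leds_active) <= 0:
            raise ValueError("counts must be positive")

    @property
    def pixel_size_lr_um(self) -> float:
        """Object-space pixel size of a raw camera frame (µm)."""
        return self.camera_pixel_um / self.magnification

    @property
    def fov_extent_mm(self) -> tuple[float, float]:
        """Object-space extent (rows_mm, cols_mm) of one camera frame."""
        p = self.pixel_size_lr_um / 1000.0
        return (self.frame_rows * p, self.frame_cols * p)

    def for_channel(self, channel: str) -> "InstrumentConfig":
        """Return a copy configured for the given LED colour channel."""
        try:
            lam = LED_WAVELENGTHS_UM[channel]
        except KeyError:
            raise ValueError(
                f"unknown channel {channel!r}; choose from "
                f"{sorted(LED_WAVELENGTHS_UM)}") from None
        return dataclasses.replace(self, wavelength_um=lam)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis_offset_mm"] = list(self.axis_offset_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "axis_offset_mm" in d:
            d = {**d, "axis_offset_mm": tuple(d["axis_offset_mm"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InstrumentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def paper_setup() -> InstrumentConfig:
    """The packaged default instrument profile (red channel)."""
    ref = importlib.resources.files("fptycho.data") / "paper_setup.yaml"
    return InstrumentConfig.from_dict(yaml.safe_load(ref.read_text()))
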