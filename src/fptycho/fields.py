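"""Core array containers: complex object fields and phase maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ComplexField:
    """A 2D complex field (object, transmitted wave, or reconstruction).

    ``pixel_size_um`` is the object-space sampling of the grid.
    """
    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("ComplexField data must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]."""
        return np.angle(self.data)

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size_um,
                self.shape[1] * self.pixel_size_um)


@dataclass
class PhaseMap:
    """A 2D phase map in radians.

    ``wrapped=True`` asserts that every value lies in (-pi, pi]; unwrapped
    maps are continuous surfaces defined up to one global multiple of 2*pi.
    """
    values: np.ndarray
    wrapped: bool
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PhaseMap values must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.wrapped:
            v = self.values
            if v.size and (v.min() <= -np.pi - 1e-12 or v.max() > np.pi + 1e-12):
                raise ValueError("wrapped phase must lie in (-pi, pi]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_mm2(self) -> float:
        return self.values.size * (self.pixel_size_um * 1e-3) ** 2
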