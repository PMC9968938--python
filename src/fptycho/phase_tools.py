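"""Quantitative post-processing of retrieved phase maps.

Retrieved phase comes wrapped into (-pi, pi]; slides thicker than a few
micrometres (or strongly absorbing stains such as CKpool) push the true
optical path beyond that range, producing phase jumps.  This module wraps
and unwraps phase maps, counts residues (the topological obstructions that
make unwrapping ambiguous and flag regions where the thin-sample
assumption breaks down), and converts unwrapped phase into physical
quantities: optical thickness ``t = phi * lambda / (2 pi delta_n)`` and dry
mass via the specific refraction increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.restoration import unwrap_phase as _sk_unwrap

from .fields import PhaseMap

__all__ = ["PhaseMap", "JumpReport", "wrap", "unwrap", "jump_report",
           "optical_thickness", "dry_mass", "pseudo3d_export"]

#: Residue densities above this (per mm²) void the thin-sample flag.
DEFAULT_RESIDUE_DENSITY_MAX = 10.0


@dataclass
class JumpReport:
    """Diagnostics of phase jumps and unwrapping reliability."""
    residue_count: int
    residue_density_per_mm2: float
    flagged_fraction: float      # pixels in high-gradient zones
    thin_sample_ok: bool


def _wrap_values(v: np.ndarray) -> np.ndarray:
    # maps to (-pi, pi]; the boundary value is +pi (so -pi wraps to +pi)
    return np.pi - np.mod(np.pi - np.asarray(v, dtype=float), 2 * np.pi)


def wrap(phase: PhaseMap) -> PhaseMap:
    """Reduce a phase map into the principal interval (-pi, pi]."""
    return PhaseMap(_wrap_values(phase.values), wrapped=True,
                    pixel_size_um=phase.pixel_size_um)


def unwrap(phase: PhaseMap) -> PhaseMap:
    """2D phase unwrapping (deterministic reliability-guided algorithm).

    The result is continuous wherever the underlying surface is smooth and
    is defined up to one global multiple of 2*pi.  Residue-dense regions do
    not raise; inspect :func:`jump_report` to judge their extent.
    """
    if not phase.wrapped:
        raise ValueError("unwrap expects a wrapped phase map")
    out = np.asarray(_sk_unwrap(phase.values), dtype=float)
    return PhaseMap(out, wrapped=False, pixel_size_um=phase.pixel_size_um)


def residue_map(values: np.ndarray) -> np.ndarray:
    """Signed residue charge on each 2x2 plaquette of a wrapped map.

    Sums the wrapped phase differences around every elementary loop; a
    nonzero sum (+-2*pi) marks a residue, the obstruction that makes
    path-following unwrapping path-dependent.
    """
    dx = _wrap_values(np.diff(values, axis=1))   # (r, c-1)
    dy = _wrap_values(np.diff(values, axis=0))   # (r-1, c)
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return np.rint(loop / (2 * np.pi)).astype(int)


def jump_report(phase: PhaseMap,
                density_max: float = DEFAULT_RESIDUE_DENSITY_MAX,
                gradient_thresh: float = np.pi / 2) -> JumpReport:
    """Count residues and flag whether the thin-sample assumption holds.

    ``thin_sample_ok`` is true when the residue density stays below
    ``density_max`` per mm² (a documented heuristic; scattering or strong
    absorption in thick slides shows up as dense residues where the phase
    is effectively undefined).  ``flagged_fraction`` reports the share of
    pixels whose wrapped gradient magnitude exceeds ``gradient_thresh``.
    """
    if not phase.wrapped:
        raise ValueError("jump_report expects a wrapped phase map")
    charges = residue_map(phase.values)
    count = int(np.count_nonzero(charges))
    density = count / phase.area_mm2
    dx = np.abs(_wrap_values(np.diff(phase.values, axis=1)))
    dy = np.abs(_wrap_values(np.diff(phase.values, axis=0)))
    high = (dx > gradient_thresh).sum() + (dy > gradient_thresh).sum()
    flagged = high / (dx.size + dy.size)
    return JumpReport(residue_count=count,
                      residue_density_per_mm2=float(density),
                      flagged_fraction=float(flagged),
                      thin_sample_ok=bool(density <= density_max))


def inject_vortices(phase: PhaseMap, n: int, seed: int = 0,
                    charge: int = 1) -> PhaseMap:
    """Superpose ``n`` randomly placed phase vortices (synthetic disturbance).

    Emulates the scattering/absorption zones of thick inhomogeneous slides
    where the retrieved phase carries residues and is effectively undefined.
    The output preserves the wrapped/unwrapped state of the input.
    """
    rng = np.random.default_rng(seed)
    nr, nc = phase.shape
    yy, xx = np.mgrid[0:nr, 0:nc].astype(float)
    out = phase.values.copy()
    for _ in range(n):
        cy = rng.uniform(0.2 * nr, 0.8 * nr)
        cx = rng.uniform(0.2 * nc, 0.8 * nc)
        out += charge * np.arctan2(yy - cy, xx - cx)
    if phase.wrapped:
        out = _wrap_values(out)
    return PhaseMap(out, wrapped=phase.wrapped,
                    pixel_size_um=phase.pixel_size_um)


def optical_thickness(phase: PhaseMap, delta_n: float,
                      wavelength_um: float) -> np.ndarray:
    """Per-pixel optical thickness t = phi * lambda / (2 pi delta_n), µm."""
    if phase.wrapped:
        raise ValueError("optical_thickness expects an unwrapped phase map")
    if delta_n <= 0:
        raise ValueError("delta_n must be > 0")
    return phase.values * wavelength_um / (2 * np.pi * delta_n)


def dry_mass(phase: PhaseMap, alpha_um3_per_pg: float = 0.2,
             wavelength_um: float = 0.632) -> float:
    """Total dry mass (pg) from integrated phase.

    ``m = lambda / (2 pi alpha) * sum(phi) * pixel_area`` with ``alpha``
    the specific refraction increment (default 0.2 µm³/pg, the standard
    protein value).
    """
    if phase.wrapped:
        raise ValueError("dry_mass expects an unwrapped phase map")
    if alpha_um3_per_pg <= 0:
        raise ValueError("alpha must be > 0")
    area = phase.pixel_size_um ** 2
    return float(wavelength_um / (2 * np.pi * alpha_um3_per_pg)
                 * phase.values.sum() * area)


def pseudo3d_export(phase: PhaseMap, path: str | Path, k: float = 10.0,
                    fmt: str | None = None) -> Path:
    """Write a display heightfield z = k * phi with axes in physical µm.

    ``k`` (default 10) is a pure visualisation gain and never enters any
    quantitative computation.  Formats: ``csv`` (grid of heights) or
    ``ply`` (ASCII point cloud x,y,z in µm).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    z = k * phase.values
    p = phase.pixel_size_um
    if fmt == "csv":
        np.savetxt(path, z, delimiter=",")
    elif fmt == "ply":
        nr, nc = z.shape
        ys, xs = np.mgrid[0:nr, 0:nc]
        pts = np.column_stack([(xs * p).ravel(), (ys * p).ravel(), z.ravel()])
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {pts.shape[0]}\n"
                     "property float x\nproperty float y\nproperty float z\n"
                     "end_header\n")
            np.savetxt(fh, pts, fmt="%.6g")
    else:
        raise ValueError(f"unknown export format {fmt!r} (csv or ply)")
    return path
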