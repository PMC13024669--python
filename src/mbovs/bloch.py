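"""Isochromat Bloch simulation.

Magnetization is propagated through RF + gradient events with the hard-pulse
approximation: each raster step applies a rotation about the instantaneous
effective field (transverse component ``gamma_bar * B1 * b1_scale``,
longitudinal component ``gamma_bar * Gr * z + off_resonance``, both in Hz),
optionally interleaved with exponential T1/T2 relaxation per step. Spoiling
is modeled as ideal (transverse magnetization zeroed, Mz untouched).

All state lives in an :class:`IsochromatGrid`: a 1D set of positions along
the phase-encode axis, each carrying its own tissue parameters (T1, T2,
off-resonance, transmit-scale, equilibrium magnetization) and a 3-vector
``m = (Mx, My, Mz)``.

Because each raster step is linear in ``m`` (rotation) or affine
(relaxation), the net action of a whole waveform on a fixed grid is an
affine map ``m -> A m + b`` per isochromat. :func:`affine_propagator`
extracts that map once so that repeated applications of the same
suppression module inside a sequence loop cost a single 3x3 multiply.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from .constants import GAMMA_BAR_HZ_PER_UT
from .errors import InvalidSpecError
from .pulses import (
    GradientEvent,
    MultibandSpec,
    PulseShapeSpec,
    RFWaveform,
    SlabGeometry,
    band_bandwidth,
    make_multiband,
    slab_gradient,
    synth_band,
)

__all__ = [
    "IsochromatGrid",
    "ProfileResult",
    "propagate_rf",
    "free_relax",
    "spoil",
    "affine_propagator",
    "apply_affine",
    "simulate_profile",
    "default_positions",
]


def default_positions(half_fov: float = 0.16, step: float = 1e-3) -> np.ndarray:
    """Default spatial grid: 1 mm over +/- 160 mm (320 mm field of view)."""
    n = int(round(2 * half_fov / step)) + 1
    return -half_fov + step * np.arange(n)


@dataclasses.dataclass(eq=False)
class IsochromatGrid:
    """Positions with tissue parameters and magnetization 3-vectors.

    All per-isochromat fields broadcast from scalars. ``m0`` is the
    equilibrium longitudinal magnetization (proton density); ``m`` defaults
    to equilibrium ``(0, 0, m0)``.
    """

    positions: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    off_resonance: np.ndarray = 0.0  # type: ignore[assignment]
    b1_scale: np.ndarray = 1.0  # type: ignore[assignment]
    m0: np.ndarray = 1.0  # type: ignore[assignment]
    m: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        n = self.positions.size
        for name in ("t1", "t2", "off_resonance", "b1_scale", "m0"):
            val = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,))
            setattr(self, name, val.copy())
        if np.any(self.t2 <= 0) or np.any(self.t1 < self.t2):
            raise InvalidSpecError("tissue parameters must satisfy t1 >= t2 > 0")
        if self.m is None:
            self.m = np.zeros((n, 3))
            self.m[:, 2] = self.m0
        else:
            self.m = np.array(self.m, dtype=float).reshape(n, 3)

    @classmethod
    def uniform(
        cls,
        positions: np.ndarray,
        *,
        t1: float,
        t2: float,
        off_resonance: float = 0.0,
        b1_scale: float = 1.0,
        m0: float = 1.0,
    ) -> "IsochromatGrid":
        """Grid with spatially uniform tissue parameters, at equilibrium."""
        return cls(
            positions=positions,
            t1=t1,
            t2=t2,
            off_resonance=off_resonance,
            b1_scale=b1_scale,
            m0=m0,
        )

    @property
    def n(self) -> int:
        return self.positions.size

    def copy(self) -> "IsochromatGrid":
        return IsochromatGrid(
            positions=self.positions.copy(),
            t1=self.t1.copy(),
            t2=self.t2.copy(),
            off_resonance=self.off_resonance.copy(),
            b1_scale=self.b1_scale.copy(),
            m0=self.m0.copy(),
            m=self.m.copy(),
        )

    def at_equilibrium(self) -> "IsochromatGrid":
        out = self.copy()
        out.m[:] = 0.0
        out.m[:, 2] = out.m0
        return out

    @property
    def mxy_mag(self) -> np.ndarray:
        return np.hypot(self.m[:, 0], self.m[:, 1])


def _rotate_inplace(m: np.ndarray, fx, fy, fz, dt: float) -> None:
    """Rodrigues rotation of each row of ``m`` about field (fx, fy, fz) [Hz].

    Rotation angle is ``-2*pi*|f|*dt`` (precession sense); a zero field is
    the identity.
    """
    freq = np.sqrt(fx * fx + fy * fy + fz * fz)
    freq = np.broadcast_to(freq, m.shape[:1])
    phi = 2 * np.pi * freq * dt
    safe = np.where(freq > 0, freq, 1.0)
    ux = np.broadcast_to(fx, freq.shape) / safe
    uy = np.broadcast_to(fy, freq.shape) / safe
    uz = np.broadcast_to(fz, freq.shape) / safe
    c = np.cos(phi)
    s = -np.sin(phi)
    mx, my, mz = m[:, 0], m[:, 1], m[:, 2]
    dot = ux * mx + uy * my + uz * mz
    k = (1.0 - c) * dot
    cx = uy * mz - uz * my
    cy = uz * mx - ux * mz
    cz = ux * my - uy * mx
    new_x = c * mx + s * cx + k * ux
    new_y = c * my + s * cy + k * uy
    new_z = c * mz + s * cz + k * uz
    m[:, 0] = new_x
    m[:, 1] = new_y
    m[:, 2] = new_z


def propagate_rf(
    grid: IsochromatGrid,
    w: RFWaveform,
    g: GradientEvent,
    relax: bool = True,
) -> IsochromatGrid:
    """Propagate the grid through an RF pulse played under a gradient.

    Per raster step: hard-pulse rotation about the effective field, then
    (when ``relax`` is set) exponential T1/T2 decay for the step duration.
    Returns a new grid; the input is untouched.
    """
    if abs(g.duration - w.duration) > w.raster + 1e-12:
        raise InvalidSpecError(
            f"gradient duration {g.duration} inconsistent with waveform "
            f"duration {w.duration}"
        )
    out = grid.copy()
    m = out.m
    dt = w.raster
    fz = GAMMA_BAR_HZ_PER_UT * g.amplitude * out.positions + out.off_resonance
    scale = out.b1_scale
    if relax:
        e1 = np.exp(-dt / out.t1)
        e2 = np.exp(-dt / out.t2)
        m0 = out.m0
    for s in w.samples:
        fx = GAMMA_BAR_HZ_PER_UT * s.real * scale
        fy = GAMMA_BAR_HZ_PER_UT * s.imag * scale
        _rotate_inplace(m, fx, fy, fz, dt)
        if relax:
            m[:, 0] *= e2
            m[:, 1] *= e2
            m[:, 2] = m0 + (m[:, 2] - m0) * e1
    return out


def free_relax(grid: IsochromatGrid, duration: float) -> IsochromatGrid:
    """Free precession + relaxation for ``duration`` seconds.

    Mz recovers toward m0 with T1; the transverse component precesses at the
    isochromat's off-resonance frequency and decays with T2.
    """
    if duration < 0:
        raise InvalidSpecError("duration must be non-negative")
    out = grid.copy()
    if duration == 0:
        return out
    m = out.m
    theta = -2 * np.pi * out.off_resonance * duration
    c, s = np.cos(theta), np.sin(theta)
    mx = c * m[:, 0] - s * m[:, 1]
    my = s * m[:, 0] + c * m[:, 1]
    e2 = np.exp(-duration / out.t2)
    e1 = np.exp(-duration / out.t1)
    m[:, 0] = mx * e2
    m[:, 1] = my * e2
    m[:, 2] = out.m0 + (m[:, 2] - out.m0) * e1
    return out


def spoil(grid: IsochromatGrid) -> IsochromatGrid:
    """Ideal spoiling: transverse magnetization zeroed, Mz preserved."""
    out = grid.copy()
    out.m[:, 0] = 0.0
    out.m[:, 1] = 0.0
    return out


def affine_propagator(
    grid: IsochromatGrid,
    w: RFWaveform,
    g: GradientEvent,
    relax: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Extract the per-isochromat affine map of a full RF event.

    Returns ``(A, b)`` with shapes (n, 3, 3) and (n, 3) such that
    propagating magnetization ``m`` through the event equals ``A @ m + b``.
    The map depends only on the waveform, gradient, and the grid's tissue
    parameters -- not on ``m`` -- so it can be reused across repetitions.
    """
    probe = grid.copy()
    probe.m[:] = 0.0
    b = propagate_rf(probe, w, g, relax=relax).m
    A = np.empty((grid.n, 3, 3))
    for i in range(3):
        probe.m[:] = 0.0
        probe.m[:, i] = 1.0
        A[:, :, i] = propagate_rf(probe, w, g, relax=relax).m - b
    return A, b


def apply_affine(A: np.ndarray, b: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Apply the affine propagator to magnetization rows."""
    return np.einsum("nij,nj->ni", A, m) + b


@dataclasses.dataclass(eq=False)
class ProfileResult:
    """Magnetization versus position after a pulse (and ideal spoiler).

    ``mz`` is the post-spoiler longitudinal magnetization; ``mxy_mag`` the
    transverse magnitude immediately before the spoiler.
    """

    positions: np.ndarray
    mz: np.ndarray
    mxy_mag: np.ndarray
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.mxy_mag = np.asarray(self.mxy_mag, dtype=float)
        if not (self.positions.shape == self.mz.shape == self.mxy_mag.shape):
            raise InvalidSpecError("profile arrays must align with positions")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"position_m": self.positions, "mz": self.mz, "mxy": self.mxy_mag}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def write_json_sidecar(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_profile(
    shape: PulseShapeSpec,
    geometry: SlabGeometry,
    mb: Optional[MultibandSpec] = None,
    *,
    positions: Optional[np.ndarray] = None,
    t1: float = 0.3,
    t2: float = 0.08,
    off_resonance: float = 0.0,
    b1_scale: float = 1.0,
    relax: bool = True,
) -> ProfileResult:
    """Slab profile of the (multiband) saturation pulse from equilibrium.

    Synthesizes the band, computes the slab-select gradient from the pulse
    bandwidth and slab thickness, combines the bands, propagates an
    equilibrium grid through pulse + ideal spoiler, and returns Mz / |Mxy|
    versus position.
    """
    if mb is None:
        mb = MultibandSpec()
    if positions is None:
        positions = default_positions()
    band = synth_band(shape)
    gradient = slab_gradient(band_bandwidth(shape), geometry.thickness)
    wave = make_multiband(band, geometry, gradient, mb)
    gev = GradientEvent.for_waveform(gradient, wave)
    grid = IsochromatGrid.uniform(
        positions, t1=t1, t2=t2, off_resonance=off_resonance, b1_scale=b1_scale
    )
    after = propagate_rf(grid, wave, gev, relax=relax)
    mxy = after.mxy_mag
    after = spoil(after)
    meta = {
        "family": shape.family.value,
        "tbw": shape.tbw,
        "duration_s": shape.duration,
        "flip_deg": shape.flip,
        "apodization": shape.apodization.value,
        "gradient_uT_per_m": gradient,
        "peak_shift_fraction": mb.peak_shift_fraction,
        "slab_centers_m": list(geometry.centers),
        "slab_thickness_m": geometry.thickness,
        "t1_s": t1,
        "t2_s": t2,
        "off_resonance_hz": off_resonance,
        "b1_scale": b1_scale,
    }
    return ProfileResult(positions=positions, mz=after.m[:, 2], mxy_mag=mxy, metadata=meta)
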