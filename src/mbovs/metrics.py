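"""Suppression and slab-profile metrics, robustness sweeps, design table.

Metric conventions (configurable, stated here because they are not forced by
physics):

* residual signal = 100 * mean(stop-band signal with module) /
  mean(stop-band signal without module), phase-averaged; the stop-band mask
  is the central 80% of each nominal slab (mimicking ROIs drawn away from
  slab edges).
* pass-band deviation = max |1 - Mz| inside the central 80% of the
  pass-band.
* transition width = distance between the Mz = 0.1 and Mz = 0.9 crossings
  at each slab edge, averaged over edges (0.9/0.1 is the standard profile
  convention).
* sidelobe_max = max |1 - Mz| in the pass-band between the inner-edge
  Mz = 0.9 crossings, i.e. pass-band saturation not attributable to the
  nominal transition flanks.
* relative RF energy = integral |B1|^2 dt of the multiband waveform,
  normalized to the SINC TBW-40 module = 1.0 (an absolute SAR in W/kg would
  require a scanner body model).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .bloch import IsochromatGrid, ProfileResult, simulate_profile
from .constants import GAMMA_BAR_HZ_PER_UT
from .errors import (
    DegenerateProfileError,
    InvalidSpecError,
    UndefinedMetricError,
)
from .pulses import (
    MultibandSpec,
    PulseShapeSpec,
    SlabGeometry,
    band_bandwidth,
    default_geometry,
    make_multiband,
    peak_b1,
    rf_energy,
    slab_gradient,
    standard_pulse_set,
    synth_band,
)
from .sequences import (
    MbOvsModule,
    SequenceSpec,
    SignalSeries,
    cine_protocol,
    default_mbovs,
    run_interleaved_cine,
)

__all__ = [
    "residual_signal",
    "stopband_mask",
    "ProfileMetrics",
    "profile_metrics",
    "stopband_shift",
    "sweep_robustness",
    "build_design_table",
    "SuppressionReport",
]


def stopband_mask(
    positions: np.ndarray, geometry: SlabGeometry, fraction: float = 0.8
) -> np.ndarray:
    """Boolean mask of the central ``fraction`` of each saturation slab."""
    positions = np.asarray(positions, dtype=float)
    mask = np.zeros(positions.shape, dtype=bool)
    half = fraction * geometry.thickness / 2
    for c in geometry.centers:
        mask |= (positions >= c - half) & (positions <= c + half)
    return mask


def residual_signal(
    with_ovs: SignalSeries,
    baseline: SignalSeries,
    stopband: np.ndarray,
) -> float:
    """Residual stop-band signal in percent of the no-suppression baseline.

    Scale-invariant by construction: multiplying both series by any positive
    constant leaves the ratio unchanged.
    """
    if with_ovs.positions.shape != baseline.positions.shape or not np.allclose(
        with_ovs.positions, baseline.positions
    ):
        raise InvalidSpecError("series are not spatially aligned")
    denom = baseline.mean_over(stopband)
    if denom <= 0:
        raise UndefinedMetricError("baseline stop-band signal is zero")
    return 100.0 * with_ovs.mean_over(stopband) / denom


class ProfileMetrics(NamedTuple):
    passband_deviation_pct: float
    transition_width: float
    sidelobe_max: float


def _crossing_near(
    z: np.ndarray, mz: np.ndarray, level: float, edge: float
) -> float:
    """Position of the Mz = ``level`` crossing closest to ``edge``.

    Considering all sign changes (rather than the first one in scan order)
    keeps the metric robust against stop-band/pass-band ringing of
    unapodized pulses.
    """
    d = mz - level
    idx = np.nonzero(d[1:] * d[:-1] < 0)[0]
    exact = np.nonzero(d == 0)[0]
    candidates = []
    for i in idx:
        f = d[i] / (d[i] - d[i + 1])
        candidates.append(z[i] + f * (z[i + 1] - z[i]))
    candidates.extend(z[exact])
    if not candidates:
        raise DegenerateProfileError(f"no Mz = {level} crossing found near z = {edge}")
    candidates = np.asarray(candidates)
    return float(candidates[np.argmin(np.abs(candidates - edge))])


def _edge_crossings(
    positions: np.ndarray, mz: np.ndarray, edge: float, half_window: float
) -> Dict[float, float]:
    """0.1 and 0.9 crossings of the transition at a nominal slab edge."""
    sel = (positions >= edge - half_window) & (positions <= edge + half_window)
    if sel.sum() < 3:
        raise DegenerateProfileError("profile does not cover the slab edge")
    z = positions[sel]
    v = mz[sel]
    return {level: _crossing_near(z, v, level, edge) for level in (0.1, 0.9)}


def profile_metrics(p: ProfileResult, geometry: SlabGeometry) -> ProfileMetrics:
    """Pass-band deviation, transition width, and sidelobe level of a profile.

    Raises :class:`DegenerateProfileError` when the profile does not contain
    the required Mz crossings (e.g. the grid does not cover the slab edges).
    """
    if geometry.pass_band is None:
        raise InvalidSpecError("geometry has no pass-band")
    z = p.positions
    mz = p.mz

    pb_lo, pb_hi = geometry.pass_band
    pb_c = (pb_lo + pb_hi) / 2
    pb_h = 0.8 * (pb_hi - pb_lo) / 2
    core = (z >= pb_c - pb_h) & (z <= pb_c + pb_h)
    if not core.any():
        raise DegenerateProfileError("profile does not cover the pass-band core")
    deviation_pct = 100.0 * float(np.max(np.abs(1.0 - mz[core])))

    half_window = geometry.thickness / 2
    widths = []
    inner_09 = []
    for lo, hi in geometry.slab_intervals():
        c = (lo + hi) / 2
        for edge in (lo, hi):
            cross = _edge_crossings(z, mz, edge, half_window)
            widths.append(abs(cross[0.9] - cross[0.1]))
            # the 0.9 crossing of the edge facing the pass-band bounds the
            # sidelobe search region
            if abs(edge - pb_c) < abs(c - pb_c):
                inner_09.append(cross[0.9])
    transition_width = float(np.mean(widths))

    if len(inner_09) == 2:
        lo9, hi9 = sorted(inner_09)
        lobe = (z > lo9) & (z < hi9)
    else:
        lobe = core
    sidelobe_max = float(np.max(np.abs(1.0 - mz[lobe]))) if lobe.any() else 0.0
    return ProfileMetrics(
        passband_deviation_pct=deviation_pct,
        transition_width=transition_width,
        sidelobe_max=sidelobe_max,
    )


def stopband_shift(p: ProfileResult, geometry: SlabGeometry) -> float:
    """Signed mean displacement of the saturated bands from their nominal
    centers, via the center of mass of (1 - Mz) around each slab."""
    z = p.positions
    w_all = np.clip(1.0 - p.mz, 0.0, None)
    shifts = []
    for c in geometry.centers:
        half = 0.75 * geometry.thickness
        sel = (z >= c - half) & (z <= c + half)
        w = w_all[sel]
        if w.sum() <= 0:
            raise DegenerateProfileError("no saturation found near slab center")
        shifts.append(float(np.sum(z[sel] * w) / np.sum(w)) - c)
    return float(np.mean(shifts))


def _wide_positions(geometry: SlabGeometry, margin: float = 0.04) -> np.ndarray:
    half = max(abs(c) for c in geometry.centers) + geometry.thickness / 2 + margin
    n = int(round(2 * half / 1e-3)) + 1
    return -half + 1e-3 * np.arange(n)


def sweep_robustness(
    module: Optional[MbOvsModule],
    axis: str,
    values: Sequence[float],
    *,
    seq: Optional[SequenceSpec] = None,
    t1: float = 0.3,
    t2: float = 0.08,
    positions: Optional[np.ndarray] = None,
    n_beats: int = 6,
) -> pd.DataFrame:
    """Residual signal and stop-band shift versus a system imperfection.

    ``axis`` is ``"b1_scale"`` or ``"off_resonance"``; for each value the
    imperfection is applied uniformly to the grid, the interleaved CINE
    residual is recomputed against its own unswept baseline, and the
    stop-band displacement is measured on the saturation profile.
    """
    if len(values) == 0:
        raise InvalidSpecError("values must be non-empty")
    if axis not in ("b1_scale", "off_resonance"):
        raise InvalidSpecError(f"unknown sweep axis {axis!r}")
    if module is None:
        module = default_mbovs()
    if seq is None:
        seq = cine_protocol(ovs=module)
    elif seq.ovs is None:
        seq = dataclasses.replace(seq, ovs=module)
    if positions is None:
        from .bloch import default_positions

        positions = default_positions()

    mask = stopband_mask(positions, module.geometry)
    baseline_seq = dataclasses.replace(seq, ovs=None)
    profile_pos = _wide_positions(module.geometry)

    rows = []
    for v in values:
        kw = {"b1_scale": 1.0, "off_resonance": 0.0}
        kw[axis] = float(v)
        grid = IsochromatGrid.uniform(positions, t1=t1, t2=t2, **kw)
        with_ovs = run_interleaved_cine(seq, grid, n_beats=n_beats)
        base = run_interleaved_cine(baseline_seq, grid, n_beats=n_beats)
        res = residual_signal(with_ovs, base, mask)
        profile = simulate_profile(
            module.shape,
            module.geometry,
            module.mb,
            positions=profile_pos,
            t1=t1,
            t2=t2,
            **kw,
        )
        rows.append(
            {
                "swept_value": float(v),
                "residual_pct": res,
                "shift_m": stopband_shift(profile, module.geometry),
            }
        )
    return pd.DataFrame(rows)


def build_design_table(
    *,
    thickness: float = 0.15,
    flip: float = 90.0,
    mb: Optional[MultibandSpec] = None,
    include_residuals: bool = False,
    include_profiles: bool = True,
    seq: Optional[SequenceSpec] = None,
    t1: float = 0.3,
    t2: float = 0.08,
    n_beats: int = 6,
) -> pd.DataFrame:
    """Characteristics of the full saturation-pulse catalog, one row each.

    Columns: duration, TBW, slab gradient, single-band and multiband peak
    B1+, RF energy of the multiband waveform relative to SINC-40, and
    optionally simulated residual signal and profile metrics. The leading
    ``no_ovs`` / ``rf_0`` rows carry residuals only (the no-suppression
    baseline is 100% by construction).
    """
    if mb is None:
        mb = MultibandSpec()
    geometry = default_geometry(thickness)
    pulses = standard_pulse_set(flip=flip)

    per_pulse = {}
    for name, shape in pulses.items():
        band = synth_band(shape)
        gradient = slab_gradient(band_bandwidth(shape), thickness)
        wave = make_multiband(band, geometry, gradient, mb)
        per_pulse[name] = {
            "shape": shape,
            "gradient": gradient,
            "band": band,
            "wave": wave,
            "energy": rf_energy(wave),
        }
    ref_energy = per_pulse["sinc_40"]["energy"]

    residuals: Dict[str, float] = {}
    if include_residuals:
        base_seq = cine_protocol(ovs=None) if seq is None else dataclasses.replace(seq, ovs=None)
        from .bloch import default_positions

        positions = default_positions()
        grid = IsochromatGrid.uniform(positions, t1=t1, t2=t2)
        mask = stopband_mask(positions, geometry)
        baseline = run_interleaved_cine(base_seq, grid, n_beats=n_beats)
        rf0_seq = dataclasses.replace(base_seq, ovs=default_mbovs(thickness=thickness).rf0())
        residuals["rf_0"] = residual_signal(
            run_interleaved_cine(rf0_seq, grid, n_beats=n_beats), baseline, mask
        )
        for name, info in per_pulse.items():
            module = MbOvsModule(shape=info["shape"], geometry=geometry, mb=mb)
            mod_seq = dataclasses.replace(base_seq, ovs=module)
            residuals[name] = residual_signal(
                run_interleaved_cine(mod_seq, grid, n_beats=n_beats), baseline, mask
            )

    profiles: Dict[str, ProfileMetrics] = {}
    if include_profiles:
        wide = _wide_positions(geometry)
        for name, info in per_pulse.items():
            prof = simulate_profile(
                info["shape"], geometry, mb, positions=wide, t1=t1, t2=t2
            )
            profiles[name] = profile_metrics(prof, geometry)

    rows = []
    rows.append(
        {
            "pulse": "no_ovs",
            "residual_pct": 100.0 if include_residuals else np.nan,
        }
    )
    rows.append(
        {
            "pulse": "rf_0",
            "residual_pct": residuals.get("rf_0", np.nan),
        }
    )
    for name, info in per_pulse.items():
        shape = info["shape"]
        row = {
            "pulse": name,
            "duration_ms": shape.duration * 1e3,
            "tbw": shape.tbw,
            "gradient_uT_per_m": info["gradient"],
            "peak_b1_uT": peak_b1(info["band"]),
            "mb_peak_b1_uT": peak_b1(info["wave"]),
            "rel_energy": info["energy"] / ref_energy,
            "residual_pct": residuals.get(name, np.nan),
        }
        if name in profiles:
            pm = profiles[name]
            row.update(
                {
                    "passband_deviation_pct": pm.passband_deviation_pct,
                    "transition_width_m": pm.transition_width,
                    "sidelobe_max": pm.sidelobe_max,
                }
            )
        rows.append(row)
    columns = [
        "pulse",
        "duration_ms",
        "tbw",
        "gradient_uT_per_m",
        "peak_b1_uT",
        "mb_peak_b1_uT",
        "rel_energy",
        "residual_pct",
    ]
    if include_profiles:
        columns += ["passband_deviation_pct", "transition_width_m", "sidelobe_max"]
    return pd.DataFrame(rows).reindex(columns=columns)


@dataclasses.dataclass(eq=False)
class SuppressionReport:
    """Design table plus provenance, with deterministic CSV/JSON export."""

    table: pd.DataFrame
    config: dict = dataclasses.field(default_factory=dict)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    def write_json(self, path) -> None:
        doc = {
            "config": self.config,
            "rows": json.loads(
                self.table.to_json(orient="records", double_precision=10)
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def expected_offresonance_shift(off_resonance_hz: float, gradient: float) -> float:
    """Closed-form stop-band displacement dz = -df / (gamma_bar * Gr)."""
    return -off_resonance_hz / (GAMMA_BAR_HZ_PER_UT * gradient)
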