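"""Digital phantoms and tissue presets.

The suppression experiments use a 1D phantom along the phase-encode axis: a
12 cm water compartment (the imaging target) flanked by two 8 cm fat
compartments (the chest/back tissue the suppression slabs cover). A 1D model
suffices because with Cartesian readouts slice leakage -- and hence the
suppression metric -- acts only along the phase-encode dimension.

Tissue presets carry T1/T2/proton-density at 3T. The fat T1 default of
300 ms sits in the middle of the 250-350 ms range typical of subcutaneous
fat at 3T. The water T1 default (2.9 s) corresponds to undoped water; the
physical phantom's doping is unknown, so both values are configurable.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Tuple, Union

import numpy as np
import yaml

from .bloch import IsochromatGrid
from .errors import InvalidGeometryError, InvalidSpecError

__all__ = [
    "TissuePreset",
    "Segment",
    "PhantomSpec",
    "PRESETS",
    "water_fat_phantom",
    "make_phantom",
    "write_phantom_yaml",
    "read_phantom_yaml",
]

FieldModel = Union[None, float, Callable[[np.ndarray], np.ndarray]]


@dataclasses.dataclass(frozen=True)
class TissuePreset:
    """Named tissue with relaxation times (s) and relative proton density."""

    name: str
    t1: float
    t2: float
    proton_density: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 >= self.t2 > 0):
            raise InvalidSpecError(
                f"tissue '{self.name}' must satisfy t1 >= t2 > 0 "
                f"(got t1={self.t1}, t2={self.t2})"
            )
        if self.proton_density < 0:
            raise InvalidSpecError("proton_density must be non-negative")


PRESETS = {
    "water": TissuePreset("water", t1=2.9, t2=0.2),
    "fat": TissuePreset("fat", t1=0.3, t2=0.08),
    "myocardium": TissuePreset("myocardium", t1=1.4, t2=0.045),
    "blood": TissuePreset("blood", t1=1.9, t2=0.25),
}

#: Tissue parameters used where no segment covers a position (zero signal).
_BACKGROUND = TissuePreset("background", t1=1.0, t2=0.1, proton_density=0.0)


@dataclasses.dataclass(frozen=True)
class Segment:
    """Half-open spatial interval [start, stop) carrying one tissue."""

    start: float
    stop: float
    tissue: TissuePreset

    def __post_init__(self) -> None:
        if not self.stop > self.start:
            raise InvalidGeometryError(f"segment [{self.start}, {self.stop}) is empty")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """1D phantom: a field of view (m) and non-overlapping tissue segments."""

    fov: float
    segments: Tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        if not self.fov > 0:
            raise InvalidGeometryError("fov must be positive")
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        half = self.fov / 2
        for seg in segs:
            if seg.start < -half - 1e-12 or seg.stop > half + 1e-12:
                raise InvalidGeometryError(
                    f"segment [{seg.start}, {seg.stop}) outside FOV +/- {half}"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start < a.stop - 1e-12:
                raise InvalidGeometryError(
                    f"segments [{a.start}, {a.stop}) and [{b.start}, {b.stop}) overlap"
                )
        object.__setattr__(self, "segments", segs)


def water_fat_phantom(
    fov: float = 0.32,
    water_span: float = 0.12,
    fat_span: float = 0.08,
    water: Optional[TissuePreset] = None,
    fat: Optional[TissuePreset] = None,
) -> PhantomSpec:
    """12 cm water compartment between two 8 cm fat compartments (defaults).

    Emulates a water-filled sphere between two fat bottles, projected onto
    the phase-encode axis.
    """
    water = water or PRESETS["water"]
    fat = fat or PRESETS["fat"]
    hw = water_span / 2
    return PhantomSpec(
        fov=fov,
        segments=(
            Segment(-hw - fat_span, -hw, fat),
            Segment(-hw, hw, water),
            Segment(hw, hw + fat_span, fat),
        ),
    )


def _evaluate_field(model: FieldModel, positions: np.ndarray, default: float) -> np.ndarray:
    if model is None:
        return np.full_like(positions, default)
    if callable(model):
        return np.broadcast_to(np.asarray(model(positions), dtype=float), positions.shape).copy()
    return np.full_like(positions, float(model))


def make_phantom(
    spec: PhantomSpec,
    grid_step: float = 1e-3,
    off_res_model: FieldModel = None,
    b1_model: FieldModel = None,
) -> IsochromatGrid:
    """Discretize a phantom spec into an isochromat grid at equilibrium.

    Isochromats sit at segment-center positions spaced ``grid_step`` apart
    across the FOV; each carries the tissue parameters of the segment
    containing it (background with zero proton density elsewhere).
    ``off_res_model`` / ``b1_model`` may be scalars or callables of position.
    """
    if not grid_step > 0:
        raise InvalidSpecError("grid_step must be positive")
    half = spec.fov / 2
    n = int(round(spec.fov / grid_step))
    positions = -half + (np.arange(n) + 0.5) * grid_step

    t1 = np.full(n, _BACKGROUND.t1)
    t2 = np.full(n, _BACKGROUND.t2)
    m0 = np.full(n, _BACKGROUND.proton_density)
    for seg in spec.segments:
        mask = (positions >= seg.start) & (positions < seg.stop)
        t1[mask] = seg.tissue.t1
        t2[mask] = seg.tissue.t2
        m0[mask] = seg.tissue.proton_density

    return IsochromatGrid(
        positions=positions,
        t1=t1,
        t2=t2,
        off_resonance=_evaluate_field(off_res_model, positions, 0.0),
        b1_scale=_evaluate_field(b1_model, positions, 1.0),
        m0=m0,
    )


def tissue_mask(positions: np.ndarray, spec: PhantomSpec, tissue_name: str) -> np.ndarray:
    """Boolean mask of positions lying in segments of the named tissue."""
    positions = np.asarray(positions, dtype=float)
    mask = np.zeros(positions.shape, dtype=bool)
    for seg in spec.segments:
        if seg.tissue.name == tissue_name:
            mask |= (positions >= seg.start) & (positions < seg.stop)
    return mask


def write_phantom_yaml(spec: PhantomSpec, path) -> None:
    """Serialize a phantom spec to a YAML config file."""
    doc = {
        "fov": float(spec.fov),
        "segments": [
            {
                "start": float(s.start),
                "stop": float(s.stop),
                "tissue": {
                    "name": s.tissue.name,
                    "t1": float(s.tissue.t1),
                    "t2": float(s.tissue.t2),
                    "proton_density": float(s.tissue.proton_density),
                },
            }
            for s in spec.segments
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_phantom_yaml(path) -> PhantomSpec:
    """Load a phantom spec previously written by :func:`write_phantom_yaml`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        segments = tuple(
            Segment(
                start=float(s["start"]),
                stop=float(s["stop"]),
                tissue=TissuePreset(**s["tissue"]),
            )
            for s in doc.get("segments", [])
        )
        return PhantomSpec(fov=float(doc["fov"]), segments=segments)
    except (KeyError, TypeError) as exc:
        raise InvalidSpecError(f"malformed phantom config {path}: {exc}") from exc
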