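"""Virtual marker-misplacement sensitivity of segment orientations.

Each anatomical marker of a segment is displaced from -10 to +10 mm in
1 mm steps along the anterior-posterior, superior-inferior and
medio-lateral axes of a foot-specific coordinate system.  For every
displacement the segment's anatomical frame is rebuilt and its
orientation error with respect to the undisplaced reference pose is
decomposed into the three anatomical planes; an ordinary least-squares
line fitted through the 21 signed errors per plane gives the sensitivity
gradient in degrees per millimetre.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .errors import InvalidGeometryError
from .geometry import Frame, build_frame, planar_orientation_error
from .model import MarkerSet, SEGMENT_ANATOMICAL_MARKERS, anatomical_frame

DISPLACEMENT_AXES = ("anterior_posterior", "superior_inferior", "medio_lateral")
PLANES = ("sagittal", "frontal", "transverse")

#: Default displacement range: -10..+10 mm in 1 mm steps (21 points).
DEFAULT_RANGE_MM = 10.0
DEFAULT_STEP_MM = 1.0


def displacement_frame(ms: MarkerSet, side: str = "right") -> Frame:
    """Foot-specific axes used for the virtual displacements.

    x: horizontal (floor-plane) projection of the CALD->HM2 direction;
    y: lab vertical; z completes the right-handed triad (subject's
    right for both sides).  Origin at CALD.
    """
    ms.require(("CALD", "HM2"), "displacement frame")
    d = ms["HM2"] - ms["CALD"]
    x_h = np.array([d[0], 0.0, d[2]])
    if np.linalg.norm(x_h) < 1e-9:
        raise InvalidGeometryError("foot axis is vertical; displacement frame undefined")
    return build_frame(ms["CALD"], x_h, np.array([0.0, 1.0, 0.0]), "x", "y",
                       context=f"displacement frame ({side})")


@dataclasses.dataclass
class SensitivityRecord:
    segment: str
    marker: str
    axis: str                 # displacement axis name
    plane: str
    gradient: float           # |slope|, degrees per mm
    slope: float              # signed OLS slope
    r_squared: float


@dataclasses.dataclass
class SensitivityTable:
    records: List[SensitivityRecord]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def count_at_least(self, threshold: float) -> int:
        """Number of records with |gradient| >= threshold (deg/mm)."""
        return sum(1 for r in self.records if r.gradient >= threshold)

    def max_gradient(self) -> float:
        return max(r.gradient for r in self.records)

    def query(self, **conditions) -> List[SensitivityRecord]:
        out = self.records
        for key, val in conditions.items():
            out = [r for r in out if getattr(r, key) == val]
        return out

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def _fit_line(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def marker_sensitivity(static_ms: MarkerSet, segment: str, marker: str,
                       side: str = "right", *, range_mm: float = DEFAULT_RANGE_MM,
                       step_mm: float = DEFAULT_STEP_MM,
                       disp_frame: Optional[Frame] = None) -> Optional[List[SensitivityRecord]]:
    """Sensitivity gradients of one segment to misplacing one marker.

    Returns one record per (displacement axis, plane), or ``None`` when
    the marker does not participate in the segment's anatomical frame
    (an explicit not-applicable result, not zero).
    """
    if marker not in SEGMENT_ANATOMICAL_MARKERS[segment]:
        return None
    # drop any precomputed virtual midpoints so they track the displacement
    from .model import VIRTUAL_MARKERS
    static_ms = MarkerSet({n: p for n, p in static_ms.items()
                           if n not in VIRTUAL_MARKERS})
    if disp_frame is None:
        disp_frame = displacement_frame(static_ms, side)
    ref = anatomical_frame(segment, static_ms, side)
    deltas = np.arange(-range_mm, range_mm + step_mm / 2, step_mm)
    planes = PLANES if segment != "hallux" else ("sagittal", "transverse")
    records = []
    for ai, axis in enumerate(DISPLACEMENT_AXES):
        direction = disp_frame.rotation[:, ai]
        errors = np.empty((len(deltas), 3))
        for di, d in enumerate(deltas):
            moved = static_ms.replace(marker, static_ms[marker] + d * direction)
            frame = anatomical_frame(segment, moved, side)
            errors[di] = planar_orientation_error(ref.rotation, frame.rotation)
        for pi, plane in enumerate(PLANES):
            if plane not in planes:
                continue
            slope, r2 = _fit_line(deltas, errors[:, pi])
            records.append(SensitivityRecord(segment, marker, axis, plane,
                                             abs(slope), slope, r2))
    return records


def full_sensitivity_table(static_ms: MarkerSet,
                           segments: Iterable[str] = ("hindfoot", "forefoot"),
                           side: str = "right", *, range_mm: float = DEFAULT_RANGE_MM,
                           step_mm: float = DEFAULT_STEP_MM) -> SensitivityTable:
    """All (marker, displacement axis, plane) sensitivity records for the
    requested segments."""
    disp = displacement_frame(static_ms, side)
    records: List[SensitivityRecord] = []
    for seg in segments:
        for marker in SEGMENT_ANATOMICAL_MARKERS[seg]:
            recs = marker_sensitivity(static_ms, seg, marker, side,
                                      range_mm=range_mm, step_mm=step_mm,
                                      disp_frame=disp)
            if recs:
                records.extend(recs)
    return SensitivityTable(records)
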