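"""Static-trial calibration and dynamic frame reconstruction.

During the static trial all 18 physical markers are present, so the
anatomical frames can be built directly.  Each tracked segment's
anatomical frame is then stored *in its technical frame*; during gait the
technical frames are rebuilt from the tracking markers and the anatomical
frames recovered through the stored rigid transforms.  Segments without a
technical frame (midfoot, medial/lateral forefoot, hallux) are recomputed
directly every frame, since none of their defining markers is restricted
to the static trial.

The calibration also stores the two virtual arch points: CAp, the floor
projection of the virtual calcaneus point (midpoint of CALP and the
ST/PT midpoint), fixed in the hindfoot frame; and HM1p, the floor
projection of the first metatarsal head, fixed in the forefoot frame.
When the static trial was recorded without full foot contact the CAp
position can instead be taken from a reference ratio scaled by calcaneal
length (:func:`fallback_cap`).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np

from .errors import CalibrationError, MissingMarkerError
from .geometry import Frame, PlaneAngles, as_vec3, is_rotation
from .io import Trial
from .model import (
    MarkerSet,
    PHYSICAL_MARKERS,
    SEGMENTS,
    add_virtual_midpoints,
    anatomical_frame,
    technical_frame,
)

TRACKED_SEGMENTS = ("shank", "hindfoot", "forefoot")
DIRECT_SEGMENTS = ("midfoot", "medial_forefoot", "lateral_forefoot", "hallux")


@dataclasses.dataclass
class RigidTransform:
    """Rotation + translation mapping child coordinates into parent."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = as_vec3(self.translation)
        if not is_rotation(self.rotation, tol=1e-8):
            raise CalibrationError("rigid transform rotation is not orthonormal")

    @classmethod
    def between(cls, parent: Frame, child: Frame) -> "RigidTransform":
        """Child frame expressed in parent frame coordinates."""
        R = parent.rotation.T @ child.rotation
        t = parent.rotation.T @ (child.origin - parent.origin)
        return cls(R, t)

    def apply_to_frame(self, parent: Frame) -> Frame:
        """Reconstruct the child frame in lab coordinates."""
        return Frame(parent.to_lab(self.translation), parent.rotation @ self.rotation)


@dataclasses.dataclass
class SegmentCalibration:
    segment: str
    anat_in_tech: RigidTransform


@dataclasses.dataclass
class ModelCalibration:
    """Everything needed to run the model on a dynamic trial."""

    side: str
    segments: Dict[str, SegmentCalibration]
    cap_in_hindfoot: Optional[np.ndarray]
    hm1p_in_forefoot: Optional[np.ndarray]
    calcaneal_length: float
    static_angles: Dict[str, PlaneAngles]
    static_mla: Optional[float]
    static_tta: float
    full_foot_contact: bool
    cap_is_fallback: bool = False
    floor_y: float = 0.0

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "segments": {
                name: {
                    "rotation": sc.anat_in_tech.rotation.tolist(),
                    "translation": sc.anat_in_tech.translation.tolist(),
                }
                for name, sc in self.segments.items()
            },
            "cap_in_hindfoot": None if self.cap_in_hindfoot is None else self.cap_in_hindfoot.tolist(),
            "hm1p_in_forefoot": None if self.hm1p_in_forefoot is None else self.hm1p_in_forefoot.tolist(),
            "calcaneal_length": self.calcaneal_length,
            "static_angles": {j: list(a) for j, a in self.static_angles.items()},
            "static_mla": self.static_mla,
            "static_tta": self.static_tta,
            "full_foot_contact": self.full_foot_contact,
            "cap_is_fallback": self.cap_is_fallback,
            "floor_y": self.floor_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCalibration":
        return cls(
            side=d["side"],
            segments={
                name: SegmentCalibration(name, RigidTransform(np.array(v["rotation"]),
                                                              np.array(v["translation"])))
                for name, v in d["segments"].items()
            },
            cap_in_hindfoot=None if d["cap_in_hindfoot"] is None else np.array(d["cap_in_hindfoot"]),
            hm1p_in_forefoot=None if d["hm1p_in_forefoot"] is None else np.array(d["hm1p_in_forefoot"]),
            calcaneal_length=d["calcaneal_length"],
            static_angles={j: PlaneAngles(*a) for j, a in d["static_angles"].items()},
            static_mla=d.get("static_mla"),
            static_tta=d["static_tta"],
            full_foot_contact=d["full_foot_contact"],
            cap_is_fallback=d.get("cap_is_fallback", False),
            floor_y=d.get("floor_y", 0.0),
        )


def virtual_calcaneus_point(ms: MarkerSet) -> np.ndarray:
    """Midpoint of CALP and the ST/PT midpoint (pre-projection CAp)."""
    return (ms["CALP"] + (ms["ST"] + ms["PT"]) / 2.0) / 2.0


def calcaneal_length(ms: MarkerSet) -> float:
    """Distance from CALP to the ST/PT midpoint (mm)."""
    return float(np.linalg.norm(ms["CALP"] - (ms["ST"] + ms["PT"]) / 2.0))


def _floor_project(p: np.ndarray, floor_y: float) -> np.ndarray:
    out = p.copy()
    out[1] = floor_y
    return out


def static_marker_set(static_trial: Trial) -> MarkerSet:
    if static_trial.n_frames == 0:
        raise CalibrationError("static trial has zero frames")
    ms = static_trial.mean_marker_set()
    missing = [m for m in PHYSICAL_MARKERS if m not in ms]
    if missing:
        raise MissingMarkerError(missing[0], "static trial is incomplete")
    return add_virtual_midpoints(ms)


def calibrate_static(static_trial: Trial, side: str = "right", *,
                     floor_y: float = 0.0, full_foot_contact: bool = True,
                     include_optional: bool = True) -> ModelCalibration:
    """Build a model calibration from a static standing trial.

    Marker positions are averaged over the trial's frames (gap frames per
    marker excluded), anatomical and technical frames are built, and each
    tracked segment's anatomical frame is stored in its technical frame.
    """
    from .angles import joint_angles_at, mla_from_points, tta

    ms = static_marker_set(static_trial)
    anat = {seg: anatomical_frame(seg, ms, side) for seg in SEGMENTS}
    segcal = {}
    for seg in TRACKED_SEGMENTS:
        tech = technical_frame(seg, ms)
        segcal[seg] = SegmentCalibration(seg, RigidTransform.between(tech, anat[seg]))

    L = calcaneal_length(ms)
    if not L > 0:
        raise CalibrationError("calcaneal length is not positive")

    cap_lab = _floor_project(virtual_calcaneus_point(ms), floor_y)
    hm1p_lab = _floor_project(ms["HM1"], floor_y)
    if full_foot_contact:
        cap_in_hf = anat["hindfoot"].to_local(cap_lab)
    else:
        cap_in_hf = None  # supply via fallback_cap()
    hm1p_in_ff = anat["forefoot"].to_local(hm1p_lab)

    static_angles = joint_angles_at(anat, side)
    static_mla = None
    if full_foot_contact:
        static_mla = mla_from_points(ms["NAV"], cap_lab, hm1p_lab)

    return ModelCalibration(
        side=side,
        segments=segcal,
        cap_in_hindfoot=cap_in_hf,
        hm1p_in_forefoot=hm1p_in_ff,
        calcaneal_length=L,
        static_angles=static_angles,
        static_mla=static_mla,
        static_tta=tta(ms),
        full_foot_contact=full_foot_contact,
        floor_y=floor_y,
    )


def fallback_cap(cal: ModelCalibration, reference_ratio) -> ModelCalibration:
    """Place CAp from a reference position per unit calcaneal length.

    For static trials without full foot contact the floor projection is
    meaningless; instead the CAp position in hindfoot coordinates is taken
    as ``reference_ratio * calcaneal_length``.
    """
    if not cal.calcaneal_length > 0:
        raise CalibrationError("calcaneal length must be positive for the CAp fallback")
    ratio = as_vec3(reference_ratio)
    out = dataclasses.replace(cal)
    out.cap_in_hindfoot = ratio * cal.calcaneal_length
    out.cap_is_fallback = True
    return out


def default_cap_ratio(side: str = "right") -> np.ndarray:
    """CAp-per-unit-calcaneal-length ratio derived from the packaged
    synthetic template foot.

    This is a synthetic stand-in, not population reference data; labs with
    a reference dataset should extract their own ratio (CAp in hindfoot
    coordinates divided by calcaneal length).
    """
    from .synthetic import template_foot, make_static_trial
    trial = make_static_trial(template_foot(side), n_frames=1)
    cal = calibrate_static(trial, side)
    return cal.cap_in_hindfoot / cal.calcaneal_length


@dataclasses.dataclass
class ReconstructedFrames:
    """Per-frame segment poses plus reconstructed virtual arch points."""

    frames: Dict[str, List[Optional[Frame]]]
    cap_lab: np.ndarray        # (n_frames, 3), NaN where invalid
    hm1p_lab: np.ndarray
    valid: np.ndarray          # (n_frames,) bool — all requested segments valid
    side: str


def reconstruct_frames(trial: Trial, cal: ModelCalibration, *,
                       segments: tuple = SEGMENTS) -> ReconstructedFrames:
    """Rebuild anatomical frames for every frame of a dynamic trial.

    Tracked segments go through their technical frames and the stored
    static transforms; the other segments are recomputed directly from
    their (all dynamic) anatomical markers.  A frame with a missing
    tracking marker is flagged invalid for that segment, never
    interpolated.
    """
    n = trial.n_frames
    frames: Dict[str, List[Optional[Frame]]] = {seg: [None] * n for seg in segments}
    cap = np.full((n, 3), np.nan)
    hm1p = np.full((n, 3), np.nan)
    valid = np.ones(n, dtype=bool)
    for fi in range(n):
        ms = trial.marker_set(fi)
        for seg in segments:
            try:
                if seg in TRACKED_SEGMENTS:
                    f = cal.segments[seg].anat_in_tech.apply_to_frame(
                        technical_frame(seg, ms))
                else:
                    f = anatomical_frame(seg, ms, cal.side)
            except (MissingMarkerError, KeyError, ValueError):
                valid[fi] = False
                continue
            frames[seg][fi] = f
        hf = frames.get("hindfoot", [None] * n)[fi]
        ff = frames.get("forefoot", [None] * n)[fi]
        if hf is not None and cal.cap_in_hindfoot is not None:
            cap[fi] = hf.to_lab(cal.cap_in_hindfoot)
        if ff is not None and cal.hm1p_in_forefoot is not None:
            hm1p[fi] = ff.to_lab(cal.hm1p_in_forefoot)
    return ReconstructedFrames(frames, cap, hm1p, valid, cal.side)
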