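"""Joint angles, planar arch angles, ROM and two-marker-set differences.

Seven joints are reported, each as a z-x'-y'' floating-axis decomposition
between the anatomical frames of a proximal and a distal segment:

==========  ====================  ==========================
joint       proximal              distal
==========  ====================  ==========================
HF_SK       shank                 hindfoot
MF_HF       hindfoot              midfoot
FF_HF       hindfoot              forefoot
FF_MF       midfoot               forefoot
FFL_MF      midfoot               lateral_forefoot
FFM_MF      midfoot               medial_forefoot
HX_FFM      medial_forefoot       hallux
F_SK        shank                 foot (pluggable, see below)
==========  ====================  ==========================

Positive angles are dorsiflexion (sagittal), inversion (frontal) and
internal rotation at the ankle / adduction distally (transverse), for both
sides: the left foot's frontal and transverse angles are sign-flipped so
the clinical meaning is preserved.  The hallux carries a single marker, so
its frontal-plane angle is structurally undetermined and emitted as NaN.

The foot-shank (F_SK) angle is a hook: the foot frame must come from the
lower-extremity marker model in use; no default foot frame is invented
here.  Pass it under the segment name ``"foot"``.

Two planar angles complement the joint set: the medial longitudinal arch
angle MLA (at the navicular, between the projected calcaneus point CAp and
the projected first metatarsal head HM1p — larger angle = flatter arch)
and the transverse tarsal arch angle TTA (between the BM1->BM2 and
BM2->BM5 vectors).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import ModelCalibration, ReconstructedFrames, reconstruct_frames
from .errors import AfmError, MissingMarkerError
from .geometry import Frame, PlaneAngles, angle_between, cardan_zxy, planar_orientation_error
from .io import Trial
from .model import MarkerSet, SEGMENTS, anatomical_frame

#: joint -> (proximal segment, distal segment); Table order.
JOINTS: Dict[str, Tuple[str, str]] = {
    "HF_SK": ("shank", "hindfoot"),
    "MF_HF": ("hindfoot", "midfoot"),
    "FF_HF": ("hindfoot", "forefoot"),
    "FF_MF": ("midfoot", "forefoot"),
    "FFL_MF": ("midfoot", "lateral_forefoot"),
    "FFM_MF": ("midfoot", "medial_forefoot"),
    "HX_FFM": ("medial_forefoot", "hallux"),
    "F_SK": ("shank", "foot"),
}

DEFAULT_JOINTS = ("HF_SK", "MF_HF", "FF_HF", "FF_MF", "FFL_MF", "FFM_MF", "HX_FFM")

PLANES = ("sagittal", "frontal", "transverse")


def _side_adjust(angles: PlaneAngles, side: str) -> PlaneAngles:
    if side == "left":
        return PlaneAngles(angles.sagittal, -angles.frontal, -angles.transverse)
    return angles


def joint_angle(prox: Frame, dist: Frame, side: str = "right") -> PlaneAngles:
    """Cardan z-x'-y'' angles of one joint at one instant (degrees)."""
    return _side_adjust(cardan_zxy(prox.rotation, dist.rotation), side)


def joint_angles_at(frames: Dict[str, Frame], side: str = "right",
                    joints: Iterable[str] = DEFAULT_JOINTS) -> Dict[str, PlaneAngles]:
    """Joint angles from a single set of segment frames (e.g. static pose)."""
    out = {}
    for j in joints:
        prox, dist = JOINTS[j]
        if prox not in frames or dist not in frames:
            continue
        a = joint_angle(frames[prox], frames[dist], side)
        if j == "HX_FFM":
            a = PlaneAngles(a.sagittal, float("nan"), a.transverse)
        out[j] = a
    return out


@dataclasses.dataclass
class AngleCurve:
    """One joint/plane angle time series, raw or gait-cycle normalized."""

    joint: str
    plane: str
    values: np.ndarray
    rate: Optional[float] = None   # Hz; None once normalized
    normalized: bool = False
    stride: Optional[int] = None   # stride index; None for raw or averaged

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.normalized and self.values.shape[0] != 101:
            raise ValueError("normalized curves must have 101 samples (0..100%)")

    def time_axis(self) -> np.ndarray:
        if self.rate is None:
            raise ValueError("raw curve has no rate")
        return np.arange(len(self.values)) / self.rate

    def pct_axis(self) -> np.ndarray:
        return np.arange(101.0)


CurveSet = Dict[Tuple[str, str], AngleCurve]


def joint_angles(frames_by_segment: Dict[str, List[Optional[Frame]]],
                 joints: Iterable[str] = DEFAULT_JOINTS,
                 side: str = "right", rate: Optional[float] = None) -> CurveSet:
    """Per-frame joint angles for a reconstructed trial.

    Frames flagged invalid (None) propagate as NaN gaps.
    """
    n = max(len(v) for v in frames_by_segment.values())
    out: CurveSet = {}
    for j in joints:
        prox, dist = JOINTS[j]
        if prox not in frames_by_segment or dist not in frames_by_segment:
            if j in DEFAULT_JOINTS:
                raise AfmError(f"segment frames for joint {j} are missing")
            continue
        vals = {p: np.full(n, np.nan) for p in PLANES}
        for fi, (fp, fd) in enumerate(zip(frames_by_segment[prox], frames_by_segment[dist])):
            if fp is None or fd is None:
                continue
            a = joint_angle(fp, fd, side)
            vals["sagittal"][fi] = a.sagittal
            vals["frontal"][fi] = a.frontal if j != "HX_FFM" else np.nan
            vals["transverse"][fi] = a.transverse
        for p in PLANES:
            if j == "HX_FFM" and p == "frontal":
                continue
            out[(j, p)] = AngleCurve(j, p, vals[p], rate=rate)
    return out


# ---------------------------------------------------------------------------
# planar angles

def mla_from_points(nav, cap, hm1p) -> float:
    """Arch angle at the navicular between the CAp and HM1p directions."""
    return angle_between(nav - np.asarray(cap, float), nav - np.asarray(hm1p, float))


def mla(hindfoot_frame: Frame, forefoot_frame: Frame, nav, cal: ModelCalibration) -> float:
    """Medial longitudinal arch angle (degrees) at one instant.

    The stored segment-fixed CAp and HM1p points are mapped to the lab
    through the current hindfoot and forefoot frames.
    """
    if cal.cap_in_hindfoot is None or cal.hm1p_in_forefoot is None:
        raise AfmError("calibration lacks CAp/HM1p (no full foot contact and no fallback applied)")
    cap_lab = hindfoot_frame.to_lab(cal.cap_in_hindfoot)
    hm1p_lab = forefoot_frame.to_lab(cal.hm1p_in_forefoot)
    return mla_from_points(np.asarray(nav, float), cap_lab, hm1p_lab)


def tta(ms: MarkerSet) -> float:
    """Transverse tarsal arch angle: angle between BM1->BM2 and BM2->BM5."""
    ms.require(("BM1", "BM2", "BM5"), "TTA")
    return angle_between(ms["BM2"] - ms["BM1"], ms["BM5"] - ms["BM2"])


# ---------------------------------------------------------------------------
# ROM

def rom(curve) -> float:
    """Range of motion of one trial's curve: max minus min (degrees).

    Accepts an :class:`AngleCurve`, an array, or a sequence of per-trial
    curves, in which case the per-trial ROMs are averaged.
    """
    if isinstance(curve, AngleCurve):
        vals = curve.values
    elif isinstance(curve, (list, tuple)) and curve and isinstance(curve[0], (AngleCurve, list, tuple, np.ndarray)):
        return float(np.mean([rom(c) for c in curve]))
    else:
        vals = np.asarray(curve, dtype=float)
    ok = np.isfinite(vals)
    if not np.any(ok):
        raise AfmError("ROM of an all-gap curve is undefined")
    return float(np.max(vals[ok]) - np.min(vals[ok]))


# ---------------------------------------------------------------------------
# full-trial convenience pipeline

def trial_angles(trial: Trial, cal: ModelCalibration,
                 joints: Iterable[str] = DEFAULT_JOINTS,
                 include_arches: bool = True,
                 recon: Optional[ReconstructedFrames] = None) -> CurveSet:
    """Reconstruct frames and compute all requested angle curves for a
    dynamic trial, including the MLA and TTA planar angles."""
    if recon is None:
        recon = reconstruct_frames(trial, cal)
    curves = joint_angles(recon.frames, joints, cal.side, rate=trial.rate)
    if include_arches:
        n = trial.n_frames
        mla_vals = np.full(n, np.nan)
        tta_vals = np.full(n, np.nan)
        hf = recon.frames.get("hindfoot")
        ff = recon.frames.get("forefoot")
        nav = trial.positions("NAV") if trial.has_marker("NAV") else None
        for fi in range(n):
            ms = trial.marker_set(fi)
            try:
                tta_vals[fi] = tta(ms)
            except MissingMarkerError:
                pass
            if (hf is not None and ff is not None and nav is not None
                    and hf[fi] is not None and ff[fi] is not None
                    and np.all(np.isfinite(nav[fi]))
                    and cal.cap_in_hindfoot is not None):
                mla_vals[fi] = mla(hf[fi], ff[fi], nav[fi], cal)
        curves[("MLA", "planar")] = AngleCurve("MLA", "planar", mla_vals, rate=trial.rate)
        curves[("TTA", "planar")] = AngleCurve("TTA", "planar", tta_vals, rate=trial.rate)
    return curves


# ---------------------------------------------------------------------------
# two-marker-set comparison (soft-tissue-artifact style evaluation)

@dataclasses.dataclass
class MarkerSetComparison:
    """Orientation and joint-angle differences between two marker sets,
    with set A as the reference (e.g. bone-consistent positions) and set B
    as the perturbed one (e.g. including soft tissue artifacts)."""

    segment_errors: Dict[str, PlaneAngles]
    joint_differences: Dict[str, PlaneAngles]


def _kabsch(ms_a: MarkerSet, ms_b: MarkerSet):
    """Least-squares rigid transform mapping B's shared markers onto A's."""
    names = [n for n in ms_a if n in ms_b]
    if len(names) < 3:
        raise AfmError("rigid registration needs at least three shared markers")
    P = np.stack([ms_b[n] for n in names])
    Q = np.stack([ms_a[n] for n in names])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def angles_from_two_marker_sets(ms_a: MarkerSet, ms_b: MarkerSet, side: str = "right",
                                segments: Sequence[str] = SEGMENTS,
                                joints: Iterable[str] = DEFAULT_JOINTS,
                                align: bool = True) -> MarkerSetComparison:
    """Segment-orientation errors and joint-angle differences implied by
    moving every marker from configuration A to configuration B.

    With ``align`` (default) configuration B is first registered onto A by
    a least-squares rigid fit over the shared markers, so a global rigid
    motion between the two recordings does not masquerade as a segment
    orientation error.  Joint-angle differences are relative rotations and
    are unaffected by the registration.
    """
    if align:
        R, t = _kabsch(ms_a, ms_b)
        ms_b = ms_b.transformed(R, t)
    frames_a = {s: anatomical_frame(s, ms_a, side) for s in segments}
    frames_b = {s: anatomical_frame(s, ms_b, side) for s in segments}
    seg_err = {
        s: _side_adjust(planar_orientation_error(frames_a[s].rotation,
                                                 frames_b[s].rotation), side)
        for s in segments
    }
    ang_a = joint_angles_at(frames_a, side, joints)
    ang_b = joint_angles_at(frames_b, side, joints)
    joint_diff = {j: ang_b[j] - ang_a[j] for j in ang_a}
    return MarkerSetComparison(seg_err, joint_diff)
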