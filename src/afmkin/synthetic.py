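"""Synthetic foot and gait generator.

Provides (i) an anthropometric template marker set for a neutral-standing
right foot (EU shoe size ~41; mirrored in z for the left), (ii) rigid
per-segment walking trials driven by prescribed joint-angle curves with
exactly known ground truth, and (iii) perturbation injection: systematic
marker misplacement, pose-dependent soft-tissue-artifact offsets and
isotropic marker noise.

Consistency of the ground truth
-------------------------------
The model shares markers between articulating segments (BM2 and BM5
define both the midfoot and the forefoot; HM1 is a forefoot marker and
the hallux origin), so arbitrary 3-DOF motion at every joint cannot be
rigidly consistent with the model's own frame constructions.  The
generator therefore prescribes exactly the degrees of freedom that *are*
consistent:

* hindfoot-shank: full 3-DOF Cardan curves (no shared markers);
* midfoot-hindfoot: full 3-DOF (no shared markers);
* forefoot-midfoot: one DOF, a rotation about the tarsometatarsal axis
  through BM2 and BM5 — the shared markers lie on the joint axis and are
  therefore rigid in both segments;
* hallux-medial forefoot: sagittal and transverse.  The hallux frontal
  angle is structurally zero because the hallux y axis is constructed
  perpendicular to the medial forefoot z axis.

With this chain every anatomical and technical frame moves rigidly, and
the full static-calibration pipeline recovers the prescribed curves to
numerical precision on noise-free data.  Ground-truth curves for the
derived joints (FF_HF, FFM_MF, FFL_MF) are computed analytically from the
prescribed chain, never from the generated markers.

Foot trajectory and events
--------------------------
The foot centre's vertical velocity is a pair of opposite raised-cosine
bumps per stride: an upward bump peaking exactly at toe-off (push-off
rise) and a downward bump peaking exactly at initial contact (terminal
swing descent).  These peaks are the ground-truth event times and are the
same features the foot-velocity event detector looks for.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import AfmError
from .geometry import PlaneAngles, cardan_zxy, compose_cardan_zxy, rot_axis
from .io import Trial
from .model import MarkerSet, add_virtual_midpoints, anatomical_frame

#: Right-foot neutral-standing template coordinates (mm, y-up, x anterior,
#: z to the subject's right; floor at y=0).
TEMPLATE_RIGHT: Dict[str, Tuple[float, float, float]] = {
    "CALP": (-5.0, 60.0, 0.0),
    "CALD": (-5.0, 20.0, 0.0),
    "ST": (58.0, 30.0, -25.0),
    "PT": (58.0, 22.0, 30.0),
    "NAV": (75.0, 45.0, -20.0),
    "BM1": (95.0, 30.0, -25.0),
    "BM2": (105.0, 32.0, -8.0),
    "BM5": (85.0, 22.0, 30.0),
    "HM1": (165.0, 28.0, -35.0),
    "HM2": (175.0, 30.0, -10.0),
    "HM5": (150.0, 20.0, 32.0),
    "HLX": (205.0, 22.0, -28.0),
    "MM": (15.0, 75.0, -35.0),
    "LM": (15.0, 70.0, 38.0),
    "TT": (60.0, 380.0, 0.0),
    "FH": (30.0, 360.0, 45.0),
    "ASHN": (45.0, 230.0, 0.0),
    "LSHN": (25.0, 225.0, 30.0),
}

#: Markers rigidly attached to each generator body.  BM2/BM5 belong to the
#: midfoot body and sit on the forefoot-midfoot rotation axis, so they are
#: rigid in both segments.
_BODY_MARKERS = {
    "shank": ("TT", "FH", "ASHN", "LSHN", "LM", "MM"),
    "hindfoot": ("CALP", "CALD", "ST", "PT"),
    "midfoot": ("NAV", "BM2", "BM5"),
    "forefoot": ("BM1", "HM1", "HM2", "HM5"),
}


def template_foot(side: str = "right", scale: float = 1.0) -> MarkerSet:
    """The packaged neutral-standing marker template.

    ``scale`` scales uniformly about the origin (0.7-1.4 spans roughly
    child to large adult); the left side is the z-mirror.
    """
    if not scale > 0:
        raise AfmError("template scale must be positive")
    if side not in ("right", "left"):
        raise AfmError(f"side must be 'right' or 'left', got {side!r}")
    zs = 1.0 if side == "right" else -1.0
    return MarkerSet({
        name: np.array([x, y, z * zs]) * scale
        for name, (x, y, z) in TEMPLATE_RIGHT.items()
    })


@dataclasses.dataclass
class SineCurve:
    """offset + amplitude * sin(2*pi*(phase_of_cycle + phase)).

    ``offset=None`` means the template's static value for that joint and
    plane (so a zero-amplitude profile holds the static pose).
    """

    amplitude: float = 0.0
    offset: Optional[float] = None
    phase: float = 0.0

    def __call__(self, phi: np.ndarray, static: float) -> np.ndarray:
        base = static if self.offset is None else self.offset
        return base + self.amplitude * np.sin(2 * np.pi * (phi + self.phase))


@dataclasses.dataclass
class GaitProfile:
    """Prescribed joint curves plus stride timing and foot trajectory.

    Amplitudes are degrees and must stay within physiological bounds
    (<= 40 deg).  ``ff_mf`` is the single tarsometatarsal-axis rotation;
    its three-plane decomposition is part of the generated ground truth.
    """

    hf_sk: Dict[str, SineCurve] = dataclasses.field(default_factory=lambda: {
        "sagittal": SineCurve(12.0), "frontal": SineCurve(4.0, phase=0.2),
        "transverse": SineCurve(3.0, phase=0.4)})
    mf_hf: Dict[str, SineCurve] = dataclasses.field(default_factory=lambda: {
        "sagittal": SineCurve(4.0, phase=0.1), "frontal": SineCurve(3.0, phase=0.3),
        "transverse": SineCurve(2.0, phase=0.5)})
    ff_mf: SineCurve = dataclasses.field(default_factory=lambda: SineCurve(5.0, offset=0.0, phase=0.15))
    hx_ffm: Dict[str, SineCurve] = dataclasses.field(default_factory=lambda: {
        "sagittal": SineCurve(15.0, phase=0.55), "transverse": SineCurve(3.0, phase=0.7)})
    stride_time: float = 1.1          # s
    stance_fraction: float = 0.6
    n_strides: int = 3
    swing_height_mm: float = 60.0     # foot-centre clearance
    stride_length_mm: float = 1200.0
    bump_halfwidth: float = 0.10      # fraction of cycle, vertical bumps
    forward_halfwidth: float = 0.15   # fraction of cycle, progression bump
    start_phase: float = 0.25         # mid-stance start

    def validate(self) -> None:
        curves = [*self.hf_sk.values(), *self.mf_hf.values(), self.ff_mf,
                  *self.hx_ffm.values()]
        if any(abs(c.amplitude) > 40.0 for c in curves):
            raise AfmError("joint amplitudes above 40 deg are not physiological")
        if not (0.2 < self.stance_fraction < 0.8 and self.stride_time > 0
                and self.n_strides >= 1):
            raise AfmError("invalid gait profile timing")
        if self.bump_halfwidth * 2 > min(self.stance_fraction,
                                         1 - self.stance_fraction) + 1e-9:
            raise AfmError("vertical velocity bumps overlap")


#: STA model: marker -> callable(truth_angle_deviation_deg) -> offset mm.
StaModel = Mapping[str, Callable[[float], np.ndarray]]


def linear_sta(coeff_mm_per_deg) -> Callable[[float], np.ndarray]:
    """Soft-tissue offset linear in the ankle sagittal deviation."""
    c = np.asarray(coeff_mm_per_deg, dtype=float)
    return lambda dev_deg: c * dev_deg


@dataclasses.dataclass
class PerturbationSpec:
    """Marker perturbations applied to a synthesized trial.

    ``misplacement`` offsets (mm, lab axes of the neutral template) are
    applied to the template before motion, i.e. the marker is glued on in
    the wrong spot; ``sta`` adds pose-dependent offsets after rigid
    motion; ``noise_sd_mm`` adds isotropic Gaussian noise drawn from
    ``seed``.
    """

    misplacement: Dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    sta: StaModel = dataclasses.field(default_factory=dict)
    noise_sd_mm: float = 0.0
    seed: int = 0


def _smoothstep_integral(u: np.ndarray, w: float) -> np.ndarray:
    """Integral of a unit-area raised-cosine bump of half-width w."""
    out = np.clip((u + w) / (2 * w) + np.sin(np.pi * np.clip(u / w, -1, 1)) / (2 * np.pi), 0.0, 1.0)
    out[u <= -w] = 0.0
    out[u >= w] = 1.0
    return out


def _foot_translation(phi: np.ndarray, profile: GaitProfile) -> np.ndarray:
    """Lab translation of the foot root over global cycle phase."""
    to_phase = profile.stance_fraction
    k_max = int(np.ceil(phi.max())) + 1
    y = np.zeros_like(phi)
    x = np.zeros_like(phi)
    for k in range(-1, k_max + 1):
        y += profile.swing_height_mm * (
            _smoothstep_integral(phi - (k + to_phase), profile.bump_halfwidth)
            - _smoothstep_integral(phi - (k + 1.0), profile.bump_halfwidth))
        x += profile.stride_length_mm * _smoothstep_integral(
            phi - (k + (to_phase + 1.0) / 2.0), profile.forward_halfwidth)
    return np.stack([x, y, np.zeros_like(phi)], axis=1)


@dataclasses.dataclass
class SyntheticGait:
    """A synthesized walking trial plus its exact ground truth."""

    trial: Trial
    clean_trial: Trial
    truth: Dict[Tuple[str, str], np.ndarray]   # absolute clinical degrees
    ic_times: np.ndarray
    to_times: np.ndarray
    rate: float
    side: str
    profile: GaitProfile

    @property
    def ic_frames(self) -> np.ndarray:
        return np.round(self.ic_times * self.rate).astype(int)

    @property
    def to_frames(self) -> np.ndarray:
        return np.round(self.to_times * self.rate).astype(int)


def make_static_trial(ms: MarkerSet, n_frames: int = 5, rate: float = 100.0,
                      noise_sd_mm: float = 0.0, seed: int = 0) -> Trial:
    """A standing trial repeating a marker set, optionally with noise."""
    labels = list(ms)
    base = np.stack([ms[l] for l in labels])
    data = np.repeat(base[None, :, :], n_frames, axis=0)
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_mm, size=data.shape)
    return Trial(labels, data, rate, {"kind": "static", "synthetic": True})


def synthesize_gait(template: Optional[MarkerSet] = None,
                    profile: Optional[GaitProfile] = None,
                    rate: float = 100.0, side: str = "right",
                    perturb: Optional[PerturbationSpec] = None) -> SyntheticGait:
    """Generate a walking trial from the template with known ground truth."""
    if rate < 50:
        raise AfmError("sampling rate must be at least 50 Hz")
    profile = profile or GaitProfile()
    profile.validate()
    template = template or template_foot(side)
    perturb = perturb or PerturbationSpec()
    if perturb.misplacement:
        for name, off in perturb.misplacement.items():
            template = template.replace(name, template[name] + np.asarray(off, float))
    s = 1.0 if side == "right" else -1.0

    ms0 = add_virtual_midpoints(template)
    anat0 = {seg: anatomical_frame(seg, ms0, side)
             for seg in ("shank", "hindfoot", "midfoot", "forefoot",
                         "medial_forefoot", "lateral_forefoot", "hallux")}
    R0 = {seg: f.rotation for seg, f in anat0.items()}
    o0 = {seg: f.origin for seg, f in anat0.items()}

    def static_raw(prox, dist):
        return cardan_zxy(R0[prox], R0[dist])

    stat_hfsk = static_raw("shank", "hindfoot")
    stat_mfhf = static_raw("hindfoot", "midfoot")
    stat_hxffm = static_raw("medial_forefoot", "hallux")

    duration = (profile.n_strides + 1) * profile.stride_time
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    phi = profile.start_phase + t / profile.stride_time

    # clinical statics for offsets; raw = (sag, s*frontal, s*transverse)
    clin_hfsk = PlaneAngles(stat_hfsk.sagittal, s * stat_hfsk.frontal, s * stat_hfsk.transverse)
    clin_mfhf = PlaneAngles(stat_mfhf.sagittal, s * stat_mfhf.frontal, s * stat_mfhf.transverse)
    clin_hxffm = PlaneAngles(stat_hxffm.sagittal, 0.0, s * stat_hxffm.transverse)

    hfsk = {p: profile.hf_sk[p](phi, getattr(clin_hfsk, p)) for p in ("sagittal", "frontal", "transverse")}
    mfhf = {p: profile.mf_hf[p](phi, getattr(clin_mfhf, p)) for p in ("sagittal", "frontal", "transverse")}
    theta = profile.ff_mf(phi, 0.0)
    hx = {p: profile.hx_ffm[p](phi, getattr(clin_hxffm, p)) for p in ("sagittal", "transverse")}

    d = _foot_translation(phi, profile)

    # Tarsometatarsal axis (static, lab): through BM2 along BM2->BM5.
    c_axis = template["BM2"]
    a_dir = template["BM5"] - c_axis
    a_dir = a_dir / np.linalg.norm(a_dir)

    def axis_rot(angle_deg: float) -> np.ndarray:
        a = np.radians(angle_deg)
        K = np.array([[0, -a_dir[2], a_dir[1]],
                      [a_dir[2], 0, -a_dir[0]],
                      [-a_dir[1], a_dir[0], 0]])
        return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)

    labels = list(template)
    idx = {l: i for i, l in enumerate(labels)}
    base = np.stack([template[l] for l in labels])
    data = np.empty((n, len(labels), 3))

    truth: Dict[Tuple[str, str], np.ndarray] = {}
    for key in ("HF_SK", "MF_HF", "FF_HF", "FF_MF", "FFM_MF", "FFL_MF", "HX_FFM"):
        for p in ("sagittal", "frontal", "transverse"):
            truth[(key, p)] = np.empty(n)

    u_hlx = R0["hallux"].T @ (template["HLX"] - template["HM1"])

    for i in range(n):
        # raw relative rotations (right-hand Cardan; left foot flips signs)
        rel_hfsk = compose_cardan_zxy(hfsk["sagittal"][i], s * hfsk["frontal"][i],
                                      s * hfsk["transverse"][i])
        rel_mfhf = compose_cardan_zxy(mfhf["sagittal"][i], s * mfhf["frontal"][i],
                                      s * mfhf["transverse"][i])
        rel_hx = rot_axis("z", hx["sagittal"][i]) @ rot_axis("y", s * hx["transverse"][i])

        R_hf = R0["hindfoot"]                       # root: translation only
        R_sk = R_hf @ rel_hfsk.T
        R_mf = R_hf @ rel_mfhf
        # mirror-consistent: a mirrored axis needs the opposite rotation sign
        rot_ax = axis_rot(s * theta[i])
        M_mf_rot = R_mf @ R0["midfoot"].T           # rigid-motion rotation parts
        M_ff_rot = M_mf_rot @ rot_ax
        R_ffm = M_ff_rot @ R0["medial_forefoot"]
        R_hx = R_ffm @ rel_hx

        di = d[i]

        def place(names, Rm, center):
            for nm in names:
                data[i, idx[nm]] = Rm @ (base[idx[nm]] - center) + center + di

        place(_BODY_MARKERS["hindfoot"], np.eye(3), o0["hindfoot"])
        place(_BODY_MARKERS["shank"], R_sk @ R0["shank"].T, o0["hindfoot"])
        place(_BODY_MARKERS["midfoot"], M_mf_rot, o0["midfoot"])
        # forefoot: axis rotation about the static TMT line, then midfoot motion
        for nm in _BODY_MARKERS["forefoot"]:
            p_rot = rot_ax @ (base[idx[nm]] - c_axis) + c_axis
            data[i, idx[nm]] = M_mf_rot @ (p_rot - o0["midfoot"]) + o0["midfoot"] + di
        hm1_i = data[i, idx["HM1"]]
        data[i, idx["HLX"]] = hm1_i + R_hx @ u_hlx

        # analytic ground truth (clinical sign convention)
        def clin(prox_R, dist_R):
            a = cardan_zxy(prox_R, dist_R)
            return PlaneAngles(a.sagittal, s * a.frontal, s * a.transverse)

        R_ff = M_ff_rot @ R0["forefoot"]
        R_ffl = M_ff_rot @ R0["lateral_forefoot"]
        for key, val in (
            ("HF_SK", PlaneAngles(hfsk["sagittal"][i], hfsk["frontal"][i], hfsk["transverse"][i])),
            ("MF_HF", PlaneAngles(mfhf["sagittal"][i], mfhf["frontal"][i], mfhf["transverse"][i])),
            ("FF_HF", clin(R_hf, R_ff)),
            ("FF_MF", clin(R_mf, R_ff)),
            ("FFM_MF", clin(R_mf, R_ffm)),
            ("FFL_MF", clin(R_mf, R_ffl)),
            ("HX_FFM", PlaneAngles(hx["sagittal"][i], float("nan"), hx["transverse"][i])),
        ):
            truth[(key, "sagittal")][i] = val.sagittal
            truth[(key, "frontal")][i] = val.frontal
            truth[(key, "transverse")][i] = val.transverse

    clean = data.copy()

    # soft-tissue offsets: pose-dependent, driven by the ankle sagittal deviation
    if perturb.sta:
        dev = hfsk["sagittal"] - clin_hfsk.sagittal
        for nm, fn in perturb.sta.items():
            for i in range(n):
                data[i, idx[nm]] += fn(float(dev[i]))
    if perturb.noise_sd_mm > 0:
        rng = np.random.default_rng(perturb.seed)
        data = data + rng.normal(0.0, perturb.noise_sd_mm, size=data.shape)

    k_first = int(np.ceil(profile.start_phase))
    ic_times, to_times = [], []
    k = k_first - 1
    while True:
        tic = (k + 1.0 - profile.start_phase) * profile.stride_time
        tto = (k + profile.stance_fraction - profile.start_phase) * profile.stride_time
        if tto > t[-1] and tic > t[-1]:
            break
        if 0 < tto <= t[-1]:
            to_times.append(tto)
        if 0 < tic <= t[-1]:
            ic_times.append(tic)
        k += 1

    meta = {"kind": "gait", "synthetic": True, "side": side}
    trial = Trial(labels, data, rate, meta)
    clean_trial = Trial(labels, clean, rate, dict(meta))
    return SyntheticGait(trial, clean_trial, truth, np.array(sorted(ic_times)),
                         np.array(sorted(to_times)), rate, side, profile)
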