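"""Gait events from foot velocity, stride segmentation and normalization.

Initial contact (IC) and toe-off (TO) are detected from the vertical
velocity of the foot centre (midpoint of the heel and toe proxies CALD
and HM2): at heel strike the foot centre's downward velocity peaks, and
at push-off its upward velocity peaks.  The trajectory is low-pass
filtered (4th-order zero-lag Butterworth, 7 Hz by default),
differentiated by central differences, and the prominent velocity minima
/ maxima are taken as IC / TO.  Every parameter of the detector is
configurable.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

from .angles import AngleCurve
from .errors import AfmError
from .io import Trial


@dataclasses.dataclass
class EventConfig:
    heel_marker: str = "CALD"
    toe_marker: str = "HM2"
    #: 'center' = midpoint of heel and toe; 'heel' / 'toe' use one marker.
    velocity_source: str = "center"
    cutoff_hz: float = 7.0
    filter_order: int = 4          # effective order after filtfilt
    min_event_spacing_s: float = 0.35
    #: peak must exceed this fraction of the largest |velocity| ...
    rel_threshold: float = 0.25
    #: ... and this absolute floor (mm/s), so standing trials yield nothing.
    abs_threshold: float = 100.0


@dataclasses.dataclass
class GaitEvents:
    """Alternating initial contacts and toe-offs, as frame indices."""

    ic_frames: np.ndarray
    to_frames: np.ndarray
    rate: float
    direction: int = 1            # sign of walking progression along lab x

    @property
    def ic_times(self) -> np.ndarray:
        return self.ic_frames / self.rate

    @property
    def to_times(self) -> np.ndarray:
        return self.to_frames / self.rate

    @property
    def n_strides(self) -> int:
        return max(len(self.ic_frames) - 1, 0)

    def strides(self) -> List[Tuple[int, int]]:
        """(start, end) frame pairs of complete IC->IC strides."""
        return [(int(a), int(b)) for a, b in zip(self.ic_frames[:-1], self.ic_frames[1:])]


def lowpass(x: np.ndarray, rate: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass along the first axis."""
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        return np.asarray(x, float)
    sos = signal.butter(order // 2, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def foot_center_trajectory(trial: Trial, config: EventConfig) -> np.ndarray:
    heel = trial.positions(config.heel_marker)
    toe = trial.positions(config.toe_marker)
    if config.velocity_source == "heel":
        return heel
    if config.velocity_source == "toe":
        return toe
    return (heel + toe) / 2.0


def detect_events(trial: Trial, config: Optional[EventConfig] = None) -> GaitEvents:
    """Detect IC and TO events from foot velocity.

    A standing trial yields zero events (not an error); a trial shorter
    than a couple of filter lengths is rejected.
    """
    config = config or EventConfig()
    if trial.n_frames < 10:
        raise AfmError("trial too short for event detection")
    foot = foot_center_trajectory(trial, config)
    if np.any(~np.isfinite(foot)):
        raise AfmError("event detection requires gap-free heel/toe trajectories")
    filt = lowpass(foot, trial.rate, config.cutoff_hz, config.filter_order)
    vel = np.gradient(filt, 1.0 / trial.rate, axis=0)
    vy = vel[:, 1]
    vmax = float(np.max(np.abs(vy)))
    height = max(config.abs_threshold, config.rel_threshold * vmax)
    dist = max(int(round(config.min_event_spacing_s * trial.rate)), 1)
    ic, _ = signal.find_peaks(-vy, height=height, distance=dist)
    to, _ = signal.find_peaks(vy, height=height, distance=dist)
    direction = 1 if filt[-1, 0] - filt[0, 0] >= 0 else -1
    ic, to = _enforce_alternation(ic, to, vy)
    return GaitEvents(np.asarray(ic, int), np.asarray(to, int), trial.rate, direction)


def _enforce_alternation(ic, to, vy):
    """Drop the weaker of two same-type events occurring with no opposite
    event in between, so IC and TO strictly alternate."""
    events = sorted([(int(f), "ic") for f in ic] + [(int(f), "to") for f in to])
    cleaned = []
    for f, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            keep = f if abs(vy[f]) > abs(vy[prev]) else prev
            cleaned[-1] = (keep, kind)
        else:
            cleaned.append((f, kind))
    return ([f for f, k in cleaned if k == "ic"], [f for f, k in cleaned if k == "to"])


def normalize_stride(curve: AngleCurve, events: GaitEvents) -> Tuple[AngleCurve, List[AngleCurve]]:
    """Resample each IC->IC stride to 101 samples (0..100% of the gait
    cycle, inclusive) by linear interpolation, and average point-wise.

    Returns ``(mean_curve, per_stride_curves)``.
    """
    strides = events.strides()
    if not strides:
        raise AfmError("no complete stride between initial contacts")
    per_stride = []
    pct = np.linspace(0.0, 1.0, 101)
    for si, (a, b) in enumerate(strides):
        seg = curve.values[a:b + 1]
        x = np.linspace(0.0, 1.0, len(seg))
        ok = np.isfinite(seg)
        if not np.all(ok):
            if not np.any(ok):
                raise AfmError(f"stride {si} is entirely gaps")
            seg = np.interp(x, x[ok], seg[ok])
        per_stride.append(AngleCurve(curve.joint, curve.plane,
                                     np.interp(pct, x, seg),
                                     normalized=True, stride=si))
    mean_vals = np.mean([c.values for c in per_stride], axis=0)
    mean = AngleCurve(curve.joint, curve.plane, mean_vals, normalized=True)
    return mean, per_stride


def normalize_curve_set(curves, events: GaitEvents):
    """Normalize every curve of a set; returns (means, per-stride lists)
    keyed like the input."""
    means, strides = {}, {}
    for key, c in curves.items():
        means[key], strides[key] = normalize_stride(c, events)
    return means, strides
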