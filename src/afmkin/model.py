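"""Marker set and segment coordinate-system definitions.

The model uses 18 physical markers (see :data:`PHYSICAL_MARKERS`) plus four
virtual metatarsal midpoints, and defines anatomical coordinate systems for
seven segments: shank, hindfoot, midfoot, forefoot, an optional medial /
lateral split of the forefoot, and hallux.  Technical (tracking) coordinate
systems exist for the shank, hindfoot, forefoot and midfoot; the remaining
segments are rebuilt directly from their anatomical markers each frame
since none of their defining markers is restricted to the static trial.

All frames follow ISB axes: x anterior, y superior, z to the subject's
right, for both feet.  For the left foot the order of the subtraction in a
handful of cross products is flipped so that the constructions stay
right-handed with z pointing right.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, Iterable, Mapping

import numpy as np

from .errors import InvalidGeometryError, MissingMarkerError
from .geometry import Frame, as_vec3, build_frame, project_point_on_plane

#: The 18 physical marker names, in table order.
PHYSICAL_MARKERS = (
    "TT", "FH", "ASHN", "LSHN", "LM", "MM",
    "CALP", "CALD", "ST", "PT",
    "NAV",
    "BM1", "BM5", "HM1", "HM5", "BM2", "HM2",
    "HLX",
)

#: Virtual metatarsal midpoints added by :func:`add_virtual_midpoints`.
VIRTUAL_MARKERS = ("mBM12", "mBM25", "mHM12", "mHM25")

_MIDPOINT_PARENTS = {
    "mBM12": ("BM1", "BM2"),
    "mBM25": ("BM2", "BM5"),
    "mHM12": ("HM1", "HM2"),
    "mHM25": ("HM2", "HM5"),
}

#: Markers used only in the static trial to define anatomical frames; they
#: may be removed for the dynamic trials.
ANATOMICAL_ONLY = frozenset({"FH", "LM", "MM", "CALP"})

#: Markers used only for tracking, never in an anatomical definition.
TRACKING_ONLY = frozenset({"ASHN", "LSHN"})

SEGMENTS = (
    "shank", "hindfoot", "midfoot", "forefoot",
    "medial_forefoot", "lateral_forefoot", "hallux",
)

#: Optional segments (the forefoot may be split medially/laterally).
OPTIONAL_SEGMENTS = frozenset({"medial_forefoot", "lateral_forefoot"})

SIDES = ("right", "left")

#: Physical markers participating in each segment's anatomical frame.
SEGMENT_ANATOMICAL_MARKERS: Dict[str, tuple] = {
    "shank": ("LM", "MM", "FH", "TT"),
    "hindfoot": ("CALP", "CALD", "ST", "PT"),
    "midfoot": ("NAV", "BM2", "BM5"),
    "forefoot": ("BM1", "BM2", "BM5", "HM1", "HM2", "HM5"),
    "medial_forefoot": ("BM1", "BM2", "HM1", "HM2"),
    "lateral_forefoot": ("BM2", "BM5", "HM2", "HM5"),
    "hallux": ("HM1", "HLX", "BM1", "BM2", "HM2"),
}

#: Tracking-marker triples (origin marker first) for segments with a
#: technical CS.
TECHNICAL_TRIPLES: Dict[str, tuple] = {
    "shank": ("TT", "ASHN", "LSHN"),
    "hindfoot": ("CALD", "ST", "PT"),
    "forefoot": ("BM1", "HM2", "BM5"),
    "midfoot": ("NAV", "BM2", "BM5"),
}


def load_marker_aliases() -> dict:
    """Versioned mapping of common lab label spellings to model names."""
    with resources.files(__package__).joinpath("marker_aliases.json").open() as fh:
        return json.load(fh)


def canonical_marker_name(label: str, aliases: Mapping[str, str] | None = None) -> str | None:
    """Map an arbitrary lab label to a model marker name, or None."""
    if aliases is None:
        aliases = load_marker_aliases()["aliases"]
    lab = label.strip()
    if lab in PHYSICAL_MARKERS or lab in VIRTUAL_MARKERS:
        return lab
    up = lab.upper()
    if up in PHYSICAL_MARKERS:
        return up
    if up in aliases:
        return aliases[up]
    for prefix in ("R_", "L_", "R", "L", "RIGHT_", "LEFT_"):
        if up.startswith(prefix) and up[len(prefix):] in PHYSICAL_MARKERS:
            return up[len(prefix):]
    return None


class MarkerSet:
    """Labeled 3D marker positions (mm, lab frame, y-up) at one instant.

    Querying an absent marker raises :class:`MissingMarkerError`; it is
    never silently zero.
    """

    def __init__(self, positions: Mapping[str, Iterable[float]]):
        self._pos: Dict[str, np.ndarray] = {}
        for name, p in positions.items():
            if name in self._pos:
                raise ValueError(f"duplicate marker label {name!r}")
            self._pos[str(name)] = as_vec3(p)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._pos[name]
        except KeyError:
            raise MissingMarkerError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def __iter__(self):
        return iter(self._pos)

    def __len__(self):
        return len(self._pos)

    def items(self):
        return self._pos.items()

    def require(self, names: Iterable[str], context: str = "") -> None:
        for n in names:
            if n not in self._pos:
                raise MissingMarkerError(n, context)

    def replace(self, name: str, position) -> "MarkerSet":
        """New set with one marker moved (the original is untouched)."""
        d = dict(self._pos)
        d[name] = as_vec3(position)
        return MarkerSet(d)

    def transformed(self, rotation: np.ndarray, translation) -> "MarkerSet":
        """Rigidly moved copy: p -> R p + t."""
        R = np.asarray(rotation, dtype=float)
        t = as_vec3(translation)
        return MarkerSet({n: R @ p + t for n, p in self._pos.items()})

    def mirrored_z(self) -> "MarkerSet":
        """Mirror through the lab x-y plane (right foot <-> left foot)."""
        return MarkerSet({n: p * np.array([1.0, 1.0, -1.0]) for n, p in self._pos.items()})


def add_virtual_midpoints(ms: MarkerSet) -> MarkerSet:
    """Add the four virtual metatarsal midpoints mBM12, mBM25, mHM12, mHM25."""
    pos = dict(ms.items())
    for virt, (a, b) in _MIDPOINT_PARENTS.items():
        ms.require((a, b), context=f"needed for virtual midpoint {virt}")
        pos[virt] = (ms[a] + ms[b]) / 2.0
    return MarkerSet(pos)


def _check_side(side: str) -> float:
    if side not in SIDES:
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    # Sign applied to the cross-product arguments that the left foot flips.
    return 1.0 if side == "right" else -1.0


def _ensure_virtual(ms: MarkerSet) -> MarkerSet:
    if all(v in ms for v in VIRTUAL_MARKERS):
        return ms
    return add_virtual_midpoints(ms)


def anatomical_frame(segment: str, ms: MarkerSet, side: str = "right") -> Frame:
    """Anatomical coordinate system of one segment from a marker set.

    ``side`` flips the order of the flagged vector subtractions so that
    the left foot keeps ISB axes (x forward, y up, z to the subject's
    right) and right-handed rotations.
    """
    s = _check_side(side)
    if segment == "shank":
        ms.require(("LM", "MM", "FH", "TT"), "shank anatomical frame")
        o = (ms["LM"] + ms["MM"]) / 2.0
        # Quasi-frontal plane through the origin, LM and FH; the vertical
        # axis runs from the origin to the projection of TT onto it.
        n = np.cross(ms["LM"] - o, ms["FH"] - o)
        if np.linalg.norm(n) < 1e-9:
            raise InvalidGeometryError("shank: origin, LM and FH are collinear")
        tt_proj = project_point_on_plane(ms["TT"], n, o)
        y = tt_proj - o
        x = np.cross(y, s * (ms["LM"] - o))
        return build_frame(o, y, x, "y", "x", context="shank")
    if segment == "hindfoot":
        ms.require(("CALP", "CALD", "ST", "PT"), "hindfoot anatomical frame")
        o = (ms["CALD"] + ms["CALP"]) / 2.0
        x = (ms["ST"] + ms["PT"]) / 2.0 - o
        z = np.cross(x, ms["CALP"] - ms["CALD"])  # no side flip: both vectors mirror
        return build_frame(o, x, np.cross(z, x), "x", "y", context="hindfoot")
    if segment == "midfoot":
        ms.require(("NAV", "BM2", "BM5"), "midfoot anatomical frame")
        o = (ms["NAV"] + ms["BM5"]) / 2.0
        x = ms["BM2"] - o
        y = np.cross(s * (ms["BM5"] - ms["NAV"]), ms["BM2"] - ms["NAV"])
        return build_frame(o, x, y, "x", "y", context="midfoot")
    if segment == "forefoot":
        m = _ensure_virtual(ms)
        o = (m["mBM12"] + m["mBM25"]) / 2.0
        x = (m["mHM12"] + m["mHM25"]) / 2.0 - o
        y = np.cross(s * (m["mHM25"] - o), m["mHM12"] - o)
        return build_frame(o, x, y, "x", "y", context="forefoot")
    if segment == "medial_forefoot":
        m = _ensure_virtual(ms)
        o = m["mBM12"]
        x = m["mHM12"] - o
        y = np.cross(s * (ms["BM2"] - ms["BM1"]), x)
        return build_frame(o, x, y, "x", "y", context="medial forefoot")
    if segment == "lateral_forefoot":
        m = _ensure_virtual(ms)
        o = m["mBM25"]
        x = m["mHM25"] - o
        y = np.cross(s * (ms["BM5"] - ms["BM2"]), x)
        return build_frame(o, x, y, "x", "y", context="lateral forefoot")
    if segment == "hallux":
        ms.require(("HM1", "HLX"), "hallux anatomical frame")
        z_mff = anatomical_frame("medial_forefoot", ms, side).z
        o = ms["HM1"]
        x = ms["HLX"] - o
        y = np.cross(z_mff, x)
        return build_frame(o, x, y, "x", "y", context="hallux")
    raise ValueError(f"unknown segment {segment!r}")


def technical_frame(segment: str, ms: MarkerSet) -> Frame:
    """Deterministic tracking frame from a segment's 3-marker triple.

    Origin at the first marker; primary (x) axis toward the second; the
    third marker fixes the x-y plane.  The same construction is used in
    the static and dynamic trials, so the static anatomical-in-technical
    transform reconstructs the anatomical frame exactly on rigid data.
    """
    try:
        a, b, c = TECHNICAL_TRIPLES[segment]
    except KeyError:
        raise ValueError(f"segment {segment!r} has no technical frame") from None
    ms.require((a, b, c), f"{segment} technical frame")
    o = ms[a]
    return build_frame(o, ms[b] - o, ms[c] - o, "x", "y", context=f"{segment} technical")
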