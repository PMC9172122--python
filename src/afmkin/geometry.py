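"""Side-effect-free 3D primitives.

Everything downstream (segment frames, joint angles, sensitivity gradients)
is built from the handful of operations in this module: plane projection,
right-handed frame construction from a primary axis and a second in-plane
direction, and the floating-axis (Grood & Suntay style) z-x'-y'' Cardan
decomposition used for all joint and segment-orientation angles.

Conventions
-----------
* Vectors are length-3 numpy arrays in millimetres (or dimensionless for
  directions); rotations are 3x3 orthonormal matrices whose *columns* are
  the x, y, z axes of the child frame expressed in the parent frame.
* Segment frames follow ISB: x anterior, y superior, z to the subject's
  right in anatomical position.
* Angles cross module boundaries in degrees; radians are internal only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidGeometryError

_AXES = ("x", "y", "z")

#: |frontal - 90 deg| below which the z-x'-y'' decomposition is singular.
GIMBAL_TOL_RAD = 1e-6


def as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidGeometryError("vector has non-finite components")
    return a


def normalize(v, *, context: str = "") -> np.ndarray:
    v = as_vec3(v)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidGeometryError(f"zero-length vector{': ' + context if context else ''}")
    return v / n


def project_point_on_plane(p, normal, point_on_plane) -> np.ndarray:
    """Orthogonal projection of ``p`` onto the plane through
    ``point_on_plane`` with normal ``normal``."""
    p = as_vec3(p)
    n = normalize(normal, context="plane normal")
    q = as_vec3(point_on_plane)
    return p - np.dot(p - q, n) * n


class PlaneAngles(NamedTuple):
    """Sagittal / frontal / transverse plane angles in degrees.

    Sagittal is the rotation about the proximal medio-lateral (z) axis,
    frontal about the floating anterior-posterior (x) axis, transverse
    about the distal vertical (y) axis.
    """

    sagittal: float
    frontal: float
    transverse: float

    def __sub__(self, other):
        return PlaneAngles(*(a - b for a, b in zip(self, other)))

    @property
    def gimbal(self) -> bool:
        return abs(abs(self.frontal) - 90.0) < np.degrees(GIMBAL_TOL_RAD)


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-9)
    )


@dataclass(frozen=True)
class Frame:
    """A segment pose: origin (mm) plus orthonormal right-handed axes."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_vec3(self.origin))
        R = np.asarray(self.rotation, dtype=float)
        if not is_rotation(R, tol=1e-8):
            raise InvalidGeometryError("rotation is not orthonormal with det +1")
        object.__setattr__(self, "rotation", R)

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]

    def to_lab(self, p_local) -> np.ndarray:
        """Map a point from frame coordinates to lab coordinates."""
        return self.rotation @ as_vec3(p_local) + self.origin

    def to_local(self, p_lab) -> np.ndarray:
        """Map a lab point into this frame's coordinates."""
        return self.rotation.T @ (as_vec3(p_lab) - self.origin)


def build_frame(origin, primary, secondary, primary_label: str = "x",
                secondary_plane_label: str = "y", *, context: str = "") -> Frame:
    """Right-handed orthonormal frame from a primary axis direction and a
    second direction fixing the (primary, secondary) plane.

    The primary axis is the normalized ``primary``; the remaining axis
    (neither label) is the right-handed normalized cross product of the
    two inputs; the secondary axis completes the triad and therefore lies
    in the plane spanned by the inputs.
    """
    if primary_label not in _AXES or secondary_plane_label not in _AXES \
            or primary_label == secondary_plane_label:
        raise ValueError("axis labels must be two distinct names among x, y, z")
    p = normalize(primary, context=context or "primary axis")
    s = as_vec3(secondary)
    cross = np.cross(p, s)
    sin_angle = np.linalg.norm(cross) / max(np.linalg.norm(s), 1e-300)
    if sin_angle < 1e-6:
        raise InvalidGeometryError(
            f"degenerate frame: primary and secondary directions are parallel"
            f"{' (' + context + ')' if context else ''}"
        )
    i = _AXES.index(primary_label)
    j = _AXES.index(secondary_plane_label)
    k = 3 - i - j
    even = (j - i) % 3 == 1  # (i, j, k) is a cyclic permutation of (x, y, z)
    e_k = normalize(cross if even else -cross)
    e_j = np.cross(e_k, p) if even else np.cross(p, e_k)
    R = np.empty((3, 3))
    R[:, i], R[:, j], R[:, k] = p, e_j, e_k
    return Frame(as_vec3(origin), R)


def rot_axis(axis: str, angle_deg: float) -> np.ndarray:
    """Elementary rotation about a coordinate axis (right-hand rule)."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def compose_cardan_zxy(sagittal: float, frontal: float, transverse: float) -> np.ndarray:
    """Relative rotation for the z-x'-y'' sequence, angles in degrees."""
    return rot_axis("z", sagittal) @ rot_axis("x", frontal) @ rot_axis("y", transverse)


def cardan_zxy(prox: np.ndarray, dist: np.ndarray) -> PlaneAngles:
    """Decompose the relative rotation prox^T @ dist in the z-x'-y''
    (sagittal, frontal, transverse) floating-axis sequence.

    For a right foot in ISB axes, positive values are dorsiflexion,
    inversion and internal rotation / adduction.  Near the frontal-plane
    singularity (|frontal| = 90 deg) the transverse angle is set to zero
    by convention and the whole z/y rotation is folded into sagittal.
    """
    R = np.asarray(prox, dtype=float).T @ np.asarray(dist, dtype=float)
    # R = Rz(a) @ Rx(b) @ Ry(c):  R[2,1] = sin b;  R[0,1] = -sin a cos b;
    # R[1,1] = cos a cos b;  R[2,0] = -cos b sin c;  R[2,2] = cos b cos c.
    sb = np.clip(R[2, 1], -1.0, 1.0)
    b = np.arcsin(sb)
    if np.pi / 2 - abs(b) < GIMBAL_TOL_RAD:
        # Gimbal: only a -/+ c is determined; fold into sagittal, transverse = 0.
        a = np.arctan2(R[1, 0], R[0, 0])
        c = 0.0
    else:
        a = np.arctan2(-R[0, 1], R[1, 1])
        c = np.arctan2(-R[2, 0], R[2, 2])
    return PlaneAngles(float(np.degrees(a)), float(np.degrees(b)), float(np.degrees(c)))


def angle_between(u, v) -> float:
    """Unsigned angle between two 3D vectors in degrees, in [0, 180].

    Uses atan2(|u x v|, u . v), which is numerically stable for nearly
    parallel and nearly antiparallel vectors (unlike acos of the dot).
    """
    u = as_vec3(u)
    v = as_vec3(v)
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
        raise InvalidGeometryError("angle_between requires nonzero vectors")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def planar_orientation_error(ref: np.ndarray, test: np.ndarray) -> PlaneAngles:
    """Orientation of ``test`` with respect to ``ref`` decomposed into the
    three anatomical planes with the same z-x'-y'' sequence as joint
    angles (used for misplacement sensitivity and soft-tissue-artifact
    orientation errors)."""
    return cardan_zxy(ref, test)
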