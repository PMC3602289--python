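"""Vertebral coordinate frames and rigid-transform algebra.

Every vertebra is represented by a local coordinate system (a
:class:`VertebraFrame`): its center plus an orthonormal triad of axes
(columns = lateral, anterior, superior).  Frames are estimated from the
two landmark dialects available clinically:

* the 3D X-ray reconstruction carries 6 landmarks per vertebra (centers
  of the superior and inferior endplates, plus points below and above
  the left and right pedicles);
* the sagittal MRI segmentation carries 8 landmarks per vertebra (left
  and right edges of the anterior, posterior, superior and inferior
  ends of the vertebral body).

The two landmark sets share no point correspondences across modalities,
which is precisely why registration goes through per-vertebra frames and
rigid transforms between them rather than through the landmarks
directly.

All coordinates are in millimetres, in a right-handed world system with
z increasing superiorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "VertebraFrame",
    "RigidTransform",
    "XRAY_LANDMARK_NAMES",
    "MRI_LANDMARK_NAMES",
    "frame_from_xray_landmarks",
    "frame_from_mri_landmarks",
    "rigid_between",
    "compose",
    "invert",
    "apply",
]

# Named roles of the 6 X-ray landmarks of one vertebra.
XRAY_LANDMARK_NAMES = (
    "plate_superior",
    "plate_inferior",
    "pedicle_left_superior",
    "pedicle_left_inferior",
    "pedicle_right_superior",
    "pedicle_right_inferior",
)

# Named roles of the 8 MRI landmarks of one vertebra (left/right edges of
# the anterior, posterior, superior and inferior ends of the body).
MRI_LANDMARK_NAMES = (
    "anterior_left",
    "anterior_right",
    "posterior_left",
    "posterior_right",
    "superior_left",
    "superior_right",
    "inferior_left",
    "inferior_right",
)

_ORTHO_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when landmarks are collinear/coincident or a matrix is not
    a proper rotation."""


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise DegenerateGeometryError(f"{what} is degenerate (zero length)")
    return v / n


def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise DegenerateGeometryError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise DegenerateGeometryError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise DegenerateGeometryError("matrix is a reflection (det < 0)")
    return R


@dataclass
class VertebraFrame:
    """Local coordinate system of one vertebra.

    Parameters
    ----------
    label : str
        Vertebra name, ``"T1"`` .. ``"L5"``.
    center : (3,) array
        Frame origin in world mm.
    axes : (3, 3) array
        Orthonormal, det +1; columns are the lateral, anterior and
        superior unit axes expressed in world coordinates.
    """

    label: str
    center: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = _check_rotation(self.axes, tol=1e-8)

    @property
    def lateral(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def anterior(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def superior(self) -> np.ndarray:
        return self.axes[:, 2]

    @classmethod
    def identity(cls, label: str = "world") -> "VertebraFrame":
        return cls(label, np.zeros(3), np.eye(3))

    def transformed(self, T: "RigidTransform") -> "VertebraFrame":
        """Frame after moving rigidly by ``T`` (same label)."""
        return VertebraFrame(self.label, T.apply(self.center), T.rotation @ self.axes)


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = _check_rotation(self.rotation)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {M.shape}")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """Composition ``T2 o T1``: apply ``T1`` first, then ``T2``.

    Matches the right-to-left notation of the articulated chain, where
    the global transform of vertebra v is the fold of the intervertebral
    transforms ending with the world-to-first-vertebra transform.
    """
    return RigidTransform(
        T2.rotation @ T1.rotation, T2.rotation @ T1.translation + T2.translation
    )


def invert(T: RigidTransform) -> RigidTransform:
    return T.inverse()


def apply(T: RigidTransform, points: np.ndarray) -> np.ndarray:
    return T.apply(points)


def rigid_between(frame_a: VertebraFrame, frame_b: VertebraFrame) -> RigidTransform:
    """World-space rigid transform mapping ``frame_a`` onto ``frame_b``.

    ``T.apply(a.center) == b.center`` and ``T.rotation @ a.axes == b.axes``.
    """
    R = frame_b.axes @ frame_a.axes.T
    t = frame_b.center - R @ frame_a.center
    return RigidTransform(R, t)


def _as_points(
    landmarks: Mapping[str, Sequence[float]], names: Iterable[str], kind: str
) -> dict[str, np.ndarray]:
    missing = [n for n in names if n not in landmarks]
    if missing:
        raise ValueError(f"missing {kind} landmarks: {missing}")
    return {n: np.asarray(landmarks[n], dtype=float).reshape(3) for n in names}


def frame_from_xray_landmarks(
    landmarks: Mapping[str, Sequence[float]], label: str = ""
) -> VertebraFrame:
    """Vertebral frame from the 6 X-ray reconstruction landmarks.

    Center is the centroid of the six points.  The superior axis is the
    direction from the inferior to the superior endplate center (the most
    reliable landmarks, hence trusted most in the Gram-Schmidt order);
    the lateral axis comes from the right-to-left pedicle midpoint
    difference, orthogonalized against it; anterior completes the
    right-handed triad.
    """
    pts = _as_points(landmarks, XRAY_LANDMARK_NAMES, "X-ray")
    center = np.mean(list(pts.values()), axis=0)
    superior = _unit(pts["plate_superior"] - pts["plate_inferior"], "endplate axis")
    left_mid = 0.5 * (pts["pedicle_left_superior"] + pts["pedicle_left_inferior"])
    right_mid = 0.5 * (pts["pedicle_right_superior"] + pts["pedicle_right_inferior"])
    lat_raw = left_mid - right_mid
    lat_raw = lat_raw - np.dot(lat_raw, superior) * superior
    lateral = _unit(lat_raw, "pedicle lateral axis (collinear with endplate axis?)")
    anterior = np.cross(superior, lateral)
    axes = np.column_stack([lateral, anterior, superior])
    return VertebraFrame(label, center, axes)


def frame_from_mri_landmarks(
    landmarks: Mapping[str, Sequence[float]], label: str = ""
) -> VertebraFrame:
    """Vertebral frame from the 8 MRI vertebral-body edge landmarks.

    Center is the centroid of the eight points.  Superior axis from the
    superior-pair midpoint minus the inferior-pair midpoint; anterior
    axis from the anterior-pair midpoint minus the posterior-pair
    midpoint, orthogonalized; lateral completes the right-handed triad.
    """
    pts = _as_points(landmarks, MRI_LANDMARK_NAMES, "MRI")
    center = np.mean(list(pts.values()), axis=0)

    def mid(a: str, b: str) -> np.ndarray:
        return 0.5 * (pts[a] + pts[b])

    superior = _unit(
        mid("superior_left", "superior_right") - mid("inferior_left", "inferior_right"),
        "superior axis",
    )
    ant_raw = mid("anterior_left", "anterior_right") - mid(
        "posterior_left", "posterior_right"
    )
    ant_raw = ant_raw - np.dot(ant_raw, superior) * superior
    anterior = _unit(ant_raw, "anterior axis (collinear with superior axis?)")
    lateral = np.cross(anterior, superior)
    axes = np.column_stack([lateral, anterior, superior])
    return VertebraFrame(label, center, axes)
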