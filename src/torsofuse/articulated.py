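"""Articulated spine model and cross-modality bone registration.

The spine is represented as a chain of local rigid intervertebral
transformations between the frames of adjacent vertebrae.  The global
transform of vertebra v is the right-to-left fold of the chain,

    T_0,v = T_{v-1,v} o T_{v-2,v-1} o ... o T_{1,2} o T_0,1,

where T_0,1 takes the world frame onto the first (most inferior)
vertebra.  Building one such model per modality (prone MRI, standing
X-ray) gives a per-vertebra bone transform from MRI space into X-ray
space as the concatenation

    T_v-MRI-bone = T_0,v-Xray o T_0,v-MRI^-1 ,

which maps the MRI frame of vertebra v exactly onto its X-ray frame.
Each axial MRI slice is then moved rigidly by the transform of the
vertebra whose center z is closest to the slice — slices are treated as
independent 2D planes, with no continuity constraint between them.

Composition order: ``compose(T2, T1)`` applies T1 first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .geometry import (
    RigidTransform,
    VertebraFrame,
    compose,
    invert,
    rigid_between,
)
from .imagedata import AxialSlice

__all__ = [
    "ArticulatedModel",
    "build_articulated",
    "cross_modality_transforms",
    "assign_slice_vertebra",
    "apply_articulated_to_slice",
    "fit_global_rigid",
    "N_VERTEBRAE",
]

# Thoracic + lumbar chain length (T1..T12, L1..L5).
N_VERTEBRAE = 17


@dataclass
class ArticulatedModel:
    """Intervertebral transform chain of one modality.

    ``locals_[k]`` is the world-space rigid transform taking frame k
    onto frame k+1; ``globals_[k]`` is T_0,k per the chain fold;
    ``world_to_first`` is T_0,1.
    """

    modality: str
    frames: List[VertebraFrame]
    world_to_first: RigidTransform
    locals_: List[RigidTransform]
    globals_: List[RigidTransform]

    @property
    def labels(self) -> List[str]:
        return [f.label for f in self.frames]


def build_articulated(
    frames: Sequence[VertebraFrame],
    modality: str = "MRI",
    expected_count: int = N_VERTEBRAE,
) -> ArticulatedModel:
    """Build the articulated model from vertebral frames in anatomical
    (inferior -> superior) order.

    Raises
    ------
    ValueError
        If the frame count differs from ``expected_count``.
    """
    frames = list(frames)
    if expected_count is not None and len(frames) != expected_count:
        raise ValueError(
            f"expected {expected_count} vertebral frames, got {len(frames)}"
        )
    world = VertebraFrame.identity()
    world_to_first = rigid_between(world, frames[0])
    locals_ = [rigid_between(frames[k], frames[k + 1]) for k in range(len(frames) - 1)]
    globals_: List[RigidTransform] = [world_to_first]
    for T in locals_:
        globals_.append(compose(T, globals_[-1]))
    return ArticulatedModel(modality, frames, world_to_first, locals_, globals_)


def cross_modality_transforms(
    mri: ArticulatedModel, xray: ArticulatedModel
) -> List[RigidTransform]:
    """Per-vertebra bone transforms T_v-MRI-bone from MRI into X-ray space.

    Applying the k-th transform to the k-th MRI vertebral frame
    reproduces the k-th X-ray vertebral frame.
    """
    if mri.labels != xray.labels:
        raise ValueError(
            f"vertebra label mismatch: MRI {mri.labels} vs X-ray {xray.labels}"
        )
    return [
        compose(gx, invert(gm)) for gm, gx in zip(mri.globals_, xray.globals_)
    ]


def assign_slice_vertebra(
    slice_z: float, mri_frames: Sequence[VertebraFrame]
) -> str:
    """Label of the vertebra whose center z is closest to the slice.

    Ties (exactly equidistant centers) resolve to the inferior vertebra,
    i.e. the one with the smaller center z.
    """
    frames = sorted(mri_frames, key=lambda f: f.center[2])
    zs = np.array([f.center[2] for f in frames])
    d = np.abs(zs - float(slice_z))
    return frames[int(np.argmin(d))].label  # argmin takes the first (inferior) tie


def apply_articulated_to_slice(
    slice_: AxialSlice, transform: RigidTransform
) -> AxialSlice:
    """Move a slice rigidly: pose pre-multiplied, pixel data untouched."""
    return slice_.transformed(transform)


def fit_global_rigid(
    frames_a: Sequence[VertebraFrame],
    frames_b: Sequence[VertebraFrame],
    axis_arm_mm: float = 20.0,
) -> RigidTransform:
    """Least-squares single rigid transform taking frame set A onto B.

    The comparator baseline: a Kabsch fit over all vertebral centers
    plus points offset along each frame axis (so orientations, not just
    centers, constrain the fit), applied globally to every slice.
    """
    if len(frames_a) != len(frames_b):
        raise ValueError("frame sets must have equal length")

    def cloud(frames: Sequence[VertebraFrame]) -> np.ndarray:
        pts = []
        for f in frames:
            pts.append(f.center)
            for k in range(3):
                pts.append(f.center + axis_arm_mm * f.axes[:, k])
        return np.asarray(pts)

    A, B = cloud(frames_a), cloud(frames_b)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cb - R @ ca)
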