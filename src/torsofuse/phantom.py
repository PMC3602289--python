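"""Synthetic scoliotic-torso phantoms with known ground truth.

No public torso dataset pairs prone MRI slices with standing biplanar
X-ray spine reconstructions and optical surface topography (TP) of the
same patient, so the package ships a phantom generator that emulates
the acquisition geometry of such a study:

* a 17-vertebra thoracic + lumbar spine (T1..T12, L1..L5) laid out on a
  laterally curved center line with a configurable Cobb-like severity
  and apex level, plus axial vertebral rotation — the standing / X-ray
  posture;
* a "prone" variant produced by perturbing every intervertebral joint
  of the standing chain with small seeded rotations and translations
  (the postural change of lying down), under a global scanner-frame
  offset, with the exact per-joint corrections recorded as ground
  truth;
* per-vertebra landmark sets in both dialects (6 X-ray landmarks, 8
  MRI body-edge landmarks), rigid-body consistent with each vertebral
  frame;
* an elliptical-cross-section torso surface whose center line follows
  the spinal curve, with named external markers at the clinical sites
  (vertebra prominens, pilonidal dimples, iliac spines, sternum,
  spinous process, scapular angles) snapped onto the mesh;
* axial slice stacks (1 x 1 mm in-plane, 12 mm spacing, ~33 slices over
  a ~400 mm trunk) with binary torso and vertebra masks.  The prone
  torso carries an anterior soft-tissue compression (radial scale < 1
  on the anterior half) emulating the tissue compression of lying
  face-down, which is exactly the rigid + non-rigid mixture the
  registration method targets.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, VertebraFrame, compose, invert
from .imagedata import AxialSlice

__all__ = [
    "LEVELS",
    "CurvatureParams",
    "ProneParams",
    "BodyParams",
    "SpinePhantom",
    "TorsoPhantom",
    "PhantomStudy",
    "generate_spine",
    "generate_torso",
    "generate_axial_slices",
    "generate_study",
    "cobb_angle",
    "recover_standing_frames",
]

# Vertebra labels in chain order (inferior -> superior: the "first"
# vertebra of the articulated chain is the most inferior one).
LEVELS = ["L5", "L4", "L3", "L2", "L1"] + [f"T{k}" for k in range(12, 0, -1)]

_SPINE_Y = -60.0           # sagittal offset of the spine inside the torso (mm)
_Z_FIRST = 20.0            # center z of L5 (mm)
_Z_SPACING = 24.0          # intervertebral center spacing (mm)
_VERT_RX, _VERT_RY = 16.0, 12.0   # vertebral-body cross-section semi-axes (mm)
_VERT_HALF_HEIGHT = 14.0          # vertebral-body half-height (mm); covers the
                                  # 12 mm worst-case slice-to-center offset

# Local landmark templates (mm).  Both have centroid exactly at the
# frame origin so the 6-point and 8-point frame constructions agree on
# the same center; the synthetic shapes are stylized, not anatomical.
XRAY_TEMPLATE = {
    "plate_superior": (0.0, 6.0, 12.0),
    "plate_inferior": (0.0, 6.0, -12.0),
    "pedicle_left_superior": (9.0, -3.0, 5.0),
    "pedicle_left_inferior": (9.0, -3.0, -5.0),
    "pedicle_right_superior": (-9.0, -3.0, 5.0),
    "pedicle_right_inferior": (-9.0, -3.0, -5.0),
}
MRI_TEMPLATE = {
    "anterior_left": (8.0, 16.0, 0.0),
    "anterior_right": (-8.0, 16.0, 0.0),
    "posterior_left": (8.0, -16.0, 0.0),
    "posterior_right": (-8.0, -16.0, 0.0),
    "superior_left": (8.0, 0.0, 11.0),
    "superior_right": (-8.0, 0.0, 11.0),
    "inferior_left": (8.0, 0.0, -11.0),
    "inferior_right": (-8.0, 0.0, -11.0),
}


@dataclass
class CurvatureParams:
    """Lateral-curve shape of the standing spine.

    Either ``amplitude_mm`` (apex lateral deviation) or
    ``target_cobb_deg`` (solved to an amplitude) must be set; amplitude
    wins if both are given.  ``axial_rotation_deg`` is the peak axial
    vertebral rotation at the apex.
    """

    amplitude_mm: Optional[float] = None
    target_cobb_deg: Optional[float] = 50.0
    apex_level: str = "T9"
    axial_rotation_deg: float = 8.0

    def __post_init__(self) -> None:
        if self.apex_level not in LEVELS:
            raise ValueError(
                f"invalid apex level {self.apex_level!r}; expected one of T1..L5"
            )
        if self.amplitude_mm is not None and self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_mm is None and self.target_cobb_deg is None:
            raise ValueError("set amplitude_mm or target_cobb_deg")


@dataclass
class ProneParams:
    """Standing -> prone deformation model.

    Per-joint perturbations are drawn uniformly within the stated
    bounds about/along all three local axes; the anterior half of the
    torso is radially compressed by ``anterior_compression``; the whole
    prone acquisition lives in a rigidly offset scanner frame.
    """

    max_joint_rotation_deg: float = 2.0
    max_joint_translation_mm: float = 1.0
    anterior_compression: float = 0.82
    global_rotation_deg: tuple = (1.0, -2.0, 5.0)
    global_translation_mm: tuple = (10.0, 20.0, -15.0)

    def __post_init__(self) -> None:
        self.global_rotation_deg = tuple(self.global_rotation_deg)
        self.global_translation_mm = tuple(self.global_translation_mm)
        if not (0 < self.anterior_compression <= 1.0):
            raise ValueError("anterior_compression must be in (0, 1]")

    def global_offset(self) -> RigidTransform:
        R = Rotation.from_euler("xyz", self.global_rotation_deg, degrees=True)
        return RigidTransform(R.as_matrix(), np.asarray(self.global_translation_mm))


@dataclass
class BodyParams:
    """Elliptical torso body: semi-axes, how strongly the torso center
    line follows the spinal curve, and the anterior compression factor
    (1 = none; < 1 for the prone torso)."""

    radius_x: float = 150.0
    radius_y: float = 110.0
    follow_fraction: float = 0.6
    anterior_compression: float = 1.0
    n_theta: int = 96
    n_z: int = 80
    z_margin: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_x <= 0 or self.radius_y <= 0:
            raise ValueError("torso radii must be strictly positive")
        if not (0 < self.anterior_compression <= 1.0):
            raise ValueError("anterior_compression must be in (0, 1]")


@dataclass
class ProneGroundTruth:
    """Recorded prone -> standing corrections.

    Applying ``global_correction`` to the first prone vertebra and
    ``joint_corrections[k]`` (in the local frame of vertebra k+1) to
    each intervertebral transform reproduces the standing chain.
    """

    standing_frames: List[VertebraFrame]
    global_correction: RigidTransform
    joint_corrections: List[RigidTransform]
    prone_params: ProneParams


@dataclass
class SpinePhantom:
    """Spine phantom; ``scanner_pose`` is the rigid transform from the
    patient-canonical frame (in which the torso is modelled) to the
    scanner/world frame — identity for the standing posture."""

    frames: List[VertebraFrame]
    xray_landmarks: Dict[str, Dict[str, np.ndarray]]
    mri_landmarks: Dict[str, Dict[str, np.ndarray]]
    curvature_params: CurvatureParams
    posture: str = "standing"
    seed: int = 0
    ground_truth: Optional[ProneGroundTruth] = None
    scanner_pose: RigidTransform = field(default_factory=RigidTransform.identity)

    @property
    def labels(self) -> List[str]:
        return [f.label for f in self.frames]

    def center_zs(self) -> np.ndarray:
        return np.array([f.center[2] for f in self.frames])


@dataclass
class SectionModel:
    """Analytic torso cross-section.

    At height z: an ellipse centred at (center_x(z), 0) with semi-axes
    (rx, ry), radially compressed on its anterior side by a smooth
    angular profile — the radial factor is 1 posteriorly and
    ``compression`` at the anterior peak, varying as sin^2 of the
    section angle (C^1 everywhere, emulating the smooth tissue
    compression of lying prone).  The region stays star-shaped, so
    membership is exact.
    """

    z_bottom: float
    z_top: float
    spine_z: np.ndarray
    spine_x: np.ndarray
    follow: float
    rx: float
    ry: float
    compression: float

    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def center_x(self, z) -> np.ndarray:
        return self.follow * np.interp(z, self.spine_z, self.spine_x)

    def _radial_factor(self, theta) -> np.ndarray:
        s = np.maximum(np.sin(theta), 0.0)
        return 1.0 - (1.0 - self.compression) * s**2

    def surface_point(self, theta, z) -> np.ndarray:
        """Surface point(s) at section parameter theta and canonical
        height z, returned in world coordinates."""
        rho = self._radial_factor(theta)
        x = self.center_x(z) + self.rx * rho * np.cos(theta)
        y = self.ry * rho * np.sin(theta)
        pts = np.stack(
            np.broadcast_arrays(x, y, np.broadcast_to(z, np.shape(x))), axis=-1
        )
        return self.pose.apply(pts)

    def inside(self, x, y, z) -> np.ndarray:
        """Membership test for world points (exact: the canonical region
        is star-shaped per section)."""
        pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1).astype(float)
        pc = self.pose.inverse().apply(pts)
        qx = (pc[..., 0] - self.center_x(pc[..., 2])) / self.rx
        qy = pc[..., 1] / self.ry
        theta = np.arctan2(qy, qx)
        return np.hypot(qx, qy) <= self._radial_factor(theta)


@dataclass
class TorsoPhantom:
    surface: trimesh.Trimesh
    markers: Dict[str, np.ndarray]
    section: SectionModel
    slices: List[AxialSlice] = field(default_factory=list)


@dataclass
class PhantomStudy:
    """One complete synthetic patient."""

    seed: int
    spine_standing: SpinePhantom
    spine_prone: SpinePhantom
    torso_standing: TorsoPhantom          # ground-truth TP/X-ray-space torso
    torso_prone: TorsoPhantom
    slices: List[AxialSlice]
    tp_offset: RigidTransform             # misalignment applied to TP data
    tp_mesh: trimesh.Trimesh              # TP torso in its own (offset) frame
    tp_markers: Dict[str, np.ndarray]
    xray_markers: Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# spine


def _apex_t(curv: CurvatureParams) -> float:
    idx = LEVELS.index(curv.apex_level)
    return float(np.clip(idx / (len(LEVELS) - 1), 1 / 16, 15 / 16))


def _phase(t: np.ndarray, t_apex: float) -> np.ndarray:
    """Monotone phase reaching pi/2 at the apex and pi at the top end."""
    t = np.asarray(t, dtype=float)
    lower = 0.5 * np.pi * t / t_apex
    upper = 0.5 * np.pi * (1 + (t - t_apex) / (1 - t_apex))
    return np.where(t <= t_apex, lower, upper)


def _amplitude_for_cobb(target_deg: float, t_apex: float, length: float) -> float:
    """Amplitude of the half-sine lateral curve giving the requested
    Cobb-like angle (sum of the two maximal end tilts)."""
    if target_deg == 0:
        return 0.0
    sb = 0.5 * np.pi / (t_apex * length)
    st = 0.5 * np.pi / ((1 - t_apex) * length)

    def f(amp: float) -> float:
        return (
            np.degrees(np.arctan(sb * amp) + np.arctan(st * amp)) - target_deg
        )

    return float(brentq(f, 0.0, 500.0))


def _standing_frames(curv: CurvatureParams) -> List[VertebraFrame]:
    n = len(LEVELS)
    zs = _Z_FIRST + _Z_SPACING * np.arange(n)
    length = float(zs[-1] - zs[0])
    t = (zs - zs[0]) / length
    t_apex = _apex_t(curv)
    phase = _phase(t, t_apex)
    if curv.amplitude_mm is not None:
        amp = float(curv.amplitude_mm)
    else:
        amp = _amplitude_for_cobb(float(curv.target_cobb_deg), t_apex, length)
    xs = amp * np.sin(phase)
    centers = np.column_stack([xs, np.full(n, _SPINE_Y), zs])

    frames = []
    for v in range(n):
        lo, hi = max(v - 1, 0), min(v + 1, n - 1)
        sup = centers[hi] - centers[lo]
        sup = sup / np.linalg.norm(sup)
        ant = np.array([0.0, 1.0, 0.0]) - sup[1] * sup
        ant = ant / np.linalg.norm(ant)
        lat = np.cross(ant, sup)
        theta = np.radians(curv.axial_rotation_deg) * np.sin(phase[v])
        c, s = np.cos(theta), np.sin(theta)
        lat_r = c * lat + s * ant
        ant_r = -s * lat + c * ant
        axes = np.column_stack([lat_r, ant_r, sup])
        frames.append(VertebraFrame(LEVELS[v], centers[v], axes))
    return frames


def _landmarks_for(frames: List[VertebraFrame], template: dict) -> dict:
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for f in frames:
        out[f.label] = {
            name: f.center + f.axes @ np.asarray(p) for name, p in template.items()
        }
    return out


def _random_joint_perturbation(rng: np.random.Generator, pp: ProneParams) -> RigidTransform:
    ang = rng.uniform(
        -pp.max_joint_rotation_deg, pp.max_joint_rotation_deg, size=3
    )
    trans = rng.uniform(
        -pp.max_joint_translation_mm, pp.max_joint_translation_mm, size=3
    )
    return RigidTransform(
        Rotation.from_euler("xyz", ang, degrees=True).as_matrix(), trans
    )


def _frame_pose(f: VertebraFrame) -> RigidTransform:
    return RigidTransform(f.axes, f.center)


def generate_spine(
    curvature_params: CurvatureParams,
    posture: str = "standing",
    seed: int = 0,
    prone_params: Optional[ProneParams] = None,
) -> SpinePhantom:
    """Generate a 17-vertebra spine phantom in the requested posture.

    The prone posture is produced by perturbing the standing chain's
    intervertebral transforms (seeded) under a global scanner offset and
    recording the exact corrections as ground truth.
    """
    if posture not in ("standing", "prone"):
        raise ValueError(f"posture must be 'standing' or 'prone', got {posture!r}")
    frames = _standing_frames(curvature_params)
    gt = None
    scanner_pose = RigidTransform.identity()
    if posture == "prone":
        pp = prone_params or ProneParams()
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AB]))
        poses = [_frame_pose(f) for f in frames]
        intrinsics = [
            compose(invert(poses[k]), poses[k + 1]) for k in range(len(poses) - 1)
        ]
        perturbations = [_random_joint_perturbation(rng, pp) for _ in intrinsics]
        # Canonical prone chain: standing chain with perturbed joints,
        # then the whole patient posed rigidly in the scanner frame.
        scanner_pose = pp.global_offset()
        prone_poses = [compose(scanner_pose, poses[0])]
        for M, D in zip(intrinsics, perturbations):
            prone_poses.append(compose(prone_poses[-1], compose(M, D)))
        gt = ProneGroundTruth(
            standing_frames=frames,
            global_correction=invert(scanner_pose),
            joint_corrections=[invert(D) for D in perturbations],
            prone_params=pp,
        )
        frames = [
            VertebraFrame(lbl, X.translation, X.rotation)
            for lbl, X in zip(LEVELS, prone_poses)
        ]
    zs = np.array([f.center[2] for f in frames])
    if not np.all(np.diff(zs) > 0):
        raise ValueError("vertebra centers are not strictly monotonic in z")
    return SpinePhantom(
        frames=frames,
        xray_landmarks=_landmarks_for(frames, XRAY_TEMPLATE),
        mri_landmarks=_landmarks_for(frames, MRI_TEMPLATE),
        curvature_params=curvature_params,
        posture=posture,
        seed=seed,
        ground_truth=gt,
        scanner_pose=scanner_pose,
    )


def recover_standing_frames(prone: SpinePhantom) -> List[VertebraFrame]:
    """Rebuild the standing chain from a prone spine and its recorded
    ground-truth corrections (closure check)."""
    if prone.ground_truth is None:
        raise ValueError("spine carries no prone ground truth")
    gt = prone.ground_truth
    poses = [_frame_pose(f) for f in prone.frames]
    rebuilt = [compose(gt.global_correction, poses[0])]
    for k in range(len(poses) - 1):
        M_pert = compose(invert(poses[k]), poses[k + 1])
        M = compose(M_pert, gt.joint_corrections[k])
        rebuilt.append(compose(rebuilt[-1], M))
    return [
        VertebraFrame(lbl, X.translation, X.rotation)
        for lbl, X in zip(prone.labels, rebuilt)
    ]


def cobb_angle(frames: List[VertebraFrame]) -> float:
    """Cobb-like severity: range of coronal-plane endplate tilts (deg).

    The tilt of vertebra v is the angle of its superior axis in the
    frontal (x-z) plane; the Cobb-like angle is the difference between
    the most opposed tilts along the spine.
    """
    tilts = [np.degrees(np.arctan2(f.superior[0], f.superior[2])) for f in frames]
    return float(np.max(tilts) - np.min(tilts))


# ---------------------------------------------------------------------------
# torso


# Marker sites as (angle around the section, fractional trunk height).
# theta = 0 is patient-left (+x), pi/2 anterior, -pi/2 posterior.
_MARKER_SITES = {
    "vertebra_prominens": (-np.pi / 2, 0.985),
    "sternum": (np.pi / 2, 0.80),
    "spinous_process": (-np.pi / 2, 0.50),
    "pilonidal_dimple_left": (-np.pi / 2 + 0.35, 0.04),
    "pilonidal_dimple_right": (-np.pi / 2 - 0.35, 0.04),
    "iliac_spine_left": (np.pi / 2 - 0.7, 0.10),
    "iliac_spine_right": (np.pi / 2 + 0.7, 0.10),
    "scapula_left": (-np.pi / 2 + 0.6, 0.78),
    "scapula_right": (-np.pi / 2 - 0.6, 0.78),
    "sternum_inferior": (np.pi / 2, 0.45),
}


def generate_torso(
    spine: SpinePhantom, body_params: Optional[BodyParams] = None, seed: int = 0
) -> TorsoPhantom:
    """Watertight elliptical-cross-section torso around a spine phantom.

    The section center line follows the spine's lateral curve by
    ``follow_fraction``; markers are placed at the clinical external
    sites and snapped exactly onto mesh vertices.
    """
    body = body_params or BodyParams()
    # Model the torso in the patient-canonical frame (the spine chain
    # before the scanner pose), then pose it rigidly: the torso moves
    # with the patient, so only joint perturbations and compression are
    # non-rigid between postures.
    inv_pose = spine.scanner_pose.inverse()
    centers = np.array([inv_pose.apply(f.center) for f in spine.frames])
    z_bottom = float(centers[:, 2].min() - body.z_margin)
    z_top = float(centers[:, 2].max() + body.z_margin)
    section = SectionModel(
        z_bottom=z_bottom,
        z_top=z_top,
        spine_z=centers[:, 2],
        spine_x=centers[:, 0],
        follow=body.follow_fraction,
        rx=body.radius_x,
        ry=body.radius_y,
        compression=body.anterior_compression,
        pose=spine.scanner_pose,
    )

    nz, nt = body.n_z, body.n_theta
    zs = np.linspace(z_bottom, z_top, nz)
    thetas = np.linspace(0, 2 * np.pi, nt, endpoint=False)
    rings = np.array([section.surface_point(thetas, z) for z in zs])  # (nz, nt, 3)
    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(nz - 1):
        base, nxt = k * nt, (k + 1) * nt
        for j in range(nt):
            a, b = base + j, base + (j + 1) % nt
            c, d = nxt + (j + 1) % nt, nxt + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    c_bot = len(verts)
    c_top = len(verts) + 1
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    for j in range(nt):
        faces.append([c_bot, (j + 1) % nt, j])
        top_base = (nz - 1) * nt
        faces.append([c_top, top_base + j, top_base + (j + 1) % nt])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight:  # pragma: no cover - construction guarantees it
        raise RuntimeError("torso mesh construction produced a leak")

    tree = cKDTree(mesh.vertices)
    markers: Dict[str, np.ndarray] = {}
    for name, (theta, frac) in _MARKER_SITES.items():
        z = z_bottom + frac * (z_top - z_bottom)
        nominal = section.surface_point(theta, z)
        _, idx = tree.query(nominal)
        markers[name] = np.array(mesh.vertices[idx])
    return TorsoPhantom(surface=mesh, markers=markers, section=section)


# ---------------------------------------------------------------------------
# slices


def generate_axial_slices(
    spine_prone: SpinePhantom,
    torso_prone: TorsoPhantom,
    spacing_mm: float = 12.0,
    n_slices: Optional[int] = None,
    in_plane_mm: float = 1.0,
    thickness_mm: float = 2.0,
    margin_mm: float = 10.0,
) -> List[AxialSlice]:
    """Axial slice stack through the prone torso.

    Slices are perpendicular to world z (scanner axial acquisition),
    ``spacing_mm`` apart (default 12 mm, 1 x 1 mm in-plane), each with a
    binary torso mask and the filled-ellipse cross-section of its
    nearest vertebra.  The default count covers the trunk:
    ``floor(extent / spacing)``, ~33 slices for a ~400 mm trunk.
    """
    if spacing_mm <= thickness_mm:
        raise ValueError("slice spacing must exceed slice thickness")
    sec = torso_prone.section
    lo, hi = torso_prone.surface.bounds
    if n_slices is None:
        # count from the canonical trunk length (~400 mm -> 33 at 12 mm)
        n_slices = int((sec.z_top - sec.z_bottom) // spacing_mm)
    if n_slices <= 0:
        raise ValueError("n_slices must be positive")

    ox, oy = lo[0] - margin_mm, lo[1] - margin_mm
    nx = int(np.ceil((hi[0] - lo[0] + 2 * margin_mm) / in_plane_mm))
    ny = int(np.ceil((hi[1] - lo[1] + 2 * margin_mm) / in_plane_mm))
    xs = ox + in_plane_mm * np.arange(nx)
    ys = oy + in_plane_mm * np.arange(ny)
    XX, YY = np.meshgrid(xs, ys)

    frames_by_label = {f.label: f for f in spine_prone.frames}
    from .articulated import assign_slice_vertebra  # local import, no cycle

    # center the stack in the (posed) torso z range
    z_start = float(lo[2]) + 0.5 * (float(hi[2] - lo[2]) - (n_slices - 1) * spacing_mm)
    slices: List[AxialSlice] = []
    for k in range(n_slices):
        z = z_start + k * spacing_mm
        torso_mask = sec.inside(XX, YY, z)
        label = assign_slice_vertebra(z, spine_prone.frames)
        f = frames_by_label[label]
        # vertebral body as a posed elliptical cylinder (no posterior
        # elements): membership of the slice's world pixel centers
        rel = np.stack([XX - f.center[0], YY - f.center[1], np.full_like(XX, z - f.center[2])], axis=-1)
        local = rel @ f.axes  # components along (lateral, anterior, superior)
        vert_mask = (
            ((local[..., 0] / _VERT_RX) ** 2 + (local[..., 1] / _VERT_RY) ** 2 <= 1.0)
            & (np.abs(local[..., 2]) <= _VERT_HALF_HEIGHT)
        )
        vert_mask &= torso_mask
        pose = np.eye(4)
        pose[:3, 3] = (ox, oy, z)
        slices.append(
            AxialSlice(
                pose=pose,
                spacing=(in_plane_mm, in_plane_mm),
                torso_mask=torso_mask,
                vertebra_mask=vert_mask,
                vertebra_label=label,
                index=k,
            )
        )
    torso_prone.slices = slices
    return slices


# ---------------------------------------------------------------------------
# full study


def generate_study(
    seed: int = 0,
    curvature: Optional[CurvatureParams] = None,
    body: Optional[BodyParams] = None,
    prone: Optional[ProneParams] = None,
    slice_spacing_mm: float = 12.0,
    n_slices: Optional[int] = None,
    in_plane_mm: float = 1.0,
) -> PhantomStudy:
    """One synthetic patient: standing spine/torso (X-ray + TP truth),
    prone spine/torso with axial slices, and TP data carried in a
    seeded rigidly-offset device frame."""
    curvature = curvature or CurvatureParams()
    body = body or BodyParams()
    prone_params = prone or ProneParams()

    spine_standing = generate_spine(curvature, "standing", seed)
    spine_prone = generate_spine(curvature, "prone", seed, prone_params)
    torso_standing = generate_torso(spine_standing, body, seed)
    body_prone = replace(body, anterior_compression=prone_params.anterior_compression)
    torso_prone = generate_torso(spine_prone, body_prone, seed)
    slices = generate_axial_slices(
        spine_prone,
        torso_prone,
        spacing_mm=slice_spacing_mm,
        n_slices=n_slices,
        in_plane_mm=in_plane_mm,
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7F0]))
    tp_offset = RigidTransform(
        Rotation.from_euler(
            "xyz", rng.uniform(-3.0, 3.0, size=3), degrees=True
        ).as_matrix(),
        rng.uniform(-15.0, 15.0, size=3),
    )
    tp_mesh = torso_standing.surface.copy()
    tp_mesh.vertices = tp_offset.apply(np.asarray(tp_mesh.vertices))
    tp_markers = {n: tp_offset.apply(p) for n, p in torso_standing.markers.items()}

    return PhantomStudy(
        seed=seed,
        spine_standing=spine_standing,
        spine_prone=spine_prone,
        torso_standing=torso_standing,
        torso_prone=torso_prone,
        slices=slices,
        tp_offset=tp_offset,
        tp_mesh=tp_mesh,
        tp_markers=tp_markers,
        xray_markers=dict(torso_standing.markers),
    )
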