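"""Per-slice non-rigid soft-tissue refinement.

After the articulated (bone) transform has placed an axial MRI slice in
X-ray space, the soft tissue still has to be confined to the volume
delimited by the trunk surface: the slice's torso contour must land on
the surface-topography (TP) contour cut at the same plane.  The
refinement works per slice:

1. cut the TP mesh with the registered slice plane (:func:`planar_cut`);
2. extract correspondence points on both contours at fixed angular
   intervals (default 30 degrees, i.e. 12 pairs) along rays from the
   vertebra center, angle 0 pointing anteriorly
   (:func:`extract_ray_correspondences`);
3. fit a planar thin-plate spline ``T_edge`` on those pairs
   (:func:`fit_edge_tps`);
4. blend ``T_edge`` with the identity using the distance-ratio weight

       rho(p) = D_vertebra(p) / (D_surface(p) + D_vertebra(p)),

   where ``D_vertebra`` / ``D_surface`` are the distances of p to the
   vertebra border and to the torso border: the deformation is the
   identity inside the (rigid) vertebra, the full edge TPS on the skin,
   and graded in between — the farther from the vertebra, the more
   weight the non-rigid part gets.

The literal scalar-times-transform weighting is ill-typed for a rigid
motion, so it is realized as identity-blended displacement,
``p + rho * (T_edge(p) - p)``, which reproduces all three limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LinearRing, LineString, Point, Polygon
from skimage import measure

from .geometry import RigidTransform
from .imagedata import AxialSlice, DeformationField
from .tps import TPSModel, evaluate_tps, fit_tps

__all__ = [
    "NoCutError",
    "RayGeometryError",
    "PlanarContour",
    "CorrespondenceSet",
    "WeightedDeformation",
    "RegistrationResult",
    "planar_cut",
    "mask_contour",
    "extract_ray_correspondences",
    "fit_edge_tps",
    "distance_maps",
    "weighted_displace",
    "invert_displacement",
    "register_slice",
]


class NoCutError(ValueError):
    """The plane does not intersect the mesh."""


class RayGeometryError(ValueError):
    """A correspondence ray found no contour crossing."""

    def __init__(self, angle_deg: float, which: str):
        self.angle_deg = angle_deg
        super().__init__(
            f"ray at {angle_deg:g} degrees has no crossing with the {which} contour"
        )


@dataclass
class PlanarContour:
    """Closed planar polyline (mm): plane point + unit normal, ordered
    vertices without a repeated endpoint."""

    point: np.ndarray
    normal: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        self.points = np.asarray(self.points, dtype=float)
        off = (self.points - self.point) @ self.normal
        if np.max(np.abs(off)) > 1e-6:
            raise ValueError("contour points are not coplanar with the plane")


@dataclass
class CorrespondenceSet:
    """Paired contour points at fixed ray angles (in-plane mm).

    ``source[i]`` / ``target[i]`` are the outermost crossings of the ray
    at ``angles[i]`` (degrees from the anterior direction, CCW) with the
    MRI torso contour and the TP cut, both rays leaving the vertebra
    center.
    """

    angles: np.ndarray
    source: np.ndarray
    target: np.ndarray
    center: np.ndarray
    anterior: np.ndarray

    def __len__(self) -> int:
        return len(self.angles)


def planar_cut(
    mesh,
    plane_point,
    plane_normal,
    inside_point: Optional[np.ndarray] = None,
) -> PlanarContour:
    """Ordered closed intersection contour of a watertight mesh and a plane.

    When the section has several loops, the one enclosing
    ``inside_point`` (projected to the plane) is returned; without a
    hint, the largest loop wins.
    """
    plane_point = np.asarray(plane_point, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    path = mesh.section(plane_origin=plane_point, plane_normal=plane_normal)
    if path is None:
        raise NoCutError("plane does not intersect the mesh")
    # Orthonormal in-plane basis for loop selection.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(plane_normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(plane_normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(plane_normal, u)

    def to2d(pts3):
        rel = pts3 - plane_point
        return np.column_stack([rel @ u, rel @ v])

    loops = []
    for poly in path.discrete:
        pts = np.asarray(poly, dtype=float)
        if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
            pts = pts[:-1]
        if len(pts) >= 3:
            loops.append(pts)
    if not loops:
        raise NoCutError("plane section produced no closed loop")

    chosen = None
    if inside_point is not None and len(loops) > 1:
        q = Point(*to2d(np.asarray(inside_point, dtype=float)[None, :])[0])
        for pts in loops:
            if Polygon(to2d(pts)).contains(q):
                chosen = pts
                break
    if chosen is None:
        chosen = max(loops, key=lambda pts: Polygon(to2d(pts)).area)
    # Snap residual numerical off-plane error before the coplanarity check.
    chosen = chosen - np.outer((chosen - plane_point) @ plane_normal, plane_normal)
    return PlanarContour(plane_point, plane_normal, chosen)


def mask_contour(mask: np.ndarray, spacing: Tuple[float, float]) -> np.ndarray:
    """Longest closed iso-contour of a binary mask, in in-plane mm
    (u = column * spacing_u, v = row * spacing_v)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour (empty mask?)")
    rc = max(contours, key=len)
    if np.linalg.norm(rc[0] - rc[-1]) < 1e-9:
        rc = rc[:-1]
    return np.column_stack([rc[:, 1] * spacing[0], rc[:, 0] * spacing[1]])


def _ring_crossing(
    ring: LinearRing, center: np.ndarray, direction: np.ndarray, reach: float
) -> Optional[np.ndarray]:
    """Outermost crossing of the ray ``center + t * direction`` (t > 0)."""
    ray = LineString([center, center + reach * direction])
    inter = ray.intersection(ring)
    if inter.is_empty:
        return None
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.geom_type == "Point":
            pts.append([geom.x, geom.y])
        else:  # collinear overlap: keep its endpoints
            pts.extend(np.asarray(geom.coords))
    pts = np.asarray(pts, dtype=float)
    t = (pts - center) @ direction
    pts = pts[t > 1e-9]
    if len(pts) == 0:
        return None
    return pts[np.argmax((pts - center) @ direction)]


def extract_ray_correspondences(
    mri_torso_mask: np.ndarray,
    tp_contour: np.ndarray,
    vertebra_center: np.ndarray,
    anterior_dir: np.ndarray,
    angular_step: float = 30.0,
    spacing: Tuple[float, float] = (1.0, 1.0),
) -> CorrespondenceSet:
    """Contour correspondences at fixed angular intervals.

    For each angle (0, step, ..., 360-step; angle 0 along the anterior
    direction, positive CCW) a ray from the vertebra center is
    intersected with the MRI torso contour (source) and the TP cut
    contour (target); the outermost crossing is kept on each.

    All geometry is in the slice's in-plane mm coordinates.
    """
    if angular_step <= 0 or 360.0 % angular_step != 0:
        raise ValueError("angular_step must divide 360")
    center = np.asarray(vertebra_center, dtype=float).reshape(2)
    ant = np.asarray(anterior_dir, dtype=float).reshape(2)
    ant = ant / np.linalg.norm(ant)

    src_pts = mask_contour(mri_torso_mask, spacing)
    tgt_pts = np.asarray(tp_contour, dtype=float)
    src_ring, tgt_ring = LinearRing(src_pts), LinearRing(tgt_pts)
    c = Point(*center)
    if not Polygon(src_pts).contains(c):
        raise ValueError("vertebra center is not strictly inside the MRI contour")
    if not Polygon(tgt_pts).contains(c):
        raise ValueError("vertebra center is not strictly inside the TP contour")
    reach = 10.0 * max(
        np.abs(src_pts - center).max(), np.abs(tgt_pts - center).max()
    )

    k = int(round(360.0 / angular_step))
    angles = angular_step * np.arange(k)
    source, target = [], []
    for a in angles:
        th = np.radians(a)
        cth, sth = np.cos(th), np.sin(th)
        d = np.array([cth * ant[0] - sth * ant[1], sth * ant[0] + cth * ant[1]])
        s = _ring_crossing(src_ring, center, d, reach)
        if s is None:
            raise RayGeometryError(a, "MRI torso")
        t = _ring_crossing(tgt_ring, center, d, reach)
        if t is None:
            raise RayGeometryError(a, "TP cut")
        source.append(s)
        target.append(t)
    return CorrespondenceSet(
        angles=angles,
        source=np.asarray(source),
        target=np.asarray(target),
        center=center,
        anterior=ant,
    )


def fit_edge_tps(correspondences: CorrespondenceSet, lam: float = 1e-3) -> TPSModel:
    """Planar TPS taking the MRI contour samples onto the TP cut samples.

    This is the unweighted edge transform; lam > 0 makes it an
    approximating (smoothed) rather than interpolating fit.
    """
    return fit_tps(correspondences.source, correspondences.target, lam=lam)


_CROSS = ndimage.generate_binary_structure(2, 1)


def distance_maps(
    torso_mask: np.ndarray,
    vertebra_mask: np.ndarray,
    pixel_size: Tuple[float, float] = (1.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel Euclidean distances (mm) to the vertebra border and to
    the torso border.

    A border pixel is a mask pixel with a 4-neighbour outside the mask;
    the maps are exactly zero on the respective borders.
    """
    torso_mask = np.asarray(torso_mask, dtype=bool)
    vertebra_mask = np.asarray(vertebra_mask, dtype=bool)
    if not torso_mask.any() or not vertebra_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(vertebra_mask & ~torso_mask):
        raise ValueError("vertebra mask must be contained in the torso mask")
    sampling = (pixel_size[1], pixel_size[0])  # (row, col) mm

    def border(mask: np.ndarray) -> np.ndarray:
        return mask & ~ndimage.binary_erosion(mask, structure=_CROSS)

    d_vertebra = ndimage.distance_transform_edt(
        ~border(vertebra_mask), sampling=sampling
    )
    d_surface = ndimage.distance_transform_edt(~border(torso_mask), sampling=sampling)
    return d_vertebra, d_surface


@dataclass
class WeightedDeformation:
    """Distance-weighted per-slice deformation (the rigidity-constrained
    soft-tissue transform).

    Identity at every pixel inside ``vertebra_mask``; elsewhere the edge
    TPS displacement scaled by ``rho = d_vertebra / (d_surface +
    d_vertebra)``, which is 0 on the vertebra border and 1 on the torso
    border.
    """

    edge_model: TPSModel
    d_vertebra: np.ndarray
    d_surface: np.ndarray
    vertebra_mask: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)

    def rho(self) -> np.ndarray:
        tot = self.d_vertebra + self.d_surface
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot > 0, self.d_vertebra / np.where(tot > 0, tot, 1.0), 0.0)
        r[self.vertebra_mask] = 0.0
        return r

    def _sample(self, grid: np.ndarray, points: np.ndarray, order: int) -> np.ndarray:
        pts = np.atleast_2d(points)
        rows = pts[:, 1] / self.spacing[1]
        cols = pts[:, 0] / self.spacing[0]
        return ndimage.map_coordinates(
            grid.astype(float), [rows, cols], order=order, mode="nearest"
        )

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Apply the weighted transform to in-plane points (…, 2) mm."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        inside = self._sample(self.vertebra_mask, p, order=0) > 0.5
        r = self._sample(self.rho(), p, order=1)
        moved = evaluate_tps(self.edge_model, p)
        out = p + r[:, None] * (moved - p)
        out[inside] = p[inside]
        return out[0] if single else out

    def displacement_field(self) -> DeformationField:
        """Dense forward displacement (mm) on the slice pixel grid."""
        ny, nx = self.vertebra_mask.shape
        u = np.arange(nx) * self.spacing[0]
        v = np.arange(ny) * self.spacing[1]
        uu, vv = np.meshgrid(u, v)
        grid = np.column_stack([uu.ravel(), vv.ravel()])
        moved = evaluate_tps(self.edge_model, grid)
        disp = (moved - grid).reshape(ny, nx, 2)
        disp *= self.rho()[..., None]
        disp[self.vertebra_mask] = 0.0
        return DeformationField(disp, self.spacing)


def weighted_displace(p: np.ndarray, deformation: WeightedDeformation) -> np.ndarray:
    """Transform one point (or stack of points) by the weighted
    deformation — identity inside the vertebra, blended elsewhere."""
    return deformation.displace(p)


def invert_displacement(
    disp: np.ndarray, spacing: Tuple[float, float], n_iter: int = 20
) -> np.ndarray:
    """Approximate inverse of a forward displacement field by fixed-point
    iteration ``v(y) = -u(y + v(y))`` (adequate for the smooth, moderate
    fields produced here)."""
    ny, nx, _ = disp.shape
    u = np.arange(nx) * spacing[0]
    v = np.arange(ny) * spacing[1]
    uu, vv = np.meshgrid(u, v)
    inv = -disp.copy()
    for _ in range(n_iter):
        rows = (vv + inv[..., 1]) / spacing[1]
        cols = (uu + inv[..., 0]) / spacing[0]
        sampled = np.stack(
            [
                ndimage.map_coordinates(disp[..., k], [rows, cols], order=1, mode="nearest")
                for k in range(2)
            ],
            axis=-1,
        )
        inv = -sampled
    return inv


def _resample_mask_inverse(
    mask: np.ndarray, inv_disp: np.ndarray, spacing: Tuple[float, float]
) -> np.ndarray:
    """Nearest-neighbour pull-back of a mask through an inverse field."""
    ny, nx = mask.shape
    u = np.arange(nx) * spacing[0]
    v = np.arange(ny) * spacing[1]
    uu, vv = np.meshgrid(u, v)
    rows = (vv + inv_disp[..., 1]) / spacing[1]
    cols = (uu + inv_disp[..., 0]) / spacing[0]
    out = ndimage.map_coordinates(
        mask.astype(np.uint8), [rows, cols], order=0, mode="constant", cval=0
    )
    return out.astype(bool)


@dataclass
class RegistrationResult:
    """Everything produced by one per-slice registration."""

    slice: AxialSlice                 # bone-transformed slice, masks resampled
    deformation: WeightedDeformation
    field: DeformationField
    tp_cut: PlanarContour
    tp_cut_2d: np.ndarray             # TP cut in slice-plane coords
    source_contour_2d: np.ndarray     # MRI torso contour before soft warp
    warped_contour_2d: np.ndarray     # MRI torso contour after soft warp
    correspondences: CorrespondenceSet
    bone_transform: RigidTransform


def register_slice(
    slice_: AxialSlice,
    bone_transform: RigidTransform,
    tp_mesh,
    lam: float = 1e-3,
    angular_step: float = 30.0,
    anterior_dir_world: Optional[np.ndarray] = None,
    resample: bool = True,
) -> RegistrationResult:
    """Full per-slice registration: articulated bone transform followed
    by the weighted soft-tissue transform.

    Parameters
    ----------
    slice_ : AxialSlice
        Prone MRI slice with torso and vertebra masks.
    bone_transform : RigidTransform
        Per-vertebra articulated transform into X-ray space.
    tp_mesh : trimesh.Trimesh
        Surface topography mesh already registered into X-ray space.
    lam : float
        Smoothing of the edge TPS (0 interpolates the 360/step pairs).
    anterior_dir_world : (3,) array, optional
        World anterior direction for angle 0 (the assigned vertebra's
        anterior axis); defaults to the slice's row direction.
    resample : bool
        Pull the slice masks through the (iteratively inverted)
        deformation so the returned slice shows the registered anatomy.
    """
    moved = slice_.transformed(bone_transform)

    ij = np.argwhere(moved.vertebra_mask)
    if len(ij) == 0:
        raise ValueError("slice has an empty vertebra mask")
    centroid_ij = ij.mean(axis=0)
    center_world = moved.pixel_to_world(centroid_ij)
    center2 = moved.world_to_plane(center_world)

    cut = planar_cut(tp_mesh, moved.origin, moved.normal, inside_point=center_world)
    tp2 = moved.world_to_plane(cut.points)

    if anterior_dir_world is None:
        ant2 = np.array([0.0, 1.0])
    else:
        a = np.asarray(anterior_dir_world, dtype=float)
        ant2 = np.array([a @ moved.u_dir, a @ moved.v_dir])
        ant2 = ant2 / np.linalg.norm(ant2)

    corr = extract_ray_correspondences(
        moved.torso_mask, tp2, center2, ant2, angular_step, moved.spacing
    )
    edge_model = fit_edge_tps(corr, lam=lam)
    d_vertebra, d_surface = distance_maps(
        moved.torso_mask, moved.vertebra_mask, moved.spacing
    )
    deformation = WeightedDeformation(
        edge_model, d_vertebra, d_surface, moved.vertebra_mask, moved.spacing
    )
    field = deformation.displacement_field()

    source_contour = mask_contour(moved.torso_mask, moved.spacing)
    # Contour points sit on the torso border (D_surface = 0, rho = 1):
    # the full edge transform applies there.
    warped_contour = evaluate_tps(edge_model, source_contour)

    out_slice = moved
    if resample:
        inv = invert_displacement(field.displacements, moved.spacing)
        out_slice = AxialSlice(
            moved.pose,
            moved.spacing,
            _resample_mask_inverse(moved.torso_mask, inv, moved.spacing),
            _resample_mask_inverse(moved.vertebra_mask, inv, moved.spacing),
            vertebra_label=moved.vertebra_label,
            index=moved.index,
        )
    return RegistrationResult(
        slice=out_slice,
        deformation=deformation,
        field=field,
        tp_cut=cut,
        tp_cut_2d=tp2,
        source_contour_2d=source_contour,
        warped_contour_2d=warped_contour,
        correspondences=corr,
        bone_transform=bone_transform,
    )
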