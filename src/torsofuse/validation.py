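"""Registration quality metrics: 2D/3D Dice overlap, Jacobian
determinant maps, and method comparison.

The Dice similarity coefficient is the standard overlap statistic

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|)  in [0, 1],

1 meaning perfect overlap.  Per-slice 2D Dice compares the registered
MRI torso mask with the interior of the surface-topography cut at the
same plane; 3D Dice compares voxelized volumes (default 1 x 1 x 3 mm)
of the full torso meshes, which also probes the interpolation between
the widely spaced slices.

The local quality of a deformation is summarized by the determinant of
the Jacobian of the mapping x -> x + u(x), with partial derivatives
approximated by first-order Gaussian derivatives (sigma = 1 pixel).
det = 1 means local volume preservation (required inside vertebrae),
det > 1 local expansion of the forward map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import shapely
import trimesh
from scipy import ndimage, stats
from shapely.geometry import Polygon

from .imagedata import DeformationField, VoxelVolume
from .soft_tissue import PlanarContour

__all__ = [
    "UndefinedDiceError",
    "DiceReport",
    "MethodComparison",
    "dice_2d",
    "polygon_dice",
    "build_torso_mesh",
    "voxelize",
    "dice_3d",
    "jacobian_determinant",
    "compare_methods",
    "save_jacobian_overlay",
]


class UndefinedDiceError(ValueError):
    """Dice of two empty masks is undefined (not silently 0)."""


def dice_2d(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks on the same grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedDiceError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def rasterize_polygons(
    polys: Sequence[np.ndarray], pixel_mm: float = 1.0, margin_mm: float = 2.0
) -> List[np.ndarray]:
    """Rasterize closed 2D polygons onto one shared pixel grid
    (pixel-center convention); returns one mask per polygon."""
    allpts = np.vstack(polys)
    lo = allpts.min(axis=0) - margin_mm
    hi = allpts.max(axis=0) + margin_mm
    nx = int(np.ceil((hi[0] - lo[0]) / pixel_mm))
    ny = int(np.ceil((hi[1] - lo[1]) / pixel_mm))
    xs = lo[0] + pixel_mm * (np.arange(nx) + 0.5)
    ys = lo[1] + pixel_mm * (np.arange(ny) + 0.5)
    XX, YY = np.meshgrid(xs, ys)
    masks = []
    for poly in polys:
        g = Polygon(np.asarray(poly))
        if not g.is_valid:
            g = g.buffer(0)
        masks.append(shapely.contains_xy(g, XX, YY))
    return masks


def polygon_dice(poly_a: np.ndarray, poly_b: np.ndarray, pixel_mm: float = 1.0) -> float:
    """2D Dice of two closed polygons rasterized on a common grid."""
    ma, mb = rasterize_polygons([poly_a, poly_b], pixel_mm=pixel_mm)
    return dice_2d(ma, mb)


@dataclass
class DiceReport:
    """Per-slice Dice values of one registration method."""

    method: str
    per_slice: List[Tuple[int, float]]

    @property
    def indices(self) -> List[int]:
        return [i for i, _ in self.per_slice]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.per_slice], dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        """Sample variance (ddof=1) of the per-slice values."""
        v = self.values
        return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


# ---------------------------------------------------------------------------
# 3D machinery


def _resample_ring(points: np.ndarray, samples: int) -> np.ndarray:
    """Resample a closed ring at uniform polar angles around its
    centroid (rings are star-shaped from the centroid for torso
    contours), CCW, starting at the anterior (+y) direction.  This
    aligns vertices across rings so the stack can be stitched without
    twist."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    order = np.argsort(ang)
    ang, pts = ang[order], pts[order]
    # close the angular interval for periodic interpolation
    ang_ext = np.concatenate([ang, ang[:1] + 2 * np.pi])
    pts_ext = np.vstack([pts, pts[:1]])
    # angle 0 at anterior (+y): ray angle pi/2 in atan2 terms
    targets = np.pi / 2 + 2 * np.pi * np.arange(samples) / samples
    targets = (targets + np.pi) % (2 * np.pi) - np.pi
    out = np.empty((samples, pts.shape[1]))
    for k, t in enumerate(targets):
        tt = t if t >= ang_ext[0] else t + 2 * np.pi
        for d in range(pts.shape[1]):
            out[k, d] = np.interp(tt, ang_ext, pts_ext[:, d])
    return out


def build_torso_mesh(
    contours: Sequence[Union[PlanarContour, np.ndarray]],
    samples: int = 72,
    subdivide: bool = True,
) -> trimesh.Trimesh:
    """Watertight torso surface over a stack of registered slice contours.

    Each closed contour is resampled to ``samples`` ring-aligned points;
    consecutive rings are stitched with triangles, the ends are capped
    by centroid fans, and one round of 1-to-4 linear (midpoint)
    subdivision refines the result.
    """
    rings = []
    for cnt in contours:
        pts = cnt.points if isinstance(cnt, PlanarContour) else np.asarray(cnt)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError("each contour must be a closed (n>=3, 3) polyline")
        rings.append(_resample_ring(pts, samples))
    if len(rings) < 2:
        raise ValueError("need at least 2 slice contours")
    rings.sort(key=lambda r: float(r[:, 2].mean()))

    verts = np.vstack(rings)
    nt = samples
    faces = []
    for k in range(len(rings) - 1):
        base, nxt = k * nt, (k + 1) * nt
        for j in range(nt):
            a, b = base + j, base + (j + 1) % nt
            c, d = nxt + (j + 1) % nt, nxt + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    c_bot, c_top = len(verts), len(verts) + 1
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    top_base = (len(rings) - 1) * nt
    for j in range(nt):
        faces.append([c_bot, (j + 1) % nt, j])
        faces.append([c_top, top_base + j, top_base + (j + 1) % nt])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise ValueError("stitched contour stack is not watertight")
    if subdivide:
        v, f = trimesh.remesh.subdivide(mesh.vertices, mesh.faces)
        mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    return mesh


def voxelize(mesh: trimesh.Trimesh, spacing: Tuple[float, float, float] = (1.0, 1.0, 3.0)) -> VoxelVolume:
    """Binary occupancy of a watertight mesh on an anisotropic grid.

    Voxel centers inside the surface are 1; the origin is the mesh
    bounding-box minimum; slices are parallel to the x-y plane.
    """
    if not mesh.is_watertight:
        broken = trimesh.repair.broken_faces(mesh)
        where = (
            mesh.triangles_center[broken[0]] if len(broken) else mesh.bounds.mean(axis=0)
        )
        raise ValueError(f"mesh is not watertight (leak near {np.round(where, 1)})")
    lo, hi = mesh.bounds
    n = np.maximum(np.ceil((hi - lo) / np.asarray(spacing)).astype(int), 1)
    occ = np.zeros(tuple(n), dtype=np.uint8)
    xs = lo[0] + spacing[0] * (np.arange(n[0]) + 0.5)
    ys = lo[1] + spacing[1] * (np.arange(n[1]) + 0.5)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    for iz in range(n[2]):
        z = lo[2] + spacing[2] * (iz + 0.5)
        path = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if path is None:
            continue
        polys = []
        for loop in path.discrete:
            pts = np.asarray(loop)[:, :2]
            if len(pts) >= 3:
                p = Polygon(pts)
                if not p.is_valid:
                    p = p.buffer(0)
                polys.append(p)
        if not polys:
            continue
        region = shapely.unary_union(polys)
        occ[:, :, iz] = shapely.contains_xy(region, XX, YY)
    return VoxelVolume(occ, tuple(spacing), lo)


def dice_3d(vol_a: VoxelVolume, vol_b: VoxelVolume) -> float:
    """Dice overlap of two occupancy volumes.

    The grids must share spacing; they are placed on a common grid
    first, with the relative origin snapped to the nearest voxel.
    """
    if not np.allclose(vol_a.spacing, vol_b.spacing):
        raise ValueError(
            f"voxel spacings differ: {vol_a.spacing} vs {vol_b.spacing}"
        )
    sp = np.asarray(vol_a.spacing, dtype=float)
    off_b = np.round((vol_b.origin - vol_a.origin) / sp).astype(int)
    lo = np.minimum(0, off_b)
    hi = np.maximum(vol_a.occupancy.shape, off_b + np.asarray(vol_b.occupancy.shape))
    shape = tuple(hi - lo)
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    sa = tuple(slice(-lo[k], -lo[k] + vol_a.occupancy.shape[k]) for k in range(3))
    sb = tuple(
        slice(off_b[k] - lo[k], off_b[k] - lo[k] + vol_b.occupancy.shape[k])
        for k in range(3)
    )
    a[sa] = vol_a.occupancy.astype(bool)
    b[sb] = vol_b.occupancy.astype(bool)
    return dice_2d(a, b)


def jacobian_determinant(
    field: Union[DeformationField, np.ndarray],
    spacing: Sequence[float] = None,
    sigma: float = 1.0,
    truncate: float = 3.0,
) -> np.ndarray:
    """Determinant of the Jacobian of the mapping x -> x + u(x).

    Partial derivatives of the displacement are approximated with
    first-order Gaussian derivatives (sigma in pixels, support
    truncated at ``truncate * sigma``), so the determinant is exactly 1
    wherever the mapping is locally the identity over the kernel
    support.  Works for 2-vector fields on 2D grids and 3-vector fields
    on 3D grids.
    """
    if isinstance(field, DeformationField):
        disp = field.displacements
        spacing = field.spacing if spacing is None else spacing
    else:
        disp = np.asarray(field, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = disp.shape[-1]
    if disp.ndim != d + 1:
        raise ValueError("displacement grid must be (…grid…, d) with matching ndim")
    if spacing is None:
        spacing = (1.0,) * d
    # component k varies along grid axis (d - 1 - k): u (x) along the
    # last axis, v (y) along the one before, etc.
    J = np.zeros(disp.shape[:-1] + (d, d))
    for i in range(d):          # displacement component
        for j in range(d):      # derivative direction
            ax = d - 1 - j
            der = ndimage.gaussian_filter1d(
                disp[..., i], sigma=sigma, axis=ax, order=1, truncate=truncate
            ) / float(spacing[j])
            J[..., i, j] = der
        J[..., i, i] += 1.0
    return np.linalg.det(J)


@dataclass
class MethodComparison:
    """Summary of a Dice comparison across registration methods."""

    summary: pd.DataFrame
    p_values: Dict[Tuple[str, str], float]
    ordering: Dict[str, bool]


def compare_methods(
    reports: Mapping[str, DiceReport], test: str = "wilcoxon"
) -> MethodComparison:
    """Mean +/- SD per method plus pairwise paired-test p-values.

    ``test`` is ``"wilcoxon"`` (signed-rank, default) or ``"ttest"``
    (paired t).  All reports must cover the same slice indices.  A pair
    of identical reports yields p = 1 (no difference).
    """
    if test not in ("wilcoxon", "ttest"):
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    methods = list(reports)
    idx0 = reports[methods[0]].indices
    for m in methods[1:]:
        if reports[m].indices != idx0:
            raise ValueError(f"slice index sets differ between methods ({m})")
    summary = pd.DataFrame(
        {
            "mean": [reports[m].mean for m in methods],
            "sd": [reports[m].sd for m in methods],
            "n_slices": [len(reports[m].per_slice) for m in methods],
        },
        index=pd.Index(methods, name="method"),
    )
    p_values: Dict[Tuple[str, str], float] = {}
    ordering: Dict[str, bool] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            va, vb = reports[a].values, reports[b].values
            diff = va - vb
            if np.allclose(diff, 0.0):
                p = 1.0
            elif test == "wilcoxon":
                p = float(stats.wilcoxon(va, vb).pvalue)
            else:
                p = float(stats.ttest_rel(va, vb).pvalue)
            p_values[(a, b)] = p
            ordering[f"{a}>{b}"] = bool(np.mean(va) > np.mean(vb))
            ordering[f"{b}>{a}"] = bool(np.mean(vb) > np.mean(va))
    return MethodComparison(summary=summary, p_values=p_values, ordering=ordering)


def save_jacobian_overlay(det: np.ndarray, path: str, title: str = "") -> None:
    """Save a |det - 1| map with a spectral colormap (blue near 1)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.abs(det - 1.0), cmap="Spectral_r", origin="lower")
    fig.colorbar(im, ax=ax, label="|det J - 1|")
    if title:
        ax.set_title(title)
    ax.set_xlabel("u (px)")
    ax.set_ylabel("v (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
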