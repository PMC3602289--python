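"""Thin-plate-spline fitting and evaluation.

The mapping has the Bookstein form: an affine part plus a weighted sum
of radial kernel terms centred on the control points,

    f(p) = a_1 + a_2 x + a_3 y + a_4 z + sum_i w_i U(|p - p_i|),

with one coefficient set per output coordinate and the 3D kernel
U(r) = |r|.  The coefficients solve the block-linear system

    [K + lam*I  P] [w]   [V]
    [P^T        0] [a] = [0],

where K holds the pairwise kernel values between control points, P is
the homogeneous control-point matrix [1 | p_i], V the targets and lam a
smoothing (approximation) parameter; lam = 0 interpolates the targets
exactly.  The side condition P^T w = 0 removes the affine ambiguity of
the kernel part.

Planar fits (per-slice soft tissue) use the same |r| kernel with points
expressed in 2D in-plane coordinates and a 2D affine part, which keeps
the system well-posed for coplanar control points.  The dimension is
inferred from the input point arrays (columns = 2 or 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "SingularTPSError",
    "MarkerMismatchError",
    "TPSModel",
    "fit_tps",
    "evaluate_tps",
    "register_tp_to_xray",
]

_COND_WARN = 1e10


class SingularTPSError(ValueError):
    """Control points cannot support the requested fit (duplicates, or
    affinely degenerate: collinear in 2D / coplanar in 3D)."""

    def __init__(self, message: str, cond: float = float("inf")):
        super().__init__(f"{message} (condition number {cond:.3e})")
        self.cond = cond


class MarkerMismatchError(ValueError):
    """Marker name sets of the two modalities do not match 1:1."""

    def __init__(self, missing_in_target, missing_in_source):
        self.missing_in_target = sorted(missing_in_target)
        self.missing_in_source = sorted(missing_in_source)
        super().__init__(
            "marker names do not match: "
            f"missing in target {self.missing_in_target}, "
            f"missing in source {self.missing_in_source}"
        )


@dataclass
class TPSModel:
    """Fitted thin-plate spline with kernel U(r) = |r|.

    Attributes
    ----------
    control_points : (n, d) array
        Source points (mm), d in {2, 3}.
    weights : (n, d) array
        Kernel weights, one column per output coordinate.
    affine : (d + 1, d) array
        Affine coefficients; row 0 is the constant term, rows 1..d the
        linear part (column j = output coordinate j).
    regularization : float
        The lam used at fit time (0 = interpolating).
    """

    control_points: np.ndarray
    weights: np.ndarray
    affine: np.ndarray
    regularization: float = 0.0
    kernel: str = "abs_r"

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def dim(self) -> int:
        return self.control_points.shape[1]

    def side_condition_residual(self) -> float:
        """Max |P^T w| over all rows/output coordinates (should be ~0)."""
        n = self.control_points.shape[0]
        P = np.hstack([np.ones((n, 1)), self.control_points])
        return float(np.max(np.abs(P.T @ self.weights)))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return evaluate_tps(self, points)


def fit_tps(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSModel:
    """Fit a TPS mapping ``source`` -> ``target``.

    Parameters
    ----------
    source, target : (n, d) arrays, d in {2, 3}
        Paired control points (mm).  Need n >= d + 1 points that are not
        affinely degenerate (not collinear for d=2, not coplanar for d=3).
    lam : float
        Smoothing parameter added to the kernel diagonal; 0 interpolates.

    Raises
    ------
    SingularTPSError
        For duplicate or affinely degenerate source points.
    """
    source = np.atleast_2d(np.asarray(source, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if source.shape != target.shape:
        raise ValueError(
            f"source {source.shape} and target {target.shape} must match"
        )
    n, d = source.shape
    if d not in (2, 3):
        raise ValueError(f"points must be 2D or 3D, got d={d}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if n < d + 1:
        raise SingularTPSError(f"need at least {d + 1} control points, got {n}")
    if n > 1 and float(np.min(pdist(source))) < 1e-9:
        raise SingularTPSError("duplicate source control points")

    # Affine degeneracy: rank of the centred source cloud must be d.
    sv = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
    if sv[d - 1] < 1e-8 * max(sv[0], 1.0):
        cond = float("inf") if sv[d - 1] == 0 else float(sv[0] / sv[d - 1])
        kind = "collinear" if d == 2 else "coplanar"
        raise SingularTPSError(f"source control points are {kind}", cond=cond)

    K = cdist(source, source)
    P = np.hstack([np.ones((n, 1)), source])
    A = np.zeros((n + d + 1, n + d + 1))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + d + 1, d))
    rhs[:n] = target

    cond = float(np.linalg.cond(A))
    if cond > _COND_WARN:
        warnings.warn(
            f"ill-conditioned TPS system (condition number {cond:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularTPSError(str(exc), cond=cond) from exc
    return TPSModel(source, sol[:n], sol[n:], regularization=lam)


def evaluate_tps(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the spline at ``points`` ((m, d) or a single (d,) point)."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != model.dim:
        raise ValueError(f"points are {p.shape[1]}D but model is {model.dim}D")
    out = model.affine[0] + p @ model.affine[1:]
    out = out + cdist(p, model.control_points) @ model.weights
    return out[0] if single else out


def register_tp_to_xray(
    tp_markers: Mapping[str, Sequence[float]],
    xray_markers: Mapping[str, Sequence[float]],
    tp_mesh,
    lam: float = 0.0,
):
    """Register surface-topography data into X-ray space.

    Fits the TPS on the external markers visible in both modalities
    (adhesive markers on the optical scan; radio-opaque markers affixed
    on top of them for the radiographs) and applies it to every vertex
    of the TP torso mesh.  Topology is unchanged.

    Returns
    -------
    (TPSModel, trimesh.Trimesh)
        The fitted marker transform and the transformed mesh copy.
    """
    tp_names = set(tp_markers)
    xr_names = set(xray_markers)
    if tp_names != xr_names:
        raise MarkerMismatchError(tp_names - xr_names, xr_names - tp_names)
    names = sorted(tp_names)
    if len(names) < 4:
        raise ValueError(f"need at least 4 shared markers, got {len(names)}")
    source = np.array([tp_markers[n] for n in names], dtype=float)
    target = np.array([xray_markers[n] for n in names], dtype=float)
    model = fit_tps(source, target, lam=lam)
    mesh_out = tp_mesh.copy()
    mesh_out.vertices = evaluate_tps(model, np.asarray(tp_mesh.vertices))
    return model, mesh_out
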