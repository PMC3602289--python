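"""End-to-end pipeline: phantom -> TP/X-ray registration -> articulated
bone registration -> soft-tissue refinement -> validation.

The driver reproduces the full study design on a synthetic patient:

1. generate the phantom (standing spine + torso = X-ray/TP truth,
   prone spine + torso + axial slice stack, TP data in an offset device
   frame);
2. register the TP mesh into X-ray space with the marker thin-plate
   spline;
3. estimate per-vertebra frames from the landmark sets of each
   modality, build the two articulated models and the per-vertebra
   bone transforms;
4. register every axial slice with each selected method — ``rigid``
   (single least-squares rigid fit over all vertebral frames),
   ``articulated`` (per-vertebra bone transform only) and ``proposed``
   (bone transform + weighted soft-tissue TPS);
5. score per-slice 2D Dice against the TP cut, optionally 3D Dice of
   the reconstructed torso volumes, Jacobian-determinant statistics,
   and the paired-test method comparison.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml
from scipy import ndimage

from . import __version__, io
from .articulated import (
    assign_slice_vertebra,
    build_articulated,
    cross_modality_transforms,
    fit_global_rigid,
)
from .geometry import (
    RigidTransform,
    frame_from_mri_landmarks,
    frame_from_xray_landmarks,
)
from .phantom import (
    BodyParams,
    CurvatureParams,
    PhantomStudy,
    ProneParams,
    generate_study,
)
from .soft_tissue import RegistrationResult, mask_contour, planar_cut, register_slice
from .tps import register_tp_to_xray
from .validation import (
    DiceReport,
    MethodComparison,
    build_torso_mesh,
    compare_methods,
    dice_3d,
    jacobian_determinant,
    polygon_dice,
    voxelize,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline"]

METHODS = ("rigid", "articulated", "proposed")


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serializable)."""

    seed: int = 0
    methods: tuple = METHODS
    curvature: CurvatureParams = field(default_factory=CurvatureParams)
    body: BodyParams = field(default_factory=BodyParams)
    prone: ProneParams = field(default_factory=ProneParams)
    slice_spacing_mm: float = 12.0
    n_slices: Optional[int] = None
    in_plane_mm: float = 1.0
    edge_lambda: float = 1e-3
    angular_step_deg: float = 30.0
    voxel_spacing: tuple = (1.0, 1.0, 3.0)
    do_3d: bool = True
    statistical_test: str = "wilcoxon"

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")
        if self.edge_lambda < 0 or self.angular_step_deg <= 0:
            raise ValueError("edge_lambda must be >= 0 and angular_step_deg > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("curvature", CurvatureParams),
            ("body", BodyParams),
            ("prone", ProneParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "voxel_spacing" in d:
            d["voxel_spacing"] = tuple(d["voxel_spacing"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["voxel_spacing"] = list(self.voxel_spacing)
        return d


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    seed: int
    timings_s: Dict[str, float]
    checksums: Dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    study: PhantomStudy
    config: PipelineConfig
    reports: Dict[str, DiceReport]
    comparison: Optional[MethodComparison]
    dice3d: Optional[float]
    jacobian_stats: List[dict]
    registrations: List[RegistrationResult]
    bone_transforms: Dict[str, RigidTransform]
    global_rigid: RigidTransform
    tp_model: object
    manifest: RunManifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full registration + validation pipeline.

    With ``out_dir`` set, all artifacts (landmark CSVs, meshes, slice
    stacks, transforms, Dice reports, summary and manifest JSON) are
    written there; deterministic outputs are bitwise reproducible under
    a fixed seed.
    """
    timings: Dict[str, float] = {}
    t0 = time.perf_counter()
    study = generate_study(
        seed=config.seed,
        curvature=config.curvature,
        body=config.body,
        prone=config.prone,
        slice_spacing_mm=config.slice_spacing_mm,
        n_slices=config.n_slices,
        in_plane_mm=config.in_plane_mm,
    )
    timings["phantom"] = time.perf_counter() - t0

    # --- TP -> X-ray marker registration -------------------------------
    t0 = time.perf_counter()
    tp_model, tp_registered = register_tp_to_xray(
        study.tp_markers, study.xray_markers, study.tp_mesh
    )
    timings["tp_xray"] = time.perf_counter() - t0

    # --- articulated bone model ---------------------------------------
    t0 = time.perf_counter()
    labels = study.spine_prone.labels
    mri_frames = [
        frame_from_mri_landmarks(study.spine_prone.mri_landmarks[l], l) for l in labels
    ]
    xray_frames = [
        frame_from_xray_landmarks(study.spine_standing.xray_landmarks[l], l)
        for l in labels
    ]
    mri_model = build_articulated(mri_frames, "MRI")
    xray_model = build_articulated(xray_frames, "Xray")
    bone_transforms = dict(
        zip(labels, cross_modality_transforms(mri_model, xray_model))
    )
    global_rigid = fit_global_rigid(mri_frames, xray_frames)
    xray_frame_by_label = {f.label: f for f in xray_frames}
    timings["articulated"] = time.perf_counter() - t0

    # --- per-slice registration + 2D Dice ------------------------------
    t0 = time.perf_counter()
    reports: Dict[str, List] = {m: [] for m in config.methods}
    registrations: List[RegistrationResult] = []
    jacobian_stats: List[dict] = []
    for s in study.slices:
        ij = np.argwhere(s.vertebra_mask)
        slice_z = float(s.pixel_to_world(ij.mean(axis=0))[2])
        label = assign_slice_vertebra(slice_z, mri_frames)
        for method in config.methods:
            T = global_rigid if method == "rigid" else bone_transforms[label]
            if method == "proposed":
                res = register_slice(
                    s,
                    T,
                    tp_registered,
                    lam=config.edge_lambda,
                    angular_step=config.angular_step_deg,
                    anterior_dir_world=xray_frame_by_label[label].anterior,
                )
                registrations.append(res)
                d = polygon_dice(res.warped_contour_2d, res.tp_cut_2d, config.in_plane_mm)
                det = jacobian_determinant(res.field)
                interior = ndimage.binary_erosion(
                    res.deformation.vertebra_mask, iterations=3
                )
                jacobian_stats.append(
                    {
                        "slice": s.index,
                        "det_mean": float(det.mean()),
                        "det_var": float(det.var()),
                        "det_vertebra_interior_max_dev": float(
                            np.abs(det[interior] - 1.0).max()
                        )
                        if interior.any()
                        else float("nan"),
                    }
                )
            else:
                moved = s.transformed(T)
                centroid_world = moved.pixel_to_world(ij.mean(axis=0))
                cut = planar_cut(
                    tp_registered, moved.origin, moved.normal, inside_point=centroid_world
                )
                tp2 = moved.world_to_plane(cut.points)
                contour = mask_contour(moved.torso_mask, moved.spacing)
                d = polygon_dice(contour, tp2, config.in_plane_mm)
            reports[method].append((s.index, d))
    dice_reports = {m: DiceReport(m, vals) for m, vals in reports.items()}
    timings["slices"] = time.perf_counter() - t0

    # --- comparison + 3D Dice ------------------------------------------
    comparison = (
        compare_methods(dice_reports, test=config.statistical_test)
        if len(dice_reports) > 1
        else None
    )
    d3 = None
    mri_mesh = None
    if config.do_3d and registrations:
        t0 = time.perf_counter()
        contours_world = [
            r.slice.plane_to_world(r.warped_contour_2d) for r in registrations
        ]
        mri_mesh = build_torso_mesh(contours_world)
        vol_mri = voxelize(mri_mesh, config.voxel_spacing)
        vol_tp = voxelize(tp_registered, config.voxel_spacing)
        d3 = dice_3d(vol_mri, vol_tp)
        timings["dice3d"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        timings_s=timings,
        checksums={},
    )
    result = PipelineResult(
        study=study,
        config=config,
        reports=dice_reports,
        comparison=comparison,
        dice3d=d3,
        jacobian_stats=jacobian_stats,
        registrations=registrations,
        bone_transforms=bone_transforms,
        global_rigid=global_rigid,
        tp_model=tp_model,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, tp_registered, mri_mesh, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, tp_registered, mri_mesh, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    study = result.study
    io.write_landmarks_csv(
        io.spine_landmark_records(study.spine_prone), out / "landmarks_prone.csv"
    )
    io.write_landmarks_csv(
        io.spine_landmark_records(study.spine_standing), out / "landmarks_standing.csv"
    )
    io.write_markers_csv(study.tp_markers, "tp", out / "markers_tp.csv")
    io.write_markers_csv(study.xray_markers, "xray", out / "markers_xray.csv")
    io.write_mesh(tp_registered, out / "tp_registered.obj")
    if mri_mesh is not None:
        io.write_mesh(mri_mesh, out / "mri_torso_registered.obj")
    io.write_slices(study.slices, out / "slices_prone")
    if result.registrations:
        io.write_slices([r.slice for r in result.registrations], out / "slices_registered")
    transforms = {f"bone_{l}": T for l, T in result.bone_transforms.items()}
    transforms["global_rigid"] = result.global_rigid
    transforms["tp_to_xray"] = result.tp_model
    io.write_transforms_json(transforms, out / "transforms.json")
    for m, rep in result.reports.items():
        io.write_dice_report(rep, out / f"{m}_report.csv")
    summary = {
        "dice_2d_mean": {m: rep.mean for m, rep in result.reports.items()},
        "dice_2d_sd": {m: rep.sd for m, rep in result.reports.items()},
        "dice_3d": result.dice3d,
        "jacobian": result.jacobian_stats,
    }
    if result.comparison is not None:
        summary["p_values"] = {
            f"{a}_vs_{b}": p for (a, b), p in result.comparison.p_values.items()
        }
        summary["ordering"] = result.comparison.ordering
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    result.manifest.checksums = checksums
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest.to_dict(), fh, indent=1)
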