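"""File formats: landmark/marker CSV, meshes, slice stacks, transforms.

Formats are deliberately plain: CSV for point sets, OBJ/PLY for
meshes (via trimesh), NIfTI + a JSON pose sidecar for slice stacks,
JSON for rigid and thin-plate-spline transforms and for phantom ground
truth.  All readers/writers round-trip losslessly at the stated
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import RigidTransform
from .imagedata import AxialSlice
from .phantom import SpinePhantom
from .tps import TPSModel
from .validation import DiceReport

__all__ = [
    "write_landmarks_csv",
    "read_landmarks_csv",
    "landmarks_by_vertebra",
    "spine_landmark_records",
    "write_markers_csv",
    "read_markers_csv",
    "write_mesh",
    "read_mesh",
    "write_slices",
    "read_slices",
    "rigid_to_dict",
    "rigid_from_dict",
    "tps_to_dict",
    "tps_from_dict",
    "write_transforms_json",
    "read_transforms_json",
    "write_dice_report",
    "read_dice_report",
]

_LM_COLUMNS = ["name", "vertebra", "x", "y", "z", "modality"]


def spine_landmark_records(spine: SpinePhantom) -> pd.DataFrame:
    """All landmarks of a spine phantom as a tidy table."""
    rows = []
    for modality, lm in (("xray", spine.xray_landmarks), ("mri", spine.mri_landmarks)):
        for vert, pts in lm.items():
            for name, p in pts.items():
                rows.append([name, vert, p[0], p[1], p[2], modality])
    return pd.DataFrame(rows, columns=_LM_COLUMNS)


def write_landmarks_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in _LM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing columns {missing}")
    df.to_csv(path, index=False, float_format="%.10g")


def read_landmarks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _LM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: landmark CSV missing columns {missing}")
    return df


def landmarks_by_vertebra(df: pd.DataFrame, modality: str) -> Dict[str, Dict[str, np.ndarray]]:
    """Nested dict vertebra -> landmark name -> xyz for one modality."""
    sub = df[df["modality"] == modality]
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for (vert, name), row in sub.set_index(["vertebra", "name"]).iterrows():
        out.setdefault(vert, {})[name] = np.array([row["x"], row["y"], row["z"]])
    return out


def write_markers_csv(markers: Mapping[str, np.ndarray], modality: str, path) -> None:
    rows = [[n, "", p[0], p[1], p[2], modality] for n, p in sorted(markers.items())]
    pd.DataFrame(rows, columns=_LM_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_markers_csv(path) -> Dict[str, np.ndarray]:
    df = read_landmarks_csv(path)
    return {r["name"]: np.array([r["x"], r["y"], r["z"]]) for _, r in df.iterrows()}


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def read_mesh(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return m


def write_slices(slices: Sequence[AxialSlice], prefix) -> None:
    """Slice stack as two uint8 NIfTI volumes (torso/vertebra masks,
    slices stacked along the third axis) plus a JSON pose sidecar."""
    prefix = Path(prefix)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError("all slices in a stack must share one grid")
    torso = np.stack([s.torso_mask for s in slices], axis=-1).astype(np.uint8)
    vert = np.stack([s.vertebra_mask for s in slices], axis=-1).astype(np.uint8)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(torso, affine), str(prefix) + "_torso.nii")
    nib.save(nib.Nifti1Image(vert, affine), str(prefix) + "_vertebra.nii")
    sidecar = {
        "slices": [
            {
                "index": s.index,
                "vertebra_label": s.vertebra_label,
                "spacing": list(s.spacing),
                "pose": s.pose.tolist(),
            }
            for s in slices
        ]
    }
    with open(str(prefix) + "_poses.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_slices(prefix) -> List[AxialSlice]:
    prefix = str(prefix)
    torso = np.asanyarray(nib.load(prefix + "_torso.nii").dataobj).astype(bool)
    vert = np.asanyarray(nib.load(prefix + "_vertebra.nii").dataobj).astype(bool)
    with open(prefix + "_poses.json") as fh:
        sidecar = json.load(fh)
    out = []
    for k, meta in enumerate(sidecar["slices"]):
        out.append(
            AxialSlice(
                pose=np.array(meta["pose"]),
                spacing=tuple(meta["spacing"]),
                torso_mask=torso[..., k],
                vertebra_mask=vert[..., k],
                vertebra_label=meta["vertebra_label"],
                index=meta["index"],
            )
        )
    return out


def rigid_to_dict(T: RigidTransform) -> dict:
    return {"type": "rigid", "matrix": T.as_matrix().tolist()}


def rigid_from_dict(d: dict) -> RigidTransform:
    if d.get("type") != "rigid":
        raise ValueError(f"not a rigid transform record: {d.get('type')}")
    return RigidTransform.from_matrix(np.array(d["matrix"]))


def tps_to_dict(model: TPSModel) -> dict:
    return {
        "type": "tps",
        "kernel": model.kernel,
        "regularization": model.regularization,
        "control_points": model.control_points.tolist(),
        "weights": model.weights.tolist(),
        "affine": model.affine.tolist(),
    }


def tps_from_dict(d: dict) -> TPSModel:
    if d.get("type") != "tps":
        raise ValueError(f"not a TPS transform record: {d.get('type')}")
    return TPSModel(
        np.array(d["control_points"]),
        np.array(d["weights"]),
        np.array(d["affine"]),
        regularization=float(d["regularization"]),
        kernel=d["kernel"],
    )


def write_transforms_json(transforms: Mapping[str, object], path) -> None:
    """Named rigid/TPS transforms to one JSON file."""
    payload = {}
    for name, T in transforms.items():
        if isinstance(T, RigidTransform):
            payload[name] = rigid_to_dict(T)
        elif isinstance(T, TPSModel):
            payload[name] = tps_to_dict(T)
        else:
            raise TypeError(f"cannot serialize transform {name}: {type(T)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_transforms_json(path) -> Dict[str, object]:
    with open(path) as fh:
        payload = json.load(fh)
    out: Dict[str, object] = {}
    for name, d in payload.items():
        out[name] = rigid_from_dict(d) if d["type"] == "rigid" else tps_from_dict(d)
    return out


def write_dice_report(report: DiceReport, path) -> None:
    pd.DataFrame(report.per_slice, columns=["slice", "dice"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_dice_report(path, method: Optional[str] = None) -> DiceReport:
    df = pd.read_csv(path)
    name = method or Path(path).stem.replace("_report", "")
    return DiceReport(name, [(int(r["slice"]), float(r["dice"])) for _, r in df.iterrows()])
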