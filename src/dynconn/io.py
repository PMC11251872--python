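"""Readers and writers for the pipeline's on-disk formats.

ROI series are TSV (header = ROI names), voxel data are NIfTI, motion tables
are 6-column whitespace-delimited text, ground truth and reports are JSON,
and the group design is CSV (subject_id, group).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from dynconn.rois import RoiSet, default_roi_set
from dynconn.synthgen import RoiTimeSeries, VoxelScan


def write_roi_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.roi_set.names))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_roi_tsv(
    path: str | Path,
    roi_set: RoiSet | None = None,
    subject_id: str = "",
    condition: str = "",
    tr: float = 1.0,
) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    roi_set = roi_set or default_roi_set()
    missing = [n for n in roi_set.names if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ROI column(s) {missing}")
    return RoiTimeSeries(
        data=df[list(roi_set.names)].to_numpy(float),
        roi_set=roi_set,
        subject_id=subject_id or Path(path).stem,
        condition=condition,
        tr=tr,
    )


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, motion, fmt="%.8g")


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected a T x 6 motion table")
    return motion


def write_design(rows: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["subject_id", "group"]).to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"subject_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design table needs subject_id and group columns")
    return df


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    return aff


def write_nifti(
    array: np.ndarray, path: str | Path, voxel_size: float = 0.5
) -> None:
    img = nib.Nifti1Image(np.asarray(array), _affine(voxel_size))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_voxel_scan(scan: VoxelScan, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = scan.subject_id
    write_nifti(scan.bold, out / f"{sid}_bold.nii", scan.voxel_size)
    write_nifti(scan.labels.astype(np.uint8), out / f"{sid}_labels.nii", scan.voxel_size)
    for name, mask in (
        ("gm", scan.gm_mask),
        ("wm", scan.wm_mask),
        ("csf", scan.csf_mask),
        ("brain", scan.brain_mask),
    ):
        write_nifti(mask.astype(np.uint8), out / f"{sid}_{name}_mask.nii", scan.voxel_size)
    write_motion(scan.motion, out / f"{sid}_motion.txt")
    truth = {
        "spike_frames": [int(f) for f in scan.spike_frames],
        "mirror_axis": scan.mirror_axis,
        "condition": scan.condition,
    }
    if scan.state_labels is not None:
        truth["state_labels"] = [int(s) for s in scan.state_labels]
    write_json(truth, out / f"{sid}_truth.json")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_matrix_tsv(
    matrix: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> None:
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.8g")
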