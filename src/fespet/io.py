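"""File formats: TAC CSV, subject/truth CSV, NIfTI + JSON frame-timing sidecar.

On disk frame times are seconds; readers return :class:`FrameSchedule`
objects (which expose minute views used by computation).  All CSV writers use
pandas full-precision float repr, so write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_subject_csv",
    "write_subject_csv",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "read_bpnd_map",
    "write_bpnd_map",
    "read_label_mask",
    "write_label_mask",
    "SUBJECT_COLUMNS",
]

_TIME_COLS = ("frame_start_s", "frame_end_s")

SUBJECT_COLUMNS = (
    "subject_id", "group", "age_years", "shbg_nmol_L", "education_years",
    "memory_immediate", "memory_delayed", "global_cognition",
)


def write_tac_csv(path, tacs: dict) -> None:
    """Write one subject's TACs: timing columns then one column per region."""
    if not tacs:
        raise ValueError("no TACs to write")
    regions = list(tacs)
    schedule = tacs[regions[0]].schedule
    for r in regions:
        if tacs[r].schedule != schedule:
            raise ValueError(f"region {r} has a different frame schedule")
    df = pd.DataFrame({
        "frame_start_s": schedule.starts_s,
        "frame_end_s": schedule.ends_s,
        **{r: tacs[r].activity for r in regions},
    })
    df.to_csv(path, index=False)


def read_tac_csv(path) -> dict:
    """Read a TAC CSV into {region: TimeActivityCurve}.

    The header must contain frame_start_s and frame_end_s; remaining columns
    are regions (kBq/mL).  Malformed files raise ValueError naming the
    offending rows/columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TIME_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required header column(s) {missing}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric cells in column '{col}', file row(s) {rows}")
        if df[col].isna().any():
            rows = (df.index[df[col].isna()] + 2).tolist()
            raise ValueError(f"{path}: empty cells in column '{col}', file row(s) {rows}")
    starts = df["frame_start_s"].to_numpy(dtype=float)
    ends = df["frame_end_s"].to_numpy(dtype=float)
    overlap = np.nonzero(starts[1:] < ends[:-1])[0]
    if overlap.size:
        rows = (overlap + 3).tolist()  # offending frame i+1; +1 header, 1-based
        raise ValueError(f"{path}: overlapping frames at file row(s) {rows}")
    try:
        schedule = FrameSchedule(starts, ends, allow_gaps=True)
    except ValueError as exc:
        raise ValueError(f"{path}: invalid frame timing: {exc}") from exc
    return {
        str(col): TimeActivityCurve(schedule, df[col].to_numpy(dtype=float), str(col))
        for col in df.columns if col not in _TIME_COLS
    }


def write_subject_csv(path, subjects: pd.DataFrame) -> None:
    cols = [c for c in SUBJECT_COLUMNS if c in subjects.columns]
    extra = [c for c in subjects.columns if c not in cols]
    subjects[cols + extra].to_csv(path, index=False)


def read_subject_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad_groups = set(df["group"]) - {"PRE", "PERI", "POST"}
    if bad_groups:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad_groups)}")
    return df


# ---------------------------------------------------------------------------
# NIfTI + sidecar
# ---------------------------------------------------------------------------

def write_dynamic_nifti(path, image4d: np.ndarray, schedule: FrameSchedule,
                        sidecar_path=None) -> None:
    """Write a 4-D image as NIfTI-1 with a JSON frame-timing sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(image4d, dtype=np.float64), affine=np.eye(4))
    nib.save(img, path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({
        "frame_starts_s": schedule.starts_s.tolist(),
        "frame_ends_s": schedule.ends_s.tolist(),
    }, indent=1))


def read_dynamic_nifti(path, sidecar_path=None):
    """Read a 4-D NIfTI and its timing sidecar -> (image4d, FrameSchedule)."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"missing frame-timing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_starts_s", "frame_ends_s"):
        if key not in meta:
            raise ValueError(f"{sidecar}: missing key '{key}'")
    schedule = FrameSchedule(np.asarray(meta["frame_starts_s"], dtype=float),
                             np.asarray(meta["frame_ends_s"], dtype=float),
                             allow_gaps=True)
    image = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    if image.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got shape {image.shape}")
    if image.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"{path}: image has {image.shape[-1]} frames but sidecar lists "
            f"{schedule.n_frames}"
        )
    return image, schedule


def write_bpnd_map(path, bpnd_map) -> None:
    """Write a voxelwise BPnd map as NIfTI-1 (masked voxels carry NaN)."""
    img = nib.Nifti1Image(np.asarray(bpnd_map.bpnd, dtype=np.float64),
                          affine=np.eye(4))
    nib.save(img, path)


def read_bpnd_map(path):
    """Read a BPnd map written by :func:`write_bpnd_map`."""
    from .logan import BPndMap

    arr = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    mask = np.isfinite(arr)
    return BPndMap(bpnd=arr, mask=mask)


def write_label_mask(path, labels: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine=np.eye(4))
    nib.save(img, path)


def read_label_mask(path) -> np.ndarray:
    arr = np.asarray(nib.load(path).dataobj)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: label mask is not integer-valued")
        arr = np.round(arr).astype(np.int16)
    return arr


def roi_mean_tacs(image4d: np.ndarray, labels: np.ndarray, schedule: FrameSchedule,
                  label_names: dict | None = None) -> dict:
    """Extract ROI-mean TACs from a labelled 4-D image."""
    if image4d.shape[:-1] != labels.shape:
        raise ValueError("image and label mask shapes do not match")
    out = {}
    for lab in np.unique(labels):
        name = (label_names or {}).get(int(lab), f"label{int(lab)}")
        out[name] = TimeActivityCurve(
            schedule, image4d[labels == lab, :].mean(axis=0), name
        )
    return out
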