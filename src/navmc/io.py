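"""Readers and writers: NIfTI volumes, timing tables, transforms, QC reports.

Volumes are NIfTI-1 (``.nii`` / ``.nii.gz``) with the voxel-to-world affine in
mm; when qform and sform disagree beyond 1e-3 the sform is preferred and a
warning is issued.  Timing tables are CSV (header
``label,kind,start_s,duration_s``) or JSON records, with all times in seconds
from PET scan start.  Rigid transforms are plain text: four rows of four
whitespace-separated numbers, with an optional ``.json`` sidecar carrying the
six generator parameters and the rotation-convention label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import RigidTransform, from_matrix

__all__ = [
    "Volume",
    "TimingTable",
    "read_volume",
    "write_volume",
    "read_timing",
    "write_timing",
    "read_transform",
    "write_transform",
    "write_qc_report",
]

def grid_world_coords(shape, affine) -> np.ndarray:
    """World coordinates of every voxel centre of a grid, shape ``(N, 3)``."""
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    return np.ascontiguousarray((affine[:3, :3] @ idx).T + affine[:3, 3])


TIMING_COLUMNS = ["label", "kind", "start_s", "duration_s"]
TIMING_KINDS = {"navigator_burst", "pet_frame", "scan"}


@dataclass
class Volume:
    """A 3D image grid with a voxel-index -> world-mm affine.

    Used for navigators, PET frames, region masks and corrected output.
    ``frame_start`` / ``frame_duration`` (seconds from scan start) are set on
    PET frames and navigator volumes; masks and derived images leave them None.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_start: float | None = None
    frame_duration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.frame_duration is not None and self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` voxel indices to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` world mm points to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(N, 3)``."""
        return grid_world_coords(self.shape, self.affine)


def read_volume(path) -> Volume:
    """Load a 3D NIfTI volume.

    Raises a descriptive error for a missing file, non-3D data, NaNs in the
    image, or a singular affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D image, got {img.ndim}D")
    sform, scode = img.get_sform(coded=True)
    qform, qcode = img.get_qform(coded=True)
    if scode > 0 and qcode > 0 and not np.allclose(sform, qform, atol=1e-3):
        warnings.warn(
            f"{path.name}: qform and sform disagree beyond 1e-3; using sform",
            stacklevel=2,
        )
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if np.isnan(data).any():
        raise ValueError(f"{path.name}: image contains NaN values")
    return Volume(data=data, affine=np.asarray(img.affine), label=path.name)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (float32; sform and qform both set)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.set_sform(volume.affine, code=1)
    img.set_qform(volume.affine, code=1)
    nib.save(img, str(path))


@dataclass
class TimingTable:
    """Acquisition timing: navigator bursts, PET frames, and the scan window.

    Rows are ``(label, kind, start_s, duration_s)`` with
    ``kind in {navigator_burst, pet_frame, scan}``; exactly one ``scan`` row
    is allowed and navigator bursts may not overlap.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TIMING_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table, columns=TIMING_COLUMNS).copy()
        df["start_s"] = df["start_s"].astype(float)
        df["duration_s"] = df["duration_s"].astype(float)
        bad_kind = set(df["kind"]) - TIMING_KINDS
        if bad_kind:
            raise ValueError(f"unknown timing kinds: {sorted(bad_kind)}")
        if (df["start_s"] < 0).any():
            raise ValueError("start_s must be >= 0")
        if (df["duration_s"] <= 0).any():
            raise ValueError("duration_s must be > 0")
        if (df["kind"] == "scan").sum() > 1:
            raise ValueError("timing table must contain at most one scan row")
        df = df.sort_values("start_s", kind="stable").reset_index(drop=True)
        navs = df[df["kind"] == "navigator_burst"]
        ends = navs["start_s"] + navs["duration_s"]
        if (navs["start_s"].values[1:] < ends.values[:-1]).any():
            raise ValueError("navigator bursts overlap")
        self.table = df

    @property
    def nav_start_times(self) -> np.ndarray:
        """Start times (s) of navigator bursts, ascending."""
        return self.table.loc[self.table["kind"] == "navigator_burst", "start_s"].to_numpy()

    @property
    def scan_window(self) -> tuple[float, float]:
        """(scan_start_s, scan_end_s); requires a scan row."""
        scan = self.table[self.table["kind"] == "scan"]
        if scan.empty:
            raise ValueError("timing table has no scan row")
        row = scan.iloc[0]
        return float(row["start_s"]), float(row["start_s"] + row["duration_s"])


def read_timing(path) -> TimingTable:
    """Read a timing table from CSV (header ``label,kind,start_s,duration_s``)
    or a JSON list of records with the same keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such timing file: {path}")
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = set(TIMING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"timing table missing columns: {sorted(missing)}")
    return TimingTable(df[TIMING_COLUMNS])


def write_timing(timing: TimingTable, path) -> None:
    """Write a timing table; format chosen by extension (.csv or .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(timing.table.to_dict(orient="records"), indent=2) + "\n")
    else:
        timing.table.to_csv(path, index=False)


def read_transform(path) -> RigidTransform:
    """Read a rigid transform from the 4x4 plain-text format."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected 4x4 matrix, got shape {mat.shape}")
    if not np.allclose(mat[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
        raise ValueError(f"{path}: bottom row is not (0, 0, 0, 1)")
    mat[3] = [0.0, 0.0, 0.0, 1.0]  # snap: the bottom row is structural
    canonical = from_matrix(mat)
    # keep the matrix exactly as read (validated above) so that
    # write -> read -> write is byte-identical; params come from extraction
    return RigidTransform(canonical.params, mat, canonical.convention)


def write_transform(t: RigidTransform, path, sidecar: bool = True) -> None:
    """Write a transform as 4 rows x 4 numbers; optional JSON param sidecar."""
    path = Path(path)
    np.savetxt(path, t.matrix, fmt="%.17g")
    if sidecar:
        meta = {
            "params_deg_mm": [float(x) for x in t.params],
            "convention": t.convention,
            "order": "rx ry rz tx ty tz (intrinsic rotations about world origin, then translation)",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def write_qc_report(report, path) -> None:
    """Serialize a :class:`navmc.qc.QCReport` to JSON.

    Schema: ``{threshold_mm, mc_recommended, max_magnitude_mm: {point: mm},
    burst_spread_mm: [mm, ...] | null, notes}``.
    """
    payload = {
        "threshold_mm": report.threshold_mm,
        "mc_recommended": bool(report.mc_recommended),
        "max_magnitude_mm": {k: float(v) for k, v in report.max_magnitude_mm.items()},
        "burst_spread_mm": (
            None if report.burst_spread_mm is None else [float(v) for v in report.burst_spread_mm]
        ),
        "notes": report.notes,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
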