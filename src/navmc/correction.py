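"""Frame-by-frame (MAF) motion correction: realign PET frames and average.

The multiple-acquisition-frames principle: the PET scan is split into frames
(one per navigator sample), each frame is reconstructed at its own head
pose, every frame is rigidly resampled back to the pose of the first frame
(the reference — it carries no alignment transform), and the aligned frames
are averaged into a single corrected image.

Each frame's transform ``T_n`` maps reference-space coordinates to that
frame's moved-space coordinates (the convention of the registration and
simulator modules), so the corrected value at reference point ``p`` is
frame ``n`` sampled at ``T_n(p)`` — i.e. the frame is pulled back through
the motion.  Averaging is duration-weighted by default: with frame lengths
ranging over roughly 3–6 minutes, uniform weighting would mis-weight
counts; ``weighting="uniform"`` is available for a literal plain average.
Voxels that fall outside every frame's field of view accumulate zero weight
and are marked invalid (NaN), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .io import Volume, grid_world_coords

__all__ = ["CorrectedImage", "resample", "correct_frames", "total_activity"]


@dataclass
class CorrectedImage:
    """A motion-corrected average image with per-voxel weight bookkeeping.

    ``weight_map`` holds the effective seconds (or frame count, for uniform
    weighting) contributing to each voxel; voxels with zero weight are NaN
    in ``volume`` and False in ``valid``.
    """

    volume: Volume
    weight_map: np.ndarray
    frames_used: int
    weighting: str

    @property
    def valid(self) -> np.ndarray:
        return self.weight_map > 0


def resample(
    frame: Volume,
    t: RigidTransform,
    target_affine: np.ndarray | None = None,
    target_shape: tuple[int, int, int] | None = None,
    grid_pts: np.ndarray | None = None,
) -> tuple[Volume, np.ndarray]:
    """Resample ``frame`` onto a target grid through transform ``t``.

    The output value at world point ``p`` is the trilinear interpolation of
    the frame at ``t(p)``; samples outside the frame's grid are invalid
    (False in the returned mask, NaN in the data).  Defaults to the frame's
    own grid.  An identity transform onto the same grid returns the input
    values exactly.
    """
    target_affine = frame.affine if target_affine is None else np.asarray(target_affine, float)
    target_shape = frame.shape if target_shape is None else tuple(target_shape)
    if len(target_shape) != 3 or any(n < 1 for n in target_shape):
        raise ValueError(f"degenerate target grid shape {target_shape}")
    if abs(np.linalg.det(np.asarray(target_affine)[:3, :3])) < 1e-12:
        raise ValueError("degenerate target grid affine")

    if t.is_identity() and target_shape == frame.shape and np.array_equal(
        target_affine, frame.affine
    ):
        data = frame.data.astype(np.float32).copy()
        return (
            Volume(data, frame.affine, frame.frame_start, frame.frame_duration, frame.label),
            np.ones(frame.shape, dtype=bool),
        )

    if grid_pts is None:
        grid_pts = grid_world_coords(target_shape, target_affine).astype(np.float32)
    data, valid = _pull_back(frame, t, grid_pts)
    return (
        Volume(data.reshape(target_shape), target_affine, frame.frame_start,
               frame.frame_duration, frame.label),
        valid.reshape(target_shape),
    )


def _pull_back(frame: Volume, t: RigidTransform, grid_pts: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``frame`` at ``t(p)`` for flat world points ``p``; NaN outside."""
    moved = grid_pts @ t.rotation.T.astype(np.float32) + t.translation.astype(np.float32)
    inv = np.linalg.inv(frame.affine)
    vox = moved @ inv[:3, :3].T.astype(np.float32) + inv[:3, 3].astype(np.float32)
    shape = np.asarray(frame.shape, dtype=np.float32)
    valid = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    sampled = ndimage.map_coordinates(
        np.asarray(frame.data, dtype=np.float32), vox.T, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )
    return np.where(valid, sampled, np.nan).astype(np.float32), valid


def correct_frames(
    frames: list[Volume],
    transforms: list[RigidTransform],
    weighting: str = "duration",
) -> CorrectedImage:
    """Motion-correct a sequence of PET frames into one average image.

    Each frame is pulled back to the first frame's grid through its
    transform (the first transform is conventionally identity) and the
    aligned frames are combined as ``sum(w_i * frame_i) / sum(w_i)`` over
    the voxels where each frame is valid, with ``w_i`` the frame duration
    (default) or 1 (``weighting="uniform"``).
    """
    if len(frames) != len(transforms):
        raise ValueError(
            f"{len(frames)} frames but {len(transforms)} transforms"
        )
    if not frames:
        raise ValueError("at least one frame is required")
    if weighting not in ("duration", "uniform"):
        raise ValueError("weighting must be 'duration' or 'uniform'")
    if weighting == "duration" and any(f.frame_duration is None for f in frames):
        raise ValueError("duration weighting requires frame_duration on every frame")

    target = frames[0]
    pts = grid_world_coords(target.shape, target.affine).astype(np.float32)
    num = np.zeros(target.shape, dtype=np.float64)
    den = np.zeros(target.shape, dtype=np.float64)
    for frame, t in zip(frames, transforms):
        aligned, valid = resample(frame, t, target.affine, target.shape, grid_pts=pts)
        w = float(frame.frame_duration) if weighting == "duration" else 1.0
        vals = np.where(valid, aligned.data, 0.0)
        num += w * vals
        den += w * valid
    with np.errstate(invalid="ignore"):
        data = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan).astype(np.float32)
    out = Volume(
        data,
        target.affine,
        frame_start=frames[0].frame_start,
        frame_duration=float(sum(f.frame_duration or 0.0 for f in frames)) or None,
        label="motion_corrected",
    )
    return CorrectedImage(out, den, len(frames), weighting)


def total_activity(volume: Volume, valid: np.ndarray | None = None) -> float:
    """Total activity: sum over valid voxels times the voxel volume (mm^3)."""
    data = volume.data
    sel = np.isfinite(data)
    if valid is not None:
        sel &= np.asarray(valid, dtype=bool)
    return float(data[sel].sum()) * volume.voxel_volume_mm3
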