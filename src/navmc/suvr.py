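"""SUVr quantification and amyloid (PiB) positivity classification.

SUVr is the standardized-uptake-value ratio: the mean tracer uptake in a
target cortical region divided by the mean in the cerebellum reference
region.  Body-weight/dose normalisation cancels in the ratio, so region
means of the reconstructed activity image suffice.  An SUVr above 1.5
(strictly) is classified as abnormal amyloid (PiB-positive) uptake.

Invalid voxels — e.g. zero-weight voxels of a motion-corrected image that
never received data — are excluded from region means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Volume

__all__ = [
    "RegionMask",
    "region_mean",
    "compute_suvr",
    "classify_pib",
    "erode_mask",
    "PIB_CUTOFF",
]

#: SUVr strictly above this is classified as abnormal (PiB-positive) uptake.
PIB_CUTOFF = 1.5


@dataclass(frozen=True)
class RegionMask:
    """A boolean region mask on an image grid."""

    mask: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not mask.any():
            raise ValueError(f"mask {self.name!r} is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def erode_mask(region: RegionMask, iterations: int = 1) -> RegionMask:
    """Erode a mask by ``iterations`` voxels (6-connectivity).

    Used to pull region means away from blurred compartment edges; raises if
    erosion empties the mask.
    """
    eroded = ndimage.binary_erosion(region.mask, iterations=iterations)
    if not eroded.any():
        raise ValueError(f"eroding mask {region.name!r} by {iterations} emptied it")
    return RegionMask(eroded, f"{region.name}_eroded{iterations}")


def region_mean(image: Volume, region: RegionMask, valid: np.ndarray | None = None) -> float:
    """Arithmetic mean of the image over valid masked voxels.

    NaN voxels (and any voxel where ``valid`` is False) are excluded; an
    effectively empty mask is an error.
    """
    if image.shape != region.mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {region.mask.shape}"
        )
    sel = region.mask & np.isfinite(image.data)
    if valid is not None:
        sel &= np.asarray(valid, dtype=bool)
    if not sel.any():
        raise ValueError(f"no valid voxels under mask {region.name!r}")
    return float(image.data[sel].mean())


def compute_suvr(
    image: Volume,
    target: RegionMask,
    cerebellum: RegionMask,
    valid: np.ndarray | None = None,
) -> float:
    """SUVr = mean(target) / mean(cerebellum reference).

    Masks must be disjoint; a non-positive cerebellum mean is an error
    (the ratio would be meaningless).
    """
    if (target.mask & cerebellum.mask).any():
        raise ValueError("target and cerebellum masks overlap")
    ref = region_mean(image, cerebellum, valid)
    if ref <= 0:
        raise ValueError(f"cerebellum reference mean is non-positive ({ref:g})")
    return region_mean(image, target, valid) / ref


def classify_pib(suvr: float, cutoff: float = PIB_CUTOFF) -> str:
    """Classify amyloid status: ``"positive"`` iff SUVr strictly exceeds the cutoff."""
    if not suvr > 0:
        raise ValueError("SUVr must be positive")
    return "positive" if suvr > cutoff else "negative"
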