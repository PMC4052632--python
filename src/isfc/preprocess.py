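"""Volume preprocessing: intensity masking, proportional scaling, smoothing.

Order of operations is configurable; the default pipeline smooths first
and masks afterwards.  Masked (background) voxels are excluded from all
downstream statistics but kept in the volumes untouched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AnimalVolume

__all__ = [
    "BrainMask",
    "compute_intensity_mask",
    "proportional_scale",
    "gaussian_smooth",
    "fwhm_to_sigma_voxels",
    "scale_roi_table",
    "preprocess_volume",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BrainMask:
    """Boolean in-brain mask, thresholded relative to the volume mean."""

    data: np.ndarray
    mask_fraction: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def compute_intensity_mask(volume: AnimalVolume, fraction: float = 0.8) -> BrainMask:
    """Mask voxels below ``fraction`` × the mean voxel value.

    The mean is taken over the whole array (background included).  A
    voxel is in-mask iff its intensity ≥ fraction × mean.
    """
    if fraction <= 0:
        raise ValueError(f"mask fraction must be positive, got {fraction}")
    mean = float(volume.data.mean())
    if mean <= 0:
        raise ValueError(
            f"mask undefined for volume {volume.animal_id!r}: mean intensity is {mean}"
        )
    mask = volume.data >= fraction * mean
    return BrainMask(data=mask, mask_fraction=fraction)


def proportional_scale(
    volume: AnimalVolume, mask: BrainMask, target_mean: float = 100.0
) -> AnimalVolume:
    """Scale all voxels so the in-mask mean equals ``target_mean``.

    Removes per-animal global (tracer-dose) intensity differences.  The
    same factor is applied to out-of-mask voxels.
    """
    if mask.data.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if mask.n_voxels == 0:
        raise ValueError(f"empty mask for volume {volume.animal_id!r}")
    current = float(volume.data[mask.data].mean())
    if current <= 0:
        raise ValueError(
            f"non-positive in-mask mean ({current}) for volume {volume.animal_id!r}"
        )
    return volume.with_data(volume.data * (target_mean / current))


def fwhm_to_sigma_voxels(fwhm_um, voxel_size_um) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a FWHM given in μm."""
    fwhm = np.asarray(fwhm_um, dtype=float)
    vox = np.asarray(voxel_size_um, dtype=float)
    if np.any(fwhm < 0):
        raise ValueError(f"FWHM components must be non-negative, got {fwhm_um}")
    return (fwhm / vox) / _FWHM_PER_SIGMA


def gaussian_smooth(volume: AnimalVolume, fwhm_um=(120.0, 420.0, 120.0)) -> AnimalVolume:
    """Separable anisotropic Gaussian smoothing.

    Boundary handling is nearest-value extension, so the kernel weights
    form a convex combination and the output never leaves the input's
    value range.  A FWHM below the voxel size triggers a warning
    (sub-voxel kernel) but is not an error.
    """
    sigma = fwhm_to_sigma_voxels(fwhm_um, volume.voxel_size_um)
    sub = [
        axis
        for axis, (f, v) in enumerate(zip(np.atleast_1d(fwhm_um), volume.voxel_size_um))
        if 0 < f < v
    ]
    if sub:
        warnings.warn(
            f"sub-voxel smoothing kernel on axis/axes {sub}: FWHM below voxel size",
            stacklevel=2,
        )
    if np.all(sigma == 0):
        return volume.with_data(volume.data.copy())
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="nearest")
    return volume.with_data(smoothed)


def preprocess_volume(
    volume: AnimalVolume,
    mask_fraction: float = 0.8,
    fwhm_um=(120.0, 420.0, 120.0),
    target_mean: float = 100.0,
    smooth_before_mask: bool = True,
) -> tuple[AnimalVolume, BrainMask, dict]:
    """Full single-volume preprocessing: smooth, mask, proportionally scale.

    Returns the scaled volume, its mask, and a provenance dict suitable
    for a JSON sidecar.
    """
    smoothed = gaussian_smooth(volume, fwhm_um)
    if smooth_before_mask:
        mask = compute_intensity_mask(smoothed, mask_fraction)
    else:
        mask = compute_intensity_mask(volume, mask_fraction)
    scaled = proportional_scale(smoothed, mask, target_mean)
    provenance = {
        "animal_id": volume.animal_id,
        "group": volume.group,
        "mask_fraction": mask_fraction,
        "fwhm_um": list(np.atleast_1d(fwhm_um).astype(float)),
        "target_mean": target_mean,
        "smooth_before_mask": smooth_before_mask,
        "mask_voxels": mask.n_voxels,
    }
    return scaled, mask, provenance


def write_provenance(provenance: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2)


def scale_roi_table(values, target_mean: float = 100.0):
    """Row-wise proportional scaling of an animals × ROIs table.

    Table-level analogue of :func:`proportional_scale`: each animal's
    row is multiplied so its mean equals ``target_mean``, removing
    global dose differences when the image stages are bypassed.
    """
    import pandas as pd

    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(np.asarray(values))
    row_means = df.mean(axis=1)
    if (row_means <= 0).any():
        bad = list(df.index[row_means <= 0])
        raise ValueError(f"non-positive row mean(s) for animals {bad}")
    return df.mul(target_mean / row_means, axis=0)
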