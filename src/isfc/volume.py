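"""Shared 3D volume container and NIfTI I/O.

Axis convention: axis 0 = mediolateral, axis 1 = anteroposterior
(coronal plane index), axis 2 = dorsoventral.  Voxel sizes are carried
in micrometres; NIfTI headers record them as millimetres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["AnimalVolume", "load_volume", "save_volume"]


@dataclass
class AnimalVolume:
    """One animal's co-registered 3D intensity volume.

    Parameters
    ----------
    animal_id : str
        Unique animal identifier.
    group : str
        Cohort group label.
    data : ndarray
        3D array of non-negative intensities (optical-density units).
    voxel_size_um : tuple of float
        (mediolateral, anteroposterior, dorsoventral) voxel size in μm.
    bregma0_mm : float
        Bregma coordinate of the first anteroposterior plane (anterior
        positive, in mm).
    """

    animal_id: str
    group: str
    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (40.0, 140.0, 40.0)
    bregma0_mm: float = 2.98

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def ap_spacing_mm(self) -> float:
        """Anteroposterior inter-plane spacing in mm."""
        return self.voxel_size_um[1] / 1000.0

    def with_data(self, data: np.ndarray) -> "AnimalVolume":
        """Copy of this volume carrying new intensity data (same geometry)."""
        return AnimalVolume(
            animal_id=self.animal_id,
            group=self.group,
            data=data,
            voxel_size_um=self.voxel_size_um,
            bregma0_mm=self.bregma0_mm,
        )


def _affine(voxel_size_um) -> np.ndarray:
    aff = np.diag([v / 1000.0 for v in voxel_size_um] + [1.0])
    return aff


def save_volume(vol: AnimalVolume, path: str | os.PathLike) -> None:
    """Write an :class:`AnimalVolume` (or any aligned array) as NIfTI.

    Voxel sizes go into the header zooms in mm (μm × 10⁻³); the bregma
    origin is stored in the header description.
    """
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_size_um))
    img.header.set_zooms([v / 1000.0 for v in vol.voxel_size_um])
    img.header["descrip"] = f"group={vol.group};bregma0_mm={vol.bregma0_mm}".encode()[:79]
    nib.save(img, os.fspath(path))


def save_label_volume(labels: np.ndarray, voxel_size_um, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32), _affine(voxel_size_um))
    nib.save(img, os.fspath(path))


def load_volume(
    path: str | os.PathLike,
    animal_id: str,
    group: str,
    bregma0_mm: float | None = None,
) -> AnimalVolume:
    """Read a NIfTI volume into an :class:`AnimalVolume`.

    Voxel sizes are taken from the header zooms (mm → μm).  If
    ``bregma0_mm`` is not given it is recovered from the description
    field when present, else defaults to +2.98 mm.
    """
    img = nib.load(os.fspath(path))
    zooms = img.header.get_zooms()[:3]
    if bregma0_mm is None:
        bregma0_mm = 2.98
        descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
        for tok in descrip.strip("\x00").split(";"):
            if tok.startswith("bregma0_mm="):
                bregma0_mm = float(tok.split("=", 1)[1])
    return AnimalVolume(
        animal_id=animal_id,
        group=group,
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_um=tuple(z * 1000.0 for z in zooms),
        bregma0_mm=float(bregma0_mm),
    )
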