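"""Midline ROI planning and per-animal ROI mean extraction.

ROIs are small circles drawn in the coronal (mediolateral ×
dorsoventral) plane, one per coronal slice, arranged in dorsal and
ventral bands along the anteroposterior axis.  Membership of a voxel in
a circular footprint is decided by its centre: a voxel belongs to the
footprint iff its centre lies within ``diameter/2`` (μm, physical
space) of the ROI centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volume import AnimalVolume

__all__ = [
    "ROIDef",
    "ROILayout",
    "ROITable",
    "plan_midline_slices",
    "bregma_to_slice",
    "slice_to_bregma",
    "roi_footprint",
    "extract_roi_means",
]

BANDS = ("dorsal", "ventral")
HEMISPHERES = ("left", "right")


def plan_midline_slices(start_bregma: float, end_bregma: float, spacing: float) -> np.ndarray:
    """Plan the ordered bregma positions of the coronal ROI series.

    Returns an inclusive arithmetic sequence from ``start_bregma`` down
    to ``end_bregma`` (anterior positive) with step ``-spacing``.

    Raises
    ------
    ValueError
        If spacing is non-positive, start < end, or the range is not an
        integer multiple of the spacing (within 1e-6 mm).
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if start_bregma < end_bregma:
        raise ValueError("start_bregma must be anterior to (>=) end_bregma")
    span = start_bregma - end_bregma
    m = round(span / spacing)
    residual = span - m * spacing
    if abs(residual) > 1e-6:
        raise ValueError(
            f"bregma range {span:.6f} mm is not a multiple of spacing "
            f"{spacing} mm (residual {residual:.2e} mm)"
        )
    return start_bregma - spacing * np.arange(m + 1)


def bregma_to_slice(
    bregma: float,
    first_plane_bregma: float = 2.98,
    spacing: float = 0.14,
    n_planes: int | None = None,
) -> int:
    """Map a bregma coordinate (mm) to a 0-based anteroposterior index."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if bregma > first_plane_bregma + 1e-9:
        raise ValueError(
            f"bregma {bregma} mm is anterior to the first plane at {first_plane_bregma} mm"
        )
    idx = int(round((first_plane_bregma - bregma) / spacing))
    if idx < 0 or (n_planes is not None and idx >= n_planes):
        raise ValueError(f"bregma {bregma} mm maps to out-of-volume plane index {idx}")
    return idx


def slice_to_bregma(index: int, first_plane_bregma: float = 2.98, spacing: float = 0.14) -> float:
    """Inverse of :func:`bregma_to_slice`."""
    return first_plane_bregma - index * spacing


@dataclass(frozen=True)
class ROIDef:
    """One circular ROI on a single coronal slice."""

    name: str
    band: str  # dorsal | ventral
    hemisphere: str  # left | right
    bregma_mm: float
    center: tuple[int, int, int]  # (mediolateral, anteroposterior, dorsoventral) voxel index
    diameter_um: float = 100.0

    def __post_init__(self):
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}, got {self.band!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.diameter_um <= 0:
            raise ValueError(f"ROI diameter must be positive, got {self.diameter_um}")


class ROILayout:
    """Ordered series of midline ROI definitions.

    Invariants enforced at construction: within each (band, hemisphere)
    series the bregma positions are strictly decreasing and consecutive
    positions differ by ``spacing_mm``; all diameters are positive.
    """

    def __init__(self, rois: Sequence[ROIDef], spacing_mm: float = 0.14):
        if spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        self.rois = list(rois)
        self.spacing_mm = float(spacing_mm)
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        for band in BANDS:
            for hemi in HEMISPHERES:
                series = [r for r in self.rois if r.band == band and r.hemisphere == hemi]
                for a, b in zip(series, series[1:]):
                    step = a.bregma_mm - b.bregma_mm
                    if step <= 0:
                        raise ValueError(
                            f"bregma positions not strictly decreasing in {band}/{hemi} "
                            f"band at {a.name} -> {b.name}"
                        )
                    if abs(step - self.spacing_mm) > 1e-6:
                        raise ValueError(
                            f"spacing {step:.6f} mm between {a.name} and {b.name} "
                            f"differs from configured {self.spacing_mm} mm"
                        )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rois],
                "band": [r.band for r in self.rois],
                "hemisphere": [r.hemisphere for r in self.rois],
                "bregma_mm": [r.bregma_mm for r in self.rois],
                "i": [r.center[0] for r in self.rois],
                "j": [r.center[1] for r in self.rois],
                "k": [r.center[2] for r in self.rois],
                "diameter_um": [r.diameter_um for r in self.rois],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spacing_mm: float = 0.14) -> "ROILayout":
        df = pd.read_csv(path)
        rois = [
            ROIDef(
                name=str(row["name"]),
                band=str(row["band"]),
                hemisphere=str(row["hemisphere"]),
                bregma_mm=float(row["bregma_mm"]),
                center=(int(row["i"]), int(row["j"]), int(row["k"])),
                diameter_um=float(row["diameter_um"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(rois, spacing_mm=spacing_mm)


def roi_footprint(
    roi: ROIDef, shape: tuple[int, int, int], voxel_size_um: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices of the ROI's in-plane circular footprint.

    The circle lives in the coronal plane (axes 0 and 2) at the ROI's
    anteroposterior index.  Voxel-centre-in-circle rule, distances in μm.

    Returns ``(ii, jj, kk)`` index arrays suitable for fancy indexing.

    Raises
    ------
    ValueError
        If any footprint voxel falls outside ``shape`` (error names the ROI).
    """
    ci, cj, ck = roi.center
    radius = roi.diameter_um / 2.0
    vml, _, vdv = voxel_size_um
    ri = int(np.floor(radius / vml))
    rk = int(np.floor(radius / vdv))
    ii, kk = [], []
    for di in range(-ri, ri + 1):
        for dk in range(-rk, rk + 1):
            if (di * vml) ** 2 + (dk * vdv) ** 2 <= radius**2 + 1e-9:
                ii.append(ci + di)
                kk.append(ck + dk)
    ii = np.asarray(ii, dtype=np.intp)
    kk = np.asarray(kk, dtype=np.intp)
    jj = np.full_like(ii, cj)
    if (
        cj < 0
        or cj >= shape[1]
        or ii.min() < 0
        or ii.max() >= shape[0]
        or kk.min() < 0
        or kk.max() >= shape[2]
    ):
        raise ValueError(f"footprint of ROI {roi.name!r} falls outside volume of shape {shape}")
    return ii, jj, kk


@dataclass
class ROITable:
    """Animals × ROIs table of mean optical densities plus group labels."""

    values: pd.DataFrame  # index: animal ids; columns: ROI names
    groups: pd.Series  # index: animal ids; values: group labels

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            raise ValueError("every animal row needs a group label")

    def group_values(self, group: str) -> pd.DataFrame:
        sel = self.values.loc[self.groups == group]
        if sel.empty:
            raise KeyError(f"no animals in group {group!r}")
        return sel

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="animal_id")

    @classmethod
    def from_csv(cls, path) -> "ROITable":
        df = pd.read_csv(path, index_col="animal_id")
        if "group" not in df.columns:
            raise ValueError("ROI table CSV must contain a 'group' column")
        groups = df.pop("group")
        return cls(values=df.astype(float), groups=groups)


def extract_roi_means(
    volumes: Iterable[AnimalVolume],
    layout: ROILayout,
    masks: dict[str, np.ndarray] | None = None,
    average_hemispheres: bool = False,
) -> ROITable:
    """Extract each animal's mean intensity over every ROI footprint.

    Parameters
    ----------
    volumes : iterable of AnimalVolume
        Co-registered, preprocessed volumes.
    layout : ROILayout
        The ROI series; column order of the result follows it.
    masks : dict, optional
        Per-animal boolean brain masks.  A footprint partially outside
        the mask triggers a warning (with the voxel count); a fully
        masked footprint is an error.
    average_hemispheres : bool
        If True, left/right ROI pairs sharing (band, bregma) are
        averaged into a single column named after the pair.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes given")
    rows = {}
    groups = {}
    for vol in volumes:
        mask = None if masks is None else masks.get(vol.animal_id)
        vals = []
        for roi in layout:
            ii, jj, kk = roi_footprint(roi, vol.shape, vol.voxel_size_um)
            if mask is not None:
                inside = mask[ii, jj, kk]
                n_out = int((~inside).sum())
                if n_out == inside.size:
                    raise ValueError(
                        f"ROI {roi.name!r} footprint fully outside brain mask "
                        f"for animal {vol.animal_id!r}"
                    )
                if n_out:
                    warnings.warn(
                        f"ROI {roi.name!r}: {n_out} footprint voxel(s) outside "
                        f"brain mask for animal {vol.animal_id!r}",
                        stacklevel=2,
                    )
            vals.append(float(vol.data[ii, jj, kk].mean()))
        rows[vol.animal_id] = vals
        groups[vol.animal_id] = vol.group
    df = pd.DataFrame.from_dict(rows, orient="index", columns=layout.names)
    table = ROITable(values=df, groups=pd.Series(groups))
    if average_hemispheres:
        table = pool_hemispheres(table, layout)
    return table


def pool_hemispheres(table: ROITable, layout: ROILayout) -> ROITable:
    """Average left/right ROI pairs sharing (band, bregma) into one column."""
    keyed: dict[tuple[str, float], list[str]] = {}
    order: list[tuple[str, float]] = []
    for roi in layout:
        key = (roi.band, round(roi.bregma_mm, 6))
        if key not in keyed:
            keyed[key] = []
            order.append(key)
        keyed[key].append(roi.name)
    cols = {}
    for key in order:
        names = keyed[key]
        label = names[0] if len(names) == 1 else "+".join(names)
        cols[label] = table.values[names].mean(axis=1)
    return ROITable(values=pd.DataFrame(cols), groups=table.groups)
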