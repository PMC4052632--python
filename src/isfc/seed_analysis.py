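"""Seed-based voxelwise correlation mapping with cluster extent filtering.

For each in-mask voxel the Pearson correlation across animals between
the seed region's mean intensity and the voxel intensity is computed;
positive and negative effects are assessed separately as one-tailed
tests at the voxel level, then filtered by a minimum cluster extent
under a configurable lattice connectivity (6/18/26).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import AnimalVolume

__all__ = [
    "SeedDef",
    "StatMap",
    "seed_correlation_map",
    "label_components",
    "threshold_and_extent_filter",
    "summarize_clusters",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SeedDef:
    """A seed region given as an explicit boolean voxel mask."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed {self.name!r} has an empty voxel set")

    @classmethod
    def from_box(cls, name: str, shape, lo, hi) -> "SeedDef":
        """Axis-aligned box seed with corners ``lo`` (inclusive) and ``hi`` (exclusive)."""
        if any(l < 0 or h > s or l >= h for l, h, s in zip(lo, hi, shape)):
            raise ValueError(f"seed box {lo}..{hi} outside volume bounds {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return cls(name=name, mask=mask)

    def mean_value(self, volume: AnimalVolume) -> float:
        if self.mask.shape != volume.shape:
            raise ValueError(
                f"seed {self.name!r} mask shape {self.mask.shape} does not match "
                f"volume shape {volume.shape}"
            )
        return float(volume.data[self.mask].mean())


@dataclass
class StatMap:
    """Voxelwise seed-correlation statistics for one group and seed.

    ``p_pos``/``p_neg`` are one-tailed p-value volumes for positive and
    negative effects.  After thresholding, ``cluster_labels`` holds
    signed integer labels (positive clusters +1, +2, …; negative −1,
    −2, …) and ``clusters`` one record per surviving cluster.
    """

    r: np.ndarray
    t: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    n: int
    group: str
    seed_name: str
    cluster_labels: np.ndarray | None = None
    clusters: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def seed_correlation_map(
    volumes: list[AnimalVolume],
    seed: SeedDef,
    brain_mask: np.ndarray | None = None,
) -> StatMap:
    """Correlate every in-mask voxel with the per-animal seed means.

    All volumes must belong to one group and be co-registered and
    proportionally scaled.  Voxels constant across animals (or outside
    the brain mask) are flagged undefined (NaN).
    """
    if len(volumes) < 4:
        raise ValueError(f"need at least 4 animals, got {len(volumes)}")
    groups = {v.group for v in volumes}
    if len(groups) != 1:
        raise ValueError(f"volumes span multiple groups: {sorted(groups)}")
    shape = volumes[0].shape
    if any(v.shape != shape for v in volumes):
        raise ValueError("volumes are not co-registered (shapes differ)")
    n = len(volumes)
    seed_vals = np.array([seed.mean_value(v) for v in volumes])
    if seed_vals.std() == 0:
        raise ValueError(f"seed {seed.name!r} mean is constant across animals")
    stack = np.stack([v.data for v in volumes])  # (n, *shape)
    sc = seed_vals - seed_vals.mean()
    vc = stack - stack.mean(axis=0)
    cov = np.tensordot(sc, vc, axes=(0, 0)) / n
    vsd = vc.std(axis=0)
    ssd = sc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (ssd * vsd)
    r = np.clip(r, -1.0, 1.0)
    r[vsd == 0] = np.nan
    if brain_mask is not None:
        r[~np.asarray(brain_mask, dtype=bool)] = np.nan
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.clip(r, -0.9999999999, 0.9999999999)
        t = rr * np.sqrt(df / (1.0 - rr**2))
        p_pos = stats.t.sf(t, df)
        p_neg = stats.t.cdf(t, df)
    return StatMap(
        r=r, t=t, p_pos=p_pos, p_neg=p_neg, n=n, group=volumes[0].group, seed_name=seed.name
    )


def label_components(binary: np.ndarray, connectivity: int = 18) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a 3D binary field.

    ``connectivity`` is the 3D lattice neighborhood: 6 (faces), 18
    (faces + edges) or 26 (faces + edges + corners).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, count = ndimage.label(np.asarray(binary, dtype=bool), structure=structure)
    return labels, int(count)


def threshold_and_extent_filter(
    smap: StatMap, alpha: float = 0.05, k: int = 100, connectivity: int = 18
) -> StatMap:
    """Voxel-level threshold plus minimum-cluster-extent filter.

    Positive and negative one-tailed suprathreshold masks are labeled
    separately; components smaller than ``k`` voxels are discarded.
    Surviving clusters get signed labels and are recorded (sign, size,
    peak |t|) in ``clusters``, ordered by descending size within sign.
    """
    if k < 1:
        raise ValueError(f"extent threshold k must be >= 1, got {k}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    out_labels = np.zeros(smap.r.shape, dtype=np.int32)
    clusters: list[dict] = []
    for sign, pvol in ((1, smap.p_pos), (-1, smap.p_neg)):
        with np.errstate(invalid="ignore"):
            supra = (pvol < alpha) & ~np.isnan(smap.r)
        comp, count = label_components(supra, connectivity)
        if count == 0:
            continue
        sizes = np.bincount(comp.ravel(), minlength=count + 1)
        keep = [lab for lab in range(1, count + 1) if sizes[lab] >= k]
        keep.sort(key=lambda lab: -sizes[lab])
        for rank, lab in enumerate(keep, start=1):
            where = comp == lab
            out_labels[where] = sign * rank
            tvals = smap.t[where]
            peak_flat = np.nanargmax(np.abs(tvals))
            peak_idx = tuple(int(c[peak_flat]) for c in np.nonzero(where))
            clusters.append(
                {
                    "label": sign * rank,
                    "sign": sign,
                    "size": int(sizes[lab]),
                    "peak_t": float(tvals[peak_flat]),
                    "peak_ijk": peak_idx,
                }
            )
    return StatMap(
        r=smap.r,
        t=smap.t,
        p_pos=smap.p_pos,
        p_neg=smap.p_neg,
        n=smap.n,
        group=smap.group,
        seed_name=smap.seed_name,
        cluster_labels=out_labels,
        clusters=clusters,
        params={"alpha": alpha, "k": k, "connectivity": connectivity},
    )


def summarize_clusters(
    smap: StatMap, label_volume: np.ndarray, region_names: dict[int, str] | None = None
) -> pd.DataFrame:
    """Region-level summary of thresholded clusters against an atlas.

    One row per (cluster, overlapped region): region name, cluster
    sign, overlapping voxel count, peak |t| within the overlap and its
    voxel coordinates.  Rows are sorted by cluster then descending
    overlap.  Unlabeled (0) atlas voxels appear as region
    ``"unlabeled"``.
    """
    if smap.cluster_labels is None:
        raise ValueError("StatMap is not thresholded; run threshold_and_extent_filter first")
    label_volume = np.asarray(label_volume)
    if label_volume.shape != smap.cluster_labels.shape:
        raise ValueError(
            f"atlas label volume shape {label_volume.shape} does not match "
            f"map shape {smap.cluster_labels.shape}"
        )
    region_names = region_names or {}
    rows = []
    for cluster in smap.clusters:
        where = smap.cluster_labels == cluster["label"]
        regions = label_volume[where]
        for region_label in np.unique(regions):
            sel = where & (label_volume == region_label)
            tvals = smap.t[sel]
            peak_flat = int(np.nanargmax(np.abs(tvals)))
            coords = np.nonzero(sel)
            rows.append(
                {
                    "cluster": cluster["label"],
                    "sign": cluster["sign"],
                    "region": region_names.get(int(region_label))
                    or ("unlabeled" if region_label == 0 else f"region{int(region_label)}"),
                    "overlap_voxels": int(sel.sum()),
                    "peak_abs_t": float(np.abs(tvals[peak_flat])),
                    "peak_i": int(coords[0][peak_flat]),
                    "peak_j": int(coords[1][peak_flat]),
                    "peak_k": int(coords[2][peak_flat]),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "sign",
            "region",
            "overlap_voxels",
            "peak_abs_t",
            "peak_i",
            "peak_j",
            "peak_k",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["cluster", "overlap_voxels"], ascending=[True, False], ignore_index=True
        )
    return df
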