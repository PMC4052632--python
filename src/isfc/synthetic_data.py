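"""Synthetic cohorts with planted block-correlation structure.

Every downstream stage of the pipeline is validated against cohorts
generated here, because the planted covariance is known exactly.  A
cohort consists of two groups of animals; each group's ROI signal
vectors are drawn from a multivariate normal whose correlation matrix
has a configurable block structure (clusters of ROIs correlated at
``within_block_r``, everything else at ``between_block_r``), then
multiplied by a per-animal log-normal "dose" factor emulating global
tracer differences.  Signals can be rendered into full 3D volumes so
the image stages (masking, scaling, smoothing, extraction) can be
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .roi_sampling import ROIDef, ROILayout, bregma_to_slice, plan_midline_slices, roi_footprint
from .volume import AnimalVolume

__all__ = [
    "CohortSpec",
    "block_correlation_matrix",
    "sample_group_signals",
    "sample_dose_factors",
    "render_volumes",
    "make_label_volume",
    "default_layout",
    "default_cohort",
    "make_seed_cohort",
    "DEFAULT_SHAPE",
    "DEFAULT_VOXEL_UM",
]

DEFAULT_VOXEL_UM = (40.0, 140.0, 40.0)
DEFAULT_SHAPE = (64, 44, 48)
DEFAULT_FIRST_PLANE_BREGMA = 2.98


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a two-group synthetic cohort.

    ``block_assignment`` maps each group label to a length-``roi_count``
    sequence of cluster labels; ROIs sharing a label correlate at
    ``within_block_r``, ROIs in different clusters at
    ``between_block_r``.  The implied correlation matrix must be
    positive semi-definite; non-PSD targets are rejected at
    construction (never repaired), so the planted ground truth is exact.
    """

    n_per_group: Mapping[str, int]
    roi_count: int
    block_assignment: Mapping[str, Sequence[str]]
    within_block_r: float = 0.8
    between_block_r: float = 0.0
    global_scale_sd: float = 0.0
    voxel_noise_sd: float = 0.1
    signal_mean: float = 1.0
    signal_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for r, label in ((self.within_block_r, "within_block_r"), (self.between_block_r, "between_block_r")):
            if not -1.0 < r < 1.0:
                raise ValueError(f"{label} must lie in (-1, 1), got {r}")
        if self.global_scale_sd < 0 or self.voxel_noise_sd < 0 or self.signal_sd <= 0:
            raise ValueError("scale/noise SDs must be non-negative and signal_sd positive")
        for group, n in self.n_per_group.items():
            if n < 4:
                raise ValueError(f"group {group!r} needs at least 4 animals, got {n}")
        for group in self.n_per_group:
            if group not in self.block_assignment:
                raise ValueError(f"no block assignment for group {group!r}")
            labels = self.block_assignment[group]
            if len(labels) != self.roi_count:
                raise ValueError(
                    f"group {group!r}: block assignment length {len(labels)} "
                    f"!= roi_count {self.roi_count}"
                )
            corr = block_correlation_matrix(
                labels, self.within_block_r, self.between_block_r
            )
            w = np.linalg.eigvalsh(corr)
            if w.min() < -1e-8:
                blocks = sorted(set(labels))
                raise ValueError(
                    f"target correlation matrix for group {group!r} is not positive "
                    f"semi-definite (min eigenvalue {w.min():.3e}); offending blocks: {blocks} "
                    f"with within_block_r={self.within_block_r}, "
                    f"between_block_r={self.between_block_r}"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)

    def correlation_matrix(self, group: str) -> np.ndarray:
        """Target (planted) ROI correlation matrix for ``group``."""
        return block_correlation_matrix(
            self.block_assignment[group], self.within_block_r, self.between_block_r
        )

    def planted_labels(self, group: str) -> np.ndarray:
        """Ground-truth cluster label per ROI for ``group``."""
        return np.asarray(self.block_assignment[group])


def block_correlation_matrix(
    labels: Sequence[str], within_r: float, between_r: float
) -> np.ndarray:
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def sample_dose_factors(spec: CohortSpec, group: str) -> np.ndarray:
    """Per-animal multiplicative dose factors exp(N(0, global_scale_sd²))."""
    rng = substream(spec.seed, f"dose:{group}")
    return np.exp(rng.normal(0.0, spec.global_scale_sd, spec.n_per_group[group]))


def sample_group_signals(
    spec: CohortSpec,
    group: str,
    roi_names: Sequence[str] | None = None,
    apply_dose: bool = True,
) -> pd.DataFrame:
    """Draw one ROI-signal row per animal of ``group``.

    Rows are i.i.d. N(signal_mean, signal_sd² · C) where C is the
    group's planted block correlation matrix; each row is then
    multiplied by that animal's global dose factor (unless
    ``apply_dose=False``, e.g. when dose scaling is applied at the
    volume level instead).  Deterministic given (spec, seed).
    """
    if group not in spec.n_per_group:
        raise KeyError(f"group {group!r} not defined in spec (have {spec.groups})")
    n = spec.n_per_group[group]
    corr = spec.correlation_matrix(group)
    # jitter keeps Cholesky stable when the target is exactly singular
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(spec.roi_count))
    rng = substream(spec.seed, f"signals:{group}")
    z = rng.standard_normal((n, spec.roi_count))
    signals = spec.signal_mean + spec.signal_sd * (z @ chol.T)
    if apply_dose and spec.global_scale_sd > 0:
        signals = signals * sample_dose_factors(spec, group)[:, None]
    if roi_names is None:
        roi_names = [f"roi{i:03d}" for i in range(spec.roi_count)]
    index = [f"{group}{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(signals, index=index, columns=list(roi_names))


def _brain_ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    # elongated along the anteroposterior axis (clipped by the volume) so
    # that ROI slices near both ends stay inside the brain
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.array([0.45, 0.75, 0.45]) * np.asarray(shape)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return q <= 1.0


def render_volumes(
    signals: pd.DataFrame,
    layout: ROILayout,
    spec: CohortSpec,
    group: str,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_UM,
    first_plane_bregma: float = DEFAULT_FIRST_PLANE_BREGMA,
    dose_scales: np.ndarray | None = None,
) -> list[AnimalVolume]:
    """Render each signal row into a 3D volume.

    Volume = baseline (1.0 inside a brain ellipsoid, 0 outside) + each
    ROI's signal over its circular footprint, optionally multiplied by a
    per-animal dose factor, + i.i.d. Gaussian voxel noise.  Negative
    values (possible in noise tails) are clipped to 0 to respect the
    non-negativity of optical densities.
    """
    missing = [r.name for r in layout if r.name not in signals.columns]
    if missing:
        raise ValueError(f"signal table lacks columns for layout ROIs: {missing}")
    if dose_scales is not None and len(dose_scales) != len(signals):
        raise ValueError("dose_scales length must match the number of animals")
    footprints = [roi_footprint(roi, shape, voxel_size_um) for roi in layout]
    baseline = _brain_ellipsoid(shape).astype(np.float64)
    rng = substream(spec.seed, f"render:{group}")
    volumes = []
    for row_pos, (animal_id, row) in enumerate(signals.iterrows()):
        data = baseline.copy()
        for roi, (ii, jj, kk) in zip(layout, footprints):
            data[ii, jj, kk] += row[roi.name]
        if dose_scales is not None:
            data = data * float(dose_scales[row_pos])
        if spec.voxel_noise_sd > 0:
            data = data + rng.normal(0.0, spec.voxel_noise_sd, shape)
        np.clip(data, 0.0, None, out=data)
        volumes.append(
            AnimalVolume(
                animal_id=str(animal_id),
                group=group,
                data=data,
                voxel_size_um=voxel_size_um,
                bregma0_mm=first_plane_bregma,
            )
        )
    return volumes


def make_label_volume(
    layout: ROILayout,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_UM,
) -> np.ndarray:
    """Integer volume with each ROI footprint carrying a unique label.

    Label of layout ROI ``i`` is ``i + 1``; background is 0.  Overlapping
    footprints are an error naming the colliding pair.
    """
    labels = np.zeros(shape, dtype=np.int32)
    for i, roi in enumerate(layout):
        ii, jj, kk = roi_footprint(roi, shape, voxel_size_um)
        occupied = labels[ii, jj, kk]
        if np.any(occupied):
            other = layout[int(occupied[occupied > 0][0]) - 1]
            raise ValueError(
                f"ROI footprints overlap: {roi.name!r} collides with {other.name!r}"
            )
        labels[ii, jj, kk] = i + 1
    return labels


def default_layout(
    start_bregma: float = 2.56,
    end_bregma: float = -2.48,
    spacing_mm: float = 0.14,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_UM,
    first_plane_bregma: float = DEFAULT_FIRST_PLANE_BREGMA,
    diameter_um: float = 100.0,
    hemisphere: str = "right",
    dv_offset_voxels: int = 10,
) -> ROILayout:
    """Two-band midline ROI series: one dorsal + one ventral ROI per slice.

    Defaults mirror the standard geometry: 37 slices from bregma +2.56
    to −2.48 mm at 0.14 mm spacing, 100 μm ROIs, 40 × 140 × 40 μm
    voxels, first plane at bregma +2.98 mm — giving 74 ROIs in total.
    """
    positions = plan_midline_slices(start_bregma, end_bregma, spacing_mm)
    ci = shape[0] // 2
    ck = (shape[2] - 1) / 2.0
    centers_k = {"dorsal": int(round(ck)) + dv_offset_voxels, "ventral": int(round(ck)) - dv_offset_voxels}
    rois = []
    for band in ("dorsal", "ventral"):
        for idx, bregma in enumerate(positions):
            j = bregma_to_slice(bregma, first_plane_bregma, spacing_mm, n_planes=shape[1])
            rois.append(
                ROIDef(
                    name=f"{'D' if band == 'dorsal' else 'V'}{idx + 1:02d}",
                    band=band,
                    hemisphere=hemisphere,
                    bregma_mm=float(bregma),
                    center=(ci, j, centers_k[band]),
                    diameter_um=diameter_um,
                )
            )
    return ROILayout(rois, spacing_mm=spacing_mm)


def _preset_blocks(layout: ROILayout, preset: str, anterior_cut_mm: float = 0.0) -> list[str]:
    """Planted cluster label per layout ROI.

    ``control_like``: two clusters — anterior vs posterior, each spanning
    both dorsal and ventral bands (dorsal–ventral coupling within a
    cluster).  ``fear_like``: three clusters — anterior (both bands),
    posterior-dorsal, posterior-ventral.
    """
    labels = []
    for roi in layout:
        anterior = roi.bregma_mm > anterior_cut_mm
        if preset == "control_like":
            labels.append("anterior" if anterior else "posterior")
        elif preset == "fear_like":
            if anterior:
                labels.append("anterior")
            else:
                labels.append("posterior_dorsal" if roi.band == "dorsal" else "posterior_ventral")
        else:
            raise ValueError(f"unknown preset {preset!r} (use 'control_like' or 'fear_like')")
    return labels


def default_cohort(
    seed: int = 0,
    n_control: int = 11,
    n_fear: int = 13,
    within_block_r: float = 0.8,
    between_block_r: float = 0.0,
    global_scale_sd: float = 0.0,
    voxel_noise_sd: float = 0.1,
    layout: ROILayout | None = None,
    **spec_overrides,
) -> tuple[CohortSpec, ROILayout]:
    """Standard two-group cohort.

    The ``control`` group carries the control_like planted structure
    (anterior + posterior clusters), the ``fear`` group the fear_like
    structure (anterior + posterior-dorsal + posterior-ventral).
    """
    if layout is None:
        layout = default_layout()
    spec = CohortSpec(
        n_per_group={"control": n_control, "fear": n_fear},
        roi_count=len(layout),
        block_assignment={
            "control": _preset_blocks(layout, "control_like"),
            "fear": _preset_blocks(layout, "fear_like"),
        },
        within_block_r=within_block_r,
        between_block_r=between_block_r,
        global_scale_sd=global_scale_sd,
        voxel_noise_sd=voxel_noise_sd,
        seed=seed,
        **spec_overrides,
    )
    return spec, layout


def _box_mask(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


def make_seed_cohort(
    n: int = 12,
    shape: tuple[int, int, int] = (40, 30, 30),
    coupling_r: float = 0.9,
    signal_sd: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    group: str = "control",
) -> dict:
    """Cohort with a seed region plus one coupled and one anti-coupled region.

    Per animal: latent s ~ N(0,1); seed-region voxels carry
    1 + signal_sd·s, region A carries 1 + signal_sd·(ρ·s + √(1−ρ²)·a)
    (positively coupled), region B the negated coupled signal
    (anti-coupled).  All regions sit inside a baseline-1 brain ellipsoid
    with additive voxel noise.  The seed box is kept below 100 voxels so
    it cannot itself survive the default extent threshold.

    Returns a dict with ``volumes``, boolean masks ``seed_mask``,
    ``region_pos``, ``region_neg``, and the latent ``seed_signal``.
    """
    rng = np.random.default_rng(seed)
    seed_mask = _box_mask(shape, (4, 4, 4), (8, 8, 8))  # 64 voxels < extent threshold
    region_pos = _box_mask(shape, (26, 6, 6), (32, 11, 12))  # 6*5*6 = 180 voxels
    region_neg = _box_mask(shape, (26, 18, 18), (32, 23, 24))  # 180 voxels
    assert not (seed_mask & region_pos).any() and not (region_pos & region_neg).any()
    baseline = _brain_ellipsoid(shape) | seed_mask | region_pos | region_neg
    s = rng.standard_normal(n)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    mix = np.sqrt(1.0 - coupling_r**2)
    sig_pos = coupling_r * s + mix * a
    sig_neg = -(coupling_r * s + mix * b)
    volumes = []
    for i in range(n):
        data = baseline.astype(np.float64)
        data[seed_mask] += signal_sd * s[i]
        data[region_pos] += signal_sd * sig_pos[i]
        data[region_neg] += signal_sd * sig_neg[i]
        data += rng.normal(0.0, noise_sd, shape)
        np.clip(data, 0.0, None, out=data)
        volumes.append(
            AnimalVolume(
                animal_id=f"{group}{i + 1:02d}",
                group=group,
                data=data,
                voxel_size_um=DEFAULT_VOXEL_UM,
            )
        )
    return {
        "volumes": volumes,
        "seed_mask": seed_mask,
        "region_pos": region_pos,
        "region_neg": region_neg,
        "seed_signal": s,
        "brain_mask": baseline,
    }
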