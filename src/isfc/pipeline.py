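"""Config-driven orchestration of the full analysis pipeline.

Stages run in order: synthesize/load → preprocess → extract → pairwise
FC stats → graph analysis → seed analysis → exports.  Every run writes
the resolved configuration and a manifest listing each artifact with a
SHA-256 checksum; identical config + seed reproduce identical checksums
for the deterministic stages.  A stage failure aborts the run with the
stage name and moves partial outputs under a ``failed/`` prefix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fc_stats, graph_analysis, preprocess, reporting, roi_sampling, seed_analysis
from . import synthetic_data as synth
from .volume import load_volume, save_label_volume, save_volume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "export_reports"]

_MODES = ("synthetic", "volumes", "roi-table")
_PRESETS = ("control_like", "fear_like", "both")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated run configuration (unknown keys are rejected)."""

    mode: str = "synthetic"
    outdir: str = "isfc_out"
    seed: int = 0
    # synthetic mode
    preset: str = "both"
    n_control: int = 11
    n_fear: int = 13
    within_block_r: float = 0.8
    between_block_r: float = 0.0
    global_scale_sd: float = 0.0
    voxel_noise_sd: float = 0.1
    render_volumes: bool = False
    # volumes mode
    cohort_manifest: str | None = None
    layout_path: str | None = None
    # roi-table mode
    roi_table_path: str | None = None
    scale_roi_table: bool = False
    # preprocessing
    mask_fraction: float = 0.8
    fwhm_um: tuple[float, float, float] = (120.0, 420.0, 120.0)
    target_mean: float = 100.0
    smooth_before_mask: bool = True
    average_hemispheres: bool = False
    # statistics
    alpha: float = 0.05
    diff_alpha: float = 0.05
    # graph
    linkage: str = "average"
    cut_k: dict = field(default_factory=lambda: {"control": 2, "fear": 3})
    layout_seed_offset: int = 0
    # seed analysis
    seeds: list = field(default_factory=list)  # [{"name":..., "lo":[i,j,k], "hi":[i,j,k]}]
    extent_k: int = 100
    connectivity: int = 18

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.preset not in _PRESETS:
            raise ValueError(f"preset must be one of {_PRESETS}, got {self.preset!r}")
        for name in ("alpha", "diff_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.mask_fraction <= 0:
            raise ValueError("mask_fraction must be positive")
        if self.extent_k < 1:
            raise ValueError("extent_k must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.mode == "volumes" and not self.cohort_manifest:
            raise ValueError("volumes mode needs cohort_manifest")
        if self.mode == "roi-table" and not self.roi_table_path:
            raise ValueError("roi-table mode needs roi_table_path")
        self.fwhm_um = tuple(float(f) for f in np.atleast_1d(self.fwhm_um))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fwhm_um"] = list(self.fwhm_um)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}
    state: dict = {}

    def record(path: Path):
        artifacts.append(path)

    stages = [
        ("load", _stage_load),
        ("preprocess_extract", _stage_preprocess_extract),
        ("fc", _stage_fc),
        ("graph", _stage_graph),
        ("seed", _stage_seed),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config, outdir, state, record)
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            for p in artifacts:
                if p.exists() and failed not in p.parents:
                    target = failed / p.relative_to(outdir)
                    target.parent.mkdir(parents=True, exist_ok=True)
                    shutil.move(str(p), str(target))
            raise PipelineError(name, str(exc)) from exc
        timings[name] = round(time.perf_counter() - t0, 4)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    record(outdir / "config.yaml")
    manifest = {
        "config": config.to_dict(),
        "timings_s": timings,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------- stages


def _stage_load(config, outdir, state, record):
    if config.mode == "synthetic":
        spec, layout = synth.default_cohort(
            seed=config.seed,
            n_control=config.n_control,
            n_fear=config.n_fear,
            within_block_r=config.within_block_r,
            between_block_r=config.between_block_r,
            global_scale_sd=config.global_scale_sd,
            voxel_noise_sd=config.voxel_noise_sd,
        )
        state["spec"], state["layout"] = spec, layout
        layout.to_csv(outdir / "layout.csv")
        record(outdir / "layout.csv")
        if config.preset == "both":
            groups = ["control", "fear"]
        else:
            groups = ["control" if config.preset == "control_like" else "fear"]
        state["groups"] = groups
        if config.render_volumes:
            voldir = outdir / "volumes"
            voldir.mkdir(exist_ok=True)
            volumes, rows = [], []
            for group in groups:
                signals = synth.sample_group_signals(spec, group, roi_names=layout.names)
                for vol in synth.render_volumes(signals, layout, spec, group):
                    volumes.append(vol)
                    path = voldir / f"{vol.animal_id}.nii"
                    save_volume(vol, path)
                    record(path)
                    rows.append(
                        {"animal_id": vol.animal_id, "group": group, "file": str(path.name)}
                    )
            pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
            record(outdir / "cohort.csv")
            state["volumes"] = volumes
        else:
            frames, groups_s = [], {}
            for group in groups:
                signals = synth.sample_group_signals(spec, group, roi_names=layout.names)
                frames.append(signals)
                groups_s.update({a: group for a in signals.index})
            values = pd.concat(frames)
            if config.global_scale_sd > 0:
                values = preprocess.scale_roi_table(values, config.target_mean)
            state["roi_table"] = roi_sampling.ROITable(
                values=values, groups=pd.Series(groups_s)
            )
    elif config.mode == "volumes":
        manifest = pd.read_csv(config.cohort_manifest)
        base = Path(config.cohort_manifest).parent
        volumes = [
            load_volume(base / row["file"], str(row["animal_id"]), str(row["group"]))
            for _, row in manifest.iterrows()
        ]
        state["volumes"] = volumes
        state["groups"] = list(dict.fromkeys(manifest["group"].astype(str)))
        if config.layout_path:
            state["layout"] = roi_sampling.ROILayout.from_csv(config.layout_path)
    else:  # roi-table
        state["roi_table"] = roi_sampling.ROITable.from_csv(config.roi_table_path)
        if config.scale_roi_table:
            state["roi_table"] = roi_sampling.ROITable(
                values=preprocess.scale_roi_table(
                    state["roi_table"].values, config.target_mean
                ),
                groups=state["roi_table"].groups,
            )
        state["groups"] = state["roi_table"].group_names
        if config.layout_path:
            state["layout"] = roi_sampling.ROILayout.from_csv(config.layout_path)


def _stage_preprocess_extract(config, outdir, state, record):
    if "volumes" not in state:
        return  # table input modes skip the image stages
    processed, masks, prov = [], {}, []
    for vol in state["volumes"]:
        scaled, mask, p = preprocess.preprocess_volume(
            vol,
            mask_fraction=config.mask_fraction,
            fwhm_um=config.fwhm_um,
            target_mean=config.target_mean,
            smooth_before_mask=config.smooth_before_mask,
        )
        processed.append(scaled)
        masks[vol.animal_id] = mask.data
        prov.append(p)
    state["volumes"] = processed
    state["masks"] = masks
    with open(outdir / "preprocess.json", "w") as fh:
        json.dump(prov, fh, indent=2)
    record(outdir / "preprocess.json")
    if "layout" in state:
        table = roi_sampling.extract_roi_means(
            processed,
            state["layout"],
            masks=masks,
            average_hemispheres=config.average_hemispheres,
        )
        state["roi_table"] = table


def _stage_fc(config, outdir, state, record):
    if "roi_table" not in state:
        return
    table = state["roi_table"]
    table.to_csv(outdir / "roi_table.csv")
    record(outdir / "roi_table.csv")
    fcs = {}
    for group in state["groups"]:
        fc = fc_stats.pairwise_correlation_matrix(table.group_values(group), alpha=config.alpha)
        fcs[group] = fc
        for which in ("r", "z", "p", "sig"):
            path = outdir / f"fc_{group}_{which}.csv"
            fc.to_csv(path, which)
            record(path)
    state["fc"] = fcs
    if len(state["groups"]) == 2:
        a, b = state["groups"]
        comparison = fc_stats.compare_groups(fcs[a], fcs[b], alpha=config.diff_alpha)
        state["comparison"] = comparison
        for which in ("zdiff", "p", "sig"):
            path = outdir / f"comparison_{which}.csv"
            comparison.to_csv(path, which)
            record(path)


def _stage_graph(config, outdir, state, record):
    if "fc" not in state:
        return
    graphs, dendros, layouts = {}, {}, {}
    for group, fc in state["fc"].items():
        g = graph_analysis.build_fc_graph(fc)
        graphs[group] = g
        graph_analysis.write_pajek(g, outdir / f"graph_{group}.net")
        record(outdir / f"graph_{group}.net")
        graph_analysis.write_graphml(g, outdir / f"graph_{group}.graphml")
        record(outdir / f"graph_{group}.graphml")
        degrees = graph_analysis.degree_centrality(g)
        pd.DataFrame(
            {"roi": fc.roi_names, "degree": [degrees[i] for i in range(fc.n_rois)]}
        ).to_csv(outdir / f"degrees_{group}.csv", index=False)
        record(outdir / f"degrees_{group}.csv")
        if fc.n_rois >= 3:
            d1 = graph_analysis.d1_dissimilarity_matrix(g)
            pd.DataFrame(d1, index=fc.roi_names, columns=fc.roi_names).to_csv(
                outdir / f"d1_{group}.csv"
            )
            record(outdir / f"d1_{group}.csv")
            dend = graph_analysis.hierarchical_clustering(
                d1, labels=fc.roi_names, method=config.linkage
            )
            dendros[group] = dend
            with open(outdir / f"dendrogram_{group}.newick", "w") as fh:
                fh.write(dend.to_newick() + "\n")
            record(outdir / f"dendrogram_{group}.newick")
        lay = graph_analysis.kamada_kawai_layout(
            g, seed=config.seed + config.layout_seed_offset
        )
        layouts[group] = lay
        pd.DataFrame(
            {"roi": fc.roi_names, "x": lay.coords[:, 0], "y": lay.coords[:, 1]}
        ).to_csv(outdir / f"layout_{group}.csv", index=False)
        record(outdir / f"layout_{group}.csv")
    state["graphs"], state["dendrograms"], state["layouts"] = graphs, dendros, layouts


def _stage_seed(config, outdir, state, record):
    if not config.seeds or "volumes" not in state:
        return
    by_group: dict[str, list] = {}
    for vol in state["volumes"]:
        by_group.setdefault(vol.group, []).append(vol)
    shape = state["volumes"][0].shape
    label_vol = None
    if "layout" in state:
        label_vol = synth.make_label_volume(state["layout"], shape)
        save_label_volume(label_vol, state["volumes"][0].voxel_size_um, outdir / "labels.nii")
        record(outdir / "labels.nii")
    for group, vols in by_group.items():
        common_mask = np.logical_and.reduce([state["masks"][v.animal_id] for v in vols])
        for seed_cfg in config.seeds:
            sd = seed_analysis.SeedDef.from_box(
                seed_cfg["name"], shape, seed_cfg["lo"], seed_cfg["hi"]
            )
            smap = seed_analysis.seed_correlation_map(vols, sd, brain_mask=common_mask)
            smap = seed_analysis.threshold_and_extent_filter(
                smap, alpha=config.alpha, k=config.extent_k, connectivity=config.connectivity
            )
            stem = f"seedmap_{group}_{sd.name}"
            if label_vol is not None:
                names = {i + 1: roi.name for i, roi in enumerate(state["layout"])}
                table = seed_analysis.summarize_clusters(smap, label_vol, names)
            else:
                table = seed_analysis.summarize_clusters(
                    smap, np.zeros(shape, dtype=np.int32)
                )
            table.to_csv(outdir / f"{stem}_clusters.csv", index=False)
            record(outdir / f"{stem}_clusters.csv")
            with open(outdir / f"{stem}_provenance.json", "w") as fh:
                json.dump({"group": group, "seed": sd.name, "n": smap.n, **smap.params}, fh)
            record(outdir / f"{stem}_provenance.json")
            state.setdefault("seed_maps", {})[(group, sd.name)] = smap


def export_reports(outdir, manifest: dict | None = None, cut_k: dict | None = None) -> list[str]:
    """Regenerate all figure exports from a completed run directory.

    Reads the run's CSV artifacts (missing ones raise an error naming
    the artifact) and writes PNG figures next to them.  Returns the list
    of files written.
    """
    outdir = Path(outdir)
    if manifest is None:
        mpath = outdir / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(f"missing run artifact: {mpath}")
        with open(mpath) as fh:
            manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    cut_k = cut_k or config.cut_k
    groups = []
    for name in manifest["artifacts"]:
        if name.startswith("fc_") and name.endswith("_r.csv"):
            groups.append(name[len("fc_") : -len("_r.csv")])
    groups.sort()
    written: list[str] = []

    def need(name: str) -> Path:
        p = outdir / name
        if not p.exists():
            raise FileNotFoundError(f"missing run artifact: {p}")
        return p

    def load_mat(name: str) -> np.ndarray:
        return pd.read_csv(need(name), index_col=0).to_numpy(dtype=float)

    if len(groups) == 2:
        a, b = groups
        reporting.plot_heatmap_panels(
            load_mat(f"fc_{a}_z.csv"),
            load_mat(f"fc_{a}_sig.csv"),
            load_mat(f"fc_{b}_z.csv"),
            load_mat(f"fc_{b}_sig.csv"),
            load_mat("comparison_zdiff.csv"),
            load_mat("comparison_sig.csv"),
            outdir / "heatmaps.png",
            group_names=(a, b),
        )
        written.append("heatmaps.png")
    bands = None
    if (outdir / "layout.csv").exists():
        bands = list(pd.read_csv(outdir / "layout.csv")["band"])
    for group in groups:
        d1_name = f"d1_{group}.csv"
        if d1_name in manifest["artifacts"]:
            d1_df = pd.read_csv(need(d1_name), index_col=0)
            dend = graph_analysis.hierarchical_clustering(
                d1_df.to_numpy(dtype=float), labels=list(d1_df.columns), method=config.linkage
            )
            reporting.plot_dendrogram(
                dend, outdir / f"dendrogram_{group}.png", cut_k=cut_k.get(group)
            )
            written.append(f"dendrogram_{group}.png")
        # rebuild the graph from the significance matrix
        sig = pd.read_csv(need(f"fc_{group}_sig.csv"), index_col=0)
        r = pd.read_csv(need(f"fc_{group}_r.csv"), index_col=0)
        import networkx as nx

        g = nx.Graph()
        names = list(sig.columns)
        for i, name in enumerate(names):
            g.add_node(i, name=name, index=i)
        sig_m = sig.to_numpy()
        r_m = r.to_numpy()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if sig_m[i, j] != 0:
                    g.add_edge(i, j, sign=int(sig_m[i, j]), weight=float(r_m[i, j]))
        coords = pd.read_csv(need(f"layout_{group}.csv"))
        lay = graph_analysis.Layout(
            coords=coords[["x", "y"]].to_numpy(dtype=float),
            energy=0.0,
            energies=np.zeros(1),
            nodes=list(range(len(names))),
        )
        reporting.plot_energized_graph(g, lay, outdir / f"graph_{group}.png")
        written.append(f"graph_{group}.png")
        if bands is not None and len(bands) == len(names):
            reporting.plot_circular_graph(g, bands, outdir / f"circular_{group}.png")
            written.append(f"circular_{group}.png")
    return written
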