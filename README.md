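# isfc

Inter-subject functional-connectivity (FC) analysis for cohorts of
co-registered 3D brain volumes (e.g. digitized perfusion
autoradiographs), where FC is the **cross-animal** Pearson correlation
of regional intensities — one observation per animal, not a time
series.

The package implements the full analysis chain:

- **`isfc.synthetic_data`** — synthetic two-group cohorts with planted
  block covariance among midline ROIs (known ground truth for every
  downstream stage), per-animal log-normal dose factors, optional full
  3D volume rendering and atlas-style label volumes.
- **`isfc.preprocess`** — intensity masking (threshold relative to the
  mean voxel value), per-animal proportional scaling to a common mean,
  and anisotropic Gaussian smoothing (FWHM in μm, nearest-edge
  boundary).
- **`isfc.roi_sampling`** — planning of coronal ROI series along the
  anteroposterior axis (bregma coordinates), circular ROI footprints
  with a voxel-centre-in-circle rule, and per-animal ROI mean
  extraction (separate hemispheres or pooled pairs).
- **`isfc.fc_stats`** — per-group ROI×ROI Pearson/Fisher-z/p matrices
  (exact t transform, df = n−2), and the Fisher r-to-z two-sample test
  for between-group correlation differences.
- **`isfc.graph_analysis`** — signed FC graphs (edge ⇔ significant
  correlation), degree centrality, structural-equivalence `d1`
  dissimilarity on signed connection profiles, average-linkage
  hierarchical clustering with Newick export, and a Kamada–Kawai stress
  layout with a strictly non-increasing energy trajectory.
- **`isfc.seed_analysis`** — seed-based voxelwise correlation maps
  (one-tailed positive/negative), cluster extent filtering under
  6/18/26 lattice connectivity, and atlas-label cluster summaries.
- **`isfc.pipeline` / `isfc.cli` / `isfc.reporting`** — config-driven
  orchestration with checksummed run manifests, plus heatmap /
  dendrogram / energized-graph / circular-plot / seed-montage figures.

## CLI

```sh
# full synthetic run: cohort -> FC -> graphs -> figures
isfc run-all --outdir out --seed 1

# or stage by stage
isfc synth --outdir out --seed 1                 # synthetic cohort (+--render for NIfTI volumes)
isfc preprocess --in brain.nii --out brain_pp.nii
isfc extract --cohort cohort.csv --layout layout.csv --out roi_table.csv
isfc fc --roi-table out/roi_table.csv --outdir fc_out
isfc graph --roi-table out/roi_table.csv --outdir graph_out
isfc seed --config config.yaml                   # voxelwise seed maps
isfc report --rundir out                         # regenerate figures
```

`run-all` accepts a YAML config mirroring `isfc.pipeline.PipelineConfig`
(input mode `synthetic` / `volumes` / `roi-table`, preprocessing
parameters, alpha levels, extent threshold, connectivity, linkage,
seeds, RNG seed, output directory). Unknown keys are rejected; the
resolved config and a SHA-256 manifest are written next to the outputs.

## Default geometry

Voxels 40 × 140 × 40 μm (mediolateral × anteroposterior ×
dorsoventral), first coronal plane at bregma +2.98 mm, 100 μm circular
ROIs at 0.14 mm slice spacing, dorsal + ventral bands (74 ROIs). All
of it is overridable per call or via the config.
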