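# projwire

Analysis pipeline for viral-barcode projectome studies of cortical
projection neurons. In these experiments a retrograde tracer virus carrying
a distinct DNA barcode is injected into each downstream nucleus; single-cell
sequencing of the source cortex then yields, per neuron, a barcode UMI
count vector (the projectome readout) alongside its transcriptome and
spatial position. `projwire` takes the resulting cells × barcodes UMI
matrix, expression matrix and cell metadata and carries the analysis from
raw counts to wiring statistics and projection prediction:

1. **Background filtering** (`barcode_processing`) — per-target elbow
   (knee) analysis of the sorted UMI counts on a log scale separates true
   projection signal from ambient background; what survives is a per-cell
   projection intensity and binary profile.
2. **Projection structure** (`projection_structure`) — hierarchical
   clustering of projection profiles into clusters and classes (e.g. a
   pyramidal-tract class and several intratelencephalic classes);
   enumeration of binarized *projection motifs* (distinct target
   combinations) and their enrichment against the independence null
   `E[S] = N·∏_{t∈S} p_t·∏_{t∉S}(1−p_t)` with a two-sided exact binomial
   test and Benjamini–Hochberg correction.
3. **Co-projection wiring** (`coprojection_wiring`) — the φ coefficient
   (Pearson correlation of binary target columns) as the co-projection
   probability; within-class vs across-class rank-sum contrasts; Pearson
   coupling of φ with an external target×target connectivity matrix.
4. **Spatial organization** (`spatial_analysis`) — axis-binned target
   proportions with per-target z-scores (dorsoventral / anteroposterior
   gradient heatmaps), group centroids, region enrichment, and motif-level
   correlation of projection distance with spatial and transcriptomic
   distance.
5. **Co-expression modules** (`coexpression_modules`) — thresholded
   correlation networks on curated gene panels, module detection, hub
   genes, module eigengenes (first PC of the module's standardized
   submatrix), module–projection correlation, and projection-group
   differential expression.
6. **Projection prediction** (`projection_prediction`) — one XGBoost
   binary classifier per target on transcriptome PCs + (x, y, z)
   coordinates, with a 70/30 split, shuffle controls, a
   transcriptome-only ablation, and transfer of the fitted model to
   external spatial-transcriptomic datasets via shared-gene
   standardization into the stored PC space.

A synthetic-data generator (`synthetic_data`) emulates the statistical
structure of such a study — class-structured co-projection via a Gaussian
copula, negative-binomial signal UMIs over Poisson ambient background,
dorsoventral class gradients, and gene modules coupled to projection
intensity — and exports the planted truth, so every stage has a recovery
test with no external data.

## Worked example

```python
import projwire as pw

cfg = pw.SimulationConfig(n_cells=3000)          # 24 targets, 4 classes
ds, truth = pw.simulate_dataset(cfg, seed=1)

profiles = pw.filter_background(ds.barcode)       # elbow background filter
print(pw.multiplicity_summary(profiles)["fraction_multi"])
# 0.676923076923077

table = pw.motif_enrichment(profiles.binary, profiles.target_ids)
print(table[table.label != "not significant"][["signature", "observed", "expected"]].head(3))
#   signature  observed   expected
# 0     SSp-I        42  18.535605
# 1      CP-C        41  15.906571
# 2     BLA-I        39  15.759070

cp = pw.coprojection_matrix(profiles.binary, profiles.target_ids)
contrast = pw.block_contrast(cp.phi, cp.target_ids, ds.targets.class_ids)
print(round(contrast["within_median"], 3), round(contrast["across_median"], 3),
      contrast["p_value"] < 1e-6)
# 0.239 -0.051 True
```

The multi-target fraction (~0.68) reflects the generator's default regime
in which about two-thirds of projecting neurons hit two or more nuclei.
The enrichment table departs from independence in both directions: because
the planted class coupling pushes cells toward firing several same-class
targets together *or* none, exact single-target patterns are also observed
far above the independence expectation. The co-projection contrast shows
within-class target pairs sharing neurons (median φ ≈ 0.24) while
across-class pairs do not (median φ ≈ −0.05).

The same stages are available from the shell:

```bash
projwire simulate --config sim.yaml --seed 1 --out data/
projwire filter   --config analysis.yaml --seed 1 --out out/filter
projwire motifs   --config analysis.yaml --seed 1 --out out/motifs
projwire predict  --config analysis.yaml --seed 1 --out out/predict
```

`analysis.yaml` points at the four dataset files under a `dataset:` key
(see `projwire.core_io` for the on-disk formats); every run writes a
`log.txt` with the package version, seed and input checksums, and repeated
runs with the same seed are byte-identical.

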