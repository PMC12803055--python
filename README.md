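# scembed-eval

Evaluation toolkit for single-cell embedding methods. Given a cell × dimension
embedding matrix with per-cell metadata (cell type, batch, optional spatial
coordinates or perturbation condition), it computes:

- **Zero-shot metrics** — kNN graph + Leiden clustering tuned to a target
  cluster count, partition agreement (ARI, NMI, homogeneity, completeness,
  FMI), silhouette on labels, stratified-CV kNN accuracy, normalized
  cLISI/iLISI, batch-removal adapted silhouette (BRAS), graph connectivity
  and kBET.
- **Spatial-domain metrics** — median marker-gene Moran's I, 1 − Geary's C,
  1 − CHAOS and 1 − PAS on coordinates, labels and counts.
- **Few-shot evaluation** — N-way K-shot episode sampling (serializable so
  multiple methods see byte-identical episodes) and prototypical inference
  with cosine distance and a softmax over negative distances.
- **Probe fine-tuning** — a standardized supervised probe (layer norm →
  dropout → hidden linear + GELU → output, Adam with cosine LR decay, early
  stopping on a stratified validation split) plus the classical HVG+PCA
  baseline fitted strictly on the train split.
- **Perturbation-response prediction** — counterfactual transcriptome
  construction, condition-level embeddings, standardize + PCA + ridge
  regression, an additive single-effect baseline, and L2/Pearson scoring.
- **Reporting** — direction-aware normalization (per dataset × metric column
  maxima), unweighted composite scores and method ranking.

Seeded synthetic fixtures (Gaussian-mixture cell types with batch shifts,
spatial grids with domain markers, additive perturbation designs with a
linear pseudo-embedding) give every metric an oracle-checkable input with no
downloads.

## CLI

```bash
# generate fixtures (h5ad + JSON ground-truth sidecar)
scembed-eval simulate mixture --out mix.h5ad --n-cells 600 --n-types 5 --seed 0
scembed-eval simulate spatial --out grid.h5ad --grid-rows 12 --grid-cols 12
scembed-eval simulate perturb --out pert.h5ad --n-singles 8 --n-doubles 12

# individual stages
scembed-eval zero-shot mix.h5ad --out zero_shot.tsv
scembed-eval spatial grid.h5ad --out spatial.tsv
scembed-eval few-shot mix.h5ad --n-way 5 --k-shot 1 --trials 20 \
    --episodes-file episodes.json --out few_shot.tsv
scembed-eval finetune mix.h5ad --out finetune.tsv
scembed-eval perturb pert.h5ad --out perturb.tsv

# one-command benchmark from a YAML config
scembed-eval run --config config.yaml --outdir benchmark_out
```

Example `config.yaml`:

```yaml
seed: 0
datasets:
  - {name: mix, fixture: mixture, n_cells: 600, n_types: 5, n_batches: 2,
     type_separation: 8.0, batch_shift: 2.0}
  - {name: grid, fixture: spatial, grid_rows: 12, grid_cols: 12}
  - {name: mine, path: my_embeddings.h5ad}     # user data
tasks: [zero_shot, spatial, few_shot]
few_shot: {n_way: 5, k_shot: 1, trials: 20}
```

h5ad conventions: embedding in `obsm["X_emb"]`, counts in `X` or
`layers["counts"]`, labels in `obs["cell_type"]` / `obs["batch"]` /
`obs["condition"]` (`control`, `GENE`, `GENE1+GENE2`), coordinates in
`obsm["spatial"]`. All keys are overridable.

## Notes on metric conventions

- Macro F1 is the harmonic mean of macro precision and macro recall, not the
  average of per-class F1 values reported by some libraries.
- BRAS uses `1 − |ASW_batch|` per cell type so the score stays in [0, 1].
- LISI scores are computed on fixed k-nearest neighborhoods with plug-in
  proportions and normalized by the number of categories; the cell-type
  variant is reported as `1 − normalized` so higher is always better.
- Geary, CHAOS and PAS are reported as `1 − metric`; raw values are kept
  alongside where they can leave [0, 1].
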