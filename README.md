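# subcell

Subcellular analysis of molecule-resolved spatial transcriptomics.

Multiplexed imaging platforms (MERFISH, seqFISH+, Xenium, CosMx, Molecular
Cartography) report every detected RNA molecule as a 2D point with a gene
identity. Most analysis toolkits aggregate those points to per-cell counts
and study tissue-scale variation; the information *inside* each cell — where
transcripts sit relative to the nucleus and the cell membrane, which genes
colocalize, and which subcellular territories they define — is discarded.
`subcell` is a library + CLI for exactly that subcellular scale. It takes
(1) a transcript table (x, y, gene) and (2) per-cell segmentation polygons
for the cell and nucleus (GeoJSON or WKT), links them into a validated
dataset with count matrices and geometric QC, and provides three analyses:

**Localization-pattern classification** (`subcell.patterns`). Every
gene-in-cell point set is summarized by 13 dimensionless spatial features in
three groups — compartment proximity (distance to the cell and nuclear
membranes, nuclear fraction), symmetry about the center of mass
(polarization |x̄ − c|/R_eq, second-moment asymmetry, angular dispersion),
and dispersion/density (dispersion index, Ripley L statistics max(L(t)−t),
argmax, L(R/2)−R/2, Clark–Evans nearest-neighbor ratio, local density
ratio, inner-quartile fraction). An ensemble of five one-vs-rest binary
random forests assigns one or more of {cell edge, cytoplasmic, nuclear,
nuclear edge, none}, trained on simulated ground truth from
`subcell.simulate` (2,000 samples per class; Poisson abundance at 40/100/200
molecules per average cell, clamped to [5, 300]; weak/moderate/strong
pattern strengths). A 64×64 rasterization (cell 20, nucleus 40, molecule
bins 40 + 20n, /255, capped at 1) is available for image-based models.

**Compartment-specific colocalization** (`subcell.coloc`). For each ordered
gene pair A→B in each compartment of each cell, the colocation quotient

    CLQ(A→B) = (C_{A→B}/N_A) / (N′_B/(N−1))

compares the observed proportion of B among the within-radius neighbors of
A transcripts to the proportion expected from the compartment's overall
composition (N′_B = N_B − 1 for self-pairs; genes under 10 transcripts are
not scored). E[CLQ] = 1 under complete spatial randomness and the statistic
is asymmetric: attraction of A to B is not attraction of B to A. The
scores populate a (gene pair × cell × compartment) tensor with a missing
mask, decomposed by masked non-negative PARAFAC, X̂ = Σ_r x_r ⊗ y_r ⊗ z_r,
with the rank chosen over 2–12 by the elbow of the observed-entry RMSE
curve.

**Subcellular-domain segmentation** (`subcell.flux`). A uniform grid of
query pixels is laid over each cell; each query's local gene composition
v_i (counts within a fixed radius, normalized to sum to 1) is compared to
the whole-cell composition x_j through the embedding r_i = (v_i − x_j)/σ_v.
Embeddings are reduced by truncated SVD (top 10 components) and quantized by
a 1×k self-organizing map, k selected by the elbow of the quantization
error over 2–12; the resulting "fluxmap" domains are canonically ordered
(most nuclear first) and vectorized to polygons. `subcell.enrich` scores
pixels and domains against locale gene-set weights (e.g. proximity-labeling
log fold-changes for nucleus, nucleolus, ER membrane, OMM, cytosol) with
permutation-normalized z-scores, and quantifies condition shifts in domain
composition with the 1D Wasserstein distance.

## Worked example

```python
import numpy as np
from subcell import simulate as sim, patterns, flux, enrich

# 1. classify localization patterns on simulated ground truth
ts = sim.build_training_set(per_class=300, seed=0)
feats = patterns.features_from_samples(ts.samples)
model = patterns.train(feats.iloc[ts.train_idx], ts.labels[ts.train_idx], seed=0)
print(patterns.evaluate(model, feats.iloc[ts.test_idx], ts.labels[ts.test_idx])
      [["precision", "recall", "f1"]].round(3))

# 2. recover subcellular domains from a nucleus/cytoplasm gene panel
ds = sim.make_compartment_dataset(n_cells=20, molecules_per_gene=300, seed=1)
emb = flux.flux_embed(ds, step=4, radius=6)
flux.reduce(emb)
fm = flux.fit_fluxmaps(emb, k_range=range(2, 5), seed=0)
print("selected", fm.k, "domains")
print(enrich.gene_domain_composition(ds, fm, emb).round(2))
```

Output:

```
              precision  recall     f1
label
cell_edge         0.903   0.933  0.918
cytoplasmic       0.882   0.750  0.811
none              0.684   0.900  0.777
nuclear           0.950   0.950  0.950
nuclear_edge      0.873   0.917  0.894
macro             0.858   0.890  0.870
selected 2 domains
      domain_1  domain_2
gene
CYT0      0.12      0.88
NUC0      0.99      0.01
```

The classification table shows per-label precision/recall/F1 on the held-out
20% of the simulation: strongly structured classes (nuclear, cell edge) are
recovered near-perfectly, while "none" (spatial randomness) is intrinsically
confusable with weak patterns. In the domain example the quantizer selects
k = 2 domains; domain 1 (canonically the most nuclear) captures 99% of the
nucleus-confined gene's molecules and domain 2 captures 88% of the
cytoplasmic gene's, i.e. the unsupervised segmentation recovers the
nucleus/cytoplasm partition from transcript composition alone.

## Command line

`subcell` exposes the same pipeline as subcommands, each writing a JSON run
manifest (version, parameters, input digests) for reproducibility:

```bash
subcell ingest --points points.csv --shapes shapes.geojson --out ds/
subcell qc --dataset ds/ --out qc.tsv
subcell simulate --per-class 2000 --seed 7 --out sim/
subcell forest-train --per-class 2000 --seed 0 --model model.joblib
subcell forest-predict --dataset ds/ --model model.joblib --out labels.tsv
subcell coloc --dataset ds/ --radius 20 --out clq.parquet
subcell coloc-factor --tensor clq.parquet --ranks 2:12 --seed 0 --out factors/
subcell flux --dataset ds/ --step 10 --radius 40 --out flux/
subcell fluxmap --flux flux/ --k 2:12 --seed 0 --out domains/
subcell flux-render --flux flux/ --out render.png
subcell enrich --flux flux/ --domains domains/labels.tsv --weights apex.csv --out enr/
```

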