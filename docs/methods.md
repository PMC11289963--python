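# Methods

This note documents the models, algorithms, parameter defaults, and design
decisions behind `subcell`, and what its synthetic benchmarks do and do not
demonstrate.

## Data model and geometric conventions

A dataset links a molecule table (x, y, gene) to per-cell polygons named
"cell" and "nucleus" (other named compartments are carried through).
Coordinates are continuous 2D values in arbitrary "data units"; no unit
conversion is attempted, and any z column is dropped with a warning — all
analyses are strictly planar.

Conventions that the file formats and segmenters leave open are fixed as
follows:

* **Boundary inclusion.** A point exactly on a polygon boundary is *inside*.
  Segmentation masks are closed sets, and this makes grid queries on cell
  edges deterministic. The convention is exercised directly against a
  ray-casting oracle in the test suite.
* **Overlapping cells.** A molecule contained in several cell polygons is
  assigned to the smallest-area one (ties: lexicographic cell id), with a
  warning. Smallest-wins is deterministic and favors nested, nucleus-like
  shapes.
* **Canonical order.** Gene and cell identifiers are opaque strings ordered
  lexicographically wherever an axis order matters (count matrices, tensor
  axes).

Preprocessing follows the standard filters for this data type: genes are
kept when at least one cell contains `min_gene_count` (default 10) of their
molecules, and cells without an annotated nucleus are dropped when nuclear
information is required. The filter is idempotent.

### Fast geometry kernels

The simulator and feature extractor are dominated by two geometric queries:
point-in-polygon and distance-to-boundary. Cells generated by the simulator
are star-shaped radial functions r(θ) sampled at uniformly spaced angles,
so (a) containment reduces to one exact ray/segment intersection in the
point's angular sector, and (b) the segment nearest a point lies within a
few angular steps of the point's own angle. Both are compiled with numba
(with a pure-numpy fallback). The windowed distance is exact near the
boundary and can only overestimate far from it, where the edge kernels it
serves are effectively zero; distances used in *features* always search the
full ring and are exact for arbitrary polygons (verified against shapely).
Every emitted point set is re-checked against the authoritative shapely
polygon, so the containment invariant never rests on the fast path.

## Pattern simulation

The training data generator emulates single-gene smFISH point sets in
cultured cells:

* **Cell shapes.** Smoothed random star-convex blobs,
  r(θ) = R·(1 + Σ_{k=2..6} a_k cos(kθ + φ_k)) with a_k ~ N(0, 0.18/k),
  areas lognormal (σ = 0.25) around a mean of π·50² ≈ 7,854 units²
  (equivalent radius 50). The nucleus is a smaller, smoother blob at a
  jittered interior point, resampled until strictly inside with area
  between 10% and 50% of the cell. A pool of 300 such morphologies plays
  the role of a segmented shape catalog; morphological diversity is what
  matters for classifier generalization, not any particular cell line's
  outline.
* **Abundance.** Molecule counts are Poisson(level × area_scale) at levels
  40/100/200 per average-sized cell, clamped to [5, 300].
* **Patterns.** Five classes: none (complete spatial randomness over the
  cell), nuclear (uniform over the nucleus), cytoplasmic (uniform over cell
  minus nucleus), nuclear edge and cell edge (density ∝ exp(−d/τ) in the
  distance to the respective boundary, τ = 5% of the equivalent radius —
  visually "edge-like" at every cell size). Strength is a mixture weight w
  of the pattern density against CSR: w = 0.25 / 0.5 / 0.9 for weak /
  moderate / strong, so "weak" is close to spatially random. The weights
  are declared defaults, config-exposed.
* **Default set.** 2,000 samples per class (10,000 total), strengths and
  abundance levels cycled uniformly, stratified 80/20 train/test split,
  fully reproducible from one seed. Samples are generated jointly per
  (cell, pattern) group with group-derived seeds, which keeps the 10,000-
  sample default run to a few seconds on one CPU.

What the simulation does *not* model: optical blur and spot-detection
noise, segmentation errors, 3D-to-2D projection (a cytoplasmic transcript
above the nucleus appears nuclear), and cell-to-cell correlation of
patterns. Classifier scores on simulated held-out data are therefore an
upper bound on real-data performance, and the geometric features
deliberately depend only on quantities that survive those nuisances
(normalized distances, fractions, Ripley statistics).

## Localization-pattern classification

The 13 features are dimensionless — normalized by the cell equivalent
radius R_eq = √(area/π), the cell area, or the polygon's exact second
moment of area — making the vector translation-invariant exactly and
scale-invariant to floating-point precision (both are asserted
numerically). Degenerate point sets stay finite: the second-moment
asymmetry is (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1] with a 0 convention for coincident
points, and the inner-quartile feature compares molecule boundary-distances
to the cell's own area quantile computed on a deterministic 48×48 grid.
Ripley's L is used without edge correction; since every sample is scored
inside the same cell geometry, the (deterministic) edge bias cancels across
comparisons.

The ensemble is five one-vs-rest binary random forests (200 trees, balanced
class weights, fixed seed). Multilabel assignment thresholds each label's
probability at 0.5; an empty assignment falls back to {none}, so label sets
are never empty. Five-fold cross-validation per label is available at
training time. On the default simulated split the held-out macro-F1 is
≈ 0.87; "none" is the hardest label because weak patterns are close to CSR
by construction.

## Colocation quotient and tensor decomposition

For an ordered pair A→B inside one compartment of one cell,

CLQ(A→B) = (C_{A→B}/N_A) / (N′_B/(N−1)),

where C_{A→B} sums, over A transcripts, the proportion of B among that
transcript's neighbors within radius r (all transcripts are neighbors,
self excluded, boundary inclusive; a neighborless A transcript contributes
0), and N′_B = N_B − 1 for self-pairs. The expected proportion under CSR
is N′_B/(N−1) exactly, so the statistic is calibrated to 1 under
randomness — confirmed by Monte Carlo in the tests — and is insensitive to
edge effects, because the *composition* of a neighborhood is unbiased even
where its size is truncated. The statistic is asymmetric by design, and
exactly invariant to rescaling coordinates and r together. Genes with
fewer than 10 transcripts in a compartment are not scored; those entries
are missing, not zero. A binary variant (count of A transcripts with at
least one B neighbor) is exposed as `neighbor_counts` for diagnostics.

The neighborhood radius is data-dependent and *not* defaulted silently: the
tensor builder warns when falling back to 20 data units. Ordered pairs
including self-pairs populate the pair axis (flag-controlled); pairs
missing in more than 95% of (cell, compartment) slabs are dropped to bound
the axis.

The (pair × cell × compartment) tensor is factorized by non-negative CP
(PARAFAC) with the missing mask ignored in the loss: each sweep imputes
missing entries with the current reconstruction (EM) and applies HALS
non-negative updates per mode. Tolerance 1e−7 on the relative loss change,
at most 500 sweeps, best of 3 seeded restarts; perturbing masked entries
leaves the fit bit-identical (asserted). The rank is selected over 2–12 at
the elbow of the observed-entry RMSE curve — the point of maximum
perpendicular distance from the chord joining the curve's endpoints — which
is deterministic and library-free. A curve that is already ~0 at the
minimum rank (an all-constant tensor) has no elbow; it is flagged
degenerate and the minimum rank returned. On planted rank-3 non-negative
tensors the procedure selects rank 3 with RMSE < 1e−3 and, with 20% of
entries masked, recovers the generating factors with congruence > 0.95
after permutation matching.

Self- vs cross-pair comparisons use two-sided Mann–Whitney U tests on
log-CLQ, grouped by {self, cross} × compartment, with Benjamini–Hochberg
correction across the family.

## Subcellular-domain segmentation

Queries are laid on a uniform grid of step s anchored at each cell's
bounding-box minimum, keeping in-cell points only (a sub-step cell still
gets its centroid). Each query's composition v_i uses molecule counts
within a fixed radius; all-zero neighborhoods are flagged empty and
excluded from σ_v, the SVD, and SOM fitting (their pixels later inherit the
nearest labeled query's domain). The embedding r_i = (v_i − x_j)/σ_v uses
the owning cell's composition x_j and, by default, a per-cell σ_v — the
per-cell scope makes the embedding measure *intra*cellular variation and
matches the observation that domains are consistent across cells; a global
scope is a flag. Zero-variance genes take σ = 1 so their component is
exactly v − x.

Reduction is truncated SVD *without centering* (the embedding matrix is
sparse-ish and its rows already measure deviation from an expectation),
keeping the top 10 components with a deterministic sign convention; fewer
non-degenerate dimensions shrink the reduction with a warning. Note a
G-gene panel yields at most G−1 informative dimensions (compositions sum
to 1).

Quantization uses a 1×k self-organizing map: online training, 10,000
iterations, initial learning rate 0.5 and neighborhood σ = k/2 both
decaying linearly, prototypes initialized from data rows, fixed seed. The
SOM is fit jointly across all cells of a dataset (or of a cell-type group,
via the CLI's group column) — domains are shared structure; fitting
per-cell would destroy comparability. k is chosen over 2–12 by the same
perpendicular-distance elbow rule, with one addition: quantization-error
curves decrease smoothly in k and have no cliff at the true k when it
equals the smallest searched value (an endpoint can never maximize the
chord distance), so the curve is anchored by the trivial one-prototype
quantization error before applying the rule. The RMSE-vs-rank curves of
the tensor decomposition have a cliff at the true rank and are used
unanchored. Domains are relabeled canonically — descending mean nucleus
overlap, then size — so domain 1 is always the most nuclear; the 1D
Wasserstein shift metric depends on this ordering and documents it.

Domain polygons are the union of each query's step×step tile clipped to the
cell. RGB rendering maps per-query quantile ranks of the top-3 components
affinely onto [0.1, 0.9] (avoiding saturated black/white), interpolates
linearly between grid points, and leaves out-of-cell pixels transparent;
a constant component renders as 0.5.

### Benchmark geometry and scale

The domain-recovery benchmarks (left/right segregated genes; nucleus- vs
cytoplasm-confined gene sets) use step 4 and radius 6 data units on
synthetic cells of equivalent radius ≈ 50. The imaging-platform defaults
(step 10, radius 40) assume cells spanning hundreds of pixels; the
neighborhood radius must be small relative to the cell to resolve
subcellular structure, so the benchmarks scale it to roughly 10% of the
cell diameter, with molecule densities (300–600 per gene set per cell) in
the regime where composition estimates are informative — the method is
known to degrade when molecules per cell are sparse, and the benchmarks
document the regime in which it is expected to work. Under these
conditions the quantizer selects k = 2 on segregated two-gene cells with
ARI ≈ 0.93 against the generating split, and the k = 2 nuclear domain
overlaps the true nucleus with mean IoU ≈ 0.75–0.80 over 50 cells.

## Enrichment

The raw locale score of a pixel is the weighted sum of its embedding over
the genes shared between the panel and the locale's weight table (overlap
sizes are reported; zero-overlap locales are skipped with a warning). The
permutation null shuffles the *gene labels of the weight vector* within
each cell — this holds the per-pixel embedding geometry fixed, which is
exactly what the null should preserve — and z = (raw − mean)/sd over
n_perm = 1000 permutations. With random weights the z-scores are calibrated
(mean ≈ 0, sd ≈ 1). Scores are linear in the weights, exactly. Domain
summaries are the mean z and the positive-pixel fraction per (domain,
locale). Pattern-frequency enrichment applies the same weighted-sum +
permutation scheme to gene × label frequency tables, with BH correction
across the full label × locale family emitted by one call.

Composition shifts between conditions are the 1D earth-mover distance over
the canonically ordered domain axis (unit spacing, nucleus first): the
summed absolute difference of the CDFs. Identity, symmetry, and the
triangle inequality are property-tested.

## Problem sizes and determinism

The default test suite and the acceptance script run the full 10,000-sample
simulation and classifier training, 200-replicate CLQ null calibration,
planted-tensor recovery at ranks 2–6, the 50-cell domain benchmarks, and
1,000-permutation enrichment calibration; together they complete in a few
minutes on one CPU. Every stochastic stage takes an explicit seed;
rerunning any stage with the same seed reproduces its output bit-for-bit,
and CLI runs record their parameters and input digests in a JSON manifest.

## Known limitations

* Strictly 2D; z coordinates are discarded rather than modeled.
* Ripley features are uncorrected for edge effects (deliberate, see above).
* The CLQ radius and the flux step/radius are data-scale parameters the
  user must choose; defaults suit imaging data with cells hundreds of
  units across.
* The SOM quantizer, like any vector quantizer, splits continuous
  gradients into discrete domains; k selection is a heuristic, and domains
  should be interpreted together with the continuous embedding rendering.
* Tensor factors are non-orthogonal and unordered; interpretation relies on
  inspecting all three loading vectors jointly.
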