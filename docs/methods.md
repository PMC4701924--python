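# Methods

## Problem setting

Voxel-level functional connectivity treats every in-mask voxel of a 4D BOLD
acquisition as a graph vertex and the Pearson correlation between voxel
time series as the connectivity weight. At whole-brain resolution the
correlation matrix is quadratic in the voxel count: for N ≈ 228,200 in-mask
voxels (a typical 2 mm isotropic mask) the dense double-precision matrix
occupies N²·8 B ≈ 388 GiB. `voxelgraph` therefore never materializes the
matrix; it computes row blocks under an explicit byte budget and keeps only
the thresholded sparse graph.

## Data model and conventions

- **Orientation**: all tables are time × voxel (voxels in columns). Every
  downstream operation assumes this.
- **Vertex identity**: a voxel's graph id is its 0-based, x-fastest linear
  index into the mask grid, `x + nx·(y + ny·z)`. The convention is recorded
  in every edge-list header, so outputs are self-describing.
- **Precision**: data are promoted to float64 on read; metric maps are
  stored as float32 by default (float64 on request). NIfTI
  `scl_slope`/`scl_inter` calibration is applied on read. When qform and
  sform disagree, qform wins and a warning is logged.
- **Mask semantics**: any strictly positive value is in-mask. An empty mask
  is an error, not an empty result.

## Tiled correlation

After columnwise z-scoring (mean 0, sample sd 1 with denominator T−1), the
correlation of voxels a and b is `z_a·z_b/(T−1)`. A tile plan partitions
the matrix rows into blocks of height `floor(budget / (V·8))`; each block
is one dense block-times-matrix product.

Two numerical choices matter:

- **Exact tile-plan invariance.** Each tile row is computed as a separate
  matrix–vector product (`z[:, g] @ Z`) rather than one blocked
  matrix–matrix product. A blocked GEMM's summation order depends on the
  operand shapes, so different tile plans would differ in the last ulp;
  the per-row form makes the arithmetic independent of block height and
  results bit-identical across plans. This trades some BLAS-3 throughput
  for a hard determinism guarantee, which the whole pipeline (streaming,
  thresholding, checksummed manifests) relies on.
- **Zero-variance voxels.** Constant time series (e.g. voxels outside the
  scanner's field of view that a generous mask lets through) have no
  defined correlation. They are flagged during standardization, zeroed,
  and correlate 0 with everything — they become isolated vertices instead
  of NaN sources.

Thresholding uses `|r| ≥ θ` with a closed comparison; edges store the
signed r, but graph metrics use the unweighted graph. Values are clipped to
[−1, 1] to absorb last-ulp excursions. Cosine similarity of raw columns is
available as well; on standardized data it coincides with Pearson r.

At the whole-brain scale (V = 228,200, 8 B/element) a 4.2 GiB tile budget
gives a block height of 2470 rows and 93 tiles. The exact tile count for a
given deployment depends on how much of the device budget is reserved for
input buffers, so the budget is an explicit parameter rather than a
hard-coded constant.

## Graph metrics

The loader accepts whitespace-separated `i j [weight]` lines, ignores the
weight, collapses duplicates and both orientations, and drops self-loops
(counted, logged). Isolated vertices are preserved whenever the vertex
count is known (argument or `# n_vertices=` header); otherwise it defaults
to max id + 1.

- **Degree** by edge-endpoint counting; satisfies the handshake lemma.
- **Connected components** via scipy's union-find/BFS on the sparse
  adjacency, relabelled so that each label is the component's minimum
  vertex id (stable, order-independent, and comparable across tools that
  use the same convention).
- **Triangle counts** as row sums of `(A·A) ∘ A` divided by 2.
- **Local clustering** `cc = tc/(d(d−1)/2)`, defined as 0 for d < 2 where
  the formula divides by zero.
- **PageRank** by explicit power iteration on
  `p' = (1−α)/N + α·(A(p/d) + m/N)` where m is the mass on dangling
  (isolated) vertices; α defaults to 0.85, convergence is an L1 change
  below 1e−8, capped at 200 iterations (exceeded → a convergence error
  carrying the last residual, never a silent partial result). The result
  is a probability vector (sums to 1).

All metric implementations are checked against independent oracles in the
test suite: BFS for components, O(n³) triple enumeration and networkx for
triangles/clustering, dense power iteration for PageRank.

## Edge-density statistic and threshold selection

`S = log E / log K` (K = 2E/N) summarizes graph density independently of
the logarithm base; it is defined only for E ≥ 1 and K > 1. Because a
fixed correlation threshold produces very different densities on different
datasets, `select_threshold` evaluates a descending threshold grid in one
tiled pass (per-tile sorted |r| + binary search, so the grid adds no extra
correlation passes) and returns the **largest** grid threshold whose S
meets the target, breaking ties toward the larger threshold. Lowering the
threshold can only add edges, so E is non-increasing along the grid; S
itself need not be monotone, which is why the scan is explicit rather than
bisective. An unattainable target raises an error reporting the attainable
S range.

## Group stacking and truncated SVD

Subjects sharing a mask are concatenated row-wise; subject boundaries are
kept so the stack is losslessly sliceable. The truncated SVD uses ARPACK's
iterative Lanczos solver with a seeded start vector (reproducible runs);
the dense LAPACK SVD is used only when the requested k equals min(rows, V)
— a full-rank request ARPACK cannot satisfy, which only arises for small
matrices. Optional column centering turns the decomposition into PCA; it
is off by default so the plain SVD of the raw stack is the baseline
behaviour.

## Synthetic data generator

The generator plants disjoint voxel communities, each driven by its own
unit-normal latent time course: `y_v = a·L_c + σ·ε_v`. Expected
correlations are closed-form: `ρ_within = a²/(a²+σ²)` within a community,
0 between communities and for pure-noise voxels. Defaults follow the
worked configuration used throughout the tests: 5 communities × 50 voxels,
T = 400 volumes, a = 3, σ = 1 (ρ_within = 0.9), threshold 0.6. At these
settings the sampling noise of r (sd ≈ (1−ρ²)/√T ≈ 0.01 within, ≈ 0.05
between) puts within-community correlations ~30 sd above the threshold and
noise correlations ~12 sd below it, so community recovery is essentially
deterministic — which is the point: a failure indicates a pipeline defect,
not bad luck. The latent-factor construction is O(V·T) and exactly
seedable (same seed ⇒ bit-identical files; gzip members are written with
fixed mtime).

What the generator does **not** emulate: hemodynamic response shape,
temporal autocorrelation, motion and physiological artifacts, spatial
smoothness of noise, and between-community anticorrelations. Passing tests
therefore demonstrate algorithmic correctness of the pipeline, not
robustness to real acquisition confounds.

## Pipeline and provenance

`run_subject_pipeline` chains read → standardize → (optional automatic
threshold selection) → tiled threshold streaming → metrics → NIfTI maps,
and writes a JSON manifest with SHA-256 checksums of every artifact, the
graph summary (N, E, K, S) and a configuration hash. The output prefix is
excluded from that hash: where results are written must not change what is
written, so reruns into different directories are bit-identical. Group
runs execute subjects independently (outputs identical to single-subject
runs) plus an optional stack + SVD.

## Problem sizes

Default test and reproduction runs use grids of 10×10×10 voxels or
smaller, 80–2000 volumes, random graphs up to 500 vertices, and a 200×500
SVD probe — sizes chosen so the full verification cycle completes in
seconds while still exercising multi-tile plans, non-trivial component
structure, and the whole-brain arithmetic (which is evaluated at
V = 228,200 directly, since planning and footprint are O(1)).

## Known limitations

- The tile loop is serial; the tile contract is backend-agnostic but no
  multiprocess or GPU backend ships yet.
- Weighted graph metrics, partial correlation, Fisher z, betweenness and
  global efficiency are out of scope.
- NIfTI-2/CIFTI inputs and any preprocessing (motion correction, slice
  timing) are out of scope; inputs are assumed preprocessed.
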