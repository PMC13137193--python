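# Methods

This note records the models and conventions implemented in
`spatialniche`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that make results reproducible bit-for-bit.

## Spatial network reconstruction

Tissues are modelled as graphs whose nodes are cells (or spots) and
whose edges encode physical proximity.

**Delaunay with adaptive trimming** (`build_delaunay` + `trim_edges`,
combined in `build_spatial_network`). The Delaunay triangulation links
cells whose virtual (Voronoi) cells touch. On irregular point sets it
also creates long edges between cells that are geometrically adjacent
but biologically far apart, especially along tissue boundaries. Trimming
removes them adaptively: when an edge is tested at one of its endpoints,
the reference length is the mean of that node's `k_ref = 3` shortest
*other* incident edges, and the edge is dropped when its length exceeds
`factor = 2` times the reference at either endpoint (an `"and"` variant
requires both endpoints to object). The candidate edge is excluded from
its own reference so that a single artifact edge at a low-degree boundary
node cannot inflate its own threshold. Because removing an edge can
change a neighbor's reference set, the rule is applied repeatedly until
no edge is removed; the returned network is therefore a fixed point and
trimming is idempotent by construction. The node set is never changed;
isolated nodes are counted and logged. On uniform random (Poisson-like)
point sets this rule removes a substantial fraction of Delaunay edges
(~35–45%); that is a property of the stated threshold, and the remaining
graph retains the short-range contacts the downstream statistics use.

Duplicated coordinates make the triangulation undefined; the default is
an error, with an opt-in deterministic jitter of `1e-6 × d_min` driven by
the run seed.

**Lattice linking** (`build_lattice`). For regular arrays (Visium-style
spots) every pair at distance ≤ `d_min × (1 + tolerance)` is linked,
where `d_min` is the minimal pairwise inter-spot distance and the default
tolerance of 5% absorbs coordinate rounding. Interior spots of a
hexagonal array get 6 neighbors, of a square array 4.

## Mixing matrices and assortativity

For a categorical attribute with `k` categories, the mixing matrix `e`
has entries `e_ij`: the fraction of edge stub pairs joining an `i`-node
to a `j`-node. Undirected edges are counted once in each orientation
(the classical convention), so `e` is symmetric, `Σ_ij e_ij = 1`, and
the marginals `a_i = Σ_j e_ij` and `b_j = Σ_i e_ij` coincide. The
assortativity coefficient is

    r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i),

which is 1 for perfectly assortative mixing, 0 when `e` factors into its
marginals, and negative down to −1 for disassortative mixing. When only
one category is effectively present the denominator vanishes and `r` is
reported as undefined (an error), never silently 0.

**Directed networks** use `e_ij` = fraction of directed `i → j` edges;
the same formula applies with row/column marginals that now differ.

**Non-exclusive attributes** (marker-positivity flags, where one cell
may be positive for several markers): for each edge `(u, v)` and each
ordered marker pair `(i, j)` with `u` positive for `i` and `v` positive
for `j`, one count is added (both orientations when undirected), and the
count matrix is normalized by its total. This preserves every
mixing-matrix invariant, keeps `r` well-defined, and intentionally lets
multi-positive cells contribute several counts — the quantity measured
is marker-pair contact frequency, not cell-pair contact frequency.
Cells positive for no marker contribute nothing.

**Permutation z-scores.** Abundant cell types interact frequently by
abundance alone, so each matrix element and `r` are z-scored against a
null built by permuting attribute values (whole flag rows in
non-exclusive mode) across the nodes of the same sample's network —
preserving both the attribute proportions and the graph. Defaults:
`n_perm = 100` permutations (a compromise between cost and the stability
of the permutation SD; the z is a descriptive enrichment score, not a
calibrated test statistic), population SD (`ddof = 0`), per-sample
permutation. Elements whose permuted values never vary are masked as
undefined rather than given z = 0: the normality of the permutation
distribution is an assumption, and masking avoids fabricating certainty.

**Cross-sample imputation.** Rare cell types leave many per-sample
matrix elements undefined. `impute_missing_mm` first drops variables
defined in fewer than 50% of samples, then samples whose remaining
missing fraction exceeds 50%, then fills the remaining gaps with
k-nearest-neighbor imputation (k = 5) over samples in standardized
feature space. kNN was chosen for determinism and freedom from
distributional assumptions; the method is pluggable. Everything dropped
is reported.

## Neighbors Aggregation Statistics (NAS)

Each cell is described by its neighborhood: the values of the cell
itself (`include_self = True`; the neighborhood *contains* its focal
cell) and of all cells within graph distance ≤ `order` (default 1). For
every variable, summary statistics are computed over the neighborhood:
`mean` or `median` for central tendency, population `sd` or the
interdecile range (q90 − q10, linear-interpolation quantiles) for
dispersion. Categorical variables are one-hot expanded, and the
neighborhood mean of an indicator is the local type proportion. The
pooled table over all cells of all samples has `N_C` rows and exactly
`N_V × N_S` columns, rows sorted by (sample, node id) so results are
order-independent. The dispersion of a singleton neighborhood is 0 (and
logged).

Defaults: `{mean, sd}` for continuous markers, `{mean}` for one-hot
indicators — the smallest set exercising both central tendency and
dispersion.

**Niches** are clusters of the NAS table computed jointly across all
samples, so labels are comparable between patients. Columns are z-scored
first (the table mixes proportions with marker scales), then optionally
reduced (UMAP by default, 2 dimensions; PCA or no reduction as
alternatives — the no-reduction path is first-class because it scales to
large cohorts), then clustered (k-means by default; Gaussian mixture and
Leiden on a 15-NN graph as alternatives). All stages take the single run
seed. `silhouette_scan` evaluates a grid of reductions and cluster
counts by mean silhouette, subsampling tables above 10,000 rows
(seeded) to bound cost.

**Differential niche analysis** compares the NAS variables of the cells
of two niches, optionally restricted to one cell type so that
environment-driven differences are not confounded by composition
leakage. Each variable gets a two-sided Mann–Whitney rank-sum test, an
effect direction (sign of the median difference), and a
Benjamini–Hochberg q-value. Comparing a niche with itself is the defined
null: all q = 1, effects 0.

## Per-sample features

* `prop:<type>` — cell-type fractions over the global vocabulary
  (absent types are 0, rows sum to 1).
* `ratio:<a>|<b>` — `a/(a+b)` for every unordered pair; when
  `a + b = 0` the ratio is *missing*, never 0.5.
* `clr:<part>` — centered log-ratio of a compositional block:
  `log x_i − mean_j log x_j` after multiplicative zero replacement with
  δ = 0.5 × the smallest nonzero share (configurable). Output rows sum
  to 0 and the transform is invariant to positive rescaling before
  closure.
* `niche:<k>` — per-sample niche occupancy, optionally renormalized: by
  cell-type proportions (`by_celltype`), to cohort-wide unit column mean
  (`by_niche`), or CLR (`clr`).
* `mmz:<i>~<j>` — per-sample z-scored interaction elements (upper
  triangle for undirected attributes), with masked elements as missing.

`bivariate_screen` relates every feature to the outcome: Mann–Whitney
rank-sum for binary outcomes (exact null for tie-free samples of ≤ 30,
tie-corrected normal approximation otherwise), a univariate Cox model's
Wald test per feature for survival outcomes (asymptotically equivalent
to the score test), Benjamini–Hochberg correction over the testable
features, constants kept in the output but marked untestable.

## Clinical models

**Binary response**: elastic-net logistic regression, standardized
features, stratified 5-fold cross-validation over a grid of
`l1_ratio ∈ {0.1, 0.5, 0.9}` and `C ∈ {0.01, 0.1, 1, 10}` (the grid is a
package choice; nothing in the method fixes it). The selected grid
point's out-of-fold predictions give the reported ROC AUC, average
precision and Matthews correlation; the in-sample AUC is reported
separately under an explicit label. Coefficients come from a full-data
refit at the selected penalty; zero coefficients are retained.

**Survival**: elastic-net Cox proportional hazards (coordinate-descent
path), selected by mean out-of-fold concordance over the same `l1_ratio`
grid and a 10-point alpha path. Per-coefficient p-values and 95%
confidence intervals come from an *unpenalized* refit on the nonzero
support and are labelled in-sample, post-selection quantities — they are
approximate and optimistic, which the report states.

**Maximally selected log-rank split**: candidate thresholds are
midpoints between consecutive sorted unique feature values whose induced
groups both hold ≥ 10% of the samples; the threshold maximizing the
log-rank statistic is returned. Because the threshold is optimized, the
nominal p-value does not have its nominal null distribution; every
result carries a mandatory `exploratory` flag and no correction (e.g.
Lausen–Schumacher) is applied by default.

**Hyperparameter search** evaluates NAS configurations (aggregation
order, statistics, reduction, cluster count, normalization) by the
predictive performance of the resulting niche features, optionally
concatenated with earlier feature blocks (the cumulative design).
Results are cached on disk keyed by a hash of the configuration, so an
interrupted search resumes without recomputation.

## Synthetic data: the stated world

The generator exists so that every stage is testable without downloads.
Its world is deliberately simple:

* cells uniform on a square tissue of side 1000 µm (2D; 3D cubes
  supported);
* ground-truth regions are horizontal bands (`layers`, cortical-layer
  analog) or Voronoi cells of random seed points (`blobs`, tumor-niche
  analog), each with its own type composition and optional marker shift;
* markers are Gaussian: type-identity mean 2.0 on the type's own marker,
  0 elsewhere, plus the region shift, plus N(0, 0.3) noise;
* binary cohorts plant an effect by shifting the fraction of tissue in
  region 0 between groups (0.1 vs 0.4 by default); survival cohorts draw
  exponential event times with log-hazard linear in the planted fraction
  and independent exponential censoring whose rate targets the requested
  censoring probability (`P(censored) = μ/(λ+μ)` for exponential pairs);
* `hex_bin_cells` degrades resolution into pointy-top hexagonal
  metacells (centroid coordinates, averaged markers, modal or
  composition-vector types) for multi-scale experiments.

What it does **not** emulate: transcript counting noise, segmentation
errors, imaging artifacts, batch effects, realistic marker correlation
structure, or irregular tissue boundaries. A green recovery test
therefore establishes that the pipeline recovers planted compositional
structure under idealized noise — not that it would do so on any
particular real assay.

## Numerical conventions and degenerate inputs

* Population SD (`ddof = 0`) and linear-interpolation quantiles
  everywhere, so results are bit-reproducible across runs.
* All randomness flows from explicit integer seeds; equal inputs and
  seeds give identical outputs.
* Degenerate geometry (collinear 2D, coplanar 3D point sets) is an
  explicit error naming the failure; duplicated coordinates error unless
  jitter is opted in.
* Single-category assortativity, empty networks, all-zero marker flags,
  all-zero compositions, zero-event survival data, and constant features
  in a threshold scan are all explicit errors or flagged rows — never
  silent NaN/0 substitutions.
* Column roles (coordinates, sample, types, markers) are always declared
  in an explicit schema; nothing is guessed from dtypes.

## Known limitations

* The permutation z-score assumes nothing about the null's shape but is
  reported on a normal scale; tail probabilities should not be read off
  it.
* Post-selection inference for the survival model is approximate; the
  refit confidence intervals do not account for support selection.
* The no-reduction NAS path with k-means assumes roughly isotropic
  clusters in standardized NAS space; Leiden is provided for
  non-convex structure.
* Graphs are built per sample; there is no cross-sample spatial
  alignment.
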