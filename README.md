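# spatialniche

Spatial-omics tissues — CODEX/IMC multiplexed proteomics, MERFISH/Xenium
imaging transcriptomics, Visium spot arrays — deliver per-cell
coordinates plus molecular attributes, and the clinically interesting
signal is often not *which* cells a sample contains but *how they are
arranged*: which cell types preferentially touch, and which recurring
local neighborhoods ("niches") a tissue is built from. `spatialniche`
turns such tables into quantitative interaction and niche features and
relates them to binary response or right-censored survival outcomes. It
is aimed at computational biologists analyzing spatial cohorts with
clinical annotation.

## What it computes

**Spatial networks.** Cells become nodes; edges come from a Delaunay
triangulation with adaptive trimming (an edge is removed when it is
longer than twice the mean of the shortest other edges at either
endpoint), or from minimal-spacing linking for regular spot arrays.

**Mixing matrix and assortativity.** For a categorical attribute, the
mixing matrix `e` holds the fraction of edge stub pairs `e_ij` joining
an *i*-node to a *j*-node, with marginals `a_i = Σ_j e_ij`,
`b_j = Σ_i e_ij`, and the assortativity coefficient

```
r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i)   ∈ [−1, 1]
```

(`r = 1`: neighbors always share the attribute; `r = 0`: no
association; `r < 0`: disassortative). Directed networks and
*non-exclusive* binary attributes (marker positivity, where one cell
can carry several markers) are supported. To remove pure abundance
effects, every element and `r` are z-scored against label permutations
within the same sample's network.

**NAS niches.** The Neighbors Aggregation Statistics method describes
each cell by statistics (mean/median, SD/interdecile range) of every
variable over the cell and its graph neighbors up to a chosen order,
producing a cells × (variables × statistics) table; clustering that
table jointly across samples (optionally after UMAP/PCA) yields niches
comparable between patients, with silhouette-guided cluster-count
selection and a differential analysis contrasting the NAS variables of
two niches.

**Clinical models.** Per-sample features (type proportions, a/(a+b)
ratios, CLR transforms, interaction z-scores, niche occupancies) feed
elastic-net logistic regression (binary response; out-of-fold ROC AUC,
average precision, Matthews correlation) or an elastic-net Cox model
(survival; cross-validated concordance, post-selection Wald tests from
an unpenalized refit), plus maximally-selected log-rank threshold
splits (always flagged exploratory) and Kaplan–Meier estimates. A
hyperparameter search ranks NAS configurations by predictive
performance with on-disk caching.

A synthetic-tissue module generates layered or blob-structured tissues
and outcome-annotated cohorts with planted effects, so the entire
pipeline is testable without any external dataset.

## Worked example

```python
import spatialniche as sn
from sklearn.metrics import adjusted_rand_score

spec = sn.TissueSpec(
    n_cells=1000, n_types=2, layout="blobs",
    niche_specs=(sn.NicheSpec((0.9, 0.1)), sn.NicheSpec((0.1, 0.9))),
    seed=1,
)
cells = sn.generate_tissue(spec)
net = sn.build_spatial_network(cells)
print(f"{net.n_nodes} cells, {net.n_edges} edges after trimming")

mm = sn.mixing_matrix(net, "cell_type")
print(mm.to_frame().round(3))
print(f"assortativity r = {sn.assortativity(mm):.3f}")

z = sn.zscore_mixing(net, "cell_type", n_perm=100, seed=0)
print(f"z-scored assortativity = {z.z_ac:.1f}")

nas = sn.nas_table(cells, {"S0": net})
asg = sn.cluster_niches(nas, dr="pca", dr_dims=2, cluster="kmeans",
                        k_or_resolution=2, seed=0)
truth = cells.sorted().df["truth_niche"]
print(f"ARI vs planted regions = {adjusted_rand_score(truth, asg.labels):.3f}")
```

prints

```
1000 cells, 1836 edges after trimming
        type_A  type_B
type_A   0.351   0.105
type_B   0.105   0.440
assortativity r = 0.577
z-scored assortativity = 25.8
ARI vs planted regions = 0.828
```

The tissue was planted with two regions dominated by different cell
types, so same-type contacts dominate the mixing-matrix diagonal
(`r = 0.577`, far above the permutation null at z ≈ 26), and clustering
the neighborhood statistics recovers the planted regions (ARI 0.83
against ground truth; boundary cells with mixed neighborhoods account
for the remainder).

## Command line

```sh
spatialniche graph cells.csv --schema schema.yaml --out run/
spatialniche mix cells.csv --schema schema.yaml --out mixing.tsv
spatialniche nas cells.csv --schema schema.yaml --out niches.csv -k 5
spatialniche features cells.csv --schema schema.yaml --out features.csv
spatialniche fit features.csv --task binary --out report.json
spatialniche search cells.csv clinical.csv --schema schema.yaml --out run/
spatialniche run config.yaml
```

`schema.yaml` names the coordinate, sample, cell-type and marker
columns explicitly — nothing is guessed from dtypes. `run` executes the
full staged pipeline (graphs → proportions/ratios → mixing z-scores →
NAS niches → model) with per-stage caching keyed by config hashes, so
unchanged reruns are cache hits and a one-parameter edit recomputes only
downstream stages.

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic reference
quantities from scratch — the assortativity limits on constructed
networks (perfectly assortative two-type network, product-marginal
matrix, complete bipartite K3,3) and the mixing-matrix normalization on
a seeded random geometric graph:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/spatialniche/
  core.py       cell tables (explicit schemas) and spatial networks
  graph.py      Delaunay + adaptive trimming, lattice linking
  mixing.py     mixing matrices, assortativity, permutation z-scores,
                cross-sample imputation
  nas.py        neighborhood aggregation, niche clustering, silhouette
                scan, differential niche analysis
  features.py   proportions, ratios, CLR, niche features, screening
  models.py     elastic-net LR / CoxPH, log-rank splits, Kaplan-Meier,
                hyperparameter search
  synthetic.py  planted-structure tissues and cohorts, hex binning
  io.py         csv/tsv/parquet + h5ad interop, edge lists, schemas
  pipeline.py   staged, cached end-to-end runs
  cli.py        the `spatialniche` command
docs/methods.md   model conventions, defaults, limitations
```
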