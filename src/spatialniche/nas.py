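"""Neighbors Aggregation Statistics (NAS) niche discovery.

Each cell is described by statistics of its neighborhood: for every
variable (marker level, or one-hot cell-type indicator) the values of the
cell and its graph neighbors up to a chosen order are pooled, and summary
statistics — a central tendency (mean, median) and a dispersion (standard
deviation, interdecile range) — are computed.  Stacking these over all
cells of all samples yields the NAS table with N_C rows and exactly
N_V × N_S columns; clustering that table jointly across samples defines
*niches*: recurring local neighborhood classes comparable between
patients.

Conventions (stated so results are bit-reproducible): the standard
deviation uses the population convention (ddof 0); quantiles use linear
interpolation; the dispersion of a singleton neighborhood is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .core import CellTable, SpatialNetwork, to_adjacency

logger = logging.getLogger(__name__)

STATISTICS = ("mean", "median", "sd", "interdecile")


def neighborhood_matrix(
    net: SpatialNetwork, order: int = 1, include_self: bool = True
) -> sparse.csr_matrix:
    """Boolean membership matrix: row i marks all nodes within graph
    distance ≤ ``order`` of node i (plus i itself when ``include_self``)."""
    if order < 1:
        raise ValueError("order must be ≥ 1")
    adj = to_adjacency(net).astype(bool)
    if net.directed:
        adj = adj + adj.T  # aggregation ignores direction
    reach = sparse.identity(net.n_nodes, dtype=bool, format="csr")
    for _ in range(order):
        reach = reach + adj @ reach
    reach = reach.tocsr()
    reach.data[:] = True
    if not include_self:
        reach = reach.tolil()
        reach.setdiag(False)
        reach = reach.tocsr()
        reach.eliminate_zeros()
    return reach


def aggregate_neighbors(
    net: SpatialNetwork,
    variables: pd.DataFrame,
    order: int = 1,
    include_self: bool = True,
) -> List[np.ndarray]:
    """Per-node neighborhoods as index arrays into ``variables`` rows."""
    if len(variables) != net.n_nodes:
        raise ValueError("variables must be row-aligned with the network nodes")
    member = neighborhood_matrix(net, order=order, include_self=include_self)
    return [member.indices[member.indptr[i]: member.indptr[i + 1]] for i in range(net.n_nodes)]


def nas_statistics(
    variables: pd.DataFrame,
    neighborhoods: Sequence[np.ndarray] | sparse.spmatrix,
    statistics: Sequence[str] = ("mean", "sd"),
) -> pd.DataFrame:
    """Summarize each node's neighborhood values into NAS columns.

    Returns a frame with a (variable, statistic) MultiIndex over columns —
    exactly ``len(variables.columns) × len(statistics)`` of them.
    """
    stats = tuple(statistics)
    if not stats:
        raise ValueError("at least one statistic is required")
    unknown = set(stats) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistic(s) {sorted(unknown)}; choose from {STATISTICS}")
    X = variables.to_numpy(dtype=float)
    n, v = X.shape

    if sparse.issparse(neighborhoods):
        member = neighborhoods.tocsr().astype(float)
        index_lists = None
    else:
        index_lists = list(neighborhoods)
        rows = np.repeat(np.arange(n), [len(ix) for ix in index_lists])
        cols = np.concatenate(index_lists) if index_lists else np.array([], dtype=int)
        member = sparse.csr_matrix(
            (np.ones(len(cols)), (rows, cols)), shape=(n, n)
        )
    counts = np.asarray(member.sum(axis=1)).ravel()
    if (counts == 0).any():
        raise ValueError("a node has an empty neighborhood; use include_self=True")

    blocks: Dict[str, np.ndarray] = {}
    if "mean" in stats or "sd" in stats:
        mean = (member @ X) / counts[:, None]
        if "mean" in stats:
            blocks["mean"] = mean
        if "sd" in stats:
            ex2 = (member @ (X**2)) / counts[:, None]
            blocks["sd"] = np.sqrt(np.clip(ex2 - mean**2, 0.0, None))
    if "median" in stats or "interdecile" in stats:
        if index_lists is None:
            m = member.tocsr()
            index_lists = [m.indices[m.indptr[i]: m.indptr[i + 1]] for i in range(n)]
        med = np.empty((n, v))
        idr = np.empty((n, v))
        for i, ix in enumerate(index_lists):
            vals = X[ix]
            if "median" in stats:
                med[i] = np.median(vals, axis=0)
            if "interdecile" in stats:
                q90, q10 = np.quantile(vals, [0.9, 0.1], axis=0)
                idr[i] = q90 - q10
        if "median" in stats:
            blocks["median"] = med
        if "interdecile" in stats:
            blocks["interdecile"] = idr

    n_singleton = int((counts == 1).sum())
    if n_singleton and ("sd" in stats or "interdecile" in stats):
        logger.info("%d singleton neighborhood(s): dispersion reported as 0", n_singleton)

    columns = pd.MultiIndex.from_product(
        [list(variables.columns), list(stats)], names=["variable", "statistic"]
    )
    data = np.concatenate(
        [blocks[s] for s in stats], axis=1
    ).reshape(n, len(stats), v).transpose(0, 2, 1).reshape(n, v * len(stats))
    out = pd.DataFrame(data, columns=columns, index=variables.index)
    return out


def _variable_frame(cells: CellTable, use_cell_types: bool, markers: Optional[Sequence[str]]):
    """Split a cell table into (one-hot categorical, continuous) variable blocks."""
    schema = cells.schema
    onehot = None
    if use_cell_types and schema.cell_type is not None:
        cats = pd.Categorical(cells.df[schema.cell_type])
        onehot = pd.get_dummies(cats).astype(float)
        onehot.columns = [f"type:{c}" for c in onehot.columns]
        onehot.index = cells.df.index
    cont = None
    marker_cols = list(markers) if markers is not None else list(schema.continuous)
    if marker_cols:
        cont = cells.df[marker_cols].astype(float)
    return onehot, cont


def nas_table(
    cells: CellTable,
    networks: Dict[object, SpatialNetwork],
    order: int = 1,
    include_self: bool = True,
    statistics: Sequence[str] = ("mean", "sd"),
    categorical_statistics: Sequence[str] = ("mean",),
    use_cell_types: bool = True,
    markers: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pooled NAS table over all samples, rows indexed by (sample, node id).

    Cell-type labels are expanded to one-hot indicators whose neighborhood
    mean is the local type proportion; continuous markers get the full
    ``statistics`` set.  Rows are sorted by sample then node id.
    """
    pieces = []
    for sid, sub in cells.sorted().per_sample():
        net = networks[sid]
        if net.n_nodes != len(sub):
            raise ValueError(f"network for sample {sid!r} does not match its cell count")
        member = neighborhood_matrix(net, order=order, include_self=include_self)
        onehot, cont = _variable_frame(sub, use_cell_types, markers)
        blocks = []
        if onehot is not None:
            blocks.append(nas_statistics(onehot, member, categorical_statistics))
        if cont is not None:
            blocks.append(nas_statistics(cont, member, statistics))
        if not blocks:
            raise ValueError("no variables to aggregate: no cell types and no markers")
        frame = pd.concat(blocks, axis=1)
        frame.index = pd.MultiIndex.from_arrays(
            [sub.df[sub.schema.sample], sub.df[sub.schema.node]], names=["sample", "node"]
        )
        pieces.append(frame)
    out = pd.concat(pieces, axis=0)
    out.attrs["order"] = order
    out.attrs["include_self"] = include_self
    return out


# ---------------------------------------------------------------------------
# clustering into niches


@dataclass
class NicheAssignment:
    """Joint niche labels for every cell across all samples."""

    labels: pd.Series  # indexed like the NAS table rows
    n_niches: int
    proportions: pd.DataFrame  # samples × niches, rows sum to 1
    method: dict

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-sample niche proportions must sum to 1")


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _reduce(X: np.ndarray, dr: str, dr_dims: int, seed: Optional[int]) -> np.ndarray:
    if dr == "none":
        return X
    if dr == "pca":
        return PCA(n_components=min(dr_dims, X.shape[1]), random_state=seed).fit_transform(X)
    if dr == "umap":
        import umap  # deferred: numba-jitted import is slow

        reducer = umap.UMAP(n_components=dr_dims, random_state=seed)
        return reducer.fit_transform(X)
    raise ValueError(f"unknown dimensionality reduction {dr!r}")


def _cluster(X: np.ndarray, method: str, k_or_resolution, seed: Optional[int]) -> np.ndarray:
    if method == "kmeans":
        k = int(k_or_resolution)
        if k > len(X):
            raise ValueError(f"k={k} exceeds the number of cells ({len(X)})")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "gmm":
        k = int(k_or_resolution)
        if k > len(X):
            raise ValueError(f"k={k} exceeds the number of cells ({len(X)})")
        gm = GaussianMixture(n_components=k, random_state=seed)
        return gm.fit_predict(X)
    if method == "leiden":
        import igraph
        import leidenalg
        from sklearn.neighbors import NearestNeighbors

        n_neighbors = min(15, len(X) - 1)
        knn = NearestNeighbors(n_neighbors=n_neighbors).fit(X)
        _, idx = knn.kneighbors(X)
        edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
        g = igraph.Graph(n=len(X), edges=sorted(edges))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(k_or_resolution),
            seed=seed if seed is not None else 0,
        )
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_niches(
    nas: pd.DataFrame,
    dr: str = "umap",
    dr_dims: int = 2,
    cluster: str = "kmeans",
    k_or_resolution=2,
    seed: Optional[int] = 0,
) -> NicheAssignment:
    """Cluster the pooled NAS table into niches.

    Columns are z-scored first (the table mixes proportions and marker
    scales), then optionally reduced (UMAP or PCA), then clustered in a
    single run over all samples so niche labels are comparable across
    patients.  Deterministic given ``seed``.
    """
    X = _standardize(nas.to_numpy(dtype=float))
    emb = _reduce(X, dr, dr_dims, seed)
    labels = _cluster(emb, cluster, k_or_resolution, seed)
    label_series = pd.Series(labels, index=nas.index, name="niche")
    samples = nas.index.get_level_values("sample")
    counts = pd.crosstab(samples, label_series)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return NicheAssignment(
        labels=label_series,
        n_niches=int(len(np.unique(labels))),
        proportions=proportions,
        method={
            "dr": dr, "dr_dims": dr_dims, "cluster": cluster,
            "k_or_resolution": k_or_resolution, "seed": seed,
        },
    )


def silhouette_scan(
    nas: pd.DataFrame,
    dr_settings: Sequence[dict] = ({"dr": "none", "dr_dims": 0},),
    k_range: Iterable[int] = range(2, 7),
    cluster: str = "kmeans",
    seed: Optional[int] = 0,
    subsample_cap: int = 10_000,
) -> pd.DataFrame:
    """Mean silhouette score over a grid of DR settings and cluster counts.

    Tables larger than ``subsample_cap`` rows are subsampled (seeded)
    before scoring to bound cost.
    """
    X_full = _standardize(nas.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    if len(X_full) > subsample_cap:
        keep = rng.choice(len(X_full), size=subsample_cap, replace=False)
        X_full = X_full[keep]
    records = []
    for setting in dr_settings:
        emb = _reduce(X_full, setting.get("dr", "none"), setting.get("dr_dims", 2), seed)
        for k in k_range:
            if not 2 <= k <= len(emb) - 1:
                raise ValueError(f"k={k} outside the valid range [2, {len(emb) - 1}]")
            labels = _cluster(emb, cluster, k, seed)
            score = silhouette_score(emb, labels) if len(np.unique(labels)) > 1 else np.nan
            records.append({**setting, "k": k, "silhouette": score})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# differential niche analysis


def differential_niche_analysis(
    nas: pd.DataFrame,
    niches: NicheAssignment,
    niche_a,
    niche_b,
    cell_filter: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Compare NAS variables between the cells of two niches.

    Restricting to one cell type via ``cell_filter`` (a boolean Series
    aligned with the NAS rows) isolates environment-driven differences
    from composition leakage.  Each NAS column gets a two-sided rank-sum
    test, an effect direction (sign of the median difference a − b), and
    a Benjamini–Hochberg q-value; rows are sorted by q.
    """
    labels = niches.labels
    if cell_filter is not None:
        mask = cell_filter.reindex(nas.index).fillna(False).astype(bool)
        if not mask.any():
            raise ValueError("cell_filter removed every cell")
        nas = nas[mask.to_numpy()]
        labels = labels[mask.to_numpy()]
    in_a = labels == niche_a
    in_b = labels == niche_b
    if not in_a.any():
        raise ValueError(f"niche {niche_a!r} is empty after filtering")
    if not in_b.any():
        raise ValueError(f"niche {niche_b!r} is empty after filtering")

    records = []
    self_compare = niche_a == niche_b
    for col in nas.columns:
        va = nas.loc[in_a.to_numpy(), col].to_numpy(dtype=float)
        vb = nas.loc[in_b.to_numpy(), col].to_numpy(dtype=float)
        effect = float(np.median(va) - np.median(vb))
        if self_compare:
            stat, p, effect = np.nan, 1.0, 0.0
        elif np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]:
            stat, p = np.nan, 1.0  # identical constants: no information
        else:
            stat, p = mannwhitneyu(va, vb, alternative="two-sided")
        name = "|".join(map(str, col)) if isinstance(col, tuple) else str(col)
        records.append({"variable": name, "statistic": stat, "p": p, "effect": effect})
    table = pd.DataFrame(records)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("q", kind="mergesort").reset_index(drop=True)
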