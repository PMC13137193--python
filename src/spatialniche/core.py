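"""Core containers: cell tables with explicit schemas and spatial networks.

A :class:`CellTable` is a pandas DataFrame plus a :class:`CellSchema` that
names which columns hold coordinates, sample ids, the cell-type label and
the continuous markers.  Column roles are always explicit — they are never
guessed from dtypes, because spatial-omics exports disagree wildly on
conventions (integer-coded types, string sample ids, micron floats stored
as strings, ...).

A :class:`SpatialNetwork` is a light immutable-ish graph: an ordered node
set with coordinates, an edge array of positional indices, and an optional
row-aligned attribute frame.  Undirected edges are stored canonically
(smaller index first) with duplicates and self-loops rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class CellSchema:
    """Column roles for a per-cell table.

    Parameters
    ----------
    sample:
        Column holding the sample (image / patient / ROI) identifier.
    node:
        Column holding the node id, unique within each sample.
    coords:
        Coordinate columns in microns; two entries for 2D, three for 3D.
    cell_type:
        The categorical cell-type column, or ``None`` when the table has
        no type labels (e.g. spot data clustered later).
    categorical:
        Additional categorical columns (niche labels, marker-positivity
        flags treated as categories, histological region, ...).
    continuous:
        Continuous marker / gene-level columns.
    """

    sample: str = "sample_id"
    node: str = "node_id"
    coords: Tuple[str, ...] = ("x", "y")
    cell_type: Optional[str] = "cell_type"
    categorical: Tuple[str, ...] = ()
    continuous: Tuple[str, ...] = ()

    @property
    def all_categorical(self) -> Tuple[str, ...]:
        if self.cell_type is None:
            return tuple(self.categorical)
        return (self.cell_type, *self.categorical)

    @property
    def ndim(self) -> int:
        return len(self.coords)

    def required_columns(self) -> Tuple[str, ...]:
        return (
            self.sample,
            self.node,
            *self.coords,
            *self.all_categorical,
            *self.continuous,
        )


@dataclass
class CellTable:
    """Validated per-cell records for one or more samples."""

    df: pd.DataFrame
    schema: CellSchema = field(default_factory=CellSchema)

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.required_columns() if c not in self.df.columns]
        if missing:
            raise ValueError(f"cell table is missing schema column(s): {missing}")
        coords = self.df[list(self.schema.coords)]
        for col in self.schema.coords:
            values = pd.to_numeric(coords[col], errors="coerce")
            bad = values.index[~np.isfinite(values.to_numpy(dtype=float))]
            if len(bad):
                raise ValueError(
                    f"non-finite or non-numeric coordinate in column {col!r} "
                    f"at row index {bad[0]}"
                )
        dup = self.df.groupby(self.schema.sample, observed=True)[self.schema.node].apply(
            lambda s: s.duplicated().any()
        )
        if bool(dup.any()):
            offenders = list(dup.index[dup])
            raise ValueError(f"duplicate node ids within sample(s): {offenders}")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[list(self.schema.coords)].to_numpy(dtype=float)

    @property
    def samples(self) -> list:
        return list(pd.unique(self.df[self.schema.sample]))

    def per_sample(self) -> Iterator[Tuple[object, "CellTable"]]:
        """Yield ``(sample_id, sub-table)`` pairs in first-appearance order."""
        for sid in self.samples:
            mask = self.df[self.schema.sample] == sid
            yield sid, CellTable(self.df[mask].reset_index(drop=True), self.schema)

    def sorted(self) -> "CellTable":
        """Rows sorted by (sample, node id) — the reproducible canonical order."""
        out = self.df.sort_values(
            [self.schema.sample, self.schema.node], kind="mergesort"
        ).reset_index(drop=True)
        return CellTable(out, self.schema)


def _canonical_edges(edges: np.ndarray, n_nodes: int, directed: bool) -> np.ndarray:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        return edges
    if edges.min() < 0 or edges.max() >= n_nodes:
        raise ValueError("edge endpoint outside the node set")
    if np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("self-loops are not allowed")
    if not directed:
        edges = np.sort(edges, axis=1)
    edges = np.unique(edges, axis=0)
    return edges


@dataclass
class SpatialNetwork:
    """A spatial graph over an ordered node set.

    ``edges`` hold *positional* indices into the node order; ``node_ids``
    keeps the original ids so results can be joined back to cell tables.
    """

    coords: np.ndarray
    edges: np.ndarray
    directed: bool = False
    node_ids: Optional[np.ndarray] = None
    attrs: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a (n_nodes, dim) array")
        n = len(self.coords)
        self.edges = _canonical_edges(self.edges, n, self.directed)
        if self.node_ids is None:
            self.node_ids = np.arange(n)
        else:
            self.node_ids = np.asarray(self.node_ids)
            if len(self.node_ids) != n:
                raise ValueError("node_ids length does not match coords")
        if self.attrs is not None and len(self.attrs) != n:
            raise ValueError("attrs must be row-aligned with the node set")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every edge, in coordinate units."""
        u, v = self.edges[:, 0], self.edges[:, 1]
        return np.linalg.norm(self.coords[u] - self.coords[v], axis=1)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def with_edges(self, edges: np.ndarray) -> "SpatialNetwork":
        return replace(self, edges=edges)

    def attribute(self, attr) -> pd.Series:
        """Resolve an attribute given as a column name, Series, or array."""
        if isinstance(attr, str):
            if self.attrs is None or attr not in self.attrs.columns:
                raise KeyError(f"network has no attribute column {attr!r}")
            return self.attrs[attr].reset_index(drop=True)
        s = pd.Series(np.asarray(attr)).reset_index(drop=True)
        if len(s) != self.n_nodes:
            raise ValueError("attribute length does not match node count")
        return s


def to_adjacency(net: SpatialNetwork) -> sparse.csr_matrix:
    """Sparse 0/1 adjacency in node order; symmetric when undirected."""
    n = net.n_nodes
    if net.n_edges == 0:
        return sparse.csr_matrix((n, n))
    u, v = net.edges[:, 0], net.edges[:, 1]
    data = np.ones(len(u))
    mat = sparse.coo_matrix((data, (u, v)), shape=(n, n))
    if not net.directed:
        mat = mat + mat.T
    return mat.tocsr()


def from_adjacency(
    adj: sparse.spmatrix,
    coords: np.ndarray,
    directed: bool = False,
    node_ids: Optional[np.ndarray] = None,
    attrs: Optional[pd.DataFrame] = None,
) -> SpatialNetwork:
    """Rebuild a network from an adjacency matrix (inverse of to_adjacency)."""
    adj = sparse.csr_matrix(adj)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not directed and (adj != adj.T).nnz:
        raise ValueError("asymmetric adjacency for an undirected network")
    coo = sparse.triu(adj, k=1).tocoo() if not directed else adj.tocoo()
    edges = np.column_stack([coo.row, coo.col])
    if directed:
        edges = edges[edges[:, 0] != edges[:, 1]]
    return SpatialNetwork(
        coords=coords, edges=edges, directed=directed, node_ids=node_ids, attrs=attrs
    )


def network_from_cells(cells: CellTable, edges: np.ndarray, directed: bool = False) -> SpatialNetwork:
    """Wrap a cell table and an edge array into a SpatialNetwork."""
    tab = cells.sorted()
    return SpatialNetwork(
        coords=tab.coords,
        edges=edges,
        directed=directed,
        node_ids=tab.df[tab.schema.node].to_numpy(),
        attrs=tab.df.reset_index(drop=True),
    )
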