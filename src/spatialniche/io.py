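"""Readers and writers for cell tables, edge lists, and h5ad interop.

Column roles are always taken from an explicit :class:`CellSchema`
(optionally loaded from a YAML/TOML sidecar) — never guessed from dtypes.
Formats are inferred from the file extension (csv/tsv/parquet) unless
forced.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import CellSchema, CellTable, SpatialNetwork, from_adjacency, to_adjacency

logger = logging.getLogger(__name__)

_FORMATS = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".parquet": "parquet", ".pq": "parquet"}


def schema_from_mapping(mapping: dict) -> CellSchema:
    """Build a CellSchema from a plain dict (parsed YAML/TOML)."""
    return CellSchema(
        sample=mapping.get("sample", "sample_id"),
        node=mapping.get("node", "node_id"),
        coords=tuple(mapping.get("coords", ("x", "y"))),
        cell_type=mapping.get("cell_type", "cell_type"),
        categorical=tuple(mapping.get("categorical", ())),
        continuous=tuple(mapping.get("continuous", ())),
    )


def load_schema(path: Path) -> CellSchema:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return schema_from_mapping(yaml.safe_load(text))
    if path.suffix == ".toml":
        import tomllib

        return schema_from_mapping(tomllib.loads(text))
    raise ValueError(f"unsupported schema format {path.suffix!r}")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    try:
        return _FORMATS[Path(path).suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from extension {Path(path).suffix!r}") from None


def read_cells(path, schema: CellSchema, fmt: Optional[str] = None) -> CellTable:
    """Read and validate a cell table from csv/tsv/parquet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _infer_format(path, fmt)
    if kind == "csv":
        df = pd.read_csv(path)
    elif kind == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif kind == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unsupported format {kind!r}")
    table = CellTable(df, schema)
    counts = df[schema.sample].value_counts()
    logger.info("read %d cells across %d sample(s) from %s", len(df), len(counts), path)
    return table


def write_cells(cells: CellTable, path, fmt: Optional[str] = None) -> Path:
    path = Path(path)
    kind = _infer_format(path, fmt)
    if kind == "csv":
        cells.df.to_csv(path, index=False)
    elif kind == "tsv":
        cells.df.to_csv(path, sep="\t", index=False)
    elif kind == "parquet":
        cells.df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported format {kind!r}")
    return path


def write_edges(net: SpatialNetwork, path) -> Path:
    """Edge list as TSV: source_id, target_id, length (original node ids)."""
    path = Path(path)
    ids = net.node_ids
    frame = pd.DataFrame({
        "source_id": ids[net.edges[:, 0]],
        "target_id": ids[net.edges[:, 1]],
        "length": net.edge_lengths(),
    })
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_edges(path, net_template: SpatialNetwork) -> SpatialNetwork:
    """Rebuild a network's edges from a TSV edge list over the same nodes."""
    frame = pd.read_csv(Path(path), sep="\t")
    pos = {nid: i for i, nid in enumerate(net_template.node_ids)}
    edges = np.column_stack([
        [pos[s] for s in frame["source_id"]],
        [pos[t] for t in frame["target_id"]],
    ])
    return net_template.with_edges(edges)


# ---------------------------------------------------------------------------
# h5ad interop

SPATIAL_KEY = "spatial"
GRAPH_KEY = "spatial_connectivities"


def write_h5ad_interop(cells: CellTable, path, net: Optional[SpatialNetwork] = None):
    """Write cells (and optionally their graph) into an AnnData container.

    Continuous markers become the expression matrix X, categorical columns
    go to ``obs``, coordinates to ``obsm['spatial']``, and the adjacency
    (if a network is given) to ``obsp['spatial_connectivities']``.
    """
    import anndata as ad

    tab = cells.sorted()
    schema = tab.schema
    X = tab.df[list(schema.continuous)].to_numpy(dtype=float) if schema.continuous else \
        np.zeros((len(tab), 0))
    obs = pd.DataFrame(index=tab.df[schema.node].astype(str))
    obs[schema.sample] = tab.df[schema.sample].to_numpy()
    for col in schema.all_categorical:
        obs[col] = pd.Categorical(tab.df[col].to_numpy())
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = list(schema.continuous)
    adata.obsm[SPATIAL_KEY] = tab.coords
    adata.uns["cell_schema"] = {
        "sample": schema.sample, "node": schema.node,
        "coords": list(schema.coords), "cell_type": schema.cell_type or "",
        "categorical": list(schema.categorical), "continuous": list(schema.continuous),
    }
    if net is not None:
        adata.obsp[GRAPH_KEY] = to_adjacency(net)
    adata.write_h5ad(Path(path))
    return Path(path)


def read_h5ad_interop(path) -> tuple[CellTable, Optional[SpatialNetwork]]:
    """Read cells and the optional spatial graph back from an h5ad container."""
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    if SPATIAL_KEY not in adata.obsm:
        raise ValueError(f"h5ad container has no {SPATIAL_KEY!r} coordinate slot")
    meta = adata.uns.get("cell_schema", {})
    coords_names = tuple(meta.get("coords", ("x", "y")[: adata.obsm[SPATIAL_KEY].shape[1]]))
    schema = CellSchema(
        sample=meta.get("sample", "sample_id"),
        node=meta.get("node", "node_id"),
        coords=coords_names,
        cell_type=(meta.get("cell_type") or None),
        categorical=tuple(meta.get("categorical", ())),
        continuous=tuple(meta.get("continuous", list(adata.var_names))),
    )
    df = pd.DataFrame(adata.obs.reset_index(drop=True))
    try:
        df[schema.node] = pd.to_numeric(adata.obs.index.to_numpy())
    except (ValueError, TypeError):
        df[schema.node] = adata.obs.index.to_numpy()
    coords = np.asarray(adata.obsm[SPATIAL_KEY], dtype=float)
    for d, col in enumerate(schema.coords):
        df[col] = coords[:, d]
    for j, name in enumerate(adata.var_names):
        df[name] = np.asarray(adata.X[:, j]).ravel()
    cells = CellTable(df[list(schema.required_columns())], schema)
    net = None
    if GRAPH_KEY in adata.obsp:
        adj = adata.obsp[GRAPH_KEY]
        if (adj != adj.T).nnz:
            raise ValueError("stored adjacency is asymmetric in an undirected container")
        net = from_adjacency(
            adj, coords, directed=False,
            node_ids=df[schema.node].to_numpy(),
            attrs=df.reset_index(drop=True),
        )
    return cells, net
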