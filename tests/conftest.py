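"""Shared fixtures: tiny hand-built networks and synthetic tissues."""

import numpy as np
import pandas as pd
import pytest

from spatialniche import CellSchema, CellTable, SpatialNetwork


def make_net(coords, edges, types=None, directed=False, **attr_cols):
    """Build a SpatialNetwork from plain lists, with optional attributes."""
    coords = np.asarray(coords, dtype=float)
    attrs = {}
    if types is not None:
        attrs["cell_type"] = list(types)
    attrs.update(attr_cols)
    frame = pd.DataFrame(attrs) if attrs else None
    return SpatialNetwork(
        coords=coords, edges=np.asarray(edges).reshape(-1, 2),
        directed=directed, attrs=frame,
    )


def cells_from_points(points, types=None, sample="S0", markers=None):
    points = np.asarray(points, dtype=float)
    data = {
        "sample_id": sample,
        "node_id": np.arange(len(points)),
        "x": points[:, 0],
        "y": points[:, 1],
    }
    continuous = ()
    cell_type = None
    if types is not None:
        data["cell_type"] = list(types)
        cell_type = "cell_type"
    if markers is not None:
        for name, vals in markers.items():
            data[name] = vals
        continuous = tuple(markers)
    schema = CellSchema(cell_type=cell_type, continuous=continuous)
    return CellTable(pd.DataFrame(data), schema)


@pytest.fixture
def triangle_net():
    """Equilateral triangle, all edges length 1."""
    coords = [(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)]
    return make_net(coords, [(0, 1), (1, 2), (0, 2)], types="AAA")


@pytest.fixture
def two_triangles_net():
    """Two disjoint monochromatic triangles: one all A, one all B."""
    coords = [(0, 0), (1, 0), (0.5, 1), (10, 0), (11, 0), (10.5, 1)]
    edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    return make_net(coords, edges, types="AAABBB")


@pytest.fixture
def k33_net():
    """Complete bipartite K3,3 with side A one type, side B the other."""
    coords = [(0, i) for i in range(3)] + [(1, i) for i in range(3)]
    edges = [(i, 3 + j) for i in range(3) for j in range(3)]
    return make_net(coords, edges, types="AAABBB")


def random_geometric_net(n, rng, radius=None, n_types=3):
    """Seeded random geometric graph with random categorical labels."""
    from scipy.spatial import cKDTree

    coords = rng.uniform(0, 1, size=(n, 2))
    if radius is None:
        radius = 1.8 / np.sqrt(n)  # keeps the graph connected-ish and sparse
    pairs = cKDTree(coords).query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:  # fall back to a path so there is at least one edge
        pairs = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    types = rng.choice([f"T{i}" for i in range(n_types)], size=n)
    return make_net(coords, pairs, types=types)
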