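"""Spatial network reconstruction from cell or spot coordinates.

Two builders cover the common acquisition geometries:

* :func:`build_delaunay` — Delaunay triangulation for irregularly placed
  cells (segmented imaging data), followed by :func:`trim_edges` to remove
  the long boundary artifacts triangulation creates between cells that are
  geometrically adjacent but biologically far apart.
* :func:`build_lattice` — regular-array data (Visium-style spots) where
  every spot is linked to the neighbors at the minimal inter-spot distance.

Trimming is adaptive to local density: when an edge is tested at one of
its endpoints, the reference length is the mean of that node's three
shortest *other* incident edges, and the edge is dropped when it is
longer than ``factor`` times the reference at either endpoint.  Excluding
the candidate from its own reference keeps the rule sharp at low-degree
boundary nodes, where a single artifact edge would otherwise inflate its
own threshold.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core import CellTable, SpatialNetwork, network_from_cells

logger = logging.getLogger(__name__)


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
    except QhullError as err:  # degenerate geometry: collinear/coplanar/coincident
        raise ValueError(
            f"Delaunay triangulation failed on degenerate point set "
            f"({points.shape[0]} points in {points.shape[1]}D): {err}"
        ) from None
    simplices = tri.simplices
    k = simplices.shape[1]
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(simplices[:, [i, j]])
    edges = np.vstack(pairs)
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def build_delaunay(
    cells: CellTable,
    on_duplicates: str = "error",
    seed: Optional[int] = None,
) -> SpatialNetwork:
    """Build the Delaunay graph of a single sample's cells.

    Parameters
    ----------
    cells:
        Cell table for one sample, 2D or 3D coordinates.
    on_duplicates:
        ``"error"`` (default) rejects coincident coordinates; ``"jitter"``
        displaces duplicates deterministically by ``1e-6 × d_min`` using
        ``seed``.  Delaunay triangulation is undefined on duplicates, so
        silent jitter is opt-in.
    """
    tab = cells.sorted()
    points = tab.coords
    dim = points.shape[1]
    if len(points) < dim + 1:
        raise ValueError(
            f"need at least {dim + 1} points for a {dim}D triangulation, got {len(points)}"
        )
    uniq, counts = np.unique(points, axis=0, return_counts=True)
    if (counts > 1).any():
        if on_duplicates == "error":
            raise ValueError(
                f"{int((counts > 1).sum())} duplicated coordinate(s); "
                "pass on_duplicates='jitter' to displace them deterministically"
            )
        if on_duplicates != "jitter":
            raise ValueError(f"unknown duplicate policy {on_duplicates!r}")
        tree = cKDTree(uniq)
        d_min = tree.query(uniq, k=2)[0][:, 1].min()
        rng = np.random.default_rng(seed)
        points = points + rng.normal(scale=1e-6 * d_min, size=points.shape)
    edges = _delaunay_edges(points)
    net = network_from_cells(tab, edges, directed=False)
    return net


def trim_edges(
    net: SpatialNetwork,
    factor: float = 2.0,
    k_ref: int = 3,
    rule: str = "or",
) -> SpatialNetwork:
    """Adaptively remove implausibly long edges.

    For each node the reference length is the mean of its ``min(k_ref,
    degree)`` shortest incident edges.  Under the default ``"or"`` rule an
    edge is removed when its length exceeds ``factor × reference`` at
    *either* endpoint (the stricter reading, which removes the boundary
    artifacts Delaunay produces); ``"and"`` requires both endpoints to
    object.  The node set is unchanged — nodes isolated by trimming are
    kept and logged.
    """
    if net.directed:
        raise ValueError("trim_edges expects an undirected network")
    if rule not in ("or", "and"):
        raise ValueError(f"unknown trimming rule {rule!r}")
    if net.n_edges == 0:
        return net.with_edges(net.edges)
    n = net.n_nodes

    def one_pass(edges: np.ndarray) -> np.ndarray:
        lengths = np.linalg.norm(
            net.coords[edges[:, 0]] - net.coords[edges[:, 1]], axis=1
        )
        incident: list[list[float]] = [[] for _ in range(n)]
        for (u, v), ln in zip(edges, lengths):
            incident[u].append(ln)
            incident[v].append(ln)
        sorted_incident = [np.sort(np.asarray(lens)) for lens in incident]

        def too_long(node: int, length: float) -> bool:
            # reference = mean of the node's k_ref shortest *other*
            # incident edges; a pendant edge (no others) can never be
            # trimmed on its own endpoint's account
            lens = sorted_incident[node]
            pos = int(np.searchsorted(lens, length))
            others = np.delete(lens, pos)
            if len(others) == 0:
                return False
            ref = others[: min(k_ref, len(others))].mean()
            return length > factor * ref

        at_u = np.array([too_long(u, ln) for (u, _), ln in zip(edges, lengths)])
        at_v = np.array([too_long(v, ln) for (_, v), ln in zip(edges, lengths)])
        drop = (at_u | at_v) if rule == "or" else (at_u & at_v)
        return edges[~drop]

    # iterate to a fixed point: removing an edge can change a neighbor's
    # reference, so one pass is not idempotent on its own
    kept = net.edges
    while True:
        next_kept = one_pass(kept)
        if len(next_kept) == len(kept):
            break
        kept = next_kept
    trimmed = net.with_edges(kept)
    n_isolated = int((trimmed.degrees() == 0).sum())
    if n_isolated:
        logger.warning(
            "trim_edges removed %d/%d edges, leaving %d isolated node(s)",
            net.n_edges - len(kept),
            net.n_edges,
            n_isolated,
        )
    return trimmed


def build_spatial_network(
    cells: CellTable,
    trim_factor: Optional[float] = 2.0,
    k_ref: int = 3,
    on_duplicates: str = "error",
    seed: Optional[int] = None,
) -> SpatialNetwork:
    """Delaunay graph with adaptive trimming — the default tissue-graph recipe."""
    net = build_delaunay(cells, on_duplicates=on_duplicates, seed=seed)
    if trim_factor is not None and np.isfinite(trim_factor):
        net = trim_edges(net, factor=trim_factor, k_ref=k_ref)
    return net


def build_lattice(cells: CellTable, tolerance: float = 0.05) -> SpatialNetwork:
    """Link regular-lattice spots to all neighbors at the minimal spacing.

    Computes the minimal pairwise inter-spot distance ``d_min`` and links
    every pair at distance ≤ ``d_min × (1 + tolerance)``.  On a hexagonal
    Visium-style array interior spots get 6 neighbors; on a square grid, 4.
    """
    tab = cells.sorted()
    points = tab.coords
    if len(points) < 2:
        raise ValueError("need at least 2 spots to build a lattice graph")
    tree = cKDTree(points)
    nn_dist = tree.query(points, k=2)[0][:, 1]
    d_min = float(nn_dist.min())
    if d_min == 0.0:
        raise ValueError("coincident spots: minimal inter-spot distance is zero")
    pairs = tree.query_pairs(r=d_min * (1.0 + tolerance), output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no spot pairs within the lattice linking radius")
    return network_from_cells(tab, pairs, directed=False)
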