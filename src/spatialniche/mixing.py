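"""Mixing matrices, assortativity, permutation z-scores, and imputation.

The mixing matrix ``e`` of a network with a categorical node attribute
has elements ``e_ij`` equal to the fraction of edge *stub pairs* joining
an ``i``-node to a ``j``-node.  For undirected networks each edge is
counted once in each orientation, so ``e`` is symmetric and the marginals
``a = e.sum(axis=1)`` and ``b = e.sum(axis=0)`` coincide.  The
assortativity coefficient

    r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i)

is 1 when neighbors always share the attribute, 0 when the matrix factors
into its marginals (no association), and negative — down to −1 — when
neighbors preferentially differ.

Because abundant cell types interact often purely through abundance, raw
``e_ij`` values are normalized against a permutation null: attributes are
shuffled across the nodes of the *same* network (preserving the attribute
proportions) and each element is z-scored against the permuted ensemble.
Elements whose permuted values never vary are reported as undefined via a
mask, never as a silent 0.

Non-exclusive attributes (marker-positivity flags, where one cell may be
positive for several markers) are supported by counting one ordered stub
pair per (edge, positive-marker-of-u, positive-marker-of-v) combination
and normalizing by the total count, which preserves every mixing-matrix
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .core import SpatialNetwork

__all__ = [
    "MixingMatrix",
    "ZScoredStats",
    "mixing_matrix",
    "mixing_matrix_nonexclusive",
    "mixing_matrix_directed",
    "assortativity",
    "zscore_mixing",
    "impute_missing_mm",
]


@dataclass
class MixingMatrix:
    """Square edge-fraction matrix with marginals and category labels."""

    e: np.ndarray
    labels: list
    directed: bool = False
    exclusive: bool = True
    n_edges_counted: int = 0

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if self.e.ndim != 2 or self.e.shape[0] != self.e.shape[1]:
            raise ValueError("mixing matrix must be square")
        if len(self.labels) != self.e.shape[0]:
            raise ValueError("label count does not match matrix size")
        if (self.e < -1e-12).any():
            raise ValueError("mixing matrix has negative elements")
        if self.n_edges_counted and abs(self.e.sum() - 1.0) > 1e-9:
            raise ValueError("mixing matrix elements must sum to 1")

    @property
    def a(self) -> np.ndarray:
        """Row marginals a_i = Σ_j e_ij."""
        return self.e.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        """Column marginals b_j = Σ_i e_ij."""
        return self.e.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.e, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format (attr_i, attr_j, e) — the lossless on-disk layout."""
        frame = self.to_frame().stack()
        out = frame.rename_axis(["attr_i", "attr_j"]).rename("e").reset_index()
        return out


@dataclass
class ZScoredStats:
    """Permutation z-scores for a mixing matrix and its assortativity."""

    z_mm: np.ndarray
    z_ac: float
    observed: MixingMatrix
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    n_perm: int
    seed: Optional[int]
    undefined_mask: np.ndarray
    z_ac_undefined: bool = False

    def z_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            self.z_mm, index=self.observed.labels, columns=self.observed.labels
        )
        return out.mask(pd.DataFrame(self.undefined_mask, index=out.index, columns=out.columns))


def _codes(values: pd.Series) -> tuple[np.ndarray, list]:
    if values.isna().any():
        raise ValueError("attribute has missing values; drop or fill them first")
    cat = pd.Categorical(values)
    return cat.codes.astype(np.int64), list(cat.categories)


def _exclusive_counts(edges: np.ndarray, codes: np.ndarray, k: int, directed: bool) -> np.ndarray:
    counts = np.zeros((k, k))
    u, v = codes[edges[:, 0]], codes[edges[:, 1]]
    np.add.at(counts, (u, v), 1.0)
    if not directed:
        np.add.at(counts, (v, u), 1.0)
    return counts


def mixing_matrix(net: SpatialNetwork, attr) -> MixingMatrix:
    """Mixing matrix of an undirected network over an exclusive attribute.

    Each edge contributes one count in each orientation (two ordered stub
    pairs), so the result is symmetric and sums to 1.
    """
    if net.directed:
        raise ValueError("use mixing_matrix_directed for directed networks")
    if net.n_edges == 0:
        raise ValueError("empty network: no edges to count")
    codes, labels = _codes(net.attribute(attr))
    counts = _exclusive_counts(net.edges, codes, len(labels), directed=False)
    return MixingMatrix(
        e=counts / counts.sum(),
        labels=labels,
        directed=False,
        exclusive=True,
        n_edges_counted=net.n_edges,
    )


def mixing_matrix_directed(net: SpatialNetwork, attr) -> MixingMatrix:
    """Mixing matrix where e_ij is the fraction of directed i→j edges."""
    if not net.directed:
        raise ValueError("network is undirected; use mixing_matrix")
    if net.n_edges == 0:
        raise ValueError("empty network: no edges to count")
    codes, labels = _codes(net.attribute(attr))
    counts = _exclusive_counts(net.edges, codes, len(labels), directed=True)
    return MixingMatrix(
        e=counts / counts.sum(),
        labels=labels,
        directed=True,
        exclusive=True,
        n_edges_counted=net.n_edges,
    )


def _flag_matrix(net: SpatialNetwork, marker_flags: Sequence) -> tuple[np.ndarray, list]:
    if isinstance(marker_flags, pd.DataFrame):
        frame = marker_flags.reset_index(drop=True)
    else:
        cols = {name: net.attribute(name) for name in marker_flags}
        frame = pd.DataFrame(cols)
    values = frame.to_numpy()
    if not np.isin(values, [0, 1, True, False]).all():
        bad = [c for c in frame.columns if not frame[c].isin([0, 1, True, False]).all()]
        raise ValueError(f"marker flag column(s) {bad} are not binary")
    return values.astype(float), list(frame.columns)


def _nonexclusive_counts(edges: np.ndarray, flags: np.ndarray, directed: bool) -> np.ndarray:
    u, v = edges[:, 0], edges[:, 1]
    counts = flags[u].T @ flags[v]
    if not directed:
        counts = counts + counts.T
    return counts


def mixing_matrix_nonexclusive(net: SpatialNetwork, marker_flags) -> MixingMatrix:
    """Mixing matrix over non-exclusive binary marker flags.

    For each edge (u, v) and each ordered marker pair (i, j) with u
    positive for i and v positive for j, one count is added (in both
    orientations when undirected); counts are normalized to sum 1.
    Multi-positive nodes intentionally contribute several counts; cells
    positive for no marker contribute nothing.
    """
    if net.n_edges == 0:
        raise ValueError("empty network: no edges to count")
    flags, labels = _flag_matrix(net, marker_flags)
    counts = _nonexclusive_counts(net.edges, flags, net.directed)
    total = counts.sum()
    if total == 0:
        raise ValueError("no positive marker pairs on any edge (all flags zero?)")
    return MixingMatrix(
        e=counts / total,
        labels=labels,
        directed=net.directed,
        exclusive=False,
        n_edges_counted=net.n_edges,
    )


def assortativity(mm: MixingMatrix) -> float:
    """Assortativity coefficient r from a mixing matrix, in [−1, 1]."""
    ab = float(mm.a @ mm.b)
    denom = 1.0 - ab
    if abs(denom) < 1e-12:
        raise ValueError(
            "assortativity undefined: only one category effectively present "
            "(Σ a_i b_i = 1)"
        )
    r = (float(np.trace(mm.e)) - ab) / denom
    return float(np.clip(r, -1.0, 1.0))


def _mm_for(net, edges, codes_or_flags, k, directed, nonexclusive):
    if nonexclusive:
        counts = _nonexclusive_counts(edges, codes_or_flags, directed)
    else:
        counts = _exclusive_counts(edges, codes_or_flags, k, directed)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _r_of(e: np.ndarray) -> float:
    a, b = e.sum(axis=1), e.sum(axis=0)
    ab = float(a @ b)
    if abs(1.0 - ab) < 1e-12:
        return np.nan
    return (float(np.trace(e)) - ab) / (1.0 - ab)


def zscore_mixing(
    net: SpatialNetwork,
    attr=None,
    n_perm: int = 100,
    seed: Optional[int] = None,
    nonexclusive: bool = False,
    marker_flags=None,
) -> ZScoredStats:
    """Z-score the mixing matrix and assortativity against a label-shuffle null.

    Attribute values (whole marker-flag rows in non-exclusive mode) are
    permuted across the nodes of this network, preserving the attribute
    proportions; each matrix element and r are z-scored against the
    permuted ensemble using the population SD.  Elements with zero
    permutation SD are masked as undefined.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    rng = np.random.default_rng(seed)
    if nonexclusive:
        if marker_flags is None:
            raise ValueError("non-exclusive mode requires marker_flags")
        data, labels = _flag_matrix(net, marker_flags)
        observed = mixing_matrix_nonexclusive(net, marker_flags)
        k = len(labels)
    else:
        if attr is None:
            raise ValueError("exclusive mode requires attr")
        data, labels = _codes(net.attribute(attr))
        k = len(labels)
        observed = (
            mixing_matrix_directed(net, attr) if net.directed else mixing_matrix(net, attr)
        )
    perm_e = np.empty((n_perm, k, k))
    perm_r = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(net.n_nodes)
        shuffled = data[perm]
        e = _mm_for(net, net.edges, shuffled, k, net.directed, nonexclusive)
        perm_e[p] = e
        perm_r[p] = _r_of(e)
    perm_mean = perm_e.mean(axis=0)
    perm_sd = perm_e.std(axis=0, ddof=0)
    undefined = perm_sd == 0.0
    z_mm = np.zeros((k, k))
    np.divide(observed.e - perm_mean, perm_sd, out=z_mm, where=~undefined)
    z_mm[undefined] = np.nan

    r_obs = _r_of(observed.e)
    r_sd = float(np.nanstd(perm_r, ddof=0)) if not np.isnan(perm_r).all() else 0.0
    z_ac_undefined = np.isnan(r_obs) or r_sd == 0.0 or np.isnan(perm_r).any()
    z_ac = np.nan if z_ac_undefined else float((r_obs - np.nanmean(perm_r)) / r_sd)

    return ZScoredStats(
        z_mm=z_mm,
        z_ac=z_ac,
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        n_perm=n_perm,
        seed=seed,
        undefined_mask=undefined,
        z_ac_undefined=bool(z_ac_undefined),
    )


@dataclass
class ImputationReport:
    dropped_variables: list = field(default_factory=list)
    dropped_samples: list = field(default_factory=list)


def impute_missing_mm(
    sample_features: pd.DataFrame,
    min_defined_fraction: float = 0.5,
    max_sample_missing: float = 0.5,
    k_neighbors: int = 5,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Filter sparsely defined interaction features and impute the rest.

    Rare cell types leave many mixing-matrix elements undefined in most
    samples.  Variables defined in fewer than ``min_defined_fraction`` of
    samples are dropped; then samples whose remaining missing fraction
    exceeds ``max_sample_missing`` are dropped; remaining gaps are filled
    by k-nearest-neighbor imputation over samples in standardized feature
    space.  Returns the completed table and a report of what was removed.
    """
    if not 0.0 <= min_defined_fraction <= 1.0:
        raise ValueError("min_defined_fraction must be in [0, 1]")
    defined_frac = sample_features.notna().mean(axis=0)
    keep_cols = defined_frac[defined_frac >= min_defined_fraction].index
    dropped_cols = [c for c in sample_features.columns if c not in set(keep_cols)]
    reduced = sample_features[keep_cols]
    if reduced.shape[1] == 0:
        worst = defined_frac.sort_values().index.tolist()
        raise ValueError(
            f"no variable is defined in ≥{min_defined_fraction:.0%} of samples; "
            f"sparsest variables: {worst[:5]}"
        )
    missing_frac = reduced.isna().mean(axis=1)
    keep_rows = missing_frac[missing_frac <= max_sample_missing].index
    dropped_rows = [r for r in reduced.index if r not in set(keep_rows)]
    reduced = reduced.loc[keep_rows]
    if reduced.shape[0] == 0:
        raise ValueError("every sample exceeds the missing-fraction cap")
    report = ImputationReport(dropped_variables=dropped_cols, dropped_samples=dropped_rows)
    if not reduced.isna().any().any():
        return reduced.copy(), report
    # standardize so kNN distances weight features comparably
    mu = reduced.mean(axis=0)
    sd = reduced.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (reduced - mu) / sd
    k = min(k_neighbors, max(1, reduced.shape[0] - 1))
    imputer = KNNImputer(n_neighbors=k)
    filled = imputer.fit_transform(z.to_numpy())
    out = pd.DataFrame(filled, index=reduced.index, columns=reduced.columns) * sd + mu
    return out, report
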