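"""Synthetic tissues and cohorts with planted spatial structure.

Every downstream stage of the package (graph building, mixing statistics,
niche discovery, clinical models) is exercised on tissues generated here,
so no external dataset is ever required.  The generator states a simple
world and sticks to it:

* Cells live on a square (or cubic) tissue of side ``size_um`` microns
  (default 1000 µm), positions uniform at random.
* Regions — the ground-truth niches — are either Voronoi cells of random
  seed points (``blobs``, tumor-niche-like) or horizontal bands
  (``layers``, cortical-layer-like).  Each region has its own cell-type
  composition and optionally its own marker shift.
* Markers follow a Gaussian model: each cell type has an identity marker
  with mean 2.0 (all other types mean 0), plus an optional region shift,
  plus N(0, ``marker_noise_sd``) noise.  Heavier-tailed models are out of
  scope.
* Cohorts plant an effect through the fraction of cells in region 0:
  binary cohorts shift that fraction between groups; survival cohorts
  draw exponential event times whose log-hazard is linear in the planted
  fraction, with independent exponential censoring tuned to the requested
  censoring rate.

The ground-truth region of every cell is written to a ``truth_niche``
column so recovery can be scored with ARI/AMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CellSchema, CellTable

__all__ = [
    "NicheSpec",
    "TissueSpec",
    "CohortSpec",
    "generate_tissue",
    "generate_cohort",
    "hex_bin_cells",
]

TRUTH_COLUMN = "truth_niche"


def _check_simplex(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} is not a simplex vector: {arr.tolist()}")
    return arr


@dataclass(frozen=True)
class NicheSpec:
    """One ground-truth region: its composition and optional marker shift."""

    type_proportions: Tuple[float, ...]
    marker_shift: Optional[Tuple[float, ...]] = None
    weight: float = 1.0  # relative share of the tissue claimed by this region


@dataclass(frozen=True)
class TissueSpec:
    """Declarative description of one synthetic tissue."""

    n_cells: int = 2000
    n_types: int = 3
    type_proportions: Optional[Tuple[float, ...]] = None
    layout: str = "random"  # random | blobs | layers
    niche_specs: Tuple[NicheSpec, ...] = ()
    n_markers: Optional[int] = None  # defaults to n_types (identity markers)
    marker_noise_sd: float = 0.3
    dimension: int = 2
    size_um: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_types < 1:
            raise ValueError("n_cells and n_types must be positive")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.layout not in ("random", "blobs", "layers"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be nonnegative")
        _check_simplex(self.global_proportions, "type_proportions")
        for i, niche in enumerate(self.niche_specs):
            _check_simplex(niche.type_proportions, f"niche_specs[{i}].type_proportions")
            if len(niche.type_proportions) != self.n_types:
                raise ValueError(
                    f"niche_specs[{i}].type_proportions has "
                    f"{len(niche.type_proportions)} entries, expected {self.n_types}"
                )
        if self.layout in ("blobs", "layers") and not self.niche_specs:
            raise ValueError(f"layout {self.layout!r} requires niche_specs")

    @property
    def global_proportions(self) -> np.ndarray:
        if self.type_proportions is None:
            return np.full(self.n_types, 1.0 / self.n_types)
        return np.asarray(self.type_proportions, dtype=float)

    @property
    def marker_count(self) -> int:
        return self.n_markers if self.n_markers is not None else self.n_types

    @property
    def type_names(self) -> List[str]:
        return [f"type_{chr(ord('A') + t)}" for t in range(self.n_types)]

    @property
    def marker_names(self) -> List[str]:
        return [f"marker_{m}" for m in range(self.marker_count)]

    def schema(self) -> CellSchema:
        coords = ("x", "y") if self.dimension == 2 else ("x", "y", "z")
        return CellSchema(
            sample="sample_id",
            node="node_id",
            coords=coords,
            cell_type="cell_type",
            categorical=(TRUTH_COLUMN,),
            continuous=tuple(self.marker_names),
        )


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of tissues sharing a template, with a planted outcome effect.

    ``effect`` names the planted feature: ``"niche_fraction"`` varies the
    fraction of cells in region 0 (baseline ``base_fraction``; binary
    cohorts add ``effect_size`` in the positive group, survival cohorts
    scale the log-hazard by ``effect_size`` per SD of the fraction).
    ``"none"`` plants nothing (null cohorts).
    """

    n_samples: int = 20
    outcome_kind: str = "binary"  # binary | survival
    effect: str = "niche_fraction"  # niche_fraction | none
    effect_size: float = 0.3
    base_fraction: float = 0.1
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.outcome_kind not in ("binary", "survival"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.effect not in ("niche_fraction", "none"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# tissue generation


def _region_labels(spec: TissueSpec, points: np.ndarray, rng: np.random.Generator,
                   weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Assign each cell to a ground-truth region according to the layout."""
    n_regions = len(spec.niche_specs)
    if spec.layout == "random" or n_regions == 0:
        return np.zeros(len(points), dtype=int)
    if weights is None:
        weights = np.asarray([n.weight for n in spec.niche_specs], dtype=float)
    weights = weights / weights.sum()
    if spec.layout == "layers":
        # horizontal bands stacked bottom-to-top with heights ∝ weights
        bounds = np.concatenate([[0.0], np.cumsum(weights)]) * spec.size_um
        y = points[:, 1]
        labels = np.searchsorted(bounds, y, side="right") - 1
        return np.clip(labels, 0, n_regions - 1)
    # blobs: Voronoi cells of random seed points; weights perturb seed counts
    # by duplicating seeds proportionally so heavier regions claim more area.
    seeds_per_region = np.maximum(1, np.round(weights * max(n_regions, 8)).astype(int))
    seed_points, seed_owner = [], []
    for region, k in enumerate(seeds_per_region):
        pts = rng.uniform(0, spec.size_um, size=(k, spec.dimension))
        seed_points.append(pts)
        seed_owner.extend([region] * k)
    seed_points = np.vstack(seed_points)
    seed_owner = np.asarray(seed_owner)
    d2 = ((points[:, None, :] - seed_points[None, :, :]) ** 2).sum(axis=2)
    return seed_owner[np.argmin(d2, axis=1)]


def generate_tissue(spec: TissueSpec, sample_id: str = "S0") -> CellTable:
    """Generate one synthetic tissue; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    points = rng.uniform(0, spec.size_um, size=(spec.n_cells, spec.dimension))
    regions = _region_labels(spec, points, rng)

    types = np.empty(spec.n_cells, dtype=int)
    if spec.niche_specs and spec.layout != "random":
        for region, niche in enumerate(spec.niche_specs):
            mask = regions == region
            if mask.any():
                types[mask] = rng.choice(
                    spec.n_types, size=int(mask.sum()), p=np.asarray(niche.type_proportions)
                )
    else:
        types[:] = rng.choice(spec.n_types, size=spec.n_cells, p=spec.global_proportions)

    # identity-marker means: each type lights up its own marker at 2.0
    n_markers = spec.marker_count
    type_means = np.zeros((spec.n_types, n_markers))
    for t in range(min(spec.n_types, n_markers)):
        type_means[t, t] = 2.0
    markers = type_means[types]
    for region, niche in enumerate(spec.niche_specs):
        if niche.marker_shift is not None:
            shift = np.asarray(niche.marker_shift, dtype=float)
            if len(shift) != n_markers:
                raise ValueError(
                    f"niche_specs[{region}].marker_shift has {len(shift)} entries, "
                    f"expected {n_markers}"
                )
            markers[regions == region] += shift
    if spec.marker_noise_sd > 0:
        markers = markers + rng.normal(0.0, spec.marker_noise_sd, size=markers.shape)

    schema = spec.schema()
    data = {
        schema.sample: sample_id,
        schema.node: np.arange(spec.n_cells),
    }
    for d, col in enumerate(schema.coords):
        data[col] = points[:, d]
    data[schema.cell_type] = pd.Categorical.from_codes(types, categories=spec.type_names)
    data[TRUTH_COLUMN] = regions
    for m, col in enumerate(spec.marker_names):
        data[col] = markers[:, m]
    return CellTable(pd.DataFrame(data), schema)


# ---------------------------------------------------------------------------
# cohort generation


def _two_region_template(spec: TissueSpec, fraction: float) -> TissueSpec:
    """Rescale region weights so region 0 claims ``fraction`` of the tissue."""
    n_regions = len(spec.niche_specs)
    if n_regions < 2:
        raise ValueError("planting a niche fraction requires ≥ 2 niche_specs")
    rest = np.asarray([n.weight for n in spec.niche_specs[1:]], dtype=float)
    rest = rest / rest.sum() * (1.0 - fraction)
    new_niches = [NicheSpec(spec.niche_specs[0].type_proportions,
                            spec.niche_specs[0].marker_shift, weight=fraction)]
    for niche, w in zip(spec.niche_specs[1:], rest):
        new_niches.append(NicheSpec(niche.type_proportions, niche.marker_shift, weight=float(w)))
    return TissueSpec(
        n_cells=spec.n_cells,
        n_types=spec.n_types,
        type_proportions=spec.type_proportions,
        layout=spec.layout,
        niche_specs=tuple(new_niches),
        n_markers=spec.n_markers,
        marker_noise_sd=spec.marker_noise_sd,
        dimension=spec.dimension,
        size_um=spec.size_um,
        seed=spec.seed,
    )


def generate_cohort(
    tissue_spec: TissueSpec, cohort_spec: CohortSpec
) -> tuple[List[CellTable], pd.DataFrame]:
    """Generate per-sample tissues plus a clinical table.

    Binary cohorts assign balanced groups (first half negative) and shift
    the planted region-0 fraction by ``effect_size`` in the positive
    group.  Survival cohorts draw the planted fraction uniformly, set the
    hazard to ``baseline_hazard × exp(effect_size · z)`` where ``z`` is
    the standardized fraction, and censor with an independent exponential
    whose rate targets ``censoring_rate``.
    """
    rng = np.random.default_rng(cohort_spec.seed)
    n = cohort_spec.n_samples
    planted = np.full(n, cohort_spec.base_fraction)

    if cohort_spec.outcome_kind == "binary":
        group = (np.arange(n) % 2).astype(int) if n >= 2 else np.zeros(n, dtype=int)
        if cohort_spec.effect == "niche_fraction":
            planted = planted + cohort_spec.effect_size * group
    else:
        group = np.zeros(n, dtype=int)
        if cohort_spec.effect == "niche_fraction":
            planted = rng.uniform(0.1, 0.5, size=n)
    planted = np.clip(planted, 0.02, 0.95)

    tables: List[CellTable] = []
    for i in range(n):
        sub_seed = int((cohort_spec.seed * 100003 + 7919 * i) % (2**31 - 1))
        base = _two_region_template(tissue_spec, float(planted[i]))
        spec_i = TissueSpec(
            n_cells=base.n_cells, n_types=base.n_types,
            type_proportions=base.type_proportions, layout=base.layout,
            niche_specs=base.niche_specs, n_markers=base.n_markers,
            marker_noise_sd=base.marker_noise_sd, dimension=base.dimension,
            size_um=base.size_um, seed=sub_seed,
        )
        tables.append(generate_tissue(spec_i, sample_id=f"S{i:03d}"))

    clinical = pd.DataFrame({"sample_id": [f"S{i:03d}" for i in range(n)],
                             "planted_fraction": planted})
    if cohort_spec.outcome_kind == "binary":
        clinical["outcome"] = group
    else:
        z = (planted - planted.mean()) / (planted.std(ddof=0) or 1.0)
        hazard = cohort_spec.baseline_hazard * np.exp(cohort_spec.effect_size * z)
        event_time = rng.exponential(1.0 / hazard)
        if cohort_spec.censoring_rate > 0:
            # P(censored) = mu / (lambda + mu) for independent exponentials
            mu = cohort_spec.censoring_rate / (1.0 - cohort_spec.censoring_rate + 1e-12)
            mu = mu * hazard.mean()
            censor_time = rng.exponential(1.0 / mu, size=n)
        else:
            censor_time = np.full(n, np.inf)
        clinical["time"] = np.minimum(event_time, censor_time)
        clinical["event"] = (event_time <= censor_time).astype(int)
    return tables, clinical


# ---------------------------------------------------------------------------
# hexagonal binning ("metacells" at degraded resolution)


def hex_bin_cells(cells: CellTable, bin_width: float, type_mode: str = "modal") -> CellTable:
    """Aggregate 2D cells into pointy-top hexagonal metacells.

    ``bin_width`` is the center-to-center spacing of adjacent hexagons in
    microns.  Each output row is one occupied hexagon: coordinates are the
    centroid of its member cells, continuous attributes are averaged, and
    the cell type is the modal type (``type_mode="modal"``) or dropped in
    favor of per-type composition columns (``type_mode="composition"``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    schema = cells.schema
    if schema.ndim != 2:
        raise ValueError("hex binning requires 2D coordinates")
    df = cells.sorted().df
    x = df[schema.coords[0]].to_numpy(dtype=float)
    y = df[schema.coords[1]].to_numpy(dtype=float)
    size = bin_width / np.sqrt(3.0)  # hex circumradius for this spacing
    q = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    r = (2.0 / 3.0 * y) / size
    # cube rounding for hex assignment
    xc, zc = q, r
    yc = -xc - zc
    rx, ry, rz = np.round(xc), np.round(yc), np.round(zc)
    dx, dy, dz = np.abs(rx - xc), np.abs(ry - yc), np.abs(rz - zc)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx[fix_x] = -ry[fix_x] - rz[fix_x]
    rz[fix_z] = -rx[fix_z] - ry[fix_z]
    hex_q, hex_r = rx.astype(int), rz.astype(int)

    key = pd.DataFrame({
        "_sample": df[schema.sample].to_numpy(),
        "_q": hex_q,
        "_r": hex_r,
    })
    work = pd.concat([df.reset_index(drop=True), key], axis=1)
    grouped = work.groupby(["_sample", "_q", "_r"], sort=True, observed=True)

    agg = {c: "mean" for c in (*schema.coords, *schema.continuous)}
    out = grouped.agg(agg).reset_index()
    out = out.rename(columns={"_sample": schema.sample})
    out[schema.node] = np.arange(len(out))

    type_col = schema.cell_type
    categorical: tuple = ()
    continuous = tuple(schema.continuous)
    if type_col is not None:
        if type_mode == "modal":
            modal = grouped[type_col].agg(lambda s: s.value_counts().index[0])
            out[type_col] = modal.to_numpy()
        elif type_mode == "composition":
            comp = (
                grouped[type_col].value_counts(normalize=True).unstack(fill_value=0.0)
            )
            comp.columns = [f"frac:{c}" for c in comp.columns]
            out = out.join(comp.reset_index(drop=True))
            continuous = continuous + tuple(comp.columns)
            type_col = None
        else:
            raise ValueError(f"unknown type_mode {type_mode!r}")
    out = out.drop(columns=["_q", "_r"])
    new_schema = CellSchema(
        sample=schema.sample, node=schema.node, coords=schema.coords,
        cell_type=type_col, categorical=categorical, continuous=continuous,
    )
    return CellTable(out[list(new_schema.required_columns())], new_schema)
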