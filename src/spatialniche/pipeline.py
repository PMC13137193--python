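"""Run configuration and the staged analysis pipeline.

A :class:`RunConfig` names the inputs, the column schema, per-stage
parameters and the single seed from which all stage randomness flows.
:func:`run_pipeline` executes the stages in order — graph construction,
proportions/ratios, mixing z-scores, NAS niches, clinical model — caching
every stage artifact under the run directory keyed by a hash of the
stage's configuration, so an unchanged rerun is all cache hits and a
one-parameter edit recomputes only the affected stage and its
descendants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import features as fe
from . import graph as gb
from . import mixing as mx
from . import models as ml
from . import nas as ns
from .core import CellSchema, CellTable
from .io import read_cells, schema_from_mapping, write_edges

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full description of one pipeline run; round-trips through YAML/TOML."""

    cells_path: str
    outcome_path: str
    out_dir: str
    task: str = "binary"  # binary | survival
    schema: dict = field(default_factory=dict)
    graph: dict = field(default_factory=lambda: {"trim_factor": 2.0, "k_ref": 3})
    mixing: dict = field(default_factory=lambda: {"n_perm": 100})
    nas: dict = field(default_factory=lambda: {
        "order": 1, "statistics": ["mean", "sd"], "dr": "umap", "dr_dims": 2,
        "cluster": "kmeans", "k": 2, "normalization": "total",
    })
    model: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        if path.suffix == ".toml":
            import tomllib

            return cls.from_dict(tomllib.loads(path.read_text()))
        raise ValueError(f"unsupported config format {path.suffix!r}")

    def to_yaml(self, path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def cell_schema(self) -> CellSchema:
        return schema_from_mapping(self.schema)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _StageCache:
    """Manifest of stage artifacts keyed by config hash."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.manifest_path = out_dir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        self.hits: list[str] = []

    def is_fresh(self, stage: str, key: str) -> bool:
        entry = self.manifest.get(stage)
        if entry is None or entry["hash"] != key:
            return False
        fresh = all(Path(p).exists() for p in entry["artifacts"])
        if fresh:
            self.hits.append(stage)
        return fresh

    def record(self, stage: str, key: str, artifacts: list[Path]) -> None:
        self.manifest[stage] = {"hash": key, "artifacts": [str(p) for p in artifacts]}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage name in the raised error while
    earlier artifacts stay on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out_dir)
    config.to_yaml(out_dir / "config.yaml")
    schema = config.cell_schema()

    def stage(name, key_obj, artifact_paths, fn):
        key = _hash(key_obj)
        paths = [out_dir / p for p in artifact_paths]
        if cache.is_fresh(name, key):
            logger.info("stage %s: cache hit", name)
            return None
        try:
            fn(paths)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        cache.record(name, key, paths)
        return None

    cells = read_cells(config.cells_path, schema)
    outcome = pd.read_csv(config.outcome_path)

    nets = {}
    def build_graphs(paths):
        for i, (sid, sub) in enumerate(cells.per_sample()):
            nets[sid] = gb.build_spatial_network(sub, seed=config.seed, **config.graph)
        for p, (sid, net) in zip(paths, nets.items()):
            write_edges(net, p)

    sample_ids = cells.samples
    stage(
        "graph",
        {"cells": config.cells_path, "graph": config.graph, "seed": config.seed},
        [f"edges_{sid}.tsv" for sid in sample_ids],
        build_graphs,
    )
    if not nets:  # cache hit: rebuild in memory (graphs are cheap and deterministic)
        for sid, sub in cells.per_sample():
            nets[sid] = gb.build_spatial_network(sub, seed=config.seed, **config.graph)

    props = fe.celltype_proportions(cells)
    ratios = fe.pairwise_ratios(props)
    stage(
        "proportions",
        {"cells": config.cells_path},
        ["proportions.csv", "ratios.csv"],
        lambda paths: (props.to_csv(paths[0]), ratios.to_csv(paths[1])),
    )

    def compute_mixing(paths):
        z_by_sample = {}
        for sid, net in nets.items():
            z_by_sample[sid] = mx.zscore_mixing(
                net, attr=schema.cell_type, seed=config.seed, **config.mixing
            )
        mmz = fe.mixing_features(z_by_sample)
        mmz.to_csv(paths[0])

    stage(
        "mixing",
        {"cells": config.cells_path, "graph": config.graph,
         "mixing": config.mixing, "seed": config.seed},
        ["mixing_z.csv"],
        compute_mixing,
    )
    mmz = pd.read_csv(out_dir / "mixing_z.csv", index_col=0)

    nas_conf = dict(config.nas)
    def compute_nas(paths):
        nas = ns.nas_table(
            cells, nets, order=nas_conf.get("order", 1),
            statistics=tuple(nas_conf.get("statistics", ("mean", "sd"))),
        )
        assignment = ns.cluster_niches(
            nas, dr=nas_conf.get("dr", "umap"), dr_dims=nas_conf.get("dr_dims", 2),
            cluster=nas_conf.get("cluster", "kmeans"),
            k_or_resolution=nas_conf.get("k", 2), seed=config.seed,
        )
        niche_feats = fe.niche_proportions(
            assignment, normalization=nas_conf.get("normalization", "total")
        )
        flat = nas.copy()
        flat.columns = ["|".join(map(str, c)) for c in flat.columns]
        flat.reset_index().to_parquet(paths[0], index=False)
        assignment.labels.rename("niche").reset_index().to_csv(paths[1], index=False)
        niche_feats.to_csv(paths[2])

    stage(
        "nas",
        {"cells": config.cells_path, "graph": config.graph, "nas": nas_conf,
         "seed": config.seed},
        ["nas_table.parquet", "niche_labels.csv", "niche_features.csv"],
        compute_nas,
    )
    niche_feats = pd.read_csv(out_dir / "niche_features.csv", index_col=0)

    def fit_model(paths):
        feats = props.join(mmz, how="inner").join(niche_feats, how="inner")
        table = feats.join(outcome.set_index("sample_id"), how="inner")
        if config.task == "binary":
            report = ml.fit_binary(
                table[[*feats.columns, "outcome"]], seed=config.seed, **config.model
            )
        else:
            report = ml.fit_survival(
                table[[*feats.columns, "time", "event"]], seed=config.seed, **config.model
            )
        payload = {
            "task": report.task,
            "metrics": report.metrics,
            "coefficients": report.coefficients.to_dict(),
            "penalty": report.penalty,
            "folds": report.folds,
            "seed": report.seed,
            "notes": report.notes,
        }
        Path(paths[0]).write_text(json.dumps(payload, indent=1, default=float))

    stage(
        "model",
        {"cells": config.cells_path, "graph": config.graph, "mixing": config.mixing,
         "nas": nas_conf, "model": config.model, "task": config.task,
         "seed": config.seed},
        ["model_report.json"],
        fit_model,
    )
    logger.info("pipeline complete; cache hits: %s", cache.hits)
    return out_dir
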