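"""Per-sample feature engineering and bivariate screening.

Features of increasing sophistication are built per sample: cell-type
proportions, pairwise abundance ratios a/(a+b), centered log-ratio (CLR)
transforms of compositional blocks, and niche-proportion features under
several normalizations.  Feature names carry their provenance:
``prop:typeA``, ``ratio:typeA|typeB``, ``mmz:typeA~typeB``, ``niche:3``.

Screening relates each feature to a binary or survival outcome with
nonparametric tests and Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import CellTable
from .nas import NicheAssignment

__all__ = [
    "celltype_proportions",
    "pairwise_ratios",
    "clr_transform",
    "niche_proportions",
    "bivariate_screen",
    "mixing_features",
]


def celltype_proportions(cells: CellTable) -> pd.DataFrame:
    """Per-sample fraction of each cell type over the global type vocabulary.

    Types absent from a sample get 0, so all samples share one column set
    and every row sums to 1.
    """
    schema = cells.schema
    if schema.cell_type is None:
        raise ValueError("cell table has no cell-type column")
    df = cells.df
    counts = pd.crosstab(df[schema.sample], df[schema.cell_type])
    if (counts.sum(axis=1) == 0).any():
        empty = counts.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"empty sample(s): {empty}")
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"prop:{c}" for c in props.columns]
    props.index.name = "sample"
    return props


def pairwise_ratios(features: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """All unordered-pair ratios a/(a+b) of the selected nonnegative columns.

    When a + b = 0 the ratio is undefined and reported as missing — never
    silently 0.5.
    """
    cols = list(columns) if columns is not None else list(features.columns)
    block = features[cols]
    if (block < 0).any().any():
        bad = [c for c in cols if (block[c] < 0).any()]
        raise ValueError(f"negative values in column(s) {bad}; ratios need nonnegative inputs")
    out = {}
    for a, b in combinations(cols, 2):
        denom = block[a] + block[b]
        ratio = block[a] / denom.where(denom > 0)
        out[f"ratio:{a}|{b}"] = ratio
    return pd.DataFrame(out, index=features.index)


def clr_transform(features: pd.DataFrame, pseudocount: Optional[float] = None) -> pd.DataFrame:
    """Centered log-ratio transform of a compositional block.

    Zeros are replaced multiplicatively: each zero becomes δ (default
    0.5 × the smallest nonzero share in the table) and nonzero parts are
    scaled down so each row still sums to 1 before taking logs.  Output
    rows sum to 0.
    """
    X = features.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("compositions must be nonnegative")
    row_sums = X.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("all-zero composition row cannot be CLR-transformed")
    X = X / row_sums[:, None]
    if (X == 0).any():
        nonzero_min = X[X > 0].min()
        delta = pseudocount if pseudocount is not None else 0.5 * nonzero_min
        zeros = X == 0
        n_zero = zeros.sum(axis=1)
        X = np.where(zeros, delta, X * (1.0 - (n_zero * delta)[:, None]))
    logx = np.log(X)
    clr = logx - logx.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=features.index, columns=[f"clr:{c}" for c in features.columns])
    return out


def niche_proportions(
    niches: NicheAssignment,
    normalization: str = "total",
    celltype_props: Optional[pd.DataFrame] = None,
    cell_types: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-sample niche occupancy under the selected normalization.

    ``total``       fraction of the sample's cells in each niche.
    ``by_celltype`` each (niche, type) share is divided by the sample's
                    type proportion before re-aggregating, removing
                    composition-driven differences (requires
                    ``cell_types`` aligned with the niche labels).
    ``by_niche``    columns scaled to unit cohort-wide mean, making rare
                    niches comparable to common ones.
    ``clr``         centered log-ratio of the ``total`` proportions.
    """
    base = niches.proportions.copy()
    base.columns = [f"niche:{c}" for c in base.columns]
    if normalization == "total":
        return base
    if normalization == "clr":
        return clr_transform(base)
    if normalization == "by_niche":
        means = base.mean(axis=0).replace(0.0, np.nan)
        return base.div(means, axis=1).fillna(0.0)
    if normalization == "by_celltype":
        if cell_types is None:
            raise ValueError("by_celltype normalization requires cell_types labels")
        labels = niches.labels
        samples = labels.index.get_level_values("sample")
        df = pd.DataFrame({
            "sample": samples,
            "niche": labels.to_numpy(),
            "cell_type": np.asarray(cell_types),
        })
        type_prop = (
            df.groupby(["sample", "cell_type"], observed=True).size()
            / df.groupby("sample", observed=True).size()
        )
        pair_share = (
            df.groupby(["sample", "niche", "cell_type"], observed=True).size()
            / df.groupby("sample", observed=True).size()
        )
        enriched = pair_share / type_prop.reindex(
            pair_share.index.droplevel("niche")
        ).to_numpy()
        agg = enriched.groupby(level=["sample", "niche"]).sum().unstack(fill_value=0.0)
        agg.columns = [f"niche:{c}" for c in agg.columns]
        return agg.reindex(index=base.index, columns=base.columns, fill_value=0.0)
    raise ValueError(f"unknown normalization {normalization!r}")


def mixing_features(
    z_by_sample: dict, use_z: bool = True, undefined_as_nan: bool = True
) -> pd.DataFrame:
    """Flatten per-sample mixing statistics into a sample × feature table.

    ``z_by_sample`` maps sample id → ZScoredStats.  Feature names are
    ``mmz:i~j`` (z-scores) or ``mm:i~j`` (raw fractions); undefined
    elements become missing values for downstream filtering/imputation.
    """
    rows = {}
    for sid, zs in z_by_sample.items():
        labels = zs.observed.labels
        mat = zs.z_mm if use_z else zs.observed.e
        rec = {}
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if not zs.observed.directed and j < i:
                    continue
                val = mat[i, j]
                if use_z and undefined_as_nan and zs.undefined_mask[i, j]:
                    val = np.nan
                prefix = "mmz" if use_z else "mm"
                rec[f"{prefix}:{li}~{lj}"] = val
        rows[sid] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def bivariate_screen(
    features: pd.DataFrame,
    outcome: pd.DataFrame,
    task: str = "binary",
) -> pd.DataFrame:
    """Screen every feature against the outcome with BH-adjusted q-values.

    Binary outcomes (column ``outcome``) use the two-sided Mann–Whitney
    rank-sum test with group medians; survival outcomes (columns ``time``,
    ``event``) use a univariate Cox model's coefficient test per feature.
    Constant features are kept in the table but marked untestable.
    """
    aligned = outcome.reindex(features.index)
    records = []
    if task == "binary":
        y = aligned["outcome"].to_numpy()
        if set(np.unique(y[~pd.isna(y)])) - {0, 1}:
            raise ValueError("binary outcome column must be 0/1")
        for col in features.columns:
            x = features[col].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~pd.isna(y)
            x0, x1 = x[ok & (y == 0)], x[ok & (y == 1)]
            med0 = float(np.median(x0)) if len(x0) else np.nan
            med1 = float(np.median(x1)) if len(x1) else np.nan
            if len(np.unique(x[ok])) < 2 or not len(x0) or not len(x1):
                records.append({"feature": col, "statistic": np.nan, "p": np.nan,
                                "median_neg": med0, "median_pos": med1,
                                "direction": 0, "untestable": True})
                continue
            both = np.concatenate([x0, x1])
            # exact null for small tie-free samples, else the usual
            # tie-corrected normal approximation
            method = ("exact" if len(both) <= 30 and len(np.unique(both)) == len(both)
                      else "asymptotic")
            stat, p = mannwhitneyu(x1, x0, alternative="two-sided", method=method)
            records.append({"feature": col, "statistic": float(stat), "p": float(p),
                            "median_neg": med0, "median_pos": med1,
                            "direction": int(np.sign(med1 - med0)), "untestable": False})
    elif task == "survival":
        from lifelines import CoxPHFitter

        for col in features.columns:
            sub = pd.DataFrame({
                "x": features[col].to_numpy(dtype=float),
                "time": aligned["time"].to_numpy(dtype=float),
                "event": aligned["event"].to_numpy(dtype=float),
            }).dropna()
            if sub["x"].nunique() < 2 or sub["event"].sum() == 0:
                records.append({"feature": col, "statistic": np.nan, "p": np.nan,
                                "coef": np.nan, "direction": 0, "untestable": True})
                continue
            cph = CoxPHFitter()
            cph.fit(sub, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            records.append({"feature": col,
                            "statistic": float(cph.summary.loc["x", "z"]),
                            "p": float(cph.summary.loc["x", "p"]),
                            "coef": coef, "direction": int(np.sign(coef)),
                            "untestable": False})
    else:
        raise ValueError(f"unknown task {task!r}")
    table = pd.DataFrame(records)
    testable = ~table["untestable"]
    q = np.full(len(table), np.nan)
    if testable.any():
        q[testable.to_numpy()] = multipletests(
            table.loc[testable, "p"].to_numpy(), method="fdr_bh"
        )[1]
    table["q"] = q
    return table.sort_values("q", kind="mergesort", na_position="last").reset_index(drop=True)
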