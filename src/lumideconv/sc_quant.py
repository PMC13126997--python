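"""Single-cell quantification: normalization, rates, per-lung scaling.

Molecule counts per cell are scaled to a common per-cell total (10,000 by
default, the depth-normalization the single-cell counts were designed for);
positive-cell rates are reported per 1000 analysed cells; absolute per-lung
quantities are analysed-cell proportions scaled by the haemocytometer
lavage total; treatment arms are compared with an unpaired two-sample
t-test (Student by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import SingleCellDataset, ValidationError, logger


def normalize_per_cell(sc: SingleCellDataset, target: int = 10_000) -> SingleCellDataset:
    """Scale every cell's counts so its total equals ``target`` molecules.

    Raw counts are preserved in ``layers['counts']``.  Cells with zero total
    molecules must be removed upstream; one reaching this operation is an
    error, never silently repaired.
    """
    if target <= 0:
        raise ValidationError("normalization target must be positive")
    X = np.asarray(sc.adata.X, dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError(f"{int((totals == 0).sum())} cell(s) with zero total molecules")
    adata = sc.adata.copy()
    adata.layers["counts"] = np.asarray(sc.adata.X).copy()
    adata.X = X * (target / totals)[:, None]
    adata.uns["normalized_target"] = int(target)
    return replace(sc, adata=adata)


def positive_cells_per_1000(
    sc: SingleCellDataset,
    gene: str,
    stratify_by: tuple[str, ...] = ("group", "cell_type"),
) -> pd.DataFrame:
    """Cells with at least one raw molecule of ``gene``, per 1000 analysed.

    Positivity uses raw counts (molecule counts are integers; normalization
    never changes zero status).  Strata with no cells are simply absent from
    the result.
    """
    if gene not in sc.adata.var_names:
        raise ValidationError(f"gene {gene!r} not measured")
    raw = sc.counts[:, list(sc.adata.var_names).index(gene)]
    obs = sc.adata.obs.copy()
    obs["_positive"] = raw > 0
    grouped = obs.groupby(list(stratify_by), observed=True)["_positive"]
    out = pd.DataFrame(
        {
            "n_cells": grouped.size(),
            "n_positive": grouped.sum().astype(int),
        }
    )
    out["per_1000"] = out["n_positive"] / out["n_cells"] * 1000.0
    return out


def cells_per_lung(sc: SingleCellDataset) -> pd.DataFrame:
    """Absolute per-lung cell-type counts from analysed proportions.

    count(sample, type) = lavage total(sample) x (cells of type / cells
    analysed in the sample); summing over types recovers the lavage total
    exactly.  Samples without a lavage total are skipped with a warning.
    """
    totals = sc.lavage_totals
    obs = sc.adata.obs
    rows = []
    for sid, sub in obs.groupby("sample_id", observed=True):
        if sid not in totals:
            logger.warning("sample %s has no lavage total; skipped", sid)
            continue
        n = len(sub)
        group = sub["group"].iloc[0]
        for ct, n_ct in sub["cell_type"].value_counts().items():
            rows.append((sid, group, ct, totals[sid] * n_ct / n))
    out = pd.DataFrame(rows, columns=["sample_id", "group", "cell_type", "cells_per_lung"])
    return out.sort_values(["sample_id", "cell_type"], kind="mergesort").reset_index(drop=True)


def total_mrna_per_lung(
    sc: SingleCellDataset, gene: str, exclude_zero_cells: bool = False
) -> pd.DataFrame:
    """Total molecules of ``gene`` per lung, per (sample, cell type).

    Mean normalized per-cell expression within the stratum times the
    stratum's absolute per-lung cell count.  ``exclude_zero_cells`` drops
    zero-count cells from the per-cell mean (the convention used for
    per-cell expression displays); the default includes all cells so the
    product stays an unbiased total.
    """
    if "normalized_target" not in sc.adata.uns:
        raise ValidationError("normalize_per_cell must run before per-lung totals")
    if gene not in sc.adata.var_names:
        raise ValidationError(f"gene {gene!r} not measured")
    gi = list(sc.adata.var_names).index(gene)
    normed = np.asarray(sc.adata.X)[:, gi]
    raw = sc.counts[:, gi]
    obs = sc.adata.obs.copy()
    obs["_expr"] = normed
    obs["_raw"] = raw
    per_lung = cells_per_lung(sc).set_index(["sample_id", "cell_type"])
    rows = []
    for (sid, ct), sub in obs.groupby(["sample_id", "cell_type"], observed=True):
        if (sid, ct) not in per_lung.index:
            continue
        vals = sub.loc[sub["_raw"] > 0, "_expr"] if exclude_zero_cells else sub["_expr"]
        mean_expr = float(vals.mean()) if len(vals) else 0.0
        rows.append(
            (
                sid, sub["group"].iloc[0], ct, mean_expr,
                mean_expr * float(per_lung.loc[(sid, ct), "cells_per_lung"]),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "cell_type", "mean_expr_per_cell", "total_per_lung"],
    )
    return out.sort_values(["sample_id", "cell_type"], kind="mergesort").reset_index(drop=True)


def compare_groups(values_a, values_b, equal_var: bool = True):
    """Unpaired two-sample t-test with per-group mean +/- SEM.

    Student (pooled variance) by default; ``equal_var=False`` gives Welch.
    Returns (t, p, summary DataFrame indexed a/b with mean and sem).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    summary = pd.DataFrame(
        {
            "n": [len(a), len(b)],
            "mean": [a.mean(), b.mean()],
            "sem": [stats.sem(a), stats.sem(b)],
        },
        index=["a", "b"],
    )
    return float(t), float(p), summary
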