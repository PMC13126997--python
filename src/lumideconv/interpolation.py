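"""Marker-set cell-type interpolation of bulk differential expression.

Relative cell-type abundance changes are read out of a bulk contrast as the
mean differential expression score (DES = log2FC x -log10 q) over a curated
marker gene set, reported as mean +/- SEM over the member genes found in the
contrast.  A compartment comparison sorts genes by the difference of their
DES between luminal airway cells and tissue (delta-DES sort), and marker-set
specificity is validated against annotated single-cell data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import compute_des  # re-exported: DES belongs to both stages
from .io import (
    ContrastTable,
    MarkerSetCollection,
    SingleCellDataset,
    ValidationError,
    logger,
)

__all__ = [
    "compute_des",
    "interpolate_cell_types",
    "delta_des",
    "marker_specificity",
]


def interpolate_cell_types(
    contrast: ContrastTable, markers: MarkerSetCollection
) -> pd.DataFrame:
    """Score each cell type as mean +/- SEM of its marker genes' DES.

    Returns a table indexed by cell type with columns mean_des, sem_des,
    n_genes_used and genes_missing (comma-joined).  Sets with no measured
    gene are reported absent with a warning, not scored; if no set has any
    measured gene the result would be empty and an error is raised instead.
    SEM is the sample standard deviation over genes found divided by
    sqrt(n_genes_used) (0 when a single gene is found).
    """
    des = contrast.table["des"]
    rows = {}
    for name, genes in markers:
        found = [g for g in genes if g in des.index]
        missing = [g for g in genes if g not in des.index]
        if not found:
            logger.warning("marker set %s: no gene measured in %s", name, contrast.label)
            continue
        vals = des.loc[found].to_numpy()
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows[name] = {
            "mean_des": float(vals.mean()),
            "sem_des": sem,
            "n_genes_used": len(found),
            "genes_missing": ",".join(missing),
        }
    if not rows:
        raise ValidationError(f"no marker set has any measured gene in {contrast.label}")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_type"
    return out


def delta_des(contrast_lac: ContrastTable, contrast_tiss: ContrastTable) -> pd.DataFrame:
    """Per-gene DES difference between compartments, sorted descending.

    delta = DES(LAC) - DES(TISS) over the gene intersection; ties broken by
    gene id so the sort is fully deterministic.
    """
    common = contrast_lac.genes.intersection(contrast_tiss.genes)
    if len(common) == 0:
        raise ValidationError("compartment contrasts share no genes")
    out = pd.DataFrame(
        {
            "des_lac": contrast_lac.table.loc[common, "des"],
            "des_tiss": contrast_tiss.table.loc[common, "des"],
        }
    )
    out["delta"] = out["des_lac"] - out["des_tiss"]
    out.index.name = "gene_id"
    out = (
        out.reset_index()
        .sort_values(["delta", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )
    return out


def marker_specificity(
    sc: SingleCellDataset, markers: MarkerSetCollection, target: int = 10_000
) -> pd.Series:
    """Fraction of a marker's normalized expression falling in its own type.

    Per gene: mean per-cell normalized expression in the assigned type over
    the sum of mean normalized expression across all types (0 when the
    denominator is 0); per set: mean over member genes found.  Sets whose
    assigned type is absent from the annotations are skipped with a warning.
    """
    from .sc_quant import normalize_per_cell

    obs_types = set(sc.adata.obs["cell_type"].astype(str))
    if len(obs_types) < 2:
        raise ValidationError("specificity needs at least 2 annotated cell types")
    normed = normalize_per_cell(sc, target=target)
    X = np.asarray(normed.adata.X)
    gene_pos = {g: i for i, g in enumerate(normed.gene_ids)}
    type_means = {}
    for t in sorted(obs_types):
        mask = (normed.adata.obs["cell_type"].astype(str) == t).to_numpy()
        type_means[t] = X[mask].mean(axis=0)
    out = {}
    for name, genes in markers:
        if name not in obs_types:
            logger.warning("marker set %s: no cells of that type; skipped", name)
            continue
        specs = []
        for g in genes:
            if g not in gene_pos:
                continue
            i = gene_pos[g]
            denom = sum(type_means[t][i] for t in type_means)
            specs.append(type_means[name][i] / denom if denom > 0 else 0.0)
        if specs:
            out[name] = float(np.mean(specs))
    return pd.Series(out, name="specificity").rename_axis("cell_type")
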