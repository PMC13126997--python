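"""Set logic for combination-exposure-specific gene discovery.

Genes altered "by the combination alone" are the sign-consistent Venn
intersect of the combination-vs-particle and combination-vs-allergen DEG
sets; the enhanced-beyond-single variant works directly on the two contrast
tables at explicit thresholds and reports the conservative (minimum
absolute) DES across the two comparisons; the cross-particle operation
intersects particle-alone responses from two studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import call_degs
from .io import ContrastTable, DegSet, logger


def combination_unique_genes(deg_comb_vs_p: DegSet, deg_comb_vs_a: DegSet) -> pd.Series:
    """Sign-consistent intersection of two combination-vs-single DEG sets.

    A gene qualifies only if it is a DEG in both comparisons with the same
    direction; direction conflicts are excluded and logged.  Returns a
    gene-indexed series of +1/-1 signs, sorted by gene id.
    """
    common = deg_comb_vs_p.genes.intersection(deg_comb_vs_a.genes)
    s1 = deg_comb_vs_p.signs.loc[common]
    s2 = deg_comb_vs_a.signs.loc[common]
    conflict = s1 != s2
    if conflict.any():
        logger.info(
            "combination-unique: %d gene(s) excluded for direction conflict: %s",
            int(conflict.sum()),
            ", ".join(common[conflict][:10]),
        )
    out = s1[~conflict].sort_index()
    out.name = "direction"
    return out


def enhanced_beyond_single(
    contrast_comb_vs_a: ContrastTable,
    contrast_comb_vs_p: ContrastTable,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes regulated by the combination beyond either single exposure.

    Kept iff significant at the thresholds in BOTH combination-vs-single
    contrasts with identical direction.  The per-gene minimum |DES| over the
    two contrasts is reported as the conservative effect summary; rows are
    sorted by it, descending, ties by gene id.
    """
    d1 = call_degs(contrast_comb_vs_a, fc_threshold, q_threshold)
    d2 = call_degs(contrast_comb_vs_p, fc_threshold, q_threshold)
    signs = combination_unique_genes(d1, d2)
    genes = signs.index
    des1 = contrast_comb_vs_a.table.loc[genes, "des"]
    des2 = contrast_comb_vs_p.table.loc[genes, "des"]
    out = pd.DataFrame(
        {
            "direction": signs,
            "des_vs_a": des1,
            "des_vs_p": des2,
            "min_abs_des": np.minimum(des1.abs(), des2.abs()),
        }
    )
    out.index.name = "gene_id"
    return (
        out.reset_index()
        .sort_values(["min_abs_des", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )


def cross_particle_common(
    deg_particle1: DegSet,
    deg_particle2: DegSet,
    contrast1: ContrastTable,
    contrast2: ContrastTable,
) -> pd.DataFrame:
    """Genes altered by both particle-alone exposures, with paired DES.

    Sign-consistent intersection of the two particle-vs-control DEG sets
    (called at matching thresholds, 1.5-fold / FDR 0.05 by default upstream),
    sorted by the mean of the two DES values, descending.
    """
    if (deg_particle1.fc_threshold, deg_particle1.q_threshold) != (
        deg_particle2.fc_threshold,
        deg_particle2.q_threshold,
    ):
        logger.warning("cross-particle DEG sets called at different thresholds")
    signs = combination_unique_genes(deg_particle1, deg_particle2)
    genes = signs.index
    out = pd.DataFrame(
        {
            "direction": signs,
            "des_particle1": contrast1.table.loc[genes, "des"],
            "des_particle2": contrast2.table.loc[genes, "des"],
        }
    )
    out["mean_des"] = out[["des_particle1", "des_particle2"]].mean(axis=1)
    out.index.name = "gene_id"
    return (
        out.reset_index()
        .sort_values(["mean_des", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )
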