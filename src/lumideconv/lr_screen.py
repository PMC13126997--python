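"""Ligand-receptor co-expression screening over bulk contrasts.

A curated pair is reported when both partners are differentially expressed
in the same contrast (within-compartment screen, 1.25-fold / FDR 0.05 by
default, direction-agnostic) or when the ligand is upregulated in one
compartment and the receptor in the other (cross-compartment directional
screen).  Human database pairs are first mapped to murine symbols through an
ortholog table; mapped pairs carry species_source = "ortholog-mapped".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ContrastTable, LRPairTable, ValidationError, logger


def map_orthologs(pairs: LRPairTable, mapping: pd.DataFrame | dict) -> LRPairTable:
    """Substitute murine equivalents for human database pairs.

    ``mapping`` is source symbol -> target symbol (a dict, or a DataFrame
    whose first two columns are source and target).  Pairs with both
    partners mappable are emitted flagged ortholog-mapped; unmappable pairs
    are dropped and counted in the log.  One-to-many mappings are an error.
    """
    if isinstance(mapping, pd.DataFrame):
        src, tgt = mapping.columns[0], mapping.columns[1]
        dup = mapping[src][mapping[src].duplicated()]
        if len(dup):
            raise ValidationError(f"one-to-many ortholog mapping for {dup.iloc[0]!r}")
        mapping = dict(zip(mapping[src], mapping[tgt]))
    rows, dropped = [], 0
    for _, row in pairs.table.iterrows():
        lig, rec = mapping.get(row["ligand"]), mapping.get(row["receptor"])
        if lig is None or rec is None:
            dropped += 1
            continue
        rows.append((row["pair_id"], lig, rec, "ortholog-mapped"))
    if dropped:
        logger.info("ortholog mapping dropped %d of %d pairs", dropped, len(pairs))
    out = pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor", "species_source"])
    return LRPairTable(table=out)


def _passes(t: pd.DataFrame, gene: str, log2_thr: float, q_threshold: float,
            require_up: bool = False) -> bool | None:
    """Threshold test for one partner; None when the gene is not measured."""
    if gene not in t.index:
        return None
    fc, q = t.loc[gene, "log2_fc"], t.loc[gene, "q_value"]
    if require_up:
        return bool(fc >= log2_thr and q < q_threshold)
    return bool(abs(fc) >= log2_thr and q < q_threshold)


def screen_pairs_within(
    contrast: ContrastTable,
    pairs: LRPairTable,
    fc_threshold: float = 1.25,
    q_threshold: float = 0.05,
    require_same_direction: bool = False,
) -> pd.DataFrame:
    """Pairs whose ligand AND receptor are both DE in one contrast.

    Direction-agnostic by default (co-regulated pairs may move either way);
    ``require_same_direction`` restricts to concordant pairs.  Pairs with an
    unmeasured partner are skipped and counted.  Rows are sorted by the mean
    |DES| of the two partners, descending, ties by pair_id.
    """
    if fc_threshold <= 1 or not (0 < q_threshold < 1):
        raise ValidationError("thresholds: fc > 1 and q in (0, 1)")
    t = contrast.table
    log2_thr = np.log2(fc_threshold)
    rows, skipped = [], 0
    for _, row in pairs.table.iterrows():
        ok_l = _passes(t, row["ligand"], log2_thr, q_threshold)
        ok_r = _passes(t, row["receptor"], log2_thr, q_threshold)
        if ok_l is None or ok_r is None:
            skipped += 1
            continue
        if not (ok_l and ok_r):
            continue
        fc_l, fc_r = t.loc[row["ligand"], "log2_fc"], t.loc[row["receptor"], "log2_fc"]
        if require_same_direction and np.sign(fc_l) != np.sign(fc_r):
            continue
        des_l, des_r = t.loc[row["ligand"], "des"], t.loc[row["receptor"], "des"]
        rows.append(
            (
                row["pair_id"], row["ligand"], row["receptor"],
                fc_l, t.loc[row["ligand"], "q_value"], des_l,
                fc_r, t.loc[row["receptor"], "q_value"], des_r,
                (abs(des_l) + abs(des_r)) / 2.0,
            )
        )
    if skipped:
        logger.info("within-compartment screen skipped %d pair(s) with unmeasured partners", skipped)
    out = pd.DataFrame(
        rows,
        columns=[
            "pair_id", "ligand", "receptor",
            "ligand_log2_fc", "ligand_q", "ligand_des",
            "receptor_log2_fc", "receptor_q", "receptor_des",
            "mean_abs_des",
        ],
    )
    return out.sort_values(
        ["mean_abs_des", "pair_id"], ascending=[False, True], kind="mergesort"
    ).set_index("pair_id")


def screen_pairs_cross(
    ligand_contrast: ContrastTable,
    receptor_contrast: ContrastTable,
    pairs: LRPairTable,
    fc_threshold: float = 1.25,
    q_threshold: float = 0.05,
    ligand_compartment: str = "LAC",
    receptor_compartment: str = "TISS",
) -> pd.DataFrame:
    """Directional cross-compartment screen: ligand up here, receptor up there.

    Both partners must be upregulated (the recruitment rationale: a signal
    produced in one compartment acting on receptor-bearing cells in the
    other); the direction label records which compartment supplies which
    partner.
    """
    if fc_threshold <= 1 or not (0 < q_threshold < 1):
        raise ValidationError("thresholds: fc > 1 and q in (0, 1)")
    tl, tr = ligand_contrast.table, receptor_contrast.table
    log2_thr = np.log2(fc_threshold)
    rows, skipped = [], 0
    for _, row in pairs.table.iterrows():
        ok_l = _passes(tl, row["ligand"], log2_thr, q_threshold, require_up=True)
        ok_r = _passes(tr, row["receptor"], log2_thr, q_threshold, require_up=True)
        if ok_l is None or ok_r is None:
            skipped += 1
            continue
        if ok_l and ok_r:
            rows.append(
                (
                    row["pair_id"], row["ligand"], row["receptor"],
                    f"{ligand_compartment}->{receptor_compartment}",
                    tl.loc[row["ligand"], "des"], tr.loc[row["receptor"], "des"],
                )
            )
    if skipped:
        logger.info("cross-compartment screen skipped %d pair(s) with unmeasured partners", skipped)
    out = pd.DataFrame(
        rows,
        columns=["pair_id", "ligand", "receptor", "direction", "ligand_des", "receptor_des"],
    )
    return out.sort_values("pair_id", kind="mergesort").set_index("pair_id")
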