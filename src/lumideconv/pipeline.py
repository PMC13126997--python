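"""End-to-end orchestration: simulate -> DE -> interpolate -> combo -> LR -> sc.

One YAML config with a single seed drives every stage; the seed is fanned
out to stages by stable fixed offsets so each stage is individually
reproducible.  Every output table is written under the results directory
together with a manifest recording inputs, parameters, seed, package
version and per-stage output checksums; a failing stage aborts the run with
its name, leaving partial outputs beside a FAILED marker.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .combination import combination_unique_genes, enhanced_beyond_single
from .diffexp import call_degs, run_contrast
from .interpolation import delta_des, interpolate_cell_types, marker_specificity
from .io import (
    ValidationError,
    write_contrast,
    write_expression_matrix,
    write_marker_gmt,
    write_results_table,
    logger,
)
from .lr_screen import screen_pairs_within
from .sc_quant import cells_per_lung, normalize_per_cell, positive_cells_per_1000
from .simulate import DEFAULT_STUDY_CONFIG, make_study

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "study": dict(DEFAULT_STUDY_CONFIG),
    "contrasts": [
        {"alt": "DH", "ref": "CTRL", "compartment": "LAC"},
        {"alt": "DH", "ref": "CTRL", "compartment": "TISS"},
        {"alt": "DH", "ref": "DEP", "compartment": "LAC"},
        {"alt": "DH", "ref": "HDM", "compartment": "LAC"},
    ],
    "deg": {"fc_threshold": 2.0, "q_threshold": 0.05},
    "lr": {"fc_threshold": 1.25, "q_threshold": 0.05, "contrast": "DH_v_HDM_LAC"},
    "sc_genes_of_interest": ["syn001", "syn002"],
}


def _validate_config(cfg: dict, template: dict, path: str = "") -> None:
    unknown = set(cfg) - set(template)
    if unknown:
        raise ValidationError(f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}")
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(template.get(k), dict):
            _validate_config(v, template[k], f"{path}{k}.")


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    _validate_config(user, DEFAULT_PIPELINE_CONFIG)
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _contrast_key(c: dict) -> str:
    return f"{c['alt']}_v_{c['ref']}_{c['compartment']}"


def run_pipeline(config: dict | str | Path, out_dir) -> Path:
    """Run every stage on a synthetic study and write a results directory.

    ``config`` is a YAML path or an already-validated dict; returns the
    output directory.  Stage order: simulate, de, interpolate, deltades,
    combo, lrscreen, scquant.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        _validate_config(config, DEFAULT_PIPELINE_CONFIG)
        cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
        for k, v in config.items():
            if isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        study = make_study(cfg["study"], seed=cfg["seed"])
        write_expression_matrix(study.bulk, out / "bulk")
        write_marker_gmt(study.markers, out / "markers.gmt")
        study.lr_pairs.table.to_csv(out / "lr_pairs.csv", index=False)
        study.truth.to_json(out / "truth.json")
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": ["bulk.counts.tsv", "bulk.samples.tsv", "bulk.lengths.tsv",
                        "markers.gmt", "lr_pairs.csv", "truth.json"],
        }

        stage = "de"
        t0 = time.time()
        contrasts = {}
        for c in cfg["contrasts"]:
            key = _contrast_key(c)
            ct = run_contrast(study.bulk, c["ref"], c["alt"], c["compartment"])
            contrasts[key] = ct
            write_contrast(ct, out / f"contrast_{key}.tsv")
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": [f"contrast_{k}.tsv" for k in contrasts],
        }

        stage = "interpolate"
        t0 = time.time()
        first = cfg["contrasts"][0]
        key = _contrast_key(first)
        celltypes = interpolate_cell_types(contrasts[key], study.markers)
        write_results_table(celltypes, out / "celltypes.tsv", index_label="cell_type")
        spec = marker_specificity(study.sc, study.markers)
        write_results_table(spec.to_frame(), out / "marker_specificity.tsv", index_label="cell_type")
        outputs = ["celltypes.tsv", "marker_specificity.tsv"]
        lac_key = tiss_key = None
        for c in cfg["contrasts"]:
            if c["compartment"] == "LAC" and lac_key is None:
                lac_key = _contrast_key(c)
            if c["compartment"] == "TISS" and tiss_key is None:
                tiss_key = _contrast_key(c)
        if lac_key and tiss_key:
            dd = delta_des(contrasts[lac_key], contrasts[tiss_key])
            write_results_table(dd, out / "delta_des.tsv")
            outputs.append("delta_des.tsv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), "outputs": outputs}

        stage = "combo"
        t0 = time.time()
        fc, q = cfg["deg"]["fc_threshold"], cfg["deg"]["q_threshold"]
        vs_single = [
            k for k in contrasts
            if k.startswith(("DH_v_DEP", "DH_v_HDM", "CH_v_CEP", "CH_v_HDM"))
        ]
        outputs = []
        if len(vs_single) >= 2:
            d1 = call_degs(contrasts[vs_single[0]], fc, q)
            d2 = call_degs(contrasts[vs_single[1]], fc, q)
            combo = combination_unique_genes(d1, d2)
            write_results_table(combo.to_frame(), out / "combo_unique.tsv")
            enh = enhanced_beyond_single(contrasts[vs_single[0]], contrasts[vs_single[1]], fc, q)
            write_results_table(enh, out / "enhanced_beyond_single.tsv")
            outputs = ["combo_unique.tsv", "enhanced_beyond_single.tsv"]
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), "outputs": outputs}

        stage = "lrscreen"
        t0 = time.time()
        lr_key = cfg["lr"]["contrast"]
        outputs = []
        if lr_key in contrasts:
            lr = screen_pairs_within(
                contrasts[lr_key], study.lr_pairs,
                cfg["lr"]["fc_threshold"], cfg["lr"]["q_threshold"],
            )
            write_results_table(lr, out / "lr_within.tsv", index_label="pair_id")
            outputs = ["lr_within.tsv"]
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), "outputs": outputs}

        stage = "scquant"
        t0 = time.time()
        normed = normalize_per_cell(study.sc)
        cpl = cells_per_lung(normed)
        write_results_table(cpl, out / "cells_per_lung.tsv", index_label="row")
        outputs = ["cells_per_lung.tsv"]
        for gene in cfg["sc_genes_of_interest"]:
            if gene in normed.adata.var_names:
                rates = positive_cells_per_1000(normed, gene)
                write_results_table(
                    rates.reset_index(), out / f"positive_{gene}.tsv", index_label="row"
                )
                outputs.append(f"positive_{gene}.tsv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), "outputs": outputs}
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %s", stage)
        raise

    for st in manifest["stages"].values():
        st["checksums"] = {f: _sha256(out / f) for f in st["outputs"]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
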