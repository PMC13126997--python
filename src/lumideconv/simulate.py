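"""Synthetic two-compartment co-exposure studies with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: bulk counts are negative-binomial draws around a mixture of
cell-type expression signatures, where the treatment signal is primarily a
shift in cell-type composition (the premise of marker-set interpolation);
a designated pool of "synergy" genes is additionally multiplied only in the
particle+allergen combination arms, giving the combination-effect set logic
a recoverable truth; single-cell counts are multinomial draws from the same
signatures; ligand-receptor pairs are wired either to synergy genes (true
pairs) or to background genes (null pairs).

Every generator is deterministic given its seed (NumPy PCG64 via
``default_rng``); ``make_study`` fans one seed out to the sub-generators by
fixed offsets so stages are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    LRPairTable,
    MarkerSetCollection,
    SampleInfo,
    SingleCellDataset,
    ValidationError,
    logger,
)

#: default cell types; the first is the AAM-like type whose luminal fraction
#: expands CTRL 0.02 -> DEP 0.05 -> HDM 0.15 -> DH 0.35
DEFAULT_CELL_TYPES = ("AAM", "AM", "AM.Cyc", "IM", "MC", "EOS", "BC", "TC", "NEU", "EC")

# Fractions per (group, compartment); every row sums to 1.  The non-AAM rows
# were chosen so that (a) each type has a distinct combination-vs-CTRL change
# (ranks are informative), and (b) non-AAM combination-vs-single abundance
# ratios stay inside (0.5, 2), keeping composition-driven markers out of the
# 2-fold combination-unique call.  CEP/CH mirror DEP/DH: the two particles
# share one composition shift by design.
_LAC = {
    "CTRL": [0.02, 0.48, 0.075, 0.060, 0.012, 0.040, 0.050, 0.100, 0.120, 0.043],
    "DEP":  [0.05, 0.40, 0.068, 0.075, 0.016, 0.050, 0.055, 0.104, 0.130, 0.052],
    "HDM":  [0.15, 0.38, 0.060, 0.080, 0.030, 0.080, 0.065, 0.105, 0.030, 0.020],
    "DH":   [0.35, 0.216, 0.042, 0.078, 0.036, 0.075, 0.070, 0.083, 0.024, 0.026],
}
_TISS = {
    "CTRL": [0.02, 0.45, 0.070, 0.100, 0.010, 0.030, 0.050, 0.120, 0.100, 0.050],
    "DEP":  [0.025, 0.44, 0.070, 0.105, 0.011, 0.033, 0.052, 0.119, 0.100, 0.045],
    "HDM":  [0.05, 0.40, 0.060, 0.110, 0.015, 0.050, 0.060, 0.130, 0.080, 0.045],
    "DH":   [0.10, 0.36, 0.050, 0.120, 0.025, 0.070, 0.070, 0.120, 0.050, 0.035],
}


def default_composition() -> pd.DataFrame:
    """Cell-type fractions per (group, compartment), rows summing to 1."""
    rows = {}
    for comp, table in (("LAC", _LAC), ("TISS", _TISS)):
        for group, fr in table.items():
            rows[(group, comp)] = fr
        rows[("CEP", comp)] = table["DEP"]
        rows[("CH", comp)] = table["DH"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=DEFAULT_CELL_TYPES)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["group", "compartment"])
    return df


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the generated study."""

    signature_matrix: pd.DataFrame      # genes x cell types, mean expression
    composition: pd.DataFrame           # (group, compartment) x cell types
    synergy_genes: list[str]            # elevated only in combination arms
    synergy_multiplier: float
    de_effects: pd.DataFrame | None     # genes x groups log2-fold multipliers (optional)
    dispersion: pd.Series               # NB dispersion alpha per gene
    seed: int
    library_size_range: tuple[int, int]
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    lr_truth: dict[str, bool] = field(default_factory=dict)  # pair_id -> is true pair
    #: synergy genes are a luminal phenomenon: the multiplier applies only in
    #: this compartment, so tissue contrasts carry no injected combination signal
    synergy_compartment: str = "LAC"

    def __post_init__(self):
        sums = self.composition.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("composition rows must sum to 1")
        if (self.dispersion <= 0).any():
            raise ValidationError("dispersion must be positive")
        universe = set(self.signature_matrix.index)
        if not set(self.synergy_genes) <= universe:
            raise ValidationError("synergy genes outside the gene universe")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signature_matrix.index)

    def expected_gene_fractions(self, group: str, compartment: str) -> pd.Series:
        """Expected relative abundance of each gene for one study arm.

        The mixture profile (composition-weighted signatures, times the
        synergy multiplier in combination arms and any optional per-gene
        effects) normalized to sum 1; expected counts are this times the
        library size.
        """
        pi = self.composition.loc[(group, compartment)]
        mix = self.signature_matrix.to_numpy() @ pi.to_numpy()
        mix = pd.Series(mix, index=self.signature_matrix.index)
        if (
            group in ("DH", "CH")
            and compartment == self.synergy_compartment
            and self.synergy_genes
        ):
            mix.loc[self.synergy_genes] *= self.synergy_multiplier
        if self.de_effects is not None and group in self.de_effects.columns:
            mix = mix * np.exp2(self.de_effects[group])
        total = mix.sum()
        if total <= 0:
            raise ValidationError(f"degenerate mixture for ({group}, {compartment})")
        return mix / total

    def to_json(self, path) -> None:
        payload = {
            "signature_matrix": {
                "index": list(self.signature_matrix.index),
                "columns": list(self.signature_matrix.columns),
                "values": self.signature_matrix.to_numpy().tolist(),
            },
            "composition": {
                "index": [list(t) for t in self.composition.index],
                "columns": list(self.composition.columns),
                "values": self.composition.to_numpy().tolist(),
            },
            "synergy_genes": self.synergy_genes,
            "synergy_multiplier": self.synergy_multiplier,
            "de_effects": None
            if self.de_effects is None
            else {
                "index": list(self.de_effects.index),
                "columns": list(self.de_effects.columns),
                "values": self.de_effects.to_numpy().tolist(),
            },
            "dispersion": self.dispersion.to_dict(),
            "seed": self.seed,
            "library_size_range": list(self.library_size_range),
            "marker_sets": self.marker_sets,
            "lr_truth": self.lr_truth,
            "synergy_compartment": self.synergy_compartment,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        sig = pd.DataFrame(
            d["signature_matrix"]["values"],
            index=d["signature_matrix"]["index"],
            columns=d["signature_matrix"]["columns"],
        )
        comp = pd.DataFrame(
            d["composition"]["values"],
            index=pd.MultiIndex.from_tuples(
                [tuple(t) for t in d["composition"]["index"]],
                names=["group", "compartment"],
            ),
            columns=d["composition"]["columns"],
        )
        de = d["de_effects"]
        de_df = (
            None
            if de is None
            else pd.DataFrame(de["values"], index=de["index"], columns=de["columns"])
        )
        return cls(
            signature_matrix=sig,
            composition=comp,
            synergy_genes=d["synergy_genes"],
            synergy_multiplier=d["synergy_multiplier"],
            de_effects=de_df,
            dispersion=pd.Series(d["dispersion"]).loc[sig.index],
            seed=d["seed"],
            library_size_range=tuple(d["library_size_range"]),
            marker_sets=d["marker_sets"],
            lr_truth=d.get("lr_truth", {}),
            synergy_compartment=d.get("synergy_compartment", "LAC"),
        )


def generate_signatures(
    n_types: int,
    markers_per_type: int,
    n_background_genes: int,
    seed: int,
    marker_mean: float = 100.0,
    background_mean: float = 10.0,
    n_synergy_genes: int = 0,
    dispersion: float = 0.1,
    cell_type_names: tuple[str, ...] | None = None,
    gene_cap: int = 50_000,
) -> SyntheticTruth:
    """Build exclusive marker signatures plus shared background genes.

    Each cell type gets exactly ``markers_per_type`` exclusive markers (mean
    ``marker_mean`` in its own type, zero elsewhere); background genes get a
    lognormal mean shared across all types (median ``background_mean``).  The
    first ``n_synergy_genes`` background genes are designated the synergy
    pool.  Composition and library sizes are filled with defaults and can be
    overridden afterwards.
    """
    if min(n_types, markers_per_type, n_background_genes) <= 0:
        raise ValidationError("all signature dimensions must be positive")
    if n_types * markers_per_type > gene_cap:
        raise ValidationError(
            f"{n_types} x {markers_per_type} markers exceeds the {gene_cap}-gene cap"
        )
    if n_synergy_genes > n_background_genes:
        raise ValidationError("more synergy genes than background genes")
    rng = np.random.default_rng(seed)
    if cell_type_names is None:
        cell_type_names = (
            DEFAULT_CELL_TYPES
            if n_types == len(DEFAULT_CELL_TYPES)
            else tuple(f"CT{i + 1:02d}" for i in range(n_types))
        )
    marker_sets: dict[str, list[str]] = {}
    gene_ids: list[str] = []
    blocks = []
    for t, ct in enumerate(cell_type_names):
        names = [f"{ct}.m{j + 1:02d}" for j in range(markers_per_type)]
        marker_sets[ct] = names
        gene_ids.extend(names)
        block = np.zeros((markers_per_type, n_types))
        # mild within-set variation keeps markers from being interchangeable
        block[:, t] = marker_mean * rng.lognormal(0.0, 0.25, size=markers_per_type)
        blocks.append(block)
    syn = [f"syn{j + 1:03d}" for j in range(n_synergy_genes)]
    bg = syn + [f"bg{j + 1:04d}" for j in range(n_background_genes - n_synergy_genes)]
    gene_ids.extend(bg)
    bg_means = background_mean * rng.lognormal(0.0, 0.5, size=n_background_genes)
    blocks.append(np.tile(bg_means[:, None], (1, n_types)))
    sig = pd.DataFrame(np.vstack(blocks), index=gene_ids, columns=list(cell_type_names))
    return SyntheticTruth(
        signature_matrix=sig,
        composition=default_composition()[list(cell_type_names)]
        if cell_type_names == DEFAULT_CELL_TYPES
        else _uniform_composition(cell_type_names),
        synergy_genes=syn,
        synergy_multiplier=4.0,
        de_effects=None,
        dispersion=pd.Series(dispersion, index=gene_ids),
        seed=seed,
        library_size_range=(1_000_000, 3_000_000),
        marker_sets=marker_sets,
    )


def _uniform_composition(cell_types) -> pd.DataFrame:
    groups = ["CTRL", "DEP", "HDM", "DH", "CEP", "CH"]
    idx = pd.MultiIndex.from_product(
        [groups, ["LAC", "TISS"]], names=["group", "compartment"]
    )
    return pd.DataFrame(1.0 / len(cell_types), index=idx, columns=list(cell_types))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 draw with variance mu + alpha*mu^2, via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        lam = rng.gamma(shape=1.0 / alpha[~tiny], scale=alpha[~tiny] * mean[~tiny])
        out[~tiny] = rng.poisson(lam)
    return out


def generate_bulk(
    truth: SyntheticTruth,
    n_replicates: int,
    seed: int,
    groups: tuple[str, ...] = ("CTRL", "DEP", "HDM", "DH"),
    compartments: tuple[str, ...] = ("LAC", "TISS"),
) -> ExpressionMatrix:
    """Draw an NB bulk count matrix for every (group, compartment, replicate).

    Expected counts are library size times the arm's normalized mixture
    profile (see :meth:`SyntheticTruth.expected_gene_fractions`); library
    sizes are uniform over ``truth.library_size_range``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    alpha = truth.dispersion.loc[genes].to_numpy()
    lo, hi = truth.library_size_range
    samples: list[SampleInfo] = []
    cols = {}
    for comp in compartments:
        for group in groups:
            if (group, comp) not in truth.composition.index:
                raise ValidationError(f"no composition row for ({group}, {comp})")
            p = truth.expected_gene_fractions(group, comp).to_numpy()
            for rep in range(1, n_replicates + 1):
                lib = int(rng.integers(lo, hi + 1))
                sid = f"{group}_{comp}_r{rep}"
                cols[sid] = _nb_draw(rng, lib * p, alpha)
                samples.append(SampleInfo(sid, group, comp, rep))
    counts = pd.DataFrame(cols, index=genes)
    lengths = pd.Series(
        rng.integers(500, 5001, size=len(genes)), index=genes, name="length_bp"
    )
    return ExpressionMatrix(counts=counts, gene_lengths_bp=lengths, samples=samples)


def generate_sc(
    truth: SyntheticTruth,
    cells_per_sample: int,
    molecules_per_cell: int,
    seed: int,
    groups: tuple[str, ...] = ("CTRL", "DEP", "HDM", "DH"),
    n_samples_per_group: int = 3,
    compartment: str = "LAC",
    lavage_total_range: tuple[int, int] = (200_000, 500_000),
    lavage_group_factor: dict | None = None,
) -> SingleCellDataset:
    """Sample single-cell molecule counts from the lavage compartment.

    Cell types are drawn from the arm's composition; each cell's counts are
    multinomial over its type's signature (with the synergy multiplier in
    combination arms) with exactly ``molecules_per_cell`` trials.  The true
    type is stored in ``obs['cell_type']``; per-sample haemocytometer totals
    are drawn uniformly from ``lavage_total_range`` scaled by a per-group
    inflammation factor (airway cellularity rises with allergen and
    co-exposure, as lavage counts do in vivo).
    """
    import anndata

    if min(cells_per_sample, molecules_per_cell) <= 0:
        raise ValidationError("cells_per_sample and molecules_per_cell must be positive")
    rng = np.random.default_rng(seed)
    if lavage_group_factor is None:
        lavage_group_factor = {
            "CTRL": 1.0, "DEP": 1.2, "HDM": 2.0, "DH": 3.0, "CEP": 1.2, "CH": 3.0,
        }
    genes = truth.gene_ids
    types = list(truth.signature_matrix.columns)
    X_rows, obs_rows = [], []
    lavage: dict[str, int] = {}
    for group in groups:
        pi = truth.composition.loc[(group, compartment)].to_numpy()
        # per-type gene profiles for this arm
        profiles = {}
        for t in types:
            prof = truth.signature_matrix[t].copy()
            if group in ("DH", "CH") and truth.synergy_genes:
                prof.loc[truth.synergy_genes] *= truth.synergy_multiplier
            total = prof.sum()
            profiles[t] = (prof / total).to_numpy() if total > 0 else None
        for s in range(1, n_samples_per_group + 1):
            sid = f"{group}_sc{s}"
            factor = lavage_group_factor.get(group, 1.0)
            lavage[sid] = int(round(factor * rng.integers(*lavage_total_range)))
            type_draws = rng.choice(len(types), size=cells_per_sample, p=pi)
            for ci, ti in enumerate(type_draws):
                prof = profiles[types[ti]]
                if prof is None:
                    counts = np.zeros(len(genes), dtype=np.int64)
                else:
                    counts = rng.multinomial(molecules_per_cell, prof)
                X_rows.append(counts)
                obs_rows.append((f"{sid}_c{ci + 1}", types[ti], sid, group))
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "cell_type", "sample_id", "group"]
    ).set_index("cell_id")
    adata = anndata.AnnData(
        X=np.asarray(X_rows, dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )
    adata.uns["total_lavage_cells_per_lung"] = lavage
    return SingleCellDataset(adata=adata, cell_type_vocabulary=tuple(types))


def generate_lr_table(
    truth: SyntheticTruth, n_true_pairs: int, n_null_pairs: int, seed: int
) -> LRPairTable:
    """Wire true pairs to synergy genes and null pairs to background genes.

    Records which pairs are true in ``truth.lr_truth``.
    """
    rng = np.random.default_rng(seed)
    syn = list(truth.synergy_genes)
    if 2 * n_true_pairs > len(syn):
        raise ValidationError(
            f"{n_true_pairs} true pairs need {2 * n_true_pairs} synergy genes; "
            f"only {len(syn)} exist"
        )
    background = [
        g for g in truth.gene_ids if g.startswith("bg")
    ]
    if 2 * n_null_pairs > len(background):
        raise ValidationError("not enough background genes for null pairs")
    syn_pick = rng.permutation(syn)[: 2 * n_true_pairs]
    bg_pick = rng.permutation(background)[: 2 * n_null_pairs]
    rows = []
    truth.lr_truth = {}
    for i in range(n_true_pairs):
        pid = f"TP{i + 1:03d}"
        rows.append((pid, syn_pick[2 * i], syn_pick[2 * i + 1], "native"))
        truth.lr_truth[pid] = True
    for i in range(n_null_pairs):
        pid = f"NP{i + 1:03d}"
        rows.append((pid, bg_pick[2 * i], bg_pick[2 * i + 1], "native"))
        truth.lr_truth[pid] = False
    table = pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor", "species_source"])
    return LRPairTable(table=table)


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

DEFAULT_STUDY_CONFIG = {
    "n_cell_types": 10,
    "markers_per_type": 20,
    "n_background_genes": 2000,
    "n_synergy_genes": 50,
    "synergy_multiplier": 4.0,
    "n_replicates": 5,
    "dispersion": 0.1,
    "library_size_range": [1_000_000, 3_000_000],
    "groups": ["CTRL", "DEP", "HDM", "DH"],
    "sc_cells_per_sample": 1000,
    "sc_molecules_per_cell": 5000,
    "sc_samples_per_group": 3,
    "n_true_lr_pairs": 10,
    "n_null_lr_pairs": 40,
    "null_combination": False,
}


@dataclass
class StudyBundle:
    bulk: ExpressionMatrix
    sc: SingleCellDataset
    markers: MarkerSetCollection
    lr_pairs: LRPairTable
    truth: SyntheticTruth


def make_study(config: dict | None = None, seed: int = 0) -> StudyBundle:
    """Generate a fully consistent, seed-reproducible co-exposure study.

    ``null_combination=True`` equalizes the combination arm's composition
    with both single-exposure arms and injects no synergy genes — the null
    condition for the combination-unique false-positive check.
    """
    cfg = dict(DEFAULT_STUDY_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValidationError(f"unknown study config keys: {sorted(unknown)}")
        cfg.update(config)
    # seeds fanned out by fixed offsets so each stage is reproducible alone
    truth = generate_signatures(
        cfg["n_cell_types"],
        cfg["markers_per_type"],
        cfg["n_background_genes"],
        seed=seed,
        n_synergy_genes=0 if cfg["null_combination"] else cfg["n_synergy_genes"],
        dispersion=cfg["dispersion"],
    )
    truth.synergy_multiplier = float(cfg["synergy_multiplier"])
    truth.library_size_range = tuple(cfg["library_size_range"])
    if cfg["null_combination"]:
        comp = truth.composition.copy()
        for comp_name in ("LAC", "TISS"):
            for combo, (particle, allergen) in (("DH", ("DEP", "HDM")), ("CH", ("CEP", "HDM"))):
                row = comp.loc[(allergen, comp_name)].copy()
                comp.loc[(combo, comp_name)] = row
                comp.loc[(particle, comp_name)] = row
        truth.composition = comp
    bulk = generate_bulk(
        truth, cfg["n_replicates"], seed=seed + 1, groups=tuple(cfg["groups"])
    )
    sc = generate_sc(
        truth,
        cfg["sc_cells_per_sample"],
        cfg["sc_molecules_per_cell"],
        seed=seed + 2,
        groups=tuple(cfg["groups"]),
        n_samples_per_group=cfg["sc_samples_per_group"],
    )
    n_true = 0 if (cfg["null_combination"] or cfg["n_synergy_genes"] == 0) else cfg["n_true_lr_pairs"]
    lr = generate_lr_table(truth, n_true, cfg["n_null_lr_pairs"], seed=seed + 3)
    markers = MarkerSetCollection(
        sets={k: list(v) for k, v in truth.marker_sets.items()},
        provenance={k: "synthetic exclusive markers" for k in truth.marker_sets},
    )
    _log_study(truth, bulk, sc, seed)
    return StudyBundle(bulk=bulk, sc=sc, markers=markers, lr_pairs=lr, truth=truth)


def make_particle_study(
    seed: int, particle: str = "DEP", n_replicates: int = 5
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-arm (control vs particle) study for cross-particle comparisons.

    The particle arm carries the allergen-strength composition shift (the
    HDM rows) rather than the default mild particle trajectory: a shared,
    clearly detectable particle-alone response is the condition the
    cross-particle common-gene operation is meant to recover, and a 2.5x
    expansion of a 2% population at five replicates sits below the
    detection limit of a genome-wide FDR screen.
    """
    truth = generate_signatures(
        DEFAULT_STUDY_CONFIG["n_cell_types"],
        DEFAULT_STUDY_CONFIG["markers_per_type"],
        DEFAULT_STUDY_CONFIG["n_background_genes"],
        seed=seed,
    )
    comp = truth.composition.copy()
    for c in ("LAC", "TISS"):
        comp.loc[(particle, c)] = comp.loc[("HDM", c)].to_numpy()
    truth.composition = comp
    bulk = generate_bulk(truth, n_replicates, seed=seed + 1, groups=("CTRL", particle))
    return bulk, truth


def _log_study(truth, bulk, sc, seed):
    logger.info(
        "synthetic study: %d genes, %d bulk samples, %d cells, seed %d",
        len(truth.gene_ids),
        bulk.counts.shape[1],
        sc.adata.n_obs,
        seed,
    )
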