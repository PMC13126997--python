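"""Domain types and file I/O for compartment-resolved transcriptomic studies.

The study design is a two-compartment (luminal airway cells, LAC, recovered by
bronchoalveolar lavage; post-lavage lung tissue, TISS), multi-arm co-exposure
experiment: control (CTRL), particle alone (DEP or CEP), allergen alone (HDM),
and the particle+allergen combinations (DH, CH).  Bulk counts travel as plain
TSV (genes in rows, samples in columns) with a sample sheet and a per-gene
length table; single-cell counts as MTX triples; marker sets as GMT; ligand-
receptor pairs as CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("lumideconv")

VALID_GROUPS = ("CTRL", "DEP", "HDM", "DH", "CEP", "CH")
VALID_COMPARTMENTS = ("LAC", "TISS")

#: combination arm -> its two single-exposure arms
COMBINATION_ARMS = {"DH": ("DEP", "HDM"), "CH": ("CEP", "HDM")}


class FormatError(ValueError):
    """Malformed input file (bad dialect, duplicate identifiers, ...)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


def _norm_gene(g: str) -> str:
    # single declared normalization: strip surrounding whitespace; murine
    # symbols are case-meaningful so case is never touched
    return str(g).strip()


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str
    compartment: str
    replicate: int

    def __post_init__(self):
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {VALID_GROUPS})"
            )
        if self.compartment not in VALID_COMPARTMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown compartment "
                f"{self.compartment!r} (expected one of {VALID_COMPARTMENTS})"
            )
        if not isinstance(self.replicate, (int, np.integer)) or self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be an integer >= 1"
            )


@dataclass
class ExpressionMatrix:
    """Bulk gene x sample integer counts with gene lengths and sample design."""

    counts: pd.DataFrame          # genes x samples, nonnegative integers
    gene_lengths_bp: pd.Series    # indexed by gene id, positive integers
    samples: list[SampleInfo]

    def __post_init__(self):
        genes = self.counts.index
        if genes.duplicated().any():
            dups = genes[genes.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate gene ids: {dups}")
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValidationError("counts columns do not match sample sheet order")
        keys = {(s.group, s.compartment, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValidationError("(group, compartment, replicate) not unique")
        if not self.gene_lengths_bp.index.equals(genes):
            raise ValidationError("gene length index does not match count rows")
        if (self.gene_lengths_bp <= 0).any():
            raise ValidationError("gene lengths must be positive")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "compartment": [s.compartment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id")

    def subset_samples(self, mask) -> "ExpressionMatrix":
        keep = [s for s, m in zip(self.samples, mask) if m]
        return ExpressionMatrix(
            counts=self.counts.loc[:, [s.sample_id for s in keep]].copy(),
            gene_lengths_bp=self.gene_lengths_bp.copy(),
            samples=keep,
        )

    def select(self, group: str | None = None, compartment: str | None = None):
        mask = [
            (group is None or s.group == group)
            and (compartment is None or s.compartment == compartment)
            for s in self.samples
        ]
        return self.subset_samples(mask)


@dataclass
class ContrastTable:
    """Per-gene differential expression results for one comparison (alt vs ref).

    ``table`` is indexed by gene id with columns log2_fc, p_value, q_value,
    mean_expr_ref, mean_expr_alt, des.  ``label`` prints the alternative arm
    first ("DH v CTRL"), matching the study's phrasing.
    """

    table: pd.DataFrame
    label: str

    REQUIRED = ("log2_fc", "p_value", "q_value", "mean_expr_ref", "mean_expr_alt", "des")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"contrast table missing columns {missing}")
        t = self.table
        for col in ("p_value", "q_value"):
            bad = (t[col] < 0) | (t[col] > 1)
            if bad.any():
                raise ValidationError(f"{col} outside [0,1]")
        if (t["q_value"] + 1e-12 < t["p_value"]).any():
            raise ValidationError("q_value < p_value: not a BH adjustment")

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass
class MarkerSetCollection:
    """Named cell-type -> marker gene lists used for bulk interpolation."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"marker set {name!r} is empty")
        seen: dict[str, str] = {}
        for name, genes in self.sets.items():
            for g in genes:
                if g in seen and seen[g] != name:
                    logger.warning(
                        "marker gene %s appears in sets %s and %s", g, seen[g], name
                    )
                seen.setdefault(g, name)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self):
        return len(self.sets)


@dataclass
class LRPairTable:
    """Curated ligand-receptor pairs (single-subunit partners only)."""

    table: pd.DataFrame  # columns pair_id, ligand, receptor, species_source

    def __post_init__(self):
        t = self.table
        for col in ("pair_id", "ligand", "receptor", "species_source"):
            if col not in t.columns:
                raise ValidationError(f"LR table missing column {col!r}")
        if t["pair_id"].duplicated().any():
            dup = t.loc[t["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise ValidationError(f"duplicate pair_id {dup!r}")
        if (t["ligand"].astype(str).str.len() == 0).any() or (
            t["receptor"].astype(str).str.len() == 0
        ).any():
            raise ValidationError("empty ligand or receptor gene id")
        bad = ~t["species_source"].isin(["native", "ortholog-mapped"])
        if bad.any():
            raise ValidationError("species_source must be native or ortholog-mapped")

    def __len__(self):
        return len(self.table)


@dataclass
class DegSet:
    """Genes passing fold-change and FDR thresholds, with direction signs."""

    signs: pd.Series          # index gene id, values +1 / -1
    fc_threshold: float
    q_threshold: float
    label: str

    def __post_init__(self):
        if not self.signs.isin([1, -1]).all():
            raise ValidationError("DEG direction signs must be +1 or -1")

    @property
    def genes(self) -> pd.Index:
        return self.signs.index

    def __len__(self):
        return len(self.signs)


@dataclass
class SingleCellDataset:
    """Molecule counts per cell with annotations and per-lung lavage totals.

    Backed by an :class:`anndata.AnnData` (cells x genes).  ``obs`` carries
    ``cell_type``, ``sample_id`` and ``group``; ``uns['total_lavage_cells_per_lung']``
    maps sample_id -> haemocytometer total.  ``layers['counts']`` preserves the
    raw molecule counts once normalization overwrites ``X``.
    """

    adata: "anndata.AnnData"  # noqa: F821 - imported lazily
    cell_type_vocabulary: tuple[str, ...] = ()

    def __post_init__(self):
        obs = self.adata.obs
        for col in ("cell_type", "sample_id", "group"):
            if col not in obs.columns:
                raise ValidationError(f"cell annotations missing column {col!r}")
            if obs[col].isna().any():
                raise ValidationError(f"cell annotation {col!r} has missing values")
        if self.cell_type_vocabulary:
            unknown = set(obs["cell_type"].astype(str)) - set(self.cell_type_vocabulary)
            if unknown:
                raise ValidationError(f"cell_type labels outside vocabulary: {sorted(unknown)}")
        if "total_lavage_cells_per_lung" not in self.adata.uns:
            self.adata.uns["total_lavage_cells_per_lung"] = {}

    @property
    def lavage_totals(self) -> dict:
        return dict(self.adata.uns["total_lavage_cells_per_lung"])

    @property
    def counts(self) -> np.ndarray:
        """Raw molecule counts (cells x genes), regardless of normalization."""
        if "counts" in self.adata.layers:
            return np.asarray(self.adata.layers["counts"])
        return np.asarray(self.adata.X)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.adata.var_names)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(counts_path, samplesheet_path, lengths_path) -> ExpressionMatrix:
    """Read a bulk study: counts TSV, sample sheet TSV and gene-length TSV.

    The counts file has gene ids in the first column; the sample sheet needs
    columns sample_id, group, compartment, replicate.  Row and column order is
    preserved from the files.
    """
    sep_counts = "," if str(counts_path).endswith(".csv") else "\t"
    counts = pd.read_csv(counts_path, sep=sep_counts, index_col=0)
    counts.index = [_norm_gene(g) for g in counts.index]
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    required = {"sample_id", "group", "compartment", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    if sheet[["group", "compartment", "replicate"]].isna().any().any():
        raise ValidationError("sample sheet has missing annotations")
    sheet = sheet.set_index("sample_id")
    missing = [c for c in counts.columns if c not in sheet.index]
    if missing:
        raise ValidationError(f"samples without annotation: {missing}")
    samples = [
        SampleInfo(
            sample_id=sid,
            group=str(sheet.loc[sid, "group"]),
            compartment=str(sheet.loc[sid, "compartment"]),
            replicate=int(sheet.loc[sid, "replicate"]),
        )
        for sid in counts.columns
    ]
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    lengths.index = [_norm_gene(g) for g in lengths.index]
    try:
        lengths = lengths.loc[counts.index]
    except KeyError as e:
        raise ValidationError(f"gene length table does not cover all genes: {e}")
    return ExpressionMatrix(counts=counts, gene_lengths_bp=lengths, samples=samples)


def read_marker_gmt(path) -> MarkerSetCollection:
    """Read marker gene sets from GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"duplicate marker set name {name!r}")
            genes = [_norm_gene(g) for g in fields[2:] if _norm_gene(g)]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("set %s: %d duplicate genes removed", name, len(genes) - len(deduped))
            if not deduped:
                raise ValidationError(f"marker set {name!r} has no genes")
            sets[name] = deduped
            prov[name] = desc
    return MarkerSetCollection(sets=sets, provenance=prov)


def write_marker_gmt(markers: MarkerSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in markers:
            desc = markers.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_lr_table(path, complex_delimiter: str = "+") -> LRPairTable:
    """Read a ligand-receptor pair CSV (pair_id, ligand, receptor[, species_source]).

    Multi-subunit complex rows — partners containing ``complex_delimiter`` —
    are rejected loudly: approximating subunit semantics silently would
    misreport co-expression.
    """
    t = pd.read_csv(path, dtype=str).fillna("")
    required = {"pair_id", "ligand", "receptor"}
    if not required.issubset(t.columns):
        raise FormatError(f"LR table needs columns {sorted(required)}")
    if "species_source" not in t.columns:
        t["species_source"] = "native"
    t["ligand"] = t["ligand"].map(_norm_gene)
    t["receptor"] = t["receptor"].map(_norm_gene)
    for _, row in t.iterrows():
        if complex_delimiter in row["ligand"] or complex_delimiter in row["receptor"]:
            raise FormatError(
                f"pair {row['pair_id']!r} is a multi-subunit complex "
                f"(delimiter {complex_delimiter!r}); complexes are not supported"
            )
    return LRPairTable(table=t.reset_index(drop=True))


def read_single_cell_mtx(mtx_path, genes_path, cells_path, lavage_path=None) -> SingleCellDataset:
    """Read an MTX triple (matrix, gene ids, cell annotations) into AnnData.

    ``cells_path`` is a TSV with columns cell_id, cell_type, sample_id, group;
    ``lavage_path`` a TSV with sample_id and total_lavage_cells_per_lung.
    """
    import anndata
    from scipy import io as spio

    mat = spio.mmread(mtx_path).tocsr()  # cells x genes
    genes = [
        _norm_gene(l.split("\t")[0]) for l in Path(genes_path).read_text().splitlines() if l
    ]
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    adata = anndata.AnnData(
        X=np.asarray(mat.todense()), obs=cells, var=pd.DataFrame(index=genes)
    )
    if lavage_path is not None:
        lav = pd.read_csv(lavage_path, sep="\t", index_col=0)
        adata.uns["total_lavage_cells_per_lung"] = {
            str(k): int(v) for k, v in lav.iloc[:, 0].items()
        }
    return SingleCellDataset(adata=adata)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results_table(table: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write a tabular result as TSV with a deterministic row order.

    Floats are serialized with 9 significant digits; rows keep the caller's
    order (every pipeline stage documents and applies its own sort key before
    writing), so identical inputs produce byte-identical files.
    """
    out = table.copy()
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", float_format="%.9g", index_label=index_label)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(matrix: ExpressionMatrix, prefix) -> None:
    """Write counts, sample sheet and lengths as <prefix>.{counts,samples,lengths}.tsv."""
    prefix = Path(prefix)
    matrix.counts.to_csv(f"{prefix}.counts.tsv", sep="\t", index_label="gene_id")
    matrix.sample_table.reset_index().to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)
    matrix.gene_lengths_bp.rename("length_bp").to_csv(
        f"{prefix}.lengths.tsv", sep="\t", index_label="gene_id"
    )


def write_contrast(contrast: ContrastTable, path) -> None:
    out = contrast.table.copy()
    out.attrs["label"] = contrast.label
    with open(path, "w") as fh:
        fh.write(f"# contrast: {contrast.label}\n")
        out.to_csv(fh, sep="\t", float_format="%.9g", index_label="gene_id")


def read_contrast(path) -> ContrastTable:
    with open(path) as fh:
        first = fh.readline()
        label = first.split(":", 1)[1].strip() if first.startswith("# contrast:") else ""
        t = pd.read_csv(fh, sep="\t", index_col=0)
    return ContrastTable(table=t, label=label)
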