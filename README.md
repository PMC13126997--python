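# lumideconv

Compartment-resolved transcriptomics of pollutant–allergen co-exposure in
the murine lung: a tested pipeline for negative-binomial differential
expression, marker-set cell-type interpolation, combination-specific gene
discovery, ligand–receptor co-expression screening and single-cell
quantification — validated end to end on a synthetic study generator with
recoverable ground truth.

## The problem

Inhaled particles such as diesel exhaust amplify allergen-driven type-2
airway inflammation, and the action concentrates in the airway lumen:
cells recovered by bronchoalveolar lavage (LAC) respond far more strongly
than the post-lavage tissue (TISS). Dissecting this requires a chain of
analyses over bulk and single-cell RNA-seq from a four-arm design —
control, particle, allergen, combination — and this package implements
that chain as a reusable, tested library for anyone running similar
co-exposure designs:

- **Differential expression** per gene via a negative-binomial GLM
  (log link, median-of-ratios size factors as offset), per-gene ML
  dispersion with small-sample corrections, Wald t test and
  Benjamini–Hochberg FDR; RPKM and a control-RPKM detection-floor
  sensitivity filter.
- **DES scoring and cell-type interpolation**: each gene's effect is
  summarized as DES = log₂FC × (−log₁₀ q); a cell type's abundance change
  is the mean ± SEM DES over its curated marker genes. Marker specificity
  is validated against annotated single-cell data, and a Δ-DES sort
  contrasts the two compartments gene by gene.
- **Combination-effect set logic**: genes regulated by the co-exposure
  beyond either single exposure are the sign-consistent intersection of
  the combination-vs-particle and combination-vs-allergen DEG sets;
  a cross-particle operation finds responses shared by two particles.
- **Ligand–receptor screening** over CellPhoneDB-style pair tables
  (with human→murine ortholog mapping): both partners differentially
  expressed within a compartment, or directionally across compartments.
- **Single-cell quantification**: per-cell normalization to 10,000
  molecules, positive-cell rates per 1000 analysed, absolute per-lung
  cell and transcript numbers via haemocytometer lavage totals, and
  unpaired t-tests between arms.
- **Synthetic studies** (`lumideconv.simulate`): NB bulk counts from
  cell-type signature mixtures with treatment-dependent composition,
  multinomial single cells, injected combination-only ("synergy") genes
  and wired ligand–receptor pairs — every downstream stage is tested
  against this ground truth.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole chain on the default
synthetic study (seed 1; 2200 genes, 40 bulk samples, 12,000 lavage
cells) and write their tables under `results/`. Running
`python analysis/03_cell_type_interpolation.py` prints:

```
luminal cell-type DES (mean over markers), by treatment:
            DEP   HDM     DH
cell_type
AAM        0.54  8.35  16.20
AM        -0.00 -0.12  -1.86
AM.Cyc     0.00 -0.01  -0.45
IM         0.00  0.09   0.12
MC         0.01  1.56   2.88
EOS        0.00  0.63   0.55
BC         0.00  0.07   0.28
TC         0.00 -0.00  -0.11
NEU        0.00 -4.12  -5.78
EC         0.00 -1.06  -0.55

Spearman(true composition change, mean DES) for D+H v CTRL in LAC: 0.988
```

Each row is a cell type scored by the mean DES of its markers in the
treatment-vs-control contrast: the alternatively-activated-macrophage-like
type (AAM), whose true luminal fraction the generator expands
0.02 → 0.05 → 0.15 → 0.35 across the arms, climbs from 0.5 to 16.2, while
neutrophil-like cells (NEU), which the co-exposure depletes, go strongly
negative — and the ranking across all ten types matches the generating
composition change at Spearman 0.99. Downstream,
`analysis/04_combination_effects.py` recovers the 50 injected synergy
genes from the DEG-set intersection at F1 0.88 (precision 0.80, recall
0.98), and `analysis/05_ligand_receptor_screen.py` retains all 10 wired
ligand–receptor pairs and none of the 40 null pairs at the 1.25-fold /
FDR 0.05 screen.

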