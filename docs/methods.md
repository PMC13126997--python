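# Methods

`lumideconv` analyses a two-compartment murine co-exposure design: luminal
airway cells (LAC) recovered by bronchoalveolar lavage and post-lavage lung
tissue (TISS), each sampled under control (CTRL), particle alone (DEP or
CEP), allergen alone (HDM) and the particle+allergen combination (DH, CH).
This note describes the statistical model behind each stage, the synthetic
study the pipeline is validated on, and the choices made where the design
was genuinely open.

## Differential expression

Counts for gene *g* in sample *s* are modelled as negative binomial,
NB(μ_gs, α_g), with variance μ + αμ² (NB2). Each two-group contrast fits a
log-link GLM per gene with an intercept, a group indicator and log size
factors as offset; the reported log₂ fold change is the group coefficient
divided by ln 2, so on clean balanced designs it equals the log₂ ratio of
the group means exactly.

Size factors are median-of-ratios against the geometric-mean reference
sample, rescaled to geometric mean 1; when no gene is observed in every
sample the code falls back to total-count factors with a warning.

Dispersion is estimated per gene by maximum likelihood and floored at
1e-8. Two small-sample corrections are applied before testing, because at
the study's n = 5 per arm a raw ML-dispersion Wald test with a normal
reference rejects ~12% of true nulls at α = 0.05:

1. the dispersion estimate is inflated by n/(n − p), correcting the
   downward bias of the ML estimator;
2. the Wald statistic for the group coefficient is referred to a
   t distribution with n − p degrees of freedom rather than a normal.

With both corrections the measured null rejection rate is ≈ 0.05 (the
acceptance script recomputes it on 2000 simulated null genes).

Contrast-level fits add one further refinement: each gene's ML dispersion
is shrunk toward the across-gene median with a prior weight of 10 degrees
of freedom (empirical-Bayes moderation in the edgeR/DESeq2 tradition).
Per-gene-only estimates at this sample size are noisy enough to inflate
standard errors ~1.5× for unlucky genes, which costs real power in the
downstream screens; moderation restores it while keeping the null rate
within [0.03, 0.07] (measured 0.034). `fit_gene_nb` called standalone
remains purely per-gene.

Degenerate genes are never dropped: an all-zero gene reports log₂FC 0,
p = 1; a gene observed in only one arm reports a pseudo-count fold change
(0.5 added to both normalized group means) and a fixed-dispersion
likelihood-ratio p value, since the Wald coefficient diverges there.

Multiple testing uses Benjamini–Hochberg step-up FDR ("q values"); q = 0
after rounding is floored at 1e-300 before any logarithm. DEG calling at
fold-change threshold *f* and FDR threshold *q* requires |log₂FC| ≥ log₂ f
and q below the threshold; the defaults are (2.0, 0.05), with (1.25, 0.05)
used for ligand–receptor screening and (1.5, 0.05) for the cross-particle
comparison. RPKM is counts × 10⁹ / (library size × gene length); the
sensitivity filter retains DEGs whose control-arm RPKM exceeds a detection
floor (default 0.01) and reports the retained fraction.

## DES and cell-type interpolation

The per-gene effect summary is the differential expression score,
DES = log₂FC × (−log₁₀ q). It is odd in the fold change and grows with
significance, so strongly induced, well-supported genes dominate.

Cell-type interpolation reads relative abundance changes out of a bulk
contrast as the mean DES over a curated marker gene set, reported as
mean ± SEM over the member genes found (SEM = sample SD / √n over genes
found; a single-gene set reports SEM 0). Genes absent from the contrast
are listed, not errors; a set with no measured gene is skipped with a
warning. Genes shared between sets contribute to each, with a logged
warning at collection construction. The score is a rank-level instrument:
it orders cell types by abundance change but is not a deconvolution into
absolute proportions.

The compartment comparison (Δ-DES sort) intersects the gene universes of
the LAC and TISS versions of one contrast and sorts by
DES(LAC) − DES(TISS), descending, ties broken by gene id.

Marker-set specificity against annotated single-cell data is formalized
here as: per gene, the mean depth-normalized expression in the set's own
type divided by the sum of mean normalized expression across all types
(0 when the denominator is 0); per set, the mean over member genes. This
quantitative score is this package's own construction — the original
confirmation of marker specificity was visual.

## Combination-effect set logic

Genes regulated "by the combination alone" are the sign-consistent
intersection of the combination-vs-particle and combination-vs-allergen
DEG sets; direction conflicts are excluded and logged. The operation is
symmetric in its inputs, its output is a subset of either input's
universe, and raising thresholds never grows it. No additional requirement
is placed on the single exposures versus control — the intersection itself
is the definition. The enhanced-beyond-single variant works directly on
the two contrast tables at explicit thresholds and reports each gene's
minimum |DES| across the two comparisons as the conservative effect size.
The cross-particle operation intersects two particle-alone DEG sets
(default thresholds 1.5-fold / FDR 0.05) with paired DES columns, sorted
by mean DES.

## Ligand–receptor screening

A curated pair table (CellPhoneDB-style: pair id, single-subunit ligand
and receptor) is screened against contrasts. Within one compartment a
pair is retained when both partners pass the DE thresholds (default
1.25-fold / FDR 0.05); the screen is direction-agnostic by default since
co-regulated pairs may move either way, with a flag restricting to
concordant pairs. Across compartments the screen is directional: the
ligand must be upregulated in its compartment and the receptor in the
other, the recruitment-oriented reading. Pairs with an unmeasured partner
are skipped and counted. Human database pairs are first mapped through a
one-to-one ortholog table; mapped pairs are flagged, unmappable pairs
dropped and counted, and one-to-many mappings are an error. Multi-subunit
complexes are rejected loudly by the reader rather than approximated.

## Single-cell quantification

Molecule counts per cell are scaled so every cell totals 10,000 molecules
(raw counts preserved alongside); cells with zero total must be removed
upstream and are an error here. Positive-cell rates are
(cells with raw count > 0) / (cells analysed) × 1000 per stratum —
positivity is a property of raw integer molecule counts, never of
normalized values. Absolute per-lung quantities scale analysed-cell
proportions by the per-sample haemocytometer lavage total:
count(sample, type) = lavage total × n_type / n_analysed, so summing over
types recovers the lavage total exactly. Per-lung totals of a gene
multiply the stratum's mean normalized expression by its per-lung cell
count; zero-count cells can be excluded from the per-cell mean (the
convention used for per-cell expression displays) but are included by
default so the product stays an unbiased total. Scaling happens per
sample; summaries across replicates come afterwards. Group comparisons
use the unpaired two-sample t-test, pooled-variance by default with Welch
as an option.

## The synthetic study

No accession-resolvable data accompany the design, so all inputs are
emulated by a generator with recoverable ground truth. Bulk counts are
NB draws around L_s × p_g, where p_g is the arm's mixture profile —
composition-weighted cell-type signatures, normalized to sum 1 — and L_s
is a library size uniform on [1e6, 3e6]. Signatures give each of 10 cell
types 20 exclusive markers (mean 100, lognormal CV ~25%, zero in all
other types) over 2000 background genes with lognormal means (median 10)
shared across types. Dispersion is α = 0.1 for every gene. The default
design has 5 replicates per (group, compartment): 40 bulk samples.

The treatment signal is primarily compositional, matching the premise of
marker-set interpolation. The AAM-like type's luminal fraction runs
0.02 → 0.05 → 0.15 → 0.35 across CTRL → DEP → HDM → DH. The other nine
types' rows were designed so that (a) every type has a distinct
combination-vs-control change, making rank recovery meaningful, and
(b) non-AAM combination-vs-single abundance ratios stay inside (0.5, 2),
so the combination-unique call is dominated by injected synergy genes.
The AAM trajectory itself crosses 2× against both single arms, so its
markers are expected, legitimate contaminants of the combination-unique
set — they are genes whose abundance genuinely rises only under
co-exposure. Tissue rows shift in the same directions but more mildly.

Fifty background genes (~2% of the transcriptome, the same order as the
luminal combination-specific signature in vivo) form the synergy pool:
their expression is multiplied 4× only in the combination arms and only
in the luminal compartment — the combination signature is a luminal
phenomenon, and a systemic injection would fabricate cross-compartment
ligand–receptor directionality that the data do not support.

Single-cell data are multinomial: each cell's type is drawn from its
arm's luminal composition and its 5000 molecules from the type's
signature profile (with the synergy multiplier in combination arms);
3 samples of 1000 cells per arm. Per-sample lavage totals are uniform on
[2e5, 5e5] scaled by a per-group inflammation factor (CTRL 1.0, particle
1.2, HDM 2.0, combination 3.0), reflecting the rise of BAL cellularity
with inflammation. The ligand–receptor table wires 10 true pairs among
synergy genes and 40 null pairs among background genes, recorded in the
truth object.

The cross-particle fixture (`make_particle_study`) is a separate two-arm
study whose particle arm carries the allergen-strength composition shift:
a 2.5× expansion of a 2% population at five replicates and α = 0.1 sits
below the detection limit of a genome-wide FDR screen (per-gene p ≈ 2e-3
against a BH line near 7e-4 when only ~20 genes respond), whereas the
particle-alone response the cross-particle comparison is meant to recover
was clearly detectable in vivo.

All generators are deterministic given their seed (NumPy PCG64 via
`default_rng`); `make_study` fans one seed out to sub-generators by fixed
offsets so stages reproduce individually. A null-combination switch
equalizes the combination arm's composition with both singles and injects
no synergy, providing the false-positive condition for the set logic.

### What the generator does not emulate

Ambient RNA, doublets, batch effects, per-cell depth variation,
gene–gene correlation beyond the mixture structure, dispersion trends
with expression, and read-level artefacts are all absent. Passing
recovery tests therefore demonstrates that the pipeline's inferences are
correct when its model assumptions hold, not that they are robust to
real-data pathologies those assumptions exclude.

## Problem sizes and numerical choices

The default study (2200 genes × 40 samples, 12,000 cells) keeps a full
contrast fit under ~10 s and the whole validation suite within minutes;
it is large enough for the calibration and recovery statistics to be
stable at the tolerances tested. Tolerances: exact assertions where the
arithmetic is closed-form (normalization totals, conservation, RPKM,
DES); 1e-6 for GLM coefficient identities; calibration and recovery
bands as stated per test. Ties in every sorted output are broken by
gene or pair id, so all tables are byte-deterministic. Q values are
floored at 1e-300; dispersions at 1e-8; fold changes over a zero arm use
a 0.5 pseudo-count on normalized means for reporting only.

## Known limitations

The NB test is slightly conservative after moderation (null rate ≈ 0.03–
0.05). Per-pair retention in the LR screen at the 1.25-fold / FDR 0.05
defaults is ≈ 0.95 per wired pair under the default effect size, so a
random seed occasionally drops a true pair or two. The interpolation
score is rank-level only. The pipeline consumes cell-type annotations; it
does not produce them (no clustering, embedding or label transfer), and
CellPhoneDB complex semantics, shrinkage estimators, multi-factor designs
and batch covariates are out of scope.
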