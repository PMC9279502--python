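# Methods

`icbmm` implements an integrative analysis of immune-checkpoint-blockade
(ICB) response in non-small-cell lung cancer: tumor-extrinsic cytotoxic
T-cell activity measured by a fixed 25-gene expression score, tumor-intrinsic
genomics (tumor mutational burden and HLA class-I loss of heterozygosity),
and a multimodal risk score that combines the two against real-world time to
progression (TTP). Because the patient cohort such an analysis would run on
is restricted-access, the package ships a first-class synthetic-data module
whose defaults define the study conditions; every statistical claim the test
suite makes is made on that generated data.

## Single-cell preprocessing

Cells (RNA counts, surface-protein counts, a CD45⁺/CD45⁻ sorted-fraction
label) live in an `AnnData`. QC removes cells with <200 or >2500 detected
genes and cells whose mitochondrial count fraction exceeds 6% (immune,
CD45⁺) or 20% (tumor, CD45⁻); genes detected in <3 remaining cells are then
dropped. All cutoffs are strict inequalities and surfaced as arguments. RNA
counts are scaled to 10,000 per cell and transformed with log(1+x) (natural
log — the dominant single-cell convention; the transform is recorded in
`uns`). Protein counts are CLR-transformed per cell: log1p(x) minus the
cell's mean log1p, so each cell's CLR values sum to zero.

T-cell compartments are gated on CLR protein values: CD4 = CD45⁺ CD3⁺ CD20⁻
CD68(RNA)-low CD4⁺ CD8⁻, CD8 symmetric; double-positive and double-negative
cells are excluded. The source figures show gates graphically without
numbers, so the default gate is CLR > 0 per marker (above the cell's own
geometric-mean background) and CD68 normalized expression ≤ 1; every
threshold is a config value recorded in the output, not an inferred
constant. Clustering is deliberately not reimplemented: labels are either
user-supplied (the pipeline default uses the generator's planted labels) or
produced by `cluster_cells`, a thin scanpy/Leiden backend that accepts the
published resolutions (0.7 CD8, 0.8 CD4) as pass-through parameters.

Differential expression is a two-sided Wilcoxon rank-sum of one cluster
versus all other cells per gene, normal approximation with tie correction,
switching to the exact null distribution when both sides have ≤10 cells and
the gene has no ties; p-values are Bonferroni-adjusted across tested genes.
Genes are ranked by the signed z statistic with a deterministic tie-break
(z, then log-fold-change, then lexicographic gene id) — whether the original
ranking used z or fold change is not documented anywhere authoritative, so
the choice is flagged in the result metadata. A cluster signature is the
top-25 ranked genes; a signature score is the arithmetic mean of log
expression over the signature, optionally z-scored across samples (sample
SD, ddof = 1). Missing signature genes are an error, never silently
subsetted.

## TCR repertoire

A clonotype is an identical (TRA, TRB) CDR3 amino-acid pair; cells without
a paired TRA+TRB or with multiple chains of either locus are removed first
(exactly duplicated chain records are treated as a data-integrity error
rather than a biological multi-chain). A clone is expanded if it has ≥2
cells within the analyzed group. Shannon entropy H = −Σ pᵢ ln pᵢ uses
Hutcheson's variance estimate

    Var(H) = [Σ pᵢ (ln pᵢ)² − (Σ pᵢ ln pᵢ)²]/N + (S−1)/(2N²),

and two repertoires are compared with Hutcheson's t-test,
t = (H₁−H₂)/√(V₁+V₂), with Welch–Satterthwaite (non-integer) degrees of
freedom — the classical 1970 formulation, since the exact variant used by
downstream ecology packages is not printed anywhere we could verify.

Clone sharing between clusters is a directed graph: weight(A→B) is the
percent of A's clones with at least one cell in B (an option weights by A's
cells instead; clone-level is the default and matches the figure legend
wording). Clones are compartment-wide — shared across clusters within CD4 or
CD8 separately — and singleton clones count in both numerator and
denominator (a `min_clone_size` filter exists for sensitivity analysis).
Pruning removes edges at or below the inclusive empirical quantile
(numpy `method="lower"`) of the nonzero weights, so ties at the cutoff are
removed; the published figures pruned the lowest tertile (CD4) and quartile
(CD8), available as presets.

## Genomic features

TMB counts somatic, coding, non-silent variants (missense, indel,
stop-loss) passing strict assay-specific filters — coverage >100× and
allele fraction >5% for targeted panels, >30× and >10% for whole exome —
divided by the panel's megabase size; mixed-assay tables are an error. TMB
is binarized at ≥10 mut/Mb. PD-L1 tumor proportion scores map to
negative (<1%), low (1–49%), high (≥50%).

HLA-LOH is called per heterozygous class-I locus from allele-specific read
counts. Under a clonal one-copy loss with tumor purity p and flanking total
copy number C, the lost allele's expected read fraction is
f_loss = (1−p)/((1−p)·2 + p·(C−1)); under no loss it is 0.5. A locus is
called LOH when a one-sided binomial test rejects f = 0.5 toward the minor
allele at level α (default 0.01) **and** the observed minor fraction is
closer to f_loss than to 0.5; loci that are homozygous, below `min_depth`
(default 30) total reads, or from purity-0 samples are no-calls. The
original caller's statistical threshold and minimum coverage are not
printed, so these defaults are this package's decisions. Subclonal
imbalance deliberately reads as no-LOH (the decision rule targets clonal
loss); a continuous loss-fraction estimate is emitted for diagnostics only.
Germline re-alignment correction is out of scope: inputs are assumed
allele-resolved counts. A patient is HLA-LOH if any locus is called LOH,
and HLA-homozygous if any locus has identical 4-digit alleles.

## Survival

TTP is days from treatment start to first progression (event = 1);
otherwise patients are censored at a non-progression treatment stop
(adverse event, non-compliance, other) or else at the last encounter, and
patients with no progression and <90 days of follow-up are ineligible. The
Kaplan–Meier estimator, k-group log-rank test, and Cox fitter are written
here (lifelines serves only as an independent cross-check in tests). The
Cox partial likelihood uses the Breslow approximation for ties — censored
subjects tied with an event time remain at risk — plus an optional ridge
penalty (α/2)·‖β‖² applied equally to all covariates, which are used
exactly as provided. Maximization is Newton–Raphson with step-halving;
convergence at |Δℓ| < 1e-9 or ‖∇ℓ‖∞ < 1e-8, max 100 iterations;
non-convergence is flagged, and diverging coefficients (‖β‖∞ > 50) or a
non-finite information matrix raise a separation error. Standard errors
come from the observed information of the penalized objective; hazard
ratios are exp(β) with Wald 95% CIs. The score test at β = 0 equals the
two-group log-rank statistic on untied data, which the tests verify to
1e-6.

## The multimodal (MM) score

Features are the cohort-standardized cytotoxic score — the mean of
log10-transformed bulk expression over the fixed 25 genes, z-scored — and
the 0/1 TMB-high indicator. For each of 100 seeded shuffles, a ridge
(α = 1) Breslow Cox model is fit on a random 75% of patients
(train size = ⌊0.75·n⌋) and each held-out patient receives the fitted
linear predictor (log relative hazard — the natural out-of-fold score, and
monotone in predicted risk). Per-patient MM score is the arithmetic mean
over out-of-fold appearances; training folds with zero events are redrawn
and extra shuffles are drawn until every patient is scored at least once
(both logged). The cohort median splits patients into high/low risk;
patients exactly at the median go high (mirroring the ≥10 TMB convention;
configurable). Fold assignment operates on an index-sorted canonical
ordering, so results are invariant to input row order, and the RNG is
numpy's PCG64 so seeds are portable. Standardization of the cytotoxic score
happens on the full cohort before resampling, as the source protocol
standardizes scores before survival use; this leaks the cohort mean/SD into
training folds — a deliberate fidelity choice, and a strict
within-training-fold option is available via `cytotoxic_score` on fold
subsets. Reports emit KM curves, log-rank, and an unpenalized Cox HR for
high-vs-low both cohort-wide and in subgroups (e.g. the HLA-LOH
subcohort), always reusing the cohort-level cutoff; subgroup arms with <2
patients are suppressed with a warning.

A note on nulls: retraining the MM ensemble on permuted outcomes and
log-rank-testing its own median split against the same permuted data is
anti-conservative by construction — the averaged out-of-fold direction
approaches the full-data MLE, so the split is a fitted selection. The
package therefore validates calibration with the standard permutation
null: trained risk groups held fixed, outcomes permuted, giving uniform
p-values. The optimism of the self-evaluated split is a property shared
with the original protocol and worth keeping in mind when reading its
headline p-values.

## Synthetic data: what it emulates, and what it does not

All generators draw from independent RNG streams spawned from one seed
(`SeedSequence` spawn keys), so runs are bit-reproducible and adding one
generator call never perturbs another.

* **Single cell.** Negative-binomial counts (Var = μ + φμ², φ = 0.5) over
  a 1000-gene universe containing the 25 cytotoxic genes, canonical
  T-subset markers, and ~1.3% mitochondrial genes tuned to a 3% count
  fraction (comfortably inside the QC gates). Seven planted clusters mimic
  the CD8 (GZMK/GZMB/naive) and CD4 (GZMB/activated/regulatory/naive)
  subsets, with 8-fold marker up-regulation; surface proteins follow the
  compartment (CD45/CD3 high, CD4 xor CD8, CD20 low).
* **Clonotypes.** Per compartment, each cluster assigns cells to a clone
  pool Dirichlet-multinomially with its own concentration; the Dirichlet
  weights are built from shared per-compartment uniforms through the Gamma
  quantile function, so per-cluster marginals are exactly symmetric
  Dirichlet while expanded clones coincide across clusters — emulating
  antigen-driven expansions that span phenotypic states. Cytotoxic
  concentrations (0.15/0.08 CD8, 0.10 CD4) are calibrated to the reported
  expansion levels (~83% of cytotoxic CD8 and ~54% of cytotoxic CD4 cells
  in expanded clones). Unique synthetic CDR3 strings key each clone; 8% of
  cells drop a chain and 4% gain an extra one to exercise the filters.
* **Cohort.** 123 patients by default. Bulk log10 expression carries a
  latent cytotoxic activity with loading 0.3 on the 25 genes; TMB is
  lognormal with median 5.71 mut/Mb and σ = 1.3 (≈33% of patients ≥10 —
  NSCLC panel TMB is heavy-tailed), independent of the cytotoxic score by
  construction. Event times are Weibull (shape 1.2, scale 300 d — baseline
  median TTP near 210 d) with log-hazard β_cs·CS + β_tmb·1[TMB≥10],
  defaults β = (−0.7, −0.5) (protective, matching the direction and rough
  magnitude of the reported associations); censoring is independent
  exponential with its rate matched to a 15% target, suiting a progression
  endpoint with mature follow-up. These information-content choices also
  honor the prescribed recovery calibration: both betas recoverable to
  ±0.2 at n = 400 in ≳90% of seeds.
* **HLA.** Three class-I loci per patient; per-locus homozygosity 0.087
  (→ ~24% of patients homozygous somewhere) and planted clonal one-copy
  losses at rate 0.10 per heterozygous locus (→ ~25% of patients
  HLA-LOH). Reads are Binomial(depth ~ Poisson(300), f) with f from the
  same mixture model the caller inverts.
* **Variants.** Consequence classes, depths (20–400×), and allele
  fractions (1–60%) spanning every filter threshold, with the
  filter-passing count returned as ground truth.

What the generator does **not** emulate: doublets, batch effects, ambient
RNA, UMI saturation, V(D)J biology beyond clone identity, germline
contamination of HLA counts, subclonal copy-number structure, covariate-
dependent censoring, or non-proportional hazards. Passing tests therefore
demonstrate correctness of the implemented statistics under the stated
models, not robustness to those real-data pathologies.

## Numerical and design notes

* QC is single-pass (cells on raw detected-gene counts, then genes), which
  is idempotent under the generator's margins; pathological inputs could in
  principle require a second pass.
* The log-rank covariance uses the hypergeometric variance with the
  k-group pseudo-inverse, so degenerate strata cannot crash the test.
* The exponential censoring rate is matched via the mean event time, exact
  for exponential event times and approximate (within a few percent) for
  the default Weibull shape.
* Problem sizes in the test suite (e.g. 100 recovery seeds at n = 400, 20
  MM seeds at 100 shuffles, ~500 HLA loci, 10,000-gene null DE) were
  chosen to keep the full suite around a minute while leaving Monte-Carlo
  margins well away from the asserted bounds.
* `scripts/acceptance.py` recomputes the headline quantities from scratch
  at these same scales; see the README for how to run it.

## Known limitations

The gating defaults (CLR > 0) are a convention, not fitted gates; real
antibody panels need per-marker overrides. The LOH caller assumes a single
clonal loss against a balanced-copy null and known purity. The MM score's
self-evaluated stratification inherits resampling optimism (see above).
Efron tie handling, time-varying covariates, stratified Cox, and
proportionality diagnostics are out of scope.
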