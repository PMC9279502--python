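# icbmm

Multimodal stratification of immune-checkpoint-blockade (ICB) response in
non-small-cell lung cancer (NSCLC), for computational oncologists and
biomarker methodologists. The package integrates a **tumor-extrinsic**
measure of cytotoxic T-cell activity — a fixed 25-gene expression score
derived from single-cell profiling of tumor-infiltrating CD4⁺ and CD8⁺
T cells — with **tumor-intrinsic** genomics (tumor mutational burden,
HLA class-I loss of heterozygosity) into a resampled Cox risk score for
real-world time to progression (TTP).

Because the kind of linked molecular/clinical cohort this analysis targets
is restricted-access, the package includes a synthetic-data module that
generates every input with the statistical structure the analysis assumes
(negative-binomial single-cell counts with planted subsets, skewed TCR
clone-size distributions, binomial HLA allele coverage with planted losses,
Weibull TTP with planted effects), so the entire pipeline is runnable and
testable end to end with no external data.

## The model

**Cytotoxic score.** For patient *j* with bulk log10 expression *x*,

    CS_j = mean_{g in G25} x_jg,          then z-scored across the cohort,

where G25 = {NKG7, CXCL13, GZMH, HAVCR2, CCL5, GZMK, CCL4, GZMA, CCL3,
CST7, CCL4L2, ACP5, TNFRSF9, TIGIT, GZMB, PDCD1, PRF1, LYST, SIRPG, LAG3,
CARD16, TUBA4A, PTMS, CD74, KLRD1}.

**Multimodal (MM) score.** With covariates z_j = (CS_j, 1[TMB_j ≥ 10]),
Cox proportional-hazards models with Breslow tie handling and ridge penalty
(α = 1) are fit on 100 random 75/25 shuffles of the cohort; each held-out
patient receives the fitted linear predictor β̂'z_j, and

    MM_j = mean of β̂'z_j over the shuffles where j was held out.

The cohort median of MM splits patients into high/low risk groups, compared
by Kaplan–Meier curves, the log-rank test, and an unpenalized Cox hazard
ratio — cohort-wide and within subgroups such as the HLA-LOH subcohort.

Supporting stages implement the surrounding analysis: single-cell QC
(<200/>2500 genes, >6%/>20% mitochondrial counts for immune/tumor cells,
genes in <3 cells), 10k normalization and CLR protein transform, CD4/CD8
protein gating, Wilcoxon rank-sum differential expression with Bonferroni
correction, top-25 cluster signatures; TCR clonotype calling (paired
TRA/TRB CDR3), expansion statistics, Shannon entropy with Hutcheson's
t-test, directed clone-sharing graphs with quantile pruning; TMB with
assay-specific filters (>100×/>5% panel, >30×/>10% WES), PD-L1 TPS
categories, and an HLA-LOH caller that tests allele-specific coverage
against the purity-aware mixture expectation
f_loss = (1−p)/(2(1−p) + p(C−1)).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Run the full pipeline on a generated cohort (123 patients, 3000 cells):

```sh
icbmm run-all --outdir run --seed 7
```

or equivalently from Python:

```python
from icbmm.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(outdir="run", seed=7))
```

`run/survival_report.json` then contains (numbers printed by this exact
command):

```
full_cohort.n                 123          # patients
full_cohort.n_high / n_low    62 / 61      # median split of the MM score
full_cohort.cox.hr            2.75         # hazard ratio, high vs low MM
full_cohort.cox.ci            [1.84, 4.09]
full_cohort.logrank.p         2.5e-07
full_cohort.median_ttp        {high: 138.3, low: 356.8}   # days
subgroups.hla_loh.cox.hr      3.35         # same split, LOH subcohort (n=38)
```

Read: patients in the high-MM group progress on ICB about 2.8× faster than
low-MM patients (median TTP 138 vs 357 days) — the planted protective
effects of cytotoxic expression (β = −0.7 per SD) and high TMB (β = −0.5)
are recovered as elevated risk for patients lacking both, and the
stratification persists in the HLA-LOH subcohort. `run/manifest.json`
records the seed, a config hash, and SHA-256 checksums of every output;
rerunning with the same seed reproduces them byte for byte.

Individual stages are available as subcommands (`simulate`, `sc-score`,
`tcr`, `tmb`, `hla-loh`, `mm-train`, `survival`) and as library functions
(`icbmm.fit_cox_breslow`, `icbmm.hutcheson_t_test`, ...).

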