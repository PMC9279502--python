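"""Synthetic inputs with the statistical structure the downstream analysis assumes.

The real cohort behind this analysis is restricted-access, so every pipeline
stage is exercised on generated data instead: negative-binomial single-cell
counts with planted marker programs, Dirichlet-multinomial TCR clone-size
distributions (more concentrated, i.e. more expanded, in cytotoxic clusters),
binomial HLA allele read counts with planted one-copy losses, somatic variant
tables spanning the TMB filter thresholds, and Weibull survival times whose
log-hazard is linear in the cytotoxic score and binarized TMB.

Each generator draws from its own RNG stream derived from ``SimConfig.seed``
via ``numpy.random.SeedSequence`` spawn keys, so adding a call to one
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ClusterSpec",
    "SimConfig",
    "generate_sc_dataset",
    "generate_cohort",
    "generate_hla_profiles",
    "generate_variant_table",
]

# the fixed 25-gene cytotoxic program scored on bulk expression, and the
# allele-fraction mixture model the HLA read-count generator emulates
from .cohort_model import CYTOTOXIC_GENES
from .genomic_features import expected_loss_fraction

PROTEIN_MARKERS = ("CD45", "CD3", "CD4", "CD8", "CD20")

# spawn keys: one independent RNG stream per generator
_STREAM_SC = 0
_STREAM_COHORT = 1
_STREAM_HLA = 2
_STREAM_VARIANTS = 3

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ClusterSpec:
    """One planted T-cell subpopulation.

    ``clone_concentration`` is the symmetric Dirichlet concentration that
    governs clone-size skew within the cluster: large values give near-uniform
    repertoires, values below ~1 give a few dominant (expanded) clones.
    """

    name: str
    proportion: float
    compartment: str  # "CD4" or "CD8"
    markers: tuple[str, ...]
    marker_fold_change: float = 8.0
    clone_concentration: float = 10.0
    cytotoxic: bool = False


def _default_clusters() -> tuple[ClusterSpec, ...]:
    # loosely modelled on the CD8 (GZMK / GZMB / naive-like) and CD4
    # (GZMB / activated / regulatory / naive-like) subsets seen in NSCLC;
    # cytotoxic concentrations are set so that ~83% of cytotoxic CD8 cells
    # and ~54% of cytotoxic CD4 cells sit in expanded clones
    return (
        ClusterSpec("CD8_GZMK", 0.10, "CD8", ("GZMK", "GZMA", "NKG7", "CRTAM", "CST7"),
                    8.0, 0.15, cytotoxic=True),
        ClusterSpec("CD8_GZMB", 0.12, "CD8", ("GZMB", "PRF1", "GZMH", "PDCD1", "LAG3"),
                    8.0, 0.08, cytotoxic=True),
        ClusterSpec("CD8_naive", 0.18, "CD8", ("CCR7", "IL7R", "SELL"),
                    8.0, 60.0, cytotoxic=False),
        ClusterSpec("CD4_GZMB", 0.08, "CD4", ("GZMB", "GNLY", "PRF1", "CCL5", "KLRD1"),
                    8.0, 0.10, cytotoxic=True),
        ClusterSpec("CD4_activated", 0.12, "CD4", ("CD69", "TNFRSF9"),
                    8.0, 30.0, cytotoxic=False),
        ClusterSpec("CD4_regulatory", 0.10, "CD4", ("FOXP3", "CTLA4", "TIGIT"),
                    8.0, 60.0, cytotoxic=False),
        ClusterSpec("CD4_naive", 0.30, "CD4", ("CCR7", "IL7R", "TCF7"),
                    8.0, 120.0, cytotoxic=False),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    Defaults emulate the real-world cohort scale: 123 ICB-treated patients,
    a median TMB near 5.7 mut/Mb straddling the 10 mut/Mb cutoff, protective
    planted effects (negative log-hazards) for the cytotoxic score and
    TMB-high status, and a baseline time-to-progression median near 210 days.
    """

    seed: int = 0
    # single-cell
    n_cells: int = 3000
    n_genes: int = 1000
    cluster_spec: tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    nb_dispersion: float = 0.5
    mito_fraction: float = 0.03
    chain_missing_rate: float = 0.08
    chain_multiple_rate: float = 0.04
    # cohort / survival
    n_patients: int = 123
    beta_cs: float = -0.7
    beta_tmb: float = -0.5
    weibull_shape: float = 1.2
    weibull_scale: float = 300.0
    censor_rate: float = 0.15
    tmb_log_median: float = 5.71
    tmb_log_sigma: float = 1.3
    # HLA
    purity_range: tuple[float, float] = (0.3, 0.9)
    loh_fraction: float = 0.1
    depth_mean: float = 300.0
    homozygosity_rate: float = 0.087
    flanking_total_copies: int = 2
    # variants
    n_variants: int = 60
    panel_size_mb: float = 2.4

    def validate(self) -> None:
        props = sum(c.proportion for c in self.cluster_spec)
        if abs(props - 1.0) > 1e-8:
            raise ValueError(f"cluster proportions sum to {props}, expected 1")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_patients <= 0:
            raise ValueError("counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must be within [0, 1]")
        if not (0.0 <= self.loh_fraction <= 1.0):
            raise ValueError("loh_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not np.isfinite(self.beta_cs) or not np.isfinite(self.beta_tmb):
            raise ValueError("planted betas must be finite")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape/scale must be > 0")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _gene_universe(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Gene ids with all named markers present, plus mito genes and filler."""
    special: list[str] = []
    for g in CYTOTOXIC_GENES + ("CD68", "GNLY", "SELL", "TCF7", "CTLA4",
                                "CCR7", "IL7R", "FOXP3", "CD69", "CRTAM"):
        if g not in special:
            special.append(g)
    n_mito = max(5, int(round(0.013 * config.n_genes)))
    mito = [f"MT-G{i}" for i in range(n_mito)]
    n_fill = config.n_genes - len(special) - n_mito
    if n_fill < 0:
        raise ValueError("n_genes too small for the named marker universe")
    filler = [f"FILL{i:05d}" for i in range(n_fill)]
    genes = special + mito + filler
    mito_flag = np.array([g.startswith("MT-") for g in genes])
    return genes, mito_flag


def _cdr3(prefix: str, clone_idx: int) -> str:
    """Deterministic, unique synthetic CDR3 amino-acid string per clone."""
    digits = []
    i = clone_idx
    while True:
        digits.append(_AA[i % 20])
        i //= 20
        if i == 0:
            break
    return "CA" + prefix + "".join(reversed(digits)) + "F"


def generate_sc_dataset(config: SimConfig):
    """Generate the single-cell dataset, clonotype records, and truth labels.

    Returns
    -------
    adata : anndata.AnnData
        Raw RNA counts (cells x genes) with surface-protein counts in
        ``obsm["protein"]``, mito flags in ``var["mito"]``, and the CD45
        fraction label in ``obs["fraction"]``.
    records : pandas.DataFrame
        AIRR-style long-format chain records (cell_id, locus, junction_aa).
    truth : pandas.DataFrame
        Per-cell true cluster, compartment, cytotoxic flag, and clone id.
    """
    config.validate()
    rng = _rng(config, _STREAM_SC)
    genes, mito_flag = _gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    for c in config.cluster_spec:
        missing = [g for g in c.markers if g not in gene_index]
        if missing:
            raise ValueError(f"markers not in gene universe: {missing}")

    n = config.n_cells
    props = np.array([c.proportion for c in config.cluster_spec])
    cluster_idx = rng.choice(len(props), size=n, p=props)
    clusters = np.array([config.cluster_spec[i].name for i in cluster_idx])
    compartments = np.array([config.cluster_spec[i].compartment for i in cluster_idx])
    cytotoxic = np.array([config.cluster_spec[i].cytotoxic for i in cluster_idx])

    # per-gene baseline means; mito genes tuned so mito fraction sits near
    # config.mito_fraction, far from both QC thresholds
    base_mu = rng.lognormal(mean=np.log(0.6), sigma=1.0, size=config.n_genes)
    base_mu = np.clip(base_mu, 0.05, 40.0)
    mito_mu_total = config.mito_fraction / (1 - config.mito_fraction) * base_mu[~mito_flag].sum()
    base_mu[mito_flag] = mito_mu_total / mito_flag.sum()

    mu = np.tile(base_mu, (n, 1))
    for k, c in enumerate(config.cluster_spec):
        rows = cluster_idx == k
        cols = [gene_index[g] for g in c.markers]
        mu[np.ix_(rows, cols)] *= c.marker_fold_change
    X = _nb_draw(rng, mu, config.nb_dispersion).astype(np.int64)

    # surface proteins: T cells are CD45+/CD3+/CD20-, with CD4/CD8 by compartment
    prot_mu = np.empty((n, len(PROTEIN_MARKERS)))
    prot_mu[:, PROTEIN_MARKERS.index("CD45")] = 120.0
    prot_mu[:, PROTEIN_MARKERS.index("CD3")] = 80.0
    prot_mu[:, PROTEIN_MARKERS.index("CD20")] = 1.0
    is_cd4 = compartments == "CD4"
    prot_mu[:, PROTEIN_MARKERS.index("CD4")] = np.where(is_cd4, 70.0, 1.5)
    prot_mu[:, PROTEIN_MARKERS.index("CD8")] = np.where(is_cd4, 1.5, 70.0)
    protein = _nb_draw(rng, prot_mu, 0.3).astype(np.int64)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"fraction": np.repeat("CD45pos", n), "true_cluster": clusters,
             "true_compartment": compartments},
            index=pd.Index(cell_ids, name="cell_id"),
        ),
        var=pd.DataFrame({"mito": mito_flag}, index=pd.Index(genes, name="gene_id")),
    )
    adata.obsm["protein"] = pd.DataFrame(
        protein, index=adata.obs_names, columns=list(PROTEIN_MARKERS)
    )

    # clonotypes: per compartment a clone pool; each cluster draws clone
    # assignments Dirichlet-multinomially with its own concentration. The
    # per-cluster Dirichlet weights are built from shared uniform variates
    # through the Gamma quantile function (a copula), so each cluster's
    # marginal is exactly symmetric-Dirichlet while the dominant (expanded)
    # clones coincide across clusters of a compartment — emulating
    # antigen-driven expansions that span phenotypic states.
    from scipy import stats as sp_stats

    clone_id = np.full(n, -1, dtype=np.int64)
    clone_offset = 0
    for comp in ("CD4", "CD8"):
        comp_mask = compartments == comp
        pool = int(comp_mask.sum())
        if pool == 0:
            continue
        u = rng.random(pool)
        for k, c in enumerate(config.cluster_spec):
            if c.compartment != comp:
                continue
            rows = np.where(cluster_idx == k)[0]
            if rows.size == 0:
                continue
            g = sp_stats.gamma.ppf(u, a=c.clone_concentration)
            total = g.sum()
            if not np.isfinite(total) or total <= 0:
                weights = np.zeros(pool)
                weights[np.argmax(u)] = 1.0  # degenerate: one dominant clone
            else:
                weights = g / total
            clone_id[rows] = clone_offset + rng.choice(pool, size=rows.size,
                                                       p=weights)
        clone_offset += pool

    recs: list[tuple[str, str, str]] = []
    drop = rng.random(n) < config.chain_missing_rate
    extra = rng.random(n) < config.chain_multiple_rate
    drop_locus = rng.random(n) < 0.5
    for i in range(n):
        tra = _cdr3("A", int(clone_id[i]))
        trb = _cdr3("B", int(clone_id[i]))
        if drop[i]:
            recs.append((cell_ids[i], "TRA" if drop_locus[i] else "TRB",
                         tra if drop_locus[i] else trb))
            continue
        recs.append((cell_ids[i], "TRA", tra))
        recs.append((cell_ids[i], "TRB", trb))
        if extra[i]:
            recs.append((cell_ids[i], "TRB", trb + "X"))
    records = pd.DataFrame(recs, columns=["cell_id", "locus", "junction_aa"])

    truth = pd.DataFrame(
        {"cell_id": cell_ids, "cluster": clusters, "compartment": compartments,
         "cytotoxic": cytotoxic, "clone_id": clone_id}
    )
    return adata, records, truth


@dataclass
class Cohort:
    """Bulk cohort: log10 expression, clinical covariates, and planted truth."""

    expr: pd.DataFrame          # patients x genes, log10-transformed expression
    clinical: pd.DataFrame      # patient_id, tmb, pdl1_tps, time_days, event
    truth: dict


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a bulk cohort with Weibull TTP driven by the planted betas.

    The log-hazard is ``beta_cs * CS + beta_tmb * 1[TMB >= 10]`` where CS is
    the standardized cytotoxic score as the downstream pipeline computes it
    (mean over the 25 genes of log10 expression, then z-scored). Censoring is
    independent exponential, with the rate matched to ``censor_rate``.
    """
    config.validate()
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(n)]

    latent = rng.normal(size=n)
    genes = list(CYTOTOXIC_GENES) + [f"BULK{i:04d}" for i in range(25)]
    mu_g = rng.uniform(1.0, 3.0, size=len(genes))
    expr = mu_g[None, :] + rng.normal(scale=0.15, size=(n, len(genes)))
    loading = np.zeros(len(genes))
    loading[: len(CYTOTOXIC_GENES)] = 0.3
    expr = expr + latent[:, None] * loading[None, :]
    expr = pd.DataFrame(expr, index=pd.Index(ids, name="patient_id"), columns=genes)

    cs_raw = expr[list(CYTOTOXIC_GENES)].mean(axis=1).to_numpy()
    cs = (cs_raw - cs_raw.mean()) / cs_raw.std(ddof=1)

    tmb = rng.lognormal(mean=np.log(config.tmb_log_median),
                        sigma=config.tmb_log_sigma, size=n)
    tmb_high = (tmb >= 10.0).astype(float)

    eta = config.beta_cs * cs + config.beta_tmb * tmb_high
    u = rng.uniform(size=n)
    t_event = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)

    if config.censor_rate > 0:
        # exponential censoring, rate set so the expected censored fraction
        # approximately equals censor_rate (exact for exponential event times)
        rate = config.censor_rate / (1.0 - config.censor_rate) / t_event.mean()
        t_cens = rng.exponential(1.0 / rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    pdl1_kind = rng.choice(3, size=n, p=(0.40, 0.35, 0.25))
    tps = np.where(pdl1_kind == 0, rng.uniform(0, 1, n),
                   np.where(pdl1_kind == 1, rng.uniform(1, 50, n),
                            rng.uniform(50, 100, n)))

    clinical = pd.DataFrame(
        {"patient_id": ids, "tmb": tmb, "pdl1_tps": tps,
         "time_days": time, "event": event}
    )
    truth = {"beta_cs": config.beta_cs, "beta_tmb": config.beta_tmb,
             "latent": latent, "cytotoxic_score_std": cs, "tmb_high": tmb_high}
    return Cohort(expr=expr, clinical=clinical, truth=truth)


def generate_hla_profiles(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient HLA-I allele read counts with planted clonal losses.

    Returns (profiles, truth): profiles has one row per patient x locus with
    allele genotypes, allele-specific read counts, purity and flanking copy
    state; truth flags the loci carrying a planted loss.
    """
    config.validate()
    rng = _rng(config, _STREAM_HLA)
    alleles = {
        "A": ["A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02"],
        "B": ["B*07:02", "B*08:01", "B*35:01", "B*44:02", "B*51:01"],
        "C": ["C*04:01", "C*05:01", "C*07:01", "C*07:02", "C*12:03"],
    }
    rows, truth_rows = [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        purity = rng.uniform(*config.purity_range)
        for locus in ("A", "B", "C"):
            pool = alleles[locus]
            if rng.random() < config.homozygosity_rate:
                a1 = a2 = pool[rng.integers(len(pool))]
            else:
                a1, a2 = rng.choice(len(pool), size=2, replace=False)
                a1, a2 = pool[a1], pool[a2]
            depth = int(rng.poisson(config.depth_mean))
            het = a1 != a2
            loss = bool(het and rng.random() < config.loh_fraction)
            if het:
                f_minor = (expected_loss_fraction(purity, config.flanking_total_copies)
                           if loss else 0.5)
                reads_minor = int(rng.binomial(depth, f_minor))
                reads_1, reads_2 = depth - reads_minor, reads_minor
            else:
                reads_1, reads_2 = depth, 0
            rows.append((pid, locus, a1, a2, reads_1, reads_2, purity,
                         config.flanking_total_copies))
            truth_rows.append((pid, locus, het, loss))
    profiles = pd.DataFrame(rows, columns=[
        "patient_id", "locus", "allele_1", "allele_2", "reads_1", "reads_2",
        "purity", "flanking_total_copies"])
    truth = pd.DataFrame(truth_rows,
                         columns=["patient_id", "locus", "heterozygous", "loss"])
    return profiles, truth


def generate_variant_table(config: SimConfig) -> tuple[pd.DataFrame, int]:
    """Somatic variant table spanning the TMB filter thresholds.

    Returns (variants, n_passing) where ``n_passing`` is the ground-truth
    count of variants that satisfy the panel TMB filters (somatic, coding,
    non-silent consequence, depth > 100x, allele fraction > 5%).
    """
    config.validate()
    rng = _rng(config, _STREAM_VARIANTS)
    n = config.n_variants
    consequences = rng.choice(
        ["missense", "indel", "stop_loss", "silent", "splice", "other"],
        size=n, p=[0.45, 0.10, 0.05, 0.20, 0.12, 0.08])
    depth = rng.integers(20, 400, size=n)
    af = rng.uniform(0.01, 0.6, size=n)
    somatic = rng.random(n) < 0.9
    coding = rng.random(n) < 0.9
    variants = pd.DataFrame({
        "variant_id": [f"var{i:04d}" for i in range(n)],
        "consequence": consequences,
        "coding_flag": coding,
        "somatic_flag": somatic,
        "depth": depth,
        "allele_fraction": af,
        "assay": "panel",
        "panel_size_mb": config.panel_size_mb,
    })
    passing = (somatic & coding
               & np.isin(consequences, ["missense", "indel", "stop_loss"])
               & (depth > 100) & (af > 0.05))
    return variants, int(passing.sum())


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
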