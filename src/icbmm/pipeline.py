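"""End-to-end orchestration: simulate -> single-cell/TCR -> genomic features
-> multimodal model -> survival reports, with a reproducibility manifest.

A run is described by a :class:`RunConfig` (YAML or JSON on disk). Stages
execute in dependency order; each writes plain-text outputs under the run
directory and the manifest records the package version, seed, a hash of the
resolved configuration, and a SHA-256 checksum of every output file, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as icb_io
from .cohort_model import CYTOTOXIC_GENES, cytotoxic_score, mm_stratify_report, mm_train
from .genomic_features import binarize_tmb, call_hla_loh, compute_tmb, hla_homozygosity
from .sc_pipeline import (derive_signature, differential_expression,
                          gate_t_compartments, normalize_protein_clr,
                          normalize_rna, qc_filter_cells)
from .synthetic_data import (SimConfig, generate_cohort, generate_hla_profiles,
                             generate_sc_dataset, generate_variant_table)
from .tcr_repertoire import (call_clonotypes, clone_sharing_graph,
                             expansion_stats, hutcheson_t_test)

logger = logging.getLogger("icbmm")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "sc-score", "tcr", "tmb", "hla-loh", "mm-train", "survival")


@dataclass
class RunConfig:
    """Resolved run configuration with every threshold surfaced by name."""

    outdir: str = "icbmm_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation conditions
    n_cells: int = 3000
    n_genes: int = 1000
    n_patients: int = 123
    # QC thresholds
    min_genes: int = 200
    max_genes: int = 2500
    mito_max_immune: float = 0.06
    mito_max_tumor: float = 0.20
    min_cells_per_gene: int = 3
    # signatures / DE
    top_k: int = 25
    # TCR
    prune_quantile_cd4: float = 1.0 / 3.0
    prune_quantile_cd8: float = 0.25
    # genomics
    tmb_cutoff: float = 10.0
    loh_alpha: float = 0.01
    loh_min_depth: int = 30
    # multimodal model
    n_shuffles: int = 100
    train_frac: float = 0.75
    ridge_alpha: float = 1.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        for q in (self.prune_quantile_cd4, self.prune_quantile_cd8):
            if not (0 <= q < 1):
                raise ValueError("prune quantiles must be in [0, 1)")


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.stages)
    sim = SimConfig(seed=cfg.seed, n_cells=cfg.n_cells, n_genes=cfg.n_genes,
                    n_patients=cfg.n_patients)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config_hash": _config_hash(cfg), "stages": {}, "outputs": {}}

    def _record(stage: str, *paths: Path):
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]

    # ---- simulate -------------------------------------------------------
    if "simulate" in stages:
        logger.info("stage simulate: seed=%d", cfg.seed)
        adata, records, truth = generate_sc_dataset(sim)
        cohort = generate_cohort(sim)
        profiles, hla_truth = generate_hla_profiles(sim)
        variants, n_passing = generate_variant_table(sim)
        sc_dir = out / "sc"
        icb_io.write_sc_dataset(adata, sc_dir)
        icb_io.write_airr(records, out / "clonotypes.tsv")
        truth.to_csv(out / "truth_cells.csv", index=False)
        cohort.expr.to_csv(out / "bulk_expression.csv")
        icb_io.write_table(cohort.clinical, out / "cohort.csv")
        icb_io.write_table(profiles, out / "hla_profiles.csv")
        icb_io.write_table(variants, out / "variants.csv")
        icb_io.write_json({"beta_cs": cohort.truth["beta_cs"],
                           "beta_tmb": cohort.truth["beta_tmb"],
                           "n_passing_variants": n_passing,
                           "hla_loss_loci": int(hla_truth["loss"].sum())},
                          out / "truth.json")
        _record("simulate", sc_dir / "matrix.mtx", out / "clonotypes.tsv",
                out / "bulk_expression.csv", out / "cohort.csv",
                out / "hla_profiles.csv", out / "variants.csv", out / "truth.json")

    # ---- sc-score -------------------------------------------------------
    truth_path = out / "truth_cells.csv"
    if "sc-score" in stages:
        if not (out / "sc" / "matrix.mtx").exists():
            raise FileNotFoundError("sc-score needs simulate output: sc/matrix.mtx")
        adata = icb_io.read_sc_dataset(out / "sc")
        adata = qc_filter_cells(adata, min_genes=cfg.min_genes,
                                max_genes=cfg.max_genes,
                                mito_max_immune=cfg.mito_max_immune,
                                mito_max_tumor=cfg.mito_max_tumor,
                                min_cells_per_gene=cfg.min_cells_per_gene)
        logger.info("QC report: %s", adata.uns["qc_report"])
        adata = normalize_rna(adata)
        clr = normalize_protein_clr(adata.obsm["protein"])
        adata = gate_t_compartments(adata, clr)
        # cluster labels: planted truth by default (a Leiden backend is
        # available via sc_pipeline.cluster_cells for label-free runs)
        adata.obs["cluster"] = adata.obs["true_cluster"]
        sigs = {}
        de_frames = []
        for comp in ("CD4", "CD8"):
            mask = adata.obs["compartment"] == comp
            sub = adata[mask]
            labels = sub.obs["cluster"].to_numpy()
            if len(np.unique(labels)) < 2:
                continue
            for clus in np.unique(labels):
                de = differential_expression(
                    pd.DataFrame(np.asarray(sub.X), index=sub.obs_names,
                                 columns=sub.var_names), labels, clus)
                de_frames.append(de.assign(cluster=clus, compartment=comp))
                sig = derive_signature(de, k=cfg.top_k)
                sigs[clus] = list(sig.genes)
        pd.concat(de_frames).to_csv(out / "de_results.tsv", sep="\t")
        icb_io.write_json(sigs, out / "signatures.json")
        adata.obs.reset_index().to_csv(out / "cells_processed.tsv", sep="\t",
                                       index=False)
        _record("sc-score", out / "de_results.tsv", out / "signatures.json",
                out / "cells_processed.tsv")

    # ---- tcr ------------------------------------------------------------
    if "tcr" in stages:
        if not (out / "clonotypes.tsv").exists():
            raise FileNotFoundError("tcr needs simulate output: clonotypes.tsv")
        records = icb_io.read_airr(out / "clonotypes.tsv")
        table = call_clonotypes(records)
        truth = pd.read_csv(truth_path)
        table = table.merge(truth[["cell_id", "cluster", "compartment", "cytotoxic"]],
                            on="cell_id", how="left")
        table = table.rename(columns={"cluster": "cluster_label"})
        stats_rows = []
        graphs = {}
        for comp, q in (("CD4", cfg.prune_quantile_cd4),
                        ("CD8", cfg.prune_quantile_cd8)):
            sub = table[table["compartment"] == comp].copy()
            if sub.empty:
                continue
            st = expansion_stats(sub, group_col="cluster_label")
            st["compartment"] = comp
            stats_rows.append(st)
            g = clone_sharing_graph(sub, prune_quantile=q)
            graphs[comp] = {"nodes": list(g.nodes),
                            "edges": [{"source": a, "target": b,
                                       "weight_percent": d["weight"]}
                                      for a, b, d in g.edges(data=True)],
                            "pruning_rule": g.graph["pruning_rule"]}
            cyto = sub[sub["cytotoxic"] == True]  # noqa: E712
            noncyto = sub[sub["cytotoxic"] == False]  # noqa: E712
            if not cyto.empty and not noncyto.empty:
                t, df_, p = hutcheson_t_test(
                    cyto.groupby(["tra_cdr3", "trb_cdr3"]).size().to_numpy(),
                    noncyto.groupby(["tra_cdr3", "trb_cdr3"]).size().to_numpy())
                graphs[comp]["entropy_test"] = {"t": t, "df": df_, "p": p}
        stats = pd.concat(stats_rows)
        stats["clone_size_histogram"] = stats["clone_size_histogram"].map(
            lambda h: json.dumps({int(k): int(v) for k, v in sorted(h.items())}))
        stats.to_csv(out / "tcr_stats.tsv", sep="\t")
        icb_io.write_json(graphs, out / "clone_graphs.json")
        _record("tcr", out / "tcr_stats.tsv", out / "clone_graphs.json")

    # ---- tmb ------------------------------------------------------------
    if "tmb" in stages:
        if not (out / "variants.csv").exists():
            raise FileNotFoundError("tmb needs simulate output: variants.csv")
        variants = icb_io.read_variant_table(out / "variants.csv")
        tmb = compute_tmb(variants)
        icb_io.write_json({"tmb": tmb, "status": binarize_tmb(tmb, cfg.tmb_cutoff),
                           "cutoff": cfg.tmb_cutoff}, out / "tmb.json")
        _record("tmb", out / "tmb.json")

    # ---- hla-loh --------------------------------------------------------
    if "hla-loh" in stages:
        if not (out / "hla_profiles.csv").exists():
            raise FileNotFoundError("hla-loh needs simulate output: hla_profiles.csv")
        profiles = icb_io.read_hla_profiles(out / "hla_profiles.csv")
        calls, flags = call_hla_loh(profiles, alpha=cfg.loh_alpha,
                                    min_depth=cfg.loh_min_depth)
        homo = hla_homozygosity(profiles)
        calls.to_csv(out / "hla_loh_calls.csv", index=False)
        pd.DataFrame({"hla_loh": flags, "hla_homozygous": homo}).to_csv(
            out / "hla_patient_flags.csv")
        _record("hla-loh", out / "hla_loh_calls.csv", out / "hla_patient_flags.csv")

    # ---- mm-train -------------------------------------------------------
    if "mm-train" in stages:
        if not (out / "cohort.csv").exists():
            raise FileNotFoundError("mm-train needs simulate output: cohort.csv")
        clinical = icb_io.read_cohort_clinical(out / "cohort.csv")
        expr = icb_io.read_bulk_expression(out / "bulk_expression.csv")
        cs = cytotoxic_score(expr)
        tmb_high = (clinical["tmb"].to_numpy() >= cfg.tmb_cutoff).astype(float)
        features = pd.DataFrame({"cytotoxic_score": cs.to_numpy(),
                                 "tmb_high": tmb_high},
                                index=clinical["patient_id"])
        mm = mm_train(features, clinical["time_days"], clinical["event"],
                      n_shuffles=cfg.n_shuffles, train_frac=cfg.train_frac,
                      ridge_alpha=cfg.ridge_alpha, seed=cfg.seed)
        mm.scores.to_csv(out / "mm_scores.csv")
        mm.shuffle_coefficients.to_csv(out / "mm_shuffle_coefficients.csv",
                                       index=False)
        icb_io.write_json({"median_cutoff": mm.median_cutoff,
                           "n_shuffles": mm.n_shuffles, "seed": mm.seed},
                          out / "mm_meta.json")
        _record("mm-train", out / "mm_scores.csv",
                out / "mm_shuffle_coefficients.csv", out / "mm_meta.json")

    # ---- survival -------------------------------------------------------
    if "survival" in stages:
        for need in ("mm_scores.csv", "cohort.csv"):
            if not (out / need).exists():
                raise FileNotFoundError(f"survival needs upstream output: {need}")
        clinical = icb_io.read_cohort_clinical(out / "cohort.csv")
        scores = pd.read_csv(out / "mm_scores.csv", index_col=0)
        meta = icb_io.read_json(out / "mm_meta.json")
        from .cohort_model import MMResult
        mm = MMResult(scores=scores, median_cutoff=meta["median_cutoff"],
                      shuffle_coefficients=pd.read_csv(
                          out / "mm_shuffle_coefficients.csv"),
                      seed=meta["seed"], n_shuffles=meta["n_shuffles"])
        subgroups = None
        flags_path = out / "hla_patient_flags.csv"
        if flags_path.exists():
            flags = pd.read_csv(flags_path, index_col=0)
            loh = flags["hla_loh"].reindex(clinical["patient_id"])
            mask = loh.fillna(False).astype(bool).to_numpy()
            if mask.sum() >= 4:
                subgroups = {"hla_loh": mask}
        report = mm_stratify_report(mm, clinical["time_days"], clinical["event"],
                                    subgroups=subgroups)
        icb_io.write_json(report, out / "survival_report.json")
        _record("survival", out / "survival_report.json")

    for stage, files in manifest["stages"].items():
        for f in files:
            manifest["outputs"][f] = _sha256(out / f)
    icb_io.write_json(manifest, out / "manifest.json")
    return manifest
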