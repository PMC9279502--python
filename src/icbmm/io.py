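"""Standard-format readers and writers for every pipeline input and output.

Counts travel as Matrix Market (MTX) with barcodes/features TSV sidecars,
surface-protein counts as TSV, clonotype chains as AIRR-style TSV, and the
variant / HLA-profile / cohort tables as CSV with documented headers. All
readers validate schemas up front and report the offending column or line;
all round-trips are exact for integer counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "write_sc_dataset", "read_sc_dataset",
    "write_airr", "read_airr",
    "write_table", "read_variant_table", "read_hla_profiles",
    "read_cohort_clinical", "read_bulk_expression",
    "write_json", "read_json",
]

AIRR_COLUMNS = ["cell_id", "locus", "junction_aa"]
VARIANT_COLUMNS = ["variant_id", "consequence", "coding_flag", "somatic_flag",
                   "depth", "allele_fraction", "assay", "panel_size_mb"]
HLA_COLUMNS = ["patient_id", "locus", "allele_1", "allele_2", "reads_1",
               "reads_2", "purity", "flanking_total_copies"]
CLINICAL_COLUMNS = ["patient_id", "tmb", "pdl1_tps", "time_days", "event"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def write_sc_dataset(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv (+ protein.tsv).

    The matrix is written genes x cells, the conventional orientation for
    single-cell MTX exports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(int))
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    feats = pd.DataFrame({"gene_id": adata.var_names,
                          "mito": adata.var["mito"].astype(int)})
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    if "protein" in adata.obsm:
        prot = adata.obsm["protein"]
        if not isinstance(prot, pd.DataFrame):
            prot = pd.DataFrame(prot, index=adata.obs_names)
        prot.to_csv(outdir / "protein.tsv", sep="\t")


def read_sc_dataset(outdir: str | Path) -> ad.AnnData:
    """Read a dataset written by :func:`write_sc_dataset`."""
    outdir = Path(outdir)
    X = scipy_io.mmread(str(outdir / "matrix.mtx")).T.tocsr()
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    feats = pd.read_csv(outdir / "features.tsv", sep="\t", header=None,
                        names=["gene_id", "mito"])
    obs = pd.read_csv(outdir / "cells.tsv", sep="\t").set_index("cell_id")
    obs = obs.loc[barcodes]
    adata = ad.AnnData(
        X=np.asarray(X.todense(), dtype=np.int64),
        obs=obs,
        var=pd.DataFrame({"mito": feats["mito"].astype(bool).to_numpy()},
                         index=pd.Index(feats["gene_id"], name="gene_id")),
    )
    protein_path = outdir / "protein.tsv"
    if protein_path.exists():
        prot = pd.read_csv(protein_path, sep="\t", index_col=0)
        adata.obsm["protein"] = prot.loc[adata.obs_names]
    return adata


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    _require_columns(records, AIRR_COLUMNS, "AIRR records")
    records[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: line 1: missing AIRR columns {missing}")
    bad_locus = ~df["locus"].isin(["TRA", "TRB"])
    if bad_locus.any():
        # +2: header line plus 1-based numbering
        line = int(np.where(bad_locus)[0][0]) + 2
        raise ValueError(f"{path}: line {line}: locus must be TRA or TRB")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, VARIANT_COLUMNS, str(path))
    if (df["allele_fraction"] < 0).any() or (df["allele_fraction"] > 1).any():
        raise ValueError(f"{path}: allele_fraction outside [0, 1]")
    if (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth")
    return df


def read_hla_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HLA_COLUMNS, str(path))
    if ((df["purity"] < 0) | (df["purity"] > 1)).any():
        raise ValueError(f"{path}: purity outside [0, 1]")
    if ((df["reads_1"] < 0) | (df["reads_2"] < 0)).any():
        raise ValueError(f"{path}: negative read counts")
    return df


def read_cohort_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CLINICAL_COLUMNS, str(path))
    bad = df["time_days"] <= 0
    if bad.any():
        line = int(np.where(bad)[0][0]) + 2
        raise ValueError(f"{path}: line {line}: time_days must be > 0")
    if ~df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df


def read_bulk_expression(path: str | Path) -> pd.DataFrame:
    """Patients x genes log10 expression CSV with a patient_id index column."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate patient ids")
    return df


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
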