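"""Tumor-intrinsic features: TMB, HLA-LOH calls, HLA homozygosity, PD-L1 TPS.

TMB counts somatic, coding, non-silent variants (missense, indel, stop-loss)
passing assay-specific strict thresholds — coverage >100x and allele
fraction >5% for targeted panels, >30x and >10% for whole exome — divided by
the assayed megabase size. TMB is binarized at >=10 mut/Mb.

HLA loss of heterozygosity is called per heterozygous class-I locus from
allele-specific read counts. Under a clonal one-copy loss with tumor purity
p and expected flanking total copy number C, the lost (minor) allele's
expected read fraction is

    f_loss = (1 - p) / ((1 - p) * 2 + p * (C - 1))

(1/3 at p = 0.5 with diploid flanks), against f_het = 0.5 under no loss. A
locus is called LOH when a one-sided binomial test rejects f = 0.5 toward
the minor allele at level alpha AND the observed minor fraction is closer to
f_loss than to f_het; subclonal imbalance therefore reads as no-LOH, with a
continuous loss-fraction estimate emitted for diagnostics only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expected_loss_fraction",
    "compute_tmb",
    "binarize_tmb",
    "call_hla_loh",
    "hla_homozygosity",
    "categorize_pdl1",
]

TMB_CUTOFF = 10.0
NONSYNONYMOUS = ("missense", "indel", "stop_loss")
_FILTERS = {"panel": (100, 0.05), "wes": (30, 0.10)}


def expected_loss_fraction(purity: float, flanking_total_copies: int) -> float:
    """Expected minor-allele read fraction under a clonal one-copy loss.

    Normal cells contribute one copy of each allele; tumor cells (fraction
    ``purity``) retain ``flanking_total_copies - 1`` copies, all of the kept
    allele. ``purity=0.5`` with diploid flanks gives 1/3.
    """
    p = purity
    c = flanking_total_copies
    denom = (1 - p) * 2 + p * (c - 1)
    if denom <= 0:
        return 0.0
    return (1 - p) * 1.0 / denom


def compute_tmb(variants: pd.DataFrame, panel_size_mb: float | None = None) -> float:
    """Tumor mutational burden in mutations per megabase.

    ``variants`` needs columns consequence, coding_flag, somatic_flag, depth,
    allele_fraction, assay; panel_size_mb may be a column or passed
    explicitly. All variants must come from a single assay.
    """
    assays = pd.unique(variants["assay"])
    if len(assays) > 1:
        raise ValueError(f"mixed assays in one table: {sorted(assays)}")
    assay = str(assays[0])
    if assay not in _FILTERS:
        raise ValueError(f"unknown assay {assay!r}; expected panel or wes")
    if panel_size_mb is None:
        if "panel_size_mb" not in variants.columns:
            raise ValueError("panel_size_mb not provided")
        sizes = pd.unique(variants["panel_size_mb"])
        if len(sizes) != 1:
            raise ValueError("ambiguous panel_size_mb column")
        panel_size_mb = float(sizes[0])
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be > 0")
    min_depth, min_af = _FILTERS[assay]
    passing = (
        variants["somatic_flag"].astype(bool)
        & variants["coding_flag"].astype(bool)
        & variants["consequence"].isin(NONSYNONYMOUS)
        & (variants["depth"] > min_depth)           # strict >
        & (variants["allele_fraction"] > min_af)    # strict >
    )
    return float(passing.sum() / panel_size_mb)


def binarize_tmb(tmb: float, cutoff: float = TMB_CUTOFF) -> str:
    """'high' iff tmb >= cutoff (default 10 mut/Mb), else 'low'."""
    if tmb < 0:
        raise ValueError("TMB cannot be negative")
    return "high" if tmb >= cutoff else "low"


def _loss_fraction_estimate(f_obs: float, purity: float, copies: int) -> float:
    """Fraction of tumor cells with a one-copy loss implied by f_obs.

    Solves the two-population mixture (normal diploid het + tumor with a
    fraction l of cells having lost one copy of the minor allele) for l,
    clipped to [0, 1]; diagnostic only.
    """
    p, c = purity, copies
    if p == 0:
        return float("nan")
    # minor copies: (1-p) + p*(1-l); total: 2(1-p) + p*(c - l) with c total copies
    # f = ((1-p) + p(1-l)) / (2(1-p) + p(c - l)); solve for l
    denom_l = p * (1 - f_obs)
    if denom_l == 0:
        return float("nan")
    l = ((1 - p) + p - f_obs * (2 * (1 - p) + p * c)) / denom_l
    return float(np.clip(l, 0.0, 1.0))


def call_hla_loh(profiles: pd.DataFrame, alpha: float = 0.01,
                 min_depth: int = 30) -> tuple[pd.DataFrame, pd.Series]:
    """Call HLA-LOH per locus and flag patients with LOH at any locus.

    ``profiles`` has one row per patient x locus with columns patient_id,
    locus, allele_1, allele_2, reads_1, reads_2, purity,
    flanking_total_copies.

    Returns (calls, patient_flag). Per-locus ``call`` is LOH / no-LOH /
    no-call: homozygous loci, loci below ``min_depth`` total reads, and
    purity-zero samples are no-call. ``patient_flag`` is True when any locus
    of the patient is called LOH, False when at least one locus was
    evaluable and none is LOH, and NA when no locus was evaluable.
    """
    rows = []
    for r in profiles.itertuples(index=False):
        total = int(r.reads_1 + r.reads_2)
        minor = int(min(r.reads_1, r.reads_2))
        f_obs = minor / total if total > 0 else float("nan")
        entry = {"patient_id": r.patient_id, "locus": r.locus,
                 "minor_fraction": f_obs, "depth": total,
                 "p_value": float("nan"), "loss_fraction_estimate": float("nan")}
        if r.allele_1 == r.allele_2:
            entry["call"] = "no-call"
            entry["reason"] = "homozygous"
        elif total < min_depth:
            entry["call"] = "no-call"
            entry["reason"] = "insufficient depth"
        elif r.purity <= 0:
            entry["call"] = "no-call"
            entry["reason"] = "no tumor signal"
        else:
            f_loss = expected_loss_fraction(r.purity, int(r.flanking_total_copies))
            pval = stats.binomtest(minor, total, 0.5, alternative="less").pvalue
            closer_to_loss = abs(f_obs - f_loss) < abs(f_obs - 0.5)
            entry["p_value"] = float(pval)
            entry["expected_loss_fraction"] = f_loss
            entry["loss_fraction_estimate"] = _loss_fraction_estimate(
                f_obs, r.purity, int(r.flanking_total_copies))
            entry["call"] = "LOH" if (pval < alpha and closer_to_loss) else "no-LOH"
            entry["reason"] = ""
        rows.append(entry)
    calls = pd.DataFrame(rows)

    def _flag(sub: pd.DataFrame):
        evaluable = sub[sub["call"] != "no-call"]
        if evaluable.empty:
            return pd.NA
        return bool((evaluable["call"] == "LOH").any())

    patient_flag = calls.groupby("patient_id", sort=True).apply(_flag,
                                                                include_groups=False)
    patient_flag.name = "hla_loh"
    return calls, patient_flag


def hla_homozygosity(profiles: pd.DataFrame) -> pd.Series:
    """True iff any of loci A/B/C is homozygous at 4-digit resolution.

    Patients missing any of the three loci are no-call (NA).
    """
    out = {}
    for pid, sub in profiles.groupby("patient_id", sort=True):
        loci = set(sub["locus"])
        if not {"A", "B", "C"} <= loci:
            out[pid] = pd.NA
            continue
        out[pid] = bool((sub["allele_1"] == sub["allele_2"]).any())
    s = pd.Series(out, name="hla_homozygous")
    s.index.name = "patient_id"
    return s


def categorize_pdl1(tps: float) -> str:
    """PD-L1 category from the tumor proportion score (percent).

    <1% negative, 1-49% low, >=50% high.
    """
    if not (0 <= tps <= 100):
        raise ValueError("TPS must be within [0, 100]")
    if tps < 1:
        return "negative"
    if tps < 50:
        return "low"
    return "high"
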