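"""Cytotoxic score on bulk expression and the multimodal (MM) risk score.

The cytotoxic score is the arithmetic mean, over a fixed 25-gene cytotoxic
T-cell program, of log10-transformed bulk RNA expression, z-scored across
the cohort before survival use.

The MM score integrates that tumor-extrinsic score with the tumor-intrinsic
binarized TMB status (>=10 mut/Mb): Cox proportional-hazards models with a
ridge penalty (alpha = 1) and Breslow tie handling are fit on repeated
random 75/25 shuffles of the cohort, each held-out patient is scored with
the fitted linear predictor (log relative hazard), per-patient scores are
averaged over out-of-fold appearances, and the cohort median splits
patients into high- and low-risk groups. Higher MM score means higher
predicted hazard, i.e. shorter expected time to progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxFit, fit_cox_breslow, km_estimate, logrank_test

__all__ = [
    "CYTOTOXIC_GENES",
    "MMResult",
    "cytotoxic_score",
    "mm_train",
    "mm_stratify_report",
]

# the fixed cytotoxic gene set: genes most up-regulated in cytotoxic CD4+ or
# CD8+ tumor-infiltrating T cells relative to non-cytotoxic T cells
CYTOTOXIC_GENES: tuple[str, ...] = (
    "NKG7", "CXCL13", "GZMH", "HAVCR2", "CCL5", "GZMK", "CCL4", "GZMA",
    "CCL3", "CST7", "CCL4L2", "ACP5", "TNFRSF9", "TIGIT", "GZMB", "PDCD1",
    "PRF1", "LYST", "SIRPG", "LAG3", "CARD16", "TUBA4A", "PTMS", "CD74",
    "KLRD1",
)
assert len(set(CYTOTOXIC_GENES)) == 25


def cytotoxic_score(bulk_expr: pd.DataFrame,
                    gene_set: tuple[str, ...] = CYTOTOXIC_GENES,
                    log_transform: bool = False,
                    standardize: bool = True) -> pd.Series:
    """Per-patient cytotoxic score from bulk expression (patients x genes).

    ``bulk_expr`` is expected to hold log10-transformed expression; pass
    ``log_transform=True`` to apply log10(1 + x) to raw normalized counts
    first. The score is the arithmetic mean over the gene set, z-scored
    across patients unless ``standardize=False``.
    """
    missing = [g for g in gene_set if g not in bulk_expr.columns]
    if missing:
        raise KeyError(f"cytotoxic genes missing from expression: {missing}")
    vals = bulk_expr[list(gene_set)].to_numpy(dtype=float)
    if log_transform:
        vals = np.log10(1.0 + vals)
    score = pd.Series(vals.mean(axis=1), index=bulk_expr.index,
                      name="cytotoxic_score")
    if standardize:
        sd = score.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero variance: cytotoxic score cannot be standardized")
        score = (score - score.mean()) / sd
    return score


@dataclass
class MMResult:
    """Out-of-fold MM scores, risk groups, and full resampling provenance."""

    scores: pd.DataFrame          # patient_id-indexed: mm_score, n_test_appearances, risk_group
    median_cutoff: float
    shuffle_coefficients: pd.DataFrame  # one row per shuffle: coefficients
    seed: int
    n_shuffles: int

    @property
    def risk_group(self) -> pd.Series:
        return self.scores["risk_group"]


def mm_train(features: pd.DataFrame, time, event, *, n_shuffles: int = 100,
             train_frac: float = 0.75, ridge_alpha: float = 1.0,
             seed: int = 0, max_redraws: int = 1000) -> MMResult:
    """Train the multimodal out-of-fold Cox ensemble score.

    Parameters
    ----------
    features : patients x covariates, typically the standardized cytotoxic
        score and the 0/1 TMB-high indicator. Used as provided.
    time, event : TTP days and progression indicator, aligned with rows.
    n_shuffles : number of random 75/25 cohort shuffles; each fits a
        ridge-penalized Breslow Cox model on the training fraction and scores
        the held-out patients with its linear predictor.
    seed : seeds a PCG64 generator; fixed seed gives identical results.

    Training folds with zero events are redrawn (counted in
    ``scores.attrs["n_redraws"]``); extra shuffles are drawn until every
    patient appears in at least one evaluation fold.
    """
    n = len(features)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if n < 8:
        raise ValueError("cohort too small: need >= 8 patients")
    if int(event.sum()) < 2:
        raise ValueError("need >= 2 events")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("degenerate train fraction for this cohort size")

    # fold assignment works on a canonical (index-sorted) patient ordering,
    # so the result is invariant to the row order of the input
    canon = np.argsort(features.index.to_numpy(), kind="stable")
    features = features.iloc[canon]
    time, event = time[canon], event[canon]
    inverse = np.empty(n, dtype=int)
    inverse[canon] = np.arange(n)

    sum_scores = np.zeros(n)
    n_appear = np.zeros(n, dtype=int)
    coef_rows = []
    n_redraws = 0
    shuffles_done = 0
    while shuffles_done < n_shuffles or (n_appear == 0).any():
        if shuffles_done >= n_shuffles + max_redraws:
            raise RuntimeError("could not cover every patient in evaluation folds")
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if event[train].sum() == 0:
            n_redraws += 1
            continue
        try:
            fit = fit_cox_breslow(features.iloc[train], time[train], event[train],
                                  ridge_alpha=ridge_alpha)
        except ValueError:
            n_redraws += 1  # e.g. a constant covariate in this fold
            continue
        lp = fit.linear_predictor(features.iloc[test])
        sum_scores[test] += lp
        n_appear[test] += 1
        coef_rows.append(fit.coefficients)
        shuffles_done += 1

    mm = sum_scores / n_appear
    median_cutoff = float(np.median(mm))
    # patients exactly at the median go to the high-risk group (>= convention)
    risk = np.where(mm >= median_cutoff, "high", "low")
    scores = pd.DataFrame(
        {"mm_score": mm, "n_test_appearances": n_appear, "risk_group": risk},
        index=features.index,
    ).iloc[inverse]  # back to the caller's row order
    scores.attrs["n_redraws"] = n_redraws
    return MMResult(
        scores=scores,
        median_cutoff=median_cutoff,
        shuffle_coefficients=pd.DataFrame(coef_rows).reset_index(drop=True),
        seed=seed,
        n_shuffles=shuffles_done,
    )


def _arm_report(time, event, group_high) -> dict:
    """KM curves, log-rank and Cox HR for high- vs low-risk arms."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group_high = np.asarray(group_high, dtype=int)
    out: dict = {"n": int(len(time)),
                 "n_high": int(group_high.sum()),
                 "n_low": int((1 - group_high).sum())}
    km_high, med_high = km_estimate(time[group_high == 1], event[group_high == 1])
    km_low, med_low = km_estimate(time[group_high == 0], event[group_high == 0])
    out["km"] = {"high": km_high, "low": km_low}
    out["median_ttp"] = {"high": med_high, "low": med_low}
    chi2, df, p = logrank_test(time, event, group_high)
    out["logrank"] = {"chi2": chi2, "df": df, "p": p}
    fit = fit_cox_breslow(pd.DataFrame({"high_risk": group_high}), time, event,
                          ridge_alpha=0.0)
    hr = fit.hazard_ratios.loc["high_risk"]
    out["cox"] = {"hr": float(hr["hr"]), "ci_low": float(hr["hr_ci_low"]),
                  "ci_high": float(hr["hr_ci_high"]), "p": float(hr["p"]),
                  "coef": float(hr["coef"])}
    return out


def mm_stratify_report(mm: MMResult, time, event,
                       subgroups: dict[str, np.ndarray] | None = None) -> dict:
    """Survival stratification by MM risk group, cohort-wide and in subgroups.

    Subgroup analyses (e.g. the HLA-LOH subcohort) reuse the cohort-level
    median cutoff — groups are not re-binarized within a subgroup. Subgroups
    with fewer than 2 patients in either arm are suppressed with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = (mm.risk_group == "high").to_numpy().astype(int)
    report = {"median_cutoff": mm.median_cutoff,
              "full_cohort": _arm_report(time, event, high),
              "subgroups": {}}
    for name, mask in (subgroups or {}).items():
        mask = np.asarray(mask, dtype=bool)
        h = high[mask]
        if h.sum() < 2 or (1 - h).sum() < 2:
            warnings.warn(f"subgroup {name!r}: fewer than 2 patients per arm; "
                          "report suppressed")
            report["subgroups"][name] = {"suppressed": True,
                                         "n_high": int(h.sum()),
                                         "n_low": int((1 - h).sum())}
            continue
        report["subgroups"][name] = _arm_report(time[mask], event[mask], h)
    return report
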