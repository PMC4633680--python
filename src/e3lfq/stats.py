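"""Quantifiability filters and per-protein two-sample testing.

The candidate-calling rules follow the volcano convention of the emulated
study: a protein must be quantified by at least two peptides, have
quantitative data in every run, show |log2 fold change| above 0.85
(2**0.85 ≈ 1.80, i.e. the "over 1.8-fold" rule) and a two-sided
Welch t-test p-value below 0.05 on log2 abundances.  No multiple-testing
correction enters the calling; a Benjamini–Hochberg column is emitted for
information only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import KO, WT, ProteinQuantTable, StudyDesign, ValidationError

logger = logging.getLogger(__name__)

#: p-value reported when group means differ but both variances are zero
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class Thresholds:
    """Volcano cutoffs and quantifiability filters."""

    log2fc_cutoff: float = 0.85
    p_cutoff: float = 0.05
    min_peptides: int = 2
    require_complete: bool = True

    def __post_init__(self) -> None:
        if self.log2fc_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValidationError("cutoffs must be positive")
        if self.min_peptides < 1:
            raise ValidationError("min_peptides must be >= 1")


def filter_quantifiable(
    table: ProteinQuantTable,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
) -> ProteinQuantTable:
    """Retain proteins with >= ``min_peptides`` peptides and (when
    ``require_complete``) an abundance in every run; log exclusions."""
    missing_runs = set(design.run_ids) - set(table.run_ids)
    if missing_runs:
        raise ValidationError(f"table lacks design runs: {sorted(missing_runs)}")
    keep = table.n_peptides >= thresholds.min_peptides
    for pid in table.n_peptides.index[~keep]:
        logger.info("excluded %s: %d peptide(s) < %d",
                    pid, table.n_peptides[pid], thresholds.min_peptides)
    if thresholds.require_complete:
        complete = table.abundances[design.run_ids].notna().all(axis=1)
        for pid in complete.index[keep & ~complete]:
            logger.info("excluded %s: missing abundance in >=1 run", pid)
        keep &= complete
    return table.subset(list(table.abundances.index[keep]))


def two_sample_test(
    values_ko, values_wt, flavor: str = "welch"
) -> tuple[float, float]:
    """Two-sided test of KO vs WT abundances, on the log2 scale.

    Default is Welch's unequal-variance t-test; ``flavor="mannwhitney"``
    switches to the exact Mann-Whitney U.  Degenerate zero-variance
    groups: equal means give (t=0, p=1); unequal means with zero variance
    in both groups give a signed infinite statistic and the smallest
    positive p (the measurement is then noiseless).
    """
    ko = np.asarray(values_ko, dtype=float)
    wt = np.asarray(values_wt, dtype=float)
    if len(ko) < 2 or len(wt) < 2:
        raise ValidationError("need >= 2 values per group")
    if np.any(ko <= 0) or np.any(wt <= 0):
        raise ValidationError("abundances must be strictly positive")
    lko, lwt = np.log2(ko), np.log2(wt)

    if flavor == "mannwhitney":
        res = sps.mannwhitneyu(lko, lwt, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if flavor not in ("welch", "student"):
        raise ValidationError(f"unknown test flavor {flavor!r}")

    if np.var(lko) == 0.0 and np.var(lwt) == 0.0:
        if lko.mean() == lwt.mean():
            return 0.0, 1.0
        return float(np.sign(lko.mean() - lwt.mean()) * np.inf), P_FLOOR
    t, p = sps.ttest_ind(lko, lwt, equal_var=(flavor == "student"))
    return float(t), float(max(p, P_FLOOR))


def estimate_log2_fc(
    table: ProteinQuantTable, design: StudyDesign, protein_id: str
) -> float:
    """Point estimate of one protein's KO-over-WT log2 fold change from a
    quantitation table: mean log2 abundance over the observed KO runs minus
    the same over the observed WT runs.  Equals the differential table's
    ``log2_fc`` whenever the protein has complete data; still defined when
    a run's abundance is missing (it is simply left out of the mean)."""
    row = table.abundances.loc[protein_id]
    with np.errstate(all="ignore"):
        ko = np.log2(row[design.runs_for(KO)].to_numpy(dtype=float))
        wt = np.log2(row[design.runs_for(WT)].to_numpy(dtype=float))
    if np.isnan(ko).all() or np.isnan(wt).all():
        raise ValidationError(f"{protein_id}: no abundance in one condition")
    return float(np.nanmean(ko) - np.nanmean(wt))


def build_differential_table(
    table: ProteinQuantTable,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
    flavor: str = "welch",
) -> pd.DataFrame:
    """One volcano row per protein of a filtered quantitation table.

    Columns: per-condition mean log2 abundance, ``log2_fc`` (KO − WT),
    test statistic, ``p_value``, informational BH ``q_value``, and the
    pass flags.  ``passes_fc`` ⇔ |log2_fc| > cutoff; ``passes_p`` ⇔
    p < cutoff; ``passes_filters`` re-states the quantifiability rules.
    """
    ko_runs = design.runs_for(KO)
    wt_runs = design.runs_for(WT)
    if not ko_runs or not wt_runs:
        raise ValidationError("design must contain both WT and KO runs")
    missing = set(ko_runs + wt_runs) - set(table.run_ids)
    if missing:
        raise ValidationError(f"table lacks design runs: {sorted(missing)}")

    with np.errstate(all="ignore"):
        lko = np.log2(table.abundances[ko_runs].to_numpy(dtype=float))
        lwt = np.log2(table.abundances[wt_runs].to_numpy(dtype=float))
    complete = ~(np.isnan(lko).any(axis=1) | np.isnan(lwt).any(axis=1))

    mean_ko = np.where(complete, lko.mean(axis=1), np.nan)
    mean_wt = np.where(complete, lwt.mean(axis=1), np.nan)

    t = np.full(len(table.protein_ids), np.nan)
    p = np.full(len(table.protein_ids), np.nan)
    if complete.any():
        a, b = lko[complete], lwt[complete]
        if flavor == "mannwhitney":
            tc, pc = sps.mannwhitneyu(a, b, alternative="two-sided", axis=1)
        elif flavor in ("welch", "student"):
            with np.errstate(all="ignore"), warnings.catch_warnings():
                # near-constant groups trip scipy's precision warning; the
                # exact zero-variance cases are overridden below
                warnings.simplefilter("ignore", RuntimeWarning)
                tc, pc = sps.ttest_ind(a, b, axis=1, equal_var=(flavor == "student"))
            # zero-variance conventions (noiseless measurements)
            zv = (a.var(axis=1) == 0.0) & (b.var(axis=1) == 0.0)
            eq = zv & (a.mean(axis=1) == b.mean(axis=1))
            ne = zv & ~eq
            tc = np.asarray(tc, dtype=float)
            pc = np.asarray(pc, dtype=float)
            tc[eq], pc[eq] = 0.0, 1.0
            tc[ne] = np.sign(a.mean(axis=1) - b.mean(axis=1))[ne] * np.inf
            pc[ne] = P_FLOOR
        else:
            raise ValidationError(f"unknown test flavor {flavor!r}")
        t[complete] = tc
        p[complete] = np.maximum(pc, P_FLOOR)

    df = pd.DataFrame({
        "protein_id": table.protein_ids,
        "mean_log2_ko": mean_ko,
        "mean_log2_wt": mean_wt,
        "log2_fc": mean_ko - mean_wt,
        "t_statistic": t,
        "p_value": p,
        "_complete": complete,
    })
    df["q_value"] = np.nan
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "q_value"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["passes_fc"] = df["log2_fc"].abs() > thresholds.log2fc_cutoff
    df["passes_p"] = df["p_value"] < thresholds.p_cutoff
    n_pep = table.n_peptides.reindex(df["protein_id"]).to_numpy()
    df["n_peptides"] = n_pep
    df["passes_filters"] = (n_pep >= thresholds.min_peptides) & df["_complete"]
    df = df.drop(columns=["_complete"])
    df["branch"] = table.branch
    df.attrs["thresholds"] = thresholds
    df.attrs["branch"] = table.branch
    return df
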