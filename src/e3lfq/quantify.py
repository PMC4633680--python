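"""Peptide-to-protein roll-up: Top-3 PAI and pairwise-ratio LFQ branches.

Two independent estimators turn a (normalized) ion matrix into protein
abundance profiles, mirroring the common practice of cross-checking a
quantification with two algorithms:

* :class:`Top3Quantifier` — the protein abundance index (PAI): for each
  protein, the up-to-three peptide ions with the highest mean intensity
  across runs are fixed as reference peptides, and the per-run protein
  abundance is the arithmetic mean of their observed XIC areas.
* :class:`PairwiseRatioLFQ` — a delayed-normalization-style profile: for
  every pair of runs the median peptide log2 ratio is computed, and the
  per-run log2 abundances are the least-squares solution of the resulting
  pairwise-difference system, anchored so that the summed linear abundance
  equals the summed observed peptide intensity.

Both branches are ratio-consistent: if every peptide of a protein carries
the same KO/WT ratio, both estimators return exactly that ratio.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import IonMatrix, ProteinQuantTable, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PAI branch
# ---------------------------------------------------------------------------

def _rank_ions(annotations: pd.DataFrame, intensities: pd.DataFrame) -> pd.DataFrame:
    """Ions annotated with cross-run mean intensity, sorted for selection.

    Ranking is by mean over *observed* runs (missing cells ignored), so a
    peptide missing in some runs is not penalized; exact ties fall back to
    the smallest (protein_id, peptide_seq, charge) tuple, which makes the
    selection invariant under row shuffling.
    """
    mean = intensities.mean(axis=1, skipna=True)
    frame = annotations[["protein_id", "peptide_seq", "charge"]].copy()
    frame["_mean"] = mean
    frame["_row"] = np.arange(len(frame))
    frame = frame.dropna(subset=["_mean"])  # ions with no observation at all
    return frame.sort_values(
        by=["protein_id", "_mean", "peptide_seq", "charge"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )


def select_reference_peptides(
    ions: IonMatrix, k: int = 3
) -> list[tuple[str, str, int]]:
    """Reference ion keys of a single protein: top ``min(k, available)``
    ions by cross-run mean intensity, deterministic under ties."""
    prots = ions.annotations["protein_id"].unique()
    if len(prots) != 1:
        raise ValidationError("select_reference_peptides expects ions of one protein")
    ranked = _rank_ions(ions.annotations, ions.intensities)
    if ranked.empty:
        raise ValidationError(f"protein {prots[0]!r} has no quantified ion")
    top = ranked.head(k)
    return [tuple(r) for r in top[["protein_id", "peptide_seq", "charge"]]
            .itertuples(index=False, name=None)]


def compute_pai(ions: IonMatrix, reference_keys: Sequence[tuple[str, str, int]]) -> pd.Series:
    """Per-run PAI: mean XIC area of the reference peptides observed in
    that run; missing when none of them is observed."""
    keys = ions.ion_keys()
    sel = keys.isin([tuple(k) for k in reference_keys])
    if not sel.any():
        raise ValidationError("no reference peptide present in the ion set")
    return ions.intensities.loc[sel].mean(axis=0, skipna=True)


class Top3Quantifier(BaseEstimator, TransformerMixin):
    """Protein abundance index from up to ``k`` reference peptides.

    ``fit`` fixes the reference peptides per protein (the same list for
    every run); ``transform`` averages their observed areas per run.

    Attributes
    ----------
    reference_peptides_ : dict protein_id -> list of (protein, peptide, charge)
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X: IonMatrix, y=None) -> "Top3Quantifier":
        ranked = _rank_ions(X.annotations, X.intensities)
        top = ranked.groupby("protein_id", sort=True).head(self.k)
        refs: dict[str, list[tuple[str, str, int]]] = {}
        for pid, pep, ch in zip(top["protein_id"], top["peptide_seq"], top["charge"]):
            refs.setdefault(pid, []).append((pid, pep, int(ch)))
        self.reference_peptides_ = refs
        return self

    def transform(self, X: IonMatrix) -> ProteinQuantTable:
        ranked = _rank_ions(X.annotations, X.intensities)
        n_pep = (
            X.annotations.iloc[ranked["_row"].to_numpy()]
            .groupby("protein_id")["peptide_seq"].nunique()
        )
        ref_index = {  # key -> positional row, observed ions only
            (p, s, int(c)): int(row)
            for p, s, c, row in zip(
                ranked["protein_id"], ranked["peptide_seq"],
                ranked["charge"], ranked["_row"],
            )
        }
        order = sorted(self.reference_peptides_)
        sel_rows = [
            ref_index[key]
            for pid in order
            for key in self.reference_peptides_[pid]
            if key in ref_index
        ]
        sub_ann = X.annotations.iloc[sel_rows]
        sub_int = X.intensities.iloc[sel_rows]
        abund = sub_int.groupby(sub_ann["protein_id"].to_numpy()).mean()
        abund = abund.reindex(order)
        abund.index.name = "protein_id"
        return ProteinQuantTable(
            abund,
            n_pep.reindex(order).fillna(0).astype(int),
            branch="PAI",
            reference_peptides=self.reference_peptides_,
        )


# ---------------------------------------------------------------------------
# LFQ branch
# ---------------------------------------------------------------------------

def compute_lfq_profile(
    ions: IonMatrix,
    run_order: Sequence[str] | None = None,
    min_shared_peptides: int = 1,
) -> pd.Series:
    """Pairwise-ratio least-squares profile of one protein.

    For every run pair (a, b) sharing at least ``min_shared_peptides``
    observed peptides, the pairwise statistic is the median over shared
    peptides of log2(I_a / I_b).  The per-run log2 abundances x solve the
    least-squares system x_a - x_b ≈ r_ab over all supported pairs; the
    free additive constant is fixed so that the summed linear abundance
    over the solved runs equals their summed observed peptide intensity.
    Runs outside the largest connected component of the pair graph get
    missing abundances (a warning is logged).
    """
    runs = list(run_order) if run_order is not None else ions.run_ids
    A = np.log2(ions.intensities[runs].to_numpy(dtype=float))
    if np.sum(np.any(~np.isnan(A), axis=0)) < 2:
        raise ValidationError("LFQ profile needs peptides observed in >= 2 runs")
    return pd.Series(
        _solve_pairwise(A, min_shared_peptides,
                        raw=ions.intensities[runs].to_numpy(dtype=float)),
        index=runs,
    )


def _solve_pairwise(A: np.ndarray, min_shared: int, raw: np.ndarray) -> np.ndarray:
    """Least-squares run profile from peptide log2 matrix ``A`` (ions × runs)."""
    n_runs = A.shape[1]
    # pairwise differences: D[i, a, b] = A[i, a] - A[i, b]
    D = A[:, :, None] - A[:, None, :]
    counts = np.sum(~np.isnan(D), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs are fine
        med = np.nanmedian(D, axis=0)

    edges = [
        (a, b, med[a, b])
        for a in range(n_runs)
        for b in range(a + 1, n_runs)
        if counts[a, b] >= max(1, min_shared)
    ]
    observed = np.any(~np.isnan(A), axis=0)

    comp = _largest_component(n_runs, edges, observed)
    out = np.full(n_runs, np.nan)
    if not comp:
        return out
    if len(comp) < int(observed.sum()):
        logger.warning(
            "disconnected run graph: solving %d of %d observed runs",
            len(comp), int(observed.sum()),
        )

    idx = {r: i for i, r in enumerate(comp)}
    comp_edges = [(a, b, r) for a, b, r in edges if a in idx and b in idx]
    if comp_edges:
        M = np.zeros((len(comp_edges), len(comp)))
        rhs = np.zeros(len(comp_edges))
        for row, (a, b, r) in enumerate(comp_edges):
            M[row, idx[a]] = 1.0
            M[row, idx[b]] = -1.0
            rhs[row] = r
        x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        x = x - x.mean()  # minimum-norm gauge before anchoring
    else:  # single observed run, no pairs
        x = np.zeros(len(comp))

    # anchor: summed linear abundance = summed observed intensity over comp
    total = np.nansum(raw[:, comp])
    shift = np.log2(total / np.sum(2.0**x))
    out[list(comp)] = 2.0 ** (x + shift)
    return out


def _largest_component(n_runs: int, edges, observed: np.ndarray) -> list[int]:
    parent = list(range(n_runs))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, _ in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    comps: dict[int, list[int]] = {}
    for r in range(n_runs):
        if observed[r]:
            comps.setdefault(find(r), []).append(r)
    if not comps:
        return []
    # largest component; ties broken by smallest run index
    return max(comps.values(), key=lambda c: (len(c), -min(c)))


class PairwiseRatioLFQ(BaseEstimator, TransformerMixin):
    """LFQ-style protein profiles via pairwise median peptide ratios.

    Parameters
    ----------
    min_shared_peptides : minimum shared observed peptides for a run pair
        to contribute a ratio (default 1).
    normalize : equalize per-run medians of the output table (the
        "median of all values" convention), default True.
    """

    def __init__(self, min_shared_peptides: int = 1, normalize: bool = True):
        self.min_shared_peptides = min_shared_peptides
        self.normalize = normalize

    def fit(self, X: IonMatrix, y=None) -> "PairwiseRatioLFQ":
        return self

    def transform(self, X: IonMatrix) -> ProteinQuantTable:
        runs = X.run_ids
        ann = X.annotations
        inten = X.intensities.to_numpy(dtype=float)
        order = np.argsort(ann["protein_id"].to_numpy(), kind="mergesort")
        prot_sorted = ann["protein_id"].to_numpy()[order]
        uniq, starts = np.unique(prot_sorted, return_index=True)
        bounds = list(starts) + [len(prot_sorted)]

        rows = np.full((len(uniq), len(runs)), np.nan)
        n_pep = np.zeros(len(uniq), dtype=int)
        pep_seqs = ann["peptide_seq"].to_numpy()
        for g, pid in enumerate(uniq):
            rws = order[bounds[g]:bounds[g + 1]]
            raw = inten[rws]
            obs_ion = np.any(~np.isnan(raw), axis=1)
            n_pep[g] = len(set(pep_seqs[rws[obs_ion]]))
            if np.sum(np.any(~np.isnan(raw), axis=0)) < 2:
                continue  # single-run proteins stay missing outside that run
            with np.errstate(all="ignore"):
                A = np.log2(raw)
            rows[g] = _solve_pairwise(A, self.min_shared_peptides, raw=raw)

        abund = pd.DataFrame(rows, index=pd.Index(uniq, name="protein_id"), columns=runs)
        table = ProteinQuantTable(
            abund, pd.Series(n_pep, index=abund.index, name="n_peptides"), branch="LFQ"
        )
        if self.normalize:
            table = normalize_lfq_table(table)
        return table


def normalize_lfq_table(table: ProteinQuantTable) -> ProteinQuantTable:
    """Equalize per-run medians of an LFQ table.

    Each run is divided by (run median / grand median of the run medians),
    so all per-run medians coincide afterwards.
    """
    if table.branch != "LFQ":
        raise ValidationError("normalize_lfq_table expects the LFQ branch")
    med = table.abundances.median(axis=0, skipna=True)
    if med.isna().any():
        empty = med.index[med.isna()].tolist()
        raise ValidationError(f"run(s) with no quantified protein: {empty}")
    grand = float(np.median(med.to_numpy()))
    scaled = table.abundances / (med / grand)
    return ProteinQuantTable(scaled, table.n_peptides.copy(), "LFQ",
                             table.reference_peptides)


def quantify(
    matrix: IonMatrix, branch: str, **kwargs
) -> ProteinQuantTable:
    """Run one branch ("pai" or "lfq") over a full ion matrix."""
    b = branch.lower()
    if b == "pai":
        return Top3Quantifier(**kwargs).fit(matrix).transform(matrix)
    if b == "lfq":
        return PairwiseRatioLFQ(**kwargs).fit(matrix).transform(matrix)
    raise ValidationError(f"unknown branch {branch!r}")
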