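"""Synthetic peptide-ion datasets emulating a 3-vs-3 knockout experiment.

The generator emulates the bottom-up LFQ measurement process of a
knockout (KO) vs wild-type (WT) dendritic-cell proteome comparison:

* a log-normal background proteome (~2,000 proteins, 2–12 tryptic
  peptide ions each),
* a fixed per-peptide response ("flyability") factor shared across runs,
* a per-run multiplicative loading bias,
* log-normal technical noise per measurement,
* missing cells (missing completely at random by default, optional
  left-censored mode),
* spiked substrate-like proteins whose KO abundance is multiplied by
  ``2**true_log2_fc`` — defaults are two filamin-like spikes at the
  literature fold changes 7.10 and 5.90,
* one marker protein with no signal at all in one condition, emulating a
  protein whose peptides are never attributed in the knockout.

The generated cell value is::

    XIC[ion, run] = base[protein] * 2**fc (KO runs only) * response[ion]
                    * scale[run] * exp(eps),   eps ~ N(0, ln(1 + cv^2))

Identical config (including seed) produces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import KO, WT, GroundTruth, IonMatrix, StudyDesign, ValidationError
from .io import write_design, write_ground_truth, write_ion_table

#: literature fold changes of the two filamin substrates (DN vs CD4+ cDC subsets)
FLNA_FOLD = 7.10
FLNB_FOLD = 5.90

AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R inside tryptic peptides


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic LFQ experiment.

    Defaults mirror the emulated study: ~2,000-protein proteome, three
    biological replicates per genotype, two strongly accumulating
    substrate spikes and one knockout-absent marker.
    """

    n_background_proteins: int = 2000
    peptides_per_protein: tuple[int, int] = (2, 12)  # inclusive range; (k, k) pins
    n_replicates_per_condition: int = 3
    base_abundance_log_mean: float = math.log(1e6)  # natural-log scale
    base_abundance_log_sd: float = 1.5
    peptide_response_log_sd: float = 1.0
    technical_cv: float = 0.25
    run_scale_factors: tuple[float, ...] | None = None  # None: log-uniform in [0.5, 2]
    missing_rate: float = 0.05
    censor_missing: bool = False  # True: missingness concentrates on low intensities
    spikes: tuple[tuple[str, float], ...] = (
        ("FLNA", math.log2(FLNA_FOLD)),
        ("FLNB", math.log2(FLNB_FOLD)),
    )
    absent_markers: tuple[tuple[str, str], ...] = (("ASB2A", KO),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_proteins < 0:
            raise ValidationError("n_background_proteins must be non-negative")
        if self.n_replicates_per_condition < 2:
            raise ValidationError(
                "need at least 2 replicates per condition (two-sample test)"
            )
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValidationError("peptides_per_protein must satisfy 1 <= min <= max")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must lie in [0, 1]")
        if self.technical_cv < 0 or self.peptide_response_log_sd < 0:
            raise ValidationError("noise parameters must be non-negative")
        n_runs = 2 * self.n_replicates_per_condition
        if self.run_scale_factors is not None:
            if len(self.run_scale_factors) != n_runs:
                raise ValidationError(
                    f"run_scale_factors must have one entry per run ({n_runs})"
                )
            if any(s <= 0 for s in self.run_scale_factors):
                raise ValidationError("run scale factors must be strictly positive")
        labels = [lab for lab, _ in self.spikes]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate protein labels in spikes")
        for lab, cond in self.absent_markers:
            if cond not in (WT, KO):
                raise ValidationError(f"absent-marker condition must be WT or KO, got {cond!r}")
            if lab in labels:
                raise ValidationError(f"protein {lab!r} is both spiked and an absent marker")


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition defaults, optionally with fields overridden."""
    return replace(GeneratorConfig(), **overrides)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[IonMatrix, StudyDesign, GroundTruth]:
    """Draw one synthetic experiment: ion matrix, design and ground truth.

    The same config (same seed) is bit-reproducible.  Absent markers are
    encoded as missing cells in their empty condition, never as zeros.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates_per_condition

    wt_runs = [f"WT{i + 1}" for i in range(n_rep)]
    ko_runs = [f"KO{i + 1}" for i in range(n_rep)]
    run_ids = wt_runs + ko_runs
    design = StudyDesign.from_runs(
        [(r, WT, i + 1) for i, r in enumerate(wt_runs)]
        + [(r, KO, i + 1) for i, r in enumerate(ko_runs)]
    )

    # protein roster: background + spikes + markers
    width = max(4, len(str(config.n_background_proteins)))
    protein_ids = [f"BG{i + 1:0{width}d}" for i in range(config.n_background_proteins)]
    log2_fc = [0.0] * config.n_background_proteins
    absent_cond: list[str | None] = [None] * config.n_background_proteins
    for label, fc in config.spikes:
        protein_ids.append(label)
        log2_fc.append(float(fc))
        absent_cond.append(None)
    for label, cond in config.absent_markers:
        protein_ids.append(label)
        log2_fc.append(0.0)
        absent_cond.append(cond)
    n_prot = len(protein_ids)

    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=n_prot)
    base = rng.lognormal(
        config.base_abundance_log_mean, config.base_abundance_log_sd, size=n_prot
    )

    prot_idx = np.repeat(np.arange(n_prot), n_pep)
    n_ions = prot_idx.size
    response = rng.lognormal(0.0, config.peptide_response_log_sd, size=n_ions)

    if config.run_scale_factors is None:
        scale = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(run_ids)))
    else:
        scale = np.asarray(config.run_scale_factors, dtype=float)

    fc_mult = np.ones((n_prot, len(run_ids)))
    fc_mult[:, n_rep:] = 2.0 ** np.asarray(log2_fc)[:, None]

    sigma = math.sqrt(math.log(1.0 + config.technical_cv**2))
    noise = np.exp(rng.normal(0.0, sigma, size=(n_ions, len(run_ids)))) if sigma > 0 \
        else np.ones((n_ions, len(run_ids)))

    X = (
        base[prot_idx, None]
        * fc_mult[prot_idx, :]
        * response[:, None]
        * scale[None, :]
        * noise
    )

    # missingness: MCAR, or left-censored (probability decreasing with
    # log-intensity rank, same expected overall rate)
    if config.missing_rate > 0:
        if config.censor_missing:
            order = np.argsort(np.argsort(X, axis=None))  # dense ranks, 0 = smallest
            frac = order.reshape(X.shape) / (X.size - 1 if X.size > 1 else 1)
            p_miss = np.clip(2.0 * config.missing_rate * (1.0 - frac), 0.0, 1.0)
        else:
            p_miss = np.full(X.shape, config.missing_rate)
        X = np.where(rng.random(X.shape) < p_miss, np.nan, X)

    # absent markers: wipe the stated condition entirely
    cond_cols = {WT: np.arange(n_rep), KO: np.arange(n_rep, 2 * n_rep)}
    for p, cond in enumerate(absent_cond):
        if cond is not None:
            ions = prot_idx == p
            X[np.ix_(ions, cond_cols[cond])] = np.nan
            other = KO if cond == WT else WT
            # the marker must be observable where it is expressed
            X[np.ix_(ions, cond_cols[other])] = np.where(
                np.isnan(X[np.ix_(ions, cond_cols[other])]),
                base[p] * response[ions][:, None] * scale[None, cond_cols[other]],
                X[np.ix_(ions, cond_cols[other])],
            )

    peptides = _peptide_sequences(rng, n_ions)
    annotations = pd.DataFrame({
        "protein_id": np.asarray(protein_ids, dtype=object)[prot_idx],
        "peptide_seq": peptides,
        "charge": rng.integers(2, 4, size=n_ions),
        "mz": np.round(rng.uniform(400.0, 1200.0, size=n_ions), 4),
        "rt": np.round(rng.uniform(5.0, 120.0, size=n_ions), 2),
    })
    matrix = IonMatrix(annotations, pd.DataFrame(X, columns=run_ids))

    truth = GroundTruth(pd.DataFrame({
        "protein_id": protein_ids,
        "true_log2_fc": log2_fc,
        "is_absent_marker": [c is not None for c in absent_cond],
        "absent_condition": ["" if c is None else c for c in absent_cond],
        "n_peptides": n_pep,
    }))
    return matrix, design, truth


def _peptide_sequences(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unique tryptic-looking sequences (end in K or R)."""
    lengths = rng.integers(7, 21, size=n)
    bodies = rng.integers(0, len(AMINO_ACIDS), size=(n, 20))
    ends = rng.integers(0, 2, size=n)
    seqs = np.empty(n, dtype=object)
    seen: set[str] = set()
    for i in range(n):
        s = "".join(AMINO_ACIDS[bodies[i, : lengths[i] - 1]]) + ("K" if ends[i] else "R")
        while s in seen:  # collisions are rare; disambiguate deterministically
            s = s[:-1] + AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))] + s[-1]
        seen.add(s)
        seqs[i] = s
    return seqs


def write_dataset(
    matrix: IonMatrix,
    design: StudyDesign,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write ion table, design and truth TSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ions": out / "ions.tsv",
        "design": out / "design.tsv",
        "truth": out / "ground_truth.tsv",
    }
    write_ion_table(matrix, paths["ions"])
    write_design(design, paths["design"])
    write_ground_truth(truth, paths["truth"])
    return paths
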