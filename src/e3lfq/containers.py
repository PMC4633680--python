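"""In-memory containers for the pipeline.

The central object is the :class:`IonMatrix`: a peptide-ion × run table of
XIC (extracted ion current) areas, with per-ion annotations (protein
accession, peptide sequence, charge, m/z, retention time).  Missing cells
are NaN, never zero: a zero XIC area is not a measurement.  The
:class:`StudyDesign` maps runs to genotype arms (wild type vs knockout) and
replicate indices, and a :class:`ProteinQuantTable` holds the protein-level
roll-up of one quantitation branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["protein_id", "peptide_seq", "charge", "mz", "rt"]
KEY_COLUMNS = ["protein_id", "peptide_seq", "charge"]

#: condition labels of the two genotype arms
WT = "WT"
KO = "KO"


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class IonMatrix:
    """Peptide ions × runs matrix of XIC areas.

    Parameters
    ----------
    annotations : DataFrame with columns ``protein_id, peptide_seq, charge,
        mz, rt``, one row per peptide ion.  The triple
        ``(protein_id, peptide_seq, charge)`` is the ion key and must be
        unique.
    intensities : DataFrame aligned row-wise with ``annotations``; one
        column per run; NaN marks a missing (unquantified) cell and every
        present value is strictly positive.
    provenance : free-text note, ``"raw"`` or ``"normalized"``.
    """

    annotations: pd.DataFrame
    intensities: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing_cols:
            raise ValidationError(f"annotation columns missing: {missing_cols}")
        if len(self.annotations) != len(self.intensities):
            raise ValidationError("annotations and intensities row counts differ")
        if not self.annotations.index.equals(self.intensities.index):
            raise ValidationError("annotations and intensities indexes differ")
        run_ids = list(self.intensities.columns)
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("duplicate run_id columns")
        keys = self.annotations[KEY_COLUMNS]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValidationError(f"duplicate ion key {tuple(dup)}")
        vals = self.intensities.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum(vals <= 0)
        if bad:
            raise ValidationError(
                f"{int(bad)} non-positive intensity cell(s); absence must be encoded "
                "as an empty/missing cell, not zero"
            )

    # -- convenience ---------------------------------------------------
    @property
    def run_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_ions(self) -> int:
        return len(self.annotations)

    def ion_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.annotations[KEY_COLUMNS])

    def copy(self) -> "IonMatrix":
        return IonMatrix(self.annotations.copy(), self.intensities.copy(), self.provenance)

    def for_protein(self, protein_id: str) -> "IonMatrix":
        """Sub-matrix of the ions of one protein (annotations row-aligned)."""
        mask = self.annotations["protein_id"] == protein_id
        return IonMatrix(
            self.annotations.loc[mask], self.intensities.loc[mask], self.provenance
        )


@dataclass
class StudyDesign:
    """Run → (condition, replicate) assignment of the 2-arm comparison."""

    table: pd.DataFrame  # columns: run_id, condition, replicate

    def __post_init__(self) -> None:
        for col in ("run_id", "condition", "replicate"):
            if col not in self.table.columns:
                raise ValidationError(f"design table lacks column {col!r}")
        if self.table["run_id"].duplicated().any():
            raise ValidationError("duplicate run_id in design")
        counts = self.table["condition"].value_counts()
        if (counts < 2).any():
            low = counts[counts < 2].index.tolist()
            raise ValidationError(f"conditions with <2 runs: {low}")

    @property
    def run_ids(self) -> list[str]:
        return self.table["run_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def runs_for(self, condition: str) -> list[str]:
        sel = self.table.loc[self.table["condition"] == condition, "run_id"]
        return sel.tolist()

    def condition_of(self, run_id: str) -> str:
        row = self.table.loc[self.table["run_id"] == run_id]
        if row.empty:
            raise KeyError(run_id)
        return str(row["condition"].iloc[0])

    def check_matrix(self, matrix: IonMatrix) -> None:
        """Every matrix run must be assigned in the design."""
        unknown = set(matrix.run_ids) - set(self.run_ids)
        if unknown:
            raise ValidationError(f"runs absent from design: {sorted(unknown)}")

    @classmethod
    def from_runs(cls, runs: Iterable[tuple[str, str, int]]) -> "StudyDesign":
        return cls(pd.DataFrame(runs, columns=["run_id", "condition", "replicate"]))


@dataclass
class ProteinQuantTable:
    """Protein × run abundances from one quantitation branch.

    ``abundances`` is proteins × runs (NaN = not quantified in that run);
    ``n_peptides`` counts the distinct quantified peptide sequences per
    protein; ``branch`` is ``"PAI"`` or ``"LFQ"``.  For the PAI branch,
    ``reference_peptides`` maps each protein to its 1–3 reference ion keys.
    """

    abundances: pd.DataFrame
    n_peptides: pd.Series
    branch: str
    reference_peptides: dict[str, list[tuple[str, str, int]]] | None = None

    def __post_init__(self) -> None:
        if self.branch not in ("PAI", "LFQ"):
            raise ValidationError(f"unknown branch {self.branch!r}")
        if not self.abundances.index.equals(self.n_peptides.index):
            raise ValidationError("abundance and peptide-count indexes differ")
        if self.abundances.index.duplicated().any():
            raise ValidationError("duplicate protein_id rows")
        if self.branch == "PAI" and self.reference_peptides is not None:
            for pid, keys in self.reference_peptides.items():
                n_avail = int(self.n_peptides.get(pid, 0))
                if not 1 <= len(keys) <= 3:
                    raise ValidationError(
                        f"{pid}: {len(keys)} reference peptides (expected 1-3)"
                    )

    @property
    def run_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.abundances.index)

    def subset(self, protein_ids: Sequence[str]) -> "ProteinQuantTable":
        refs = None
        if self.reference_peptides is not None:
            refs = {p: self.reference_peptides[p] for p in protein_ids
                    if p in self.reference_peptides}
        return ProteinQuantTable(
            self.abundances.loc[list(protein_ids)],
            self.n_peptides.loc[list(protein_ids)],
            self.branch,
            refs,
        )


@dataclass
class GroundTruth:
    """Per-protein simulation truth used by recovery tests.

    ``true_log2_fc`` is the knockout-over-wild-type log2 ratio (0 for the
    null background); absent markers carry a flag and the condition in
    which they yield no signal.
    """

    table: pd.DataFrame  # protein_id, true_log2_fc, is_absent_marker, absent_condition, n_peptides

    COLUMNS = ["protein_id", "true_log2_fc", "is_absent_marker", "absent_condition", "n_peptides"]

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.table.columns:
                raise ValidationError(f"truth table lacks column {col!r}")
        if self.table["protein_id"].duplicated().any():
            raise ValidationError("duplicate protein in ground truth")

    def spiked(self) -> pd.DataFrame:
        return self.table[self.table["true_log2_fc"] != 0.0]

    def flagged(self) -> pd.DataFrame:
        """Rows that are not plain null background (spiked or absent-marker)."""
        t = self.table
        return t[(t["true_log2_fc"] != 0.0) | t["is_absent_marker"]]
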