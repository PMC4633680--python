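"""TSV readers/writers and cross-run ion matching.

All tables are UTF-8 TSV with a header row and '.' decimal separator.
The ion-table dialect is: ``protein_id  peptide_seq  charge  mz  rt``
followed by one ``intensity:<run_id>`` column per run; missing cells are
empty.  Protein tables use ``abundance:<run_id>`` columns analogously.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    KEY_COLUMNS,
    GroundTruth,
    IonMatrix,
    ProteinQuantTable,
    StudyDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

INTENSITY_PREFIX = "intensity:"
ABUNDANCE_PREFIX = "abundance:"


# ---------------------------------------------------------------------------
# ion tables
# ---------------------------------------------------------------------------

def read_ion_table(path: str | Path) -> IonMatrix:
    """Parse an ion-table TSV into an :class:`IonMatrix`.

    Empty cells become missing (NaN).  Zero or negative intensities,
    non-numeric values, duplicate ion keys and unknown columns are rejected
    with the offending data row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [
        c for c in df.columns
        if c not in ANNOTATION_COLUMNS and not c.startswith(INTENSITY_PREFIX)
    ]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")

    run_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    run_ids = [c[len(INTENSITY_PREFIX):] for c in run_cols]

    ann = df[ANNOTATION_COLUMNS].copy()
    for col, caster in (("charge", int), ("mz", float), ("rt", float)):
        try:
            ann[col] = ann[col].map(caster)
        except ValueError as exc:
            bad = _first_bad_row(ann[col], caster)
            raise ValidationError(f"{path}: non-numeric {col} at row {bad}: {exc}") from exc

    inten = pd.DataFrame(index=df.index, columns=run_ids, dtype=float)
    for col, run in zip(run_cols, run_ids):
        raw = df[col]
        parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad_mask = parsed.isna() & (raw != "")
        if bad_mask.any():
            row = int(bad_mask.idxmax()) + 1
            raise ValidationError(
                f"{path}: non-numeric intensity {raw[bad_mask.idxmax()]!r} "
                f"in column {col} at row {row}"
            )
        nonpos = parsed <= 0
        if nonpos.any():
            row = int(nonpos.idxmax()) + 1
            raise ValidationError(
                f"{path}: non-positive intensity in column {col} at row {row}; "
                "missing cells must be empty, not zero"
            )
        inten[run] = parsed

    dup = ann[KEY_COLUMNS].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValidationError(f"{path}: duplicate ion key at row {row}")
    return IonMatrix(ann, inten)


def write_ion_table(matrix: IonMatrix, path: str | Path) -> None:
    out = matrix.annotations.copy()
    for run in matrix.run_ids:
        out[INTENSITY_PREFIX + run] = matrix.intensities[run]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def _first_bad_row(series: pd.Series, caster) -> int:
    for i, v in enumerate(series):
        try:
            caster(v)
        except ValueError:
            return i + 1
    return -1


# ---------------------------------------------------------------------------
# design / truth / protein / differential tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "condition": str, "replicate": int})
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "absent_condition": str},
        keep_default_na=False,
    )
    df["true_log2_fc"] = df["true_log2_fc"].astype(float)
    df["is_absent_marker"] = df["is_absent_marker"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    df["n_peptides"] = df["n_peptides"].astype(int)
    return GroundTruth(df)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the simulation truth; round-trips losslessly via TSV."""
    if truth.table.empty:
        raise ValidationError("refusing to write an empty ground-truth table")
    truth.table.to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> ProteinQuantTable:
    df = pd.read_csv(path, sep="\t")
    run_cols = [c for c in df.columns if c.startswith(ABUNDANCE_PREFIX)]
    abund = df[run_cols].copy()
    abund.columns = [c[len(ABUNDANCE_PREFIX):] for c in run_cols]
    abund.index = df["protein_id"]
    n_pep = pd.Series(df["n_peptides"].to_numpy(), index=abund.index, name="n_peptides")
    branch = str(df["branch"].iloc[0]) if len(df) else "PAI"
    return ProteinQuantTable(abund, n_pep, branch)


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    out = pd.DataFrame({
        "protein_id": table.abundances.index,
        "branch": table.branch,
        "n_peptides": table.n_peptides.to_numpy(),
    })
    for run in table.run_ids:
        out[ABUNDANCE_PREFIX + run] = table.abundances[run].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# cross-run ion matching
# ---------------------------------------------------------------------------

def match_ions(
    matrices: Sequence[IonMatrix],
    mz_tol_ppm: float = 5.0,
    rt_window: float = 0.5,
) -> IonMatrix:
    """Assemble per-run ion tables into one cross-run matrix.

    Ions are merged by exact key ``(protein_id, peptide_seq, charge)``.
    Keyless agreement is tolerated too: two ions of the same protein whose
    keys differ are merged when their m/z values agree within
    ``mz_tol_ppm`` parts-per-million and their retention times within
    ``rt_window`` minutes.  Unmatched ions are kept with missing cells in
    the other runs.  The same (peptide, charge) observed under two protein
    accessions is a conflicting assignment and is rejected.

    Each input matrix must cover exactly one run.
    """
    if not matrices:
        raise ValidationError("no matrices to match")
    run_ids: list[str] = []
    for m in matrices:
        if len(m.run_ids) != 1:
            raise ValidationError("match_ions expects single-run matrices")
        run_ids.extend(m.run_ids)
    if len(set(run_ids)) != len(run_ids):
        raise ValidationError("duplicate run ids across input matrices")

    _check_protein_conflicts(matrices)

    # consensus rows: list of dicts with annotation + per-run intensity
    rows: list[dict] = []
    by_key: dict[tuple, int] = {}

    for m in matrices:
        run = m.run_ids[0]
        ann = m.annotations.reset_index(drop=True)
        vals = m.intensities.reset_index(drop=True)[run]
        for i in range(len(ann)):
            rec = ann.iloc[i]
            key = (rec["protein_id"], rec["peptide_seq"], int(rec["charge"]))
            idx = by_key.get(key)
            if idx is None:
                idx = _tolerance_match(rows, rec, run, mz_tol_ppm, rt_window)
            if idx is None:
                rows.append({
                    "protein_id": rec["protein_id"],
                    "peptide_seq": rec["peptide_seq"],
                    "charge": int(rec["charge"]),
                    "mz": float(rec["mz"]),
                    "rt": float(rec["rt"]),
                    "intensity": {run: vals.iloc[i]},
                })
                by_key[key] = len(rows) - 1
            else:
                rows[idx]["intensity"][run] = vals.iloc[i]
                by_key.setdefault(key, idx)

    ann_out = pd.DataFrame(
        [{c: r[c] for c in ANNOTATION_COLUMNS} for r in rows]
    )
    inten_out = pd.DataFrame(
        [[r["intensity"].get(run, np.nan) for run in run_ids] for r in rows],
        columns=run_ids,
    )
    # merged keys can collide with an existing exact key only via the
    # tolerance path, which never merges two ions of the same run
    return IonMatrix(ann_out, inten_out)


def _check_protein_conflicts(matrices: Sequence[IonMatrix]) -> None:
    seen: dict[tuple[str, int], str] = {}
    for m in matrices:
        for _, rec in m.annotations.iterrows():
            pk = (rec["peptide_seq"], int(rec["charge"]))
            prot = rec["protein_id"]
            if pk in seen and seen[pk] != prot:
                raise ValidationError(
                    f"conflicting protein assignment for peptide {pk}: "
                    f"{seen[pk]} vs {prot}"
                )
            seen[pk] = prot


def _tolerance_match(rows, rec, run, mz_tol_ppm, rt_window):
    mz = float(rec["mz"])
    rt = float(rec["rt"])
    best = None
    best_dppm = None
    for idx, r in enumerate(rows):
        if r["protein_id"] != rec["protein_id"] or int(r["charge"]) != int(rec["charge"]):
            continue
        if run in r["intensity"]:
            continue  # that consensus ion already has a value in this run
        dppm = abs(mz - r["mz"]) / r["mz"] * 1e6
        if dppm <= mz_tol_ppm and abs(rt - r["rt"]) <= rt_window:
            if best is None or dppm < best_dppm:
                best, best_dppm = idx, dppm
    return best
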