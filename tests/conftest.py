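"""Shared fixtures: small handcrafted ion matrices and designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from e3lfq import IonMatrix, StudyDesign


def make_matrix(rows, run_ids):
    """Build an IonMatrix from (protein, peptide, charge, mz, rt, *intensities)
    tuples; None marks a missing cell."""
    ann = pd.DataFrame(
        [r[:5] for r in rows],
        columns=["protein_id", "peptide_seq", "charge", "mz", "rt"],
    )
    inten = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in r[5:]] for r in rows],
        columns=run_ids,
    )
    return IonMatrix(ann, inten)


@pytest.fixture
def design_3v3():
    return StudyDesign.from_runs(
        [(f"WT{i}", "WT", i) for i in (1, 2, 3)]
        + [(f"KO{i}", "KO", i) for i in (1, 2, 3)]
    )


@pytest.fixture
def design_2v2():
    return StudyDesign.from_runs(
        [("WT1", "WT", 1), ("WT2", "WT", 2), ("KO1", "KO", 1), ("KO2", "KO", 2)]
    )


@pytest.fixture
def two_run_matrix():
    """Three ions over two runs, one missing cell."""
    return make_matrix(
        [
            ("P1", "AAAK", 2, 500.1, 10.0, 100.0, 200.0),
            ("P1", "CCCK", 2, 600.2, 20.0, 50.0, 100.0),
            ("P2", "DDDR", 3, 700.3, 30.0, 80.0, None),
        ],
        ["A", "B"],
    )
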