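"""Dual-branch substrate calling, QC and end-to-end orchestration.

A protein is nominated as a ligase-substrate candidate only if it passes
the fold-change and p-value cutoffs in BOTH quantitation branches with a
positive log2 fold change (accumulation in the knockout): substrates are
degraded when the ligase is present, so they pile up when it is gone.
Depleted proteins are surfaced informationally but never called.  QC
covers the branch-overlap Venn counts, within-genotype replicate Pearson
correlations on log2 abundances, and detection of proteins with no
attributed peptide in one entire condition (knockout-absent markers).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .containers import (
    KO,
    WT,
    GroundTruth,
    IonMatrix,
    ProteinQuantTable,
    StudyDesign,
    ValidationError,
)
from .io import (
    read_design,
    read_ion_table,
    write_design,
    write_ion_table,
    write_protein_table,
)
from .normalize import MedianRatioNormalizer
from .quantify import PairwiseRatioLFQ, Top3Quantifier
from .simulate import GeneratorConfig, generate_dataset, write_ground_truth
from .stats import Thresholds, build_differential_table, filter_quantifiable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# set arithmetic and intersection
# ---------------------------------------------------------------------------

def venn_counts(ids_a: Iterable, ids_b: Iterable) -> tuple[int, int, int]:
    """(only_a, only_b, common) of two id collections."""
    a, b = set(ids_a), set(ids_b)
    return len(a - b), len(b - a), len(a & b)


def intersect_candidates(
    diff_pai: pd.DataFrame, diff_lfq: pd.DataFrame
) -> pd.DataFrame:
    """Proteins passing filters, fold-change and p cutoffs in both
    branches, accumulating in the knockout in both.

    Sorted by the smaller of the two branch log2 fold changes, descending
    (most confidently accumulating first).
    """
    ta = diff_pai.attrs.get("thresholds")
    tb = diff_lfq.attrs.get("thresholds")
    if ta != tb:
        raise ValidationError(f"branch thresholds differ: {ta} vs {tb}")

    frames = {}
    for df in (diff_pai, diff_lfq):
        br = df.attrs.get("branch", df["branch"].iloc[0] if len(df) else "?")
        passing = df[
            df["passes_filters"] & df["passes_fc"] & df["passes_p"] & (df["log2_fc"] > 0)
        ]
        frames[br] = passing.set_index("protein_id")
    (br_a, a), (br_b, b) = frames.items()
    common = a.index.intersection(b.index)
    out = pd.DataFrame({
        "protein_id": common,
        f"log2_fc_{br_a.lower()}": a.loc[common, "log2_fc"].to_numpy(),
        f"p_value_{br_a.lower()}": a.loc[common, "p_value"].to_numpy(),
        f"log2_fc_{br_b.lower()}": b.loc[common, "log2_fc"].to_numpy(),
        f"p_value_{br_b.lower()}": b.loc[common, "p_value"].to_numpy(),
    })
    out["min_log2_fc"] = np.minimum(
        out[f"log2_fc_{br_a.lower()}"], out[f"log2_fc_{br_b.lower()}"]
    )
    out = out.sort_values(["min_log2_fc", "protein_id"], ascending=[False, True])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def replicate_correlation(
    table: ProteinQuantTable, design: StudyDesign, min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of log2 abundances for within-condition run pairs.

    Each pair uses the proteins quantified in both runs; pairs with fewer
    than ``min_shared`` shared proteins get a missing entry and a warning.
    Columns: condition, run_a, run_b, pearson_r, n_proteins.
    """
    rows = []
    for cond in design.conditions:
        runs = design.runs_for(cond)
        for i, ra in enumerate(runs):
            for rb in runs[i + 1:]:
                va = table.abundances[ra]
                vb = table.abundances[rb]
                both = va.notna() & vb.notna()
                n = int(both.sum())
                if n < min_shared:
                    logger.warning("pair (%s, %s): only %d shared proteins", ra, rb, n)
                    r = np.nan
                else:
                    with np.errstate(invalid="ignore"):  # constant vectors -> NaN
                        r = float(np.corrcoef(
                            np.log2(va[both].to_numpy()), np.log2(vb[both].to_numpy())
                        )[0, 1])
                rows.append((cond, ra, rb, r, n))
    return pd.DataFrame(
        rows, columns=["condition", "run_a", "run_b", "pearson_r", "n_proteins"]
    )


def detect_absent_markers(
    matrix: IonMatrix, design: StudyDesign
) -> list[tuple[str, str]]:
    """Proteins quantified in every run of one condition and in no run of
    the other; returned with the condition carrying zero attributed
    peptides.  The strict all-runs rule: a protein merely missing in some
    runs of a condition is not a marker."""
    counts = quantified_peptides_per_run(matrix)
    out = []
    for absent, present in ((WT, KO), (KO, WT)):
        none_absent = (counts[design.runs_for(absent)] == 0).all(axis=1)
        all_present = (counts[design.runs_for(present)] > 0).all(axis=1)
        out.extend((pid, absent) for pid in counts.index[none_absent & all_present])
    return sorted(out)


def quantified_peptides_per_run(matrix: IonMatrix) -> pd.DataFrame:
    """Protein × run table of quantified peptide-ion counts."""
    present = matrix.intensities.notna()
    return present.groupby(matrix.annotations["protein_id"].to_numpy()).sum()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run settings: either simulate or point at input TSVs."""

    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ion_table: str | None = None
    design: str | None = None
    reference_run: str = "auto"
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_shared_peptides: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**_tuplify(raw.pop("generator", {})))
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(generator=gen, thresholds=thr, **raw)


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return out


@dataclass
class CandidateReport:
    """Everything the substrate call rests on, with provenance."""

    candidates: pd.DataFrame
    depleted: pd.DataFrame
    venn: tuple[int, int, int]
    correlations: pd.DataFrame
    absent_markers: list[tuple[str, str]]
    thresholds: Thresholds
    seed: int | None
    input_hashes: dict[str, str]

    def to_json_dict(self) -> dict:
        return {
            "candidates": self.candidates.to_dict(orient="records"),
            "depleted_informational": self.depleted.to_dict(orient="records"),
            "venn": {"only_pai": self.venn[0], "only_lfq": self.venn[1],
                     "common": self.venn[2]},
            "replicate_correlations": self.correlations.to_dict(orient="records"),
            "absent_markers": [list(t) for t in self.absent_markers],
            "thresholds": asdict(self.thresholds),
            "seed": self.seed,
            "input_hashes": self.input_hashes,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class AnalysisResult:
    """All stage outputs of one dataset analysis (both branches)."""

    normalized: IonMatrix
    tables: dict[str, ProteinQuantTable]      # raw per-branch roll-ups
    filtered: dict[str, ProteinQuantTable]    # after quantifiability filters
    diffs: dict[str, pd.DataFrame]            # per-branch differential tables
    candidates: pd.DataFrame
    depleted: pd.DataFrame
    venn: tuple[int, int, int]
    correlations: pd.DataFrame
    absent_markers: list[tuple[str, str]]


def analyze_dataset(
    matrix: IonMatrix,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
    reference_run: str = "auto",
    min_shared_peptides: int = 1,
) -> AnalysisResult:
    """normalize → quantify (both branches) → filter + test → intersect + QC."""
    design.check_matrix(matrix)
    logger.info("normalizing (%d ions, %d runs)", matrix.n_ions, len(matrix.run_ids))
    normalized = MedianRatioNormalizer(reference_run).fit(matrix).transform(matrix)

    tables = {
        "PAI": Top3Quantifier().fit(normalized).transform(normalized),
        "LFQ": PairwiseRatioLFQ(min_shared_peptides).fit(normalized)
        .transform(normalized),
    }
    filtered = {br: filter_quantifiable(t, design, thresholds)
                for br, t in tables.items()}
    diffs = {br: build_differential_table(t, design, thresholds)
             for br, t in filtered.items()}

    candidates = intersect_candidates(diffs["PAI"], diffs["LFQ"])
    depleted = _depleted_informational(diffs["PAI"], diffs["LFQ"])
    venn = venn_counts(diffs["PAI"]["protein_id"], diffs["LFQ"]["protein_id"])
    corr = pd.concat(
        [replicate_correlation(t, design).assign(branch=br)
         for br, t in filtered.items()],
        ignore_index=True,
    )
    markers = detect_absent_markers(matrix, design)

    # candidate set must be a subset of each branch's passing set
    for br, df in diffs.items():
        passing = set(df.loc[df["passes_fc"] & df["passes_p"] & df["passes_filters"],
                             "protein_id"])
        stray = set(candidates["protein_id"]) - passing
        if stray:
            raise AssertionError(f"candidates outside {br} passing set: {stray}")

    return AnalysisResult(normalized, tables, filtered, diffs, candidates,
                          depleted, venn, corr, markers)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> CandidateReport:
    """End-to-end run producing a :class:`CandidateReport`.

    ``seed`` overrides the generator seed when simulating.  When
    ``out_dir`` is given, all intermediate tables and a ``report.json``
    are written there; reruns with the same seed are byte-identical.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    hashes: dict[str, str] = {}
    if config.simulate:
        gen = config.generator
        if seed is not None:
            gen = replace(gen, seed=seed)
        logger.info("simulating dataset (seed=%d)", gen.seed)
        matrix, design, truth = generate_dataset(gen)
        used_seed = gen.seed
        if out is not None:
            write_ion_table(matrix, out / "ions.tsv")
            write_design(design, out / "design.tsv")
            write_ground_truth(truth, out / "ground_truth.tsv")
            hashes["ions.tsv"] = _sha256(out / "ions.tsv")
    else:
        if not config.ion_table or not config.design:
            raise ValidationError("non-simulate runs need ion_table and design paths")
        matrix = read_ion_table(config.ion_table)
        design = read_design(config.design)
        hashes["ions.tsv"] = _sha256(Path(config.ion_table))
        hashes["design.tsv"] = _sha256(Path(config.design))
        used_seed = seed

    res = analyze_dataset(
        matrix, design, config.thresholds,
        reference_run=config.reference_run,
        min_shared_peptides=config.min_shared_peptides,
    )

    report = CandidateReport(
        candidates=res.candidates,
        depleted=res.depleted,
        venn=res.venn,
        correlations=res.correlations,
        absent_markers=res.absent_markers,
        thresholds=config.thresholds,
        seed=used_seed,
        input_hashes=hashes,
    )

    if out is not None:
        write_ion_table(res.normalized, out / "ions_normalized.tsv")
        for br in res.tables:
            write_protein_table(res.tables[br], out / f"protein_{br.lower()}.tsv")
            res.diffs[br].to_csv(out / f"diff_{br.lower()}.tsv", sep="\t",
                                 index=False, na_rep="")
        res.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, na_rep="")
        res.correlations.to_csv(out / "qc_correlations.tsv", sep="\t",
                                index=False, na_rep="")
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _depleted_informational(diff_pai: pd.DataFrame, diff_lfq: pd.DataFrame) -> pd.DataFrame:
    """Proteins significantly *depleted* in the knockout in both branches —
    reported for information, never candidates."""
    sets = []
    for df in (diff_pai, diff_lfq):
        sets.append(df[
            df["passes_filters"] & df["passes_fc"] & df["passes_p"] & (df["log2_fc"] < 0)
        ].set_index("protein_id"))
    common = sets[0].index.intersection(sets[1].index)
    return pd.DataFrame({
        "protein_id": common,
        "log2_fc_pai": sets[0].loc[common, "log2_fc"].to_numpy(),
        "log2_fc_lfq": sets[1].loc[common, "log2_fc"].to_numpy(),
    }).sort_values("protein_id").reset_index(drop=True)
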