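"""Median-of-ratios run normalization.

Systematic run-to-run intensity biases (sample loading, spray efficiency)
are removed by scaling every run to a reference run: for each run the
ratios ``intensity_run / intensity_ref`` are collected over the ions
quantified in both runs, and the run is divided by the median ratio.  The
reference run itself keeps a factor of exactly 1.  Ratios are taken on raw
(not log) intensities and summarized by the standard midpoint median.
Missing cells are left missing — this module never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import IonMatrix, ValidationError


@dataclass
class NormalizationResult:
    """Per-run scale factors against a reference run.

    ``factors[run]`` multiplies the run's intensities; the reference run's
    factor is exactly 1.  ``n_shared_ions[run]`` counts the ions quantified
    in both that run and the reference.
    """

    reference_run_id: str
    factors: dict[str, float]
    n_shared_ions: dict[str, int]

    def __post_init__(self) -> None:
        if self.factors.get(self.reference_run_id) != 1.0:
            raise ValidationError("reference run factor must be exactly 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValidationError("scale factors must be strictly positive")


class MedianRatioNormalizer(BaseEstimator, TransformerMixin):
    """Scale runs so their median shared-ion ratio to a reference run is 1.

    Parameters
    ----------
    reference_run : run id, or ``"auto"`` to pick the run with the most
        quantified ions (ties broken by lexicographically smallest run id).

    Attributes
    ----------
    reference_run_ : str
        The reference run actually used.
    scale_factors_ : pandas.Series
        Multiplicative factor per run (reference = 1).
    n_shared_ions_ : pandas.Series
        Shared-ion support per run.
    """

    def __init__(self, reference_run: str = "auto"):
        self.reference_run = reference_run

    def fit(self, X: IonMatrix, y=None) -> "MedianRatioNormalizer":
        inten = X.intensities
        ref = self.reference_run
        if ref == "auto":
            counts = inten.notna().sum(axis=0)
            best = counts.max()
            ref = min(r for r in X.run_ids if counts[r] == best)
        elif ref not in X.run_ids:
            raise ValidationError(f"reference run {ref!r} not in matrix")

        ref_vals = inten[ref]
        factors: dict[str, float] = {}
        shared: dict[str, int] = {}
        for run in X.run_ids:
            if run == ref:
                factors[run] = 1.0
                shared[run] = int(ref_vals.notna().sum())
                continue
            both = inten[run].notna() & ref_vals.notna()
            n = int(both.sum())
            if n == 0:
                raise ValidationError(
                    f"run {run!r} shares no quantified ions with reference {ref!r}"
                )
            ratios = (inten.loc[both, run] / ref_vals[both]).to_numpy()
            factors[run] = 1.0 / float(np.median(ratios))
            shared[run] = n

        self.reference_run_ = ref
        self.scale_factors_ = pd.Series(factors, name="scale_factor")
        self.n_shared_ions_ = pd.Series(shared, name="n_shared_ions")
        return self

    def transform(self, X: IonMatrix) -> IonMatrix:
        missing = set(X.run_ids) - set(self.scale_factors_.index)
        if missing:
            raise ValidationError(f"no scale factor for run(s) {sorted(missing)}")
        scaled = X.intensities * self.scale_factors_[X.run_ids]
        return IonMatrix(X.annotations.copy(), scaled, provenance="normalized")

    def result_(self) -> NormalizationResult:
        return NormalizationResult(
            self.reference_run_,
            self.scale_factors_.to_dict(),
            self.n_shared_ions_.to_dict(),
        )


def compute_normalization(
    matrix: IonMatrix, reference_run: str = "auto"
) -> NormalizationResult:
    """Median-of-ratios factors of every run against the reference."""
    return MedianRatioNormalizer(reference_run).fit(matrix).result_()


def apply_normalization(matrix: IonMatrix, result: NormalizationResult) -> IonMatrix:
    """Multiply each run by its factor; output provenance is ``normalized``."""
    norm = MedianRatioNormalizer(result.reference_run_id)
    norm.reference_run_ = result.reference_run_id
    norm.scale_factors_ = pd.Series(result.factors)
    norm.n_shared_ions_ = pd.Series(result.n_shared_ions)
    return norm.transform(matrix)
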