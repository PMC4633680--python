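"""Protein roll-up: Top-3 PAI oracle checks and pairwise-ratio LFQ solver."""

import itertools

import numpy as np
import pandas as pd
import pytest

from e3lfq import (
    IonMatrix,
    PairwiseRatioLFQ,
    Top3Quantifier,
    ValidationError,
    compute_lfq_profile,
    compute_pai,
    normalize_lfq_table,
    select_reference_peptides,
)
from conftest import make_matrix


def protein_matrix(values, run_ids=None, protein="P1"):
    """IonMatrix of one protein from a peptide × run intensity array."""
    values = np.asarray(values, dtype=float)
    run_ids = run_ids or [f"R{j}" for j in range(values.shape[1])]
    rows = [
        (protein, f"PEP{i:02d}K", 2, 500.0 + i, 10.0 + i,
         *[None if np.isnan(v) else v for v in values[i]])
        for i in range(values.shape[0])
    ]
    return make_matrix(rows, run_ids)


class TestReferenceSelection:
    def test_top_three_of_five(self):
        m = protein_matrix([[100], [80], [60], [40], [20]])
        keys = select_reference_peptides(m)
        assert [k[1] for k in keys] == ["PEP00K", "PEP01K", "PEP02K"]

    def test_two_peptides_both_selected(self):
        m = protein_matrix([[100], [80]])
        assert len(select_reference_peptides(m)) == 2

    def test_mean_ignores_missing_runs(self):
        # peptide 0: mean over observed runs = 90; peptide 1: 85 across both
        m = protein_matrix([[90, np.nan], [80, 90], [10, 10], [5, 5]])
        keys = select_reference_peptides(m)
        assert [k[1] for k in keys][:2] == ["PEP00K", "PEP01K"]

    def test_tie_broken_by_smallest_key_and_stable_under_shuffling(self):
        rows = [
            ("P1", "ZZZK", 2, 1.0, 1.0, 50.0),
            ("P1", "AAAK", 2, 2.0, 2.0, 50.0),
            ("P1", "MMMK", 2, 3.0, 3.0, 50.0),
            ("P1", "BBBK", 2, 4.0, 4.0, 90.0),
        ]
        expected = None
        for perm in itertools.permutations(range(4)):
            m = make_matrix([rows[i] for i in perm], ["A"])
            keys = select_reference_peptides(m)
            if expected is None:
                expected = keys
            assert keys == expected
        assert [k[1] for k in expected] == ["BBBK", "AAAK", "MMMK"]

    def test_no_quantified_ion_rejected(self):
        m = protein_matrix([[np.nan], [np.nan]])
        with pytest.raises(ValidationError, match="no quantified ion"):
            select_reference_peptides(m)


class TestComputePai:
    def test_mean_of_three(self):
        m = protein_matrix([[100], [80], [60]])
        pai = compute_pai(m, select_reference_peptides(m))
        assert pai["R0"] == pytest.approx(80.0)

    def test_single_peptide_protein(self):
        m = protein_matrix([[123.0, 456.0]])
        pai = compute_pai(m, select_reference_peptides(m))
        assert pai.tolist() == [123.0, 456.0]

    def test_linearity_in_run_scaling(self):
        vals = np.array([[100.0, 300.0], [80.0, 240.0], [60.0, 180.0], [10.0, 30.0]])
        m = protein_matrix(vals)
        pai = compute_pai(m, select_reference_peptides(m))
        assert pai["R1"] == pytest.approx(3.0 * pai["R0"])

    def test_run_with_no_reference_observed_is_missing(self):
        m = protein_matrix([[100.0, np.nan], [80.0, np.nan], [60.0, np.nan],
                            [1.0, 5.0]])
        pai = compute_pai(m, select_reference_peptides(m))
        assert np.isnan(pai["R1"])  # only non-reference peptide observed there


def brute_force_pai(values):
    """Independent oracle: sort all peptides by nan-mean, average top <=3
    observed per run."""
    import warnings

    values = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols
        means = np.nanmean(values, axis=1)
        order = np.argsort(-means, kind="stable")
        top = order[: min(3, np.sum(~np.isnan(means)))]
        top = [i for i in top if not np.isnan(means[i])]
        if not top:
            return np.full(values.shape[1], np.nan)
        return np.nanmean(values[top], axis=0)


class TestPaiOracle:
    def test_matches_brute_force_on_1000_random_proteins(self):
        rng = np.random.default_rng(13)
        quant = Top3Quantifier()
        for trial in range(1000):
            n_pep = rng.integers(1, 8)
            n_run = rng.integers(2, 7)
            vals = rng.lognormal(5, 2, size=(n_pep, n_run))
            vals[rng.random(vals.shape) < 0.25] = np.nan
            if np.isnan(vals).all(axis=1).all():
                continue
            # distinct means almost surely -> tie-breaking irrelevant here
            m = protein_matrix(vals)
            table = quant.fit(m).transform(m)
            expected = brute_force_pai(vals)
            got = table.abundances.loc["P1"].to_numpy()
            np.testing.assert_allclose(got, expected, rtol=1e-12, equal_nan=True)


class TestLfqProfile:
    def test_consistent_twofold_ratio_recovered(self):
        vals = np.array([[100.0, 200.0], [40.0, 80.0], [7.0, 14.0]])
        prof = compute_lfq_profile(protein_matrix(vals))
        assert prof["R1"] / prof["R0"] == pytest.approx(2.0, rel=1e-9)

    def test_median_of_discordant_peptide_ratios(self):
        """Peptide ratios 2 and 8 give pairwise log2 ratios 1 and 3; their
        median 2 makes the profile ratio 2**2 = 4."""
        vals = np.array([[100.0, 200.0], [100.0, 800.0]])
        prof = compute_lfq_profile(protein_matrix(vals))
        assert prof["R1"] / prof["R0"] == pytest.approx(4.0, rel=1e-9)

    def test_abundance_anchored_to_summed_intensity(self):
        vals = np.array([[100.0, 200.0], [40.0, 80.0]])
        prof = compute_lfq_profile(protein_matrix(vals))
        assert prof.sum() == pytest.approx(vals.sum(), rel=1e-9)

    def test_three_run_consistent_ratios_exact(self):
        base = np.array([50.0, 20.0, 5.0])
        scales = np.array([1.0, 3.0, 0.5])
        vals = base[:, None] * scales[None, :]
        prof = compute_lfq_profile(protein_matrix(vals))
        np.testing.assert_allclose(
            prof.to_numpy() / prof.iloc[0], scales / scales[0], rtol=1e-9
        )

    def test_against_brute_force_grid_on_three_runs(self):
        """The least-squares solution matches direct numerical minimization
        of the pairwise objective on 3-run instances (tol 1e-6)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(14)
        for _ in range(10):
            vals = rng.lognormal(4, 1, size=(4, 3))
            vals[rng.random(vals.shape) < 0.2] = np.nan
            m = protein_matrix(vals)
            try:
                prof = compute_lfq_profile(m)
            except ValidationError:
                continue
            if prof.isna().any():
                continue
            A = np.log2(vals)
            pairs = []
            for a in range(3):
                for b in range(a + 1, 3):
                    d = A[:, a] - A[:, b]
                    if np.sum(~np.isnan(d)) >= 1:
                        pairs.append((a, b, np.nanmedian(d)))

            def objective(x):
                return sum((x[a] - x[b] - r) ** 2 for a, b, r in pairs)

            res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            got = np.log2(prof.to_numpy())
            want = res.x
            # compare profiles up to the free additive constant
            np.testing.assert_allclose(
                got - got.mean(), want - want.mean(), atol=1e-6
            )

    def test_disconnected_runs_left_missing(self):
        # peptide 0 links R0-R1; peptide 1 observed only in R2: no pair
        vals = np.array([[10.0, 20.0, np.nan], [np.nan, np.nan, 5.0]])
        prof = compute_lfq_profile(protein_matrix(vals))
        assert not np.isnan(prof["R0"]) and not np.isnan(prof["R1"])
        assert np.isnan(prof["R2"])

    def test_single_run_observation_rejected(self):
        vals = np.array([[10.0, np.nan], [20.0, np.nan]])
        with pytest.raises(ValidationError, match=">= 2 runs"):
            compute_lfq_profile(protein_matrix(vals))


class TestLfqTable:
    def test_branch_table_matches_per_protein_profiles(self):
        rows = [
            ("P1", "AK", 2, 1.0, 1.0, 100.0, 200.0),
            ("P1", "CK", 2, 2.0, 2.0, 40.0, 80.0),
            ("P2", "DK", 2, 3.0, 3.0, 10.0, 10.0),
            ("P2", "EK", 2, 4.0, 4.0, 30.0, 30.0),
        ]
        m = make_matrix(rows, ["A", "B"])
        table = PairwiseRatioLFQ(normalize=False).fit(m).transform(m)
        for pid in ("P1", "P2"):
            prof = compute_lfq_profile(m.for_protein(pid))
            np.testing.assert_allclose(
                table.abundances.loc[pid].to_numpy(), prof.to_numpy(), rtol=1e-12
            )

    def test_normalize_equalizes_run_medians(self):
        rng = np.random.default_rng(15)
        rows = [
            (f"P{i}", f"PEP{i}K", 2, 1.0 + i, 1.0 + i,
             *rng.lognormal(4, 1, 3).tolist())
            for i in range(21)
        ]
        m = make_matrix(rows, ["A", "B", "C"])
        table = PairwiseRatioLFQ(normalize=False).fit(m).transform(m)
        out = normalize_lfq_table(table)
        med = out.abundances.median(axis=0)
        assert med.max() - med.min() < 1e-9 * med.max()

    def test_already_equal_medians_identity(self):
        rows = [
            ("P1", "AK", 2, 1.0, 1.0, 10.0, 10.0),
            ("P2", "CK", 2, 2.0, 2.0, 20.0, 20.0),
            ("P3", "DK", 2, 3.0, 3.0, 30.0, 30.0),
        ]
        m = make_matrix(rows, ["A", "B"])
        table = PairwiseRatioLFQ(normalize=False).fit(m).transform(m)
        out = normalize_lfq_table(table)
        pd.testing.assert_frame_equal(out.abundances, table.abundances)

    def test_uniformly_scaled_run_divided_back(self):
        rows = [
            (f"P{i}", f"PEP{i}K", 2, 1.0 + i, 1.0 + i, float(v), 3.0 * v)
            for i, v in enumerate([10.0, 20.0, 30.0])
        ]
        m = make_matrix(rows, ["A", "B"])
        table = PairwiseRatioLFQ(normalize=False).fit(m).transform(m)
        out = normalize_lfq_table(table)
        ratio = out.abundances["B"] / out.abundances["A"]
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-9)


class TestRatioConsistency:
    def test_both_branches_reproduce_uniform_peptide_ratio(self):
        """A protein whose every peptide carries KO/WT ratio 2 yields
        exactly 2 in both the PAI and the LFQ branch (noise-free)."""
        wt = np.array([100.0, 40.0, 7.0, 3.0])
        rows = [
            ("P1", f"PEP{i}K", 2, 1.0 + i, 1.0 + i, wt[i], wt[i], 2 * wt[i], 2 * wt[i])
            for i in range(4)
        ]
        m = make_matrix(rows, ["WT1", "WT2", "KO1", "KO2"])
        pai = Top3Quantifier().fit(m).transform(m).abundances.loc["P1"]
        lfq = PairwiseRatioLFQ(normalize=False).fit(m).transform(m).abundances.loc["P1"]
        for prof in (pai, lfq):
            assert prof["KO1"] / prof["WT1"] == pytest.approx(2.0, rel=1e-9)
            assert prof["KO2"] / prof["WT2"] == pytest.approx(2.0, rel=1e-9)
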