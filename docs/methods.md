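# Methods

`e3lfq` implements a label-free quantitative (LFQ) proteomics pipeline for
nominating substrates of an E3 ubiquitin ligase from a knockout (KO) vs
wild-type (WT) comparison. The biological logic: a ligase substrate is
degraded while the ligase is present, so its steady-state level rises when
the ligase gene is deleted. The pipeline therefore looks for proteins that
*accumulate* in the knockout consistently under two independent
quantitation strategies.

## Pipeline model

The input is a peptide-ion × run table of XIC (extracted ion current)
areas; each row is a peptide ion identified by `(protein, peptide
sequence, charge)` with m/z and retention-time annotations, each column a
LC-MS run. A study design maps runs to the WT or KO arm. Missing cells are
genuinely missing (the ion was not quantified in that run); zero is not a
valid intensity and is rejected on input. The pipeline never imputes.

Stages:

1. **Median-of-ratios normalization.** Each run r is rescaled by
   `1 / median_i(x_ir / x_i,ref)` over the ions i quantified in both r
   and a reference run. The reference defaults to the run with the most
   quantified ions (ties: lexicographically smallest run id); ratios are
   formed on raw intensities and summarized by the standard midpoint
   median. After application the median shared-ion ratio of every run to
   the reference is exactly 1, and the procedure is idempotent. The
   median over shared observed ions (rather than all ions) is used,
   because ratios are undefined for cells missing on either side.

2. **Protein roll-up, branch A — Top-3 protein abundance index (PAI).**
   For each protein the up-to-three peptide ions with the highest mean
   intensity across runs are fixed as *reference peptides*; "highest
   across samples" is operationalized as the highest mean over *observed*
   runs, so a peptide missing in a few runs is not penalized. The same
   reference list is used in every run; the per-run protein abundance is
   the arithmetic mean of the reference areas observed in that run. Exact
   intensity ties fall back to the smallest `(protein, peptide, charge)`
   tuple, making the selection invariant under row order. Proteins with
   one or two peptides use what they have.

3. **Protein roll-up, branch B — pairwise-ratio LFQ.** An independent
   estimator in the delayed-normalization style: for every run pair
   (a, b) sharing ≥1 observed peptide the statistic
   `r_ab = median_peptides log2(x_a / x_b)` is computed, and the per-run
   log2 abundances x solve the least-squares system `x_a − x_b ≈ r_ab`
   over all supported pairs. The solution's free additive constant is
   anchored so that the summed linear abundance over the solved runs
   equals their summed observed peptide intensity. Runs outside the
   largest connected component of the pair graph stay missing. The
   output table is column-rescaled so all per-run medians agree (the
   "median of all values" convention). This branch is an emulation of
   the published pairwise-ratio construction restricted to unique
   peptides — razor-peptide assignment is unnecessary because the
   synthetic data has unambiguous peptide-to-protein assignment; the
   minimum pair support (1 shared peptide) is a package choice.

4. **Filters and differential test.** Per branch, only proteins
   quantified by ≥2 peptides and with an abundance in *every* run are
   tested (both rules configurable). For each retained protein,
   `log2 FC = mean(log2 KO) − mean(log2 WT)` and a two-sided Welch
   unequal-variance t-test on log2 abundances; the volcano flags are
   `|log2 FC| > 0.85` (2^0.85 ≈ 1.80, the 1.8-fold rule) and `p < 0.05`.
   A Benjamini–Hochberg q-value column is emitted for information only
   and never enters candidate calling, matching the raw-p convention of
   the emulated analysis. Testing on the log2 scale was chosen because
   the volcano axes are log2 ratios and multiplicative noise is
   approximately log-normal. Degenerate zero-variance cases use fixed
   conventions: equal means → (t = 0, p = 1); unequal means with zero
   variance in both groups → signed infinite t and the smallest positive
   double as p. A Mann-Whitney flavor is available behind a flag.

5. **Dual-branch intersection and QC.** Candidates are the proteins that
   pass filters, fold-change and p cutoffs in *both* branches with
   log2 FC > 0 in both (accumulation in the KO); significantly depleted
   proteins are listed informationally but never called. QC outputs: the
   Venn counts of proteins quantified per branch; Pearson correlation of
   log2 abundances for every within-condition run pair (computed over
   proteins complete in that pair; pairs with <3 shared proteins yield a
   missing entry); and absent-marker detection — proteins with ≥1
   quantified peptide in every run of one condition and none in any run
   of the other, the pattern expected of the deleted ligase itself.
   Reports carry thresholds, seeds and input SHA-256 hashes, and a rerun
   with the same seed is byte-identical.

## Synthetic data generator

No public raw data accompanies the emulated experiment, so the generator
is a first-class module producing datasets plus ground truth. The
measurement model is the standard bottom-up LFQ abstraction:

    XIC[ion, run] = base[protein] × 2^fc (KO runs only) × response[ion]
                    × scale[run] × exp(ε),   ε ~ N(0, ln(1 + CV²))

with per-protein base abundances log-normal, a fixed per-peptide
"flyability" response shared across runs, one multiplicative loading bias
per run, and log-normal technical noise per measurement. Cells are
removed missing-completely-at-random at the configured rate (an optional
left-censored mode concentrates missingness on low intensities at the
same expected rate); absent-marker proteins are wiped to missing in their
empty condition, and kept observable in the other condition. Missingness
is MCAR by default because the completeness filter discards incomplete
proteins regardless of the mechanism.

Defaults define the study conditions: 2,000 background proteins with
2–12 peptide ions each; 3 WT vs 3 KO runs; base abundance ln-mean
ln(10⁶), ln-sd 1.5 (≈ 4 orders of magnitude dynamic range);
peptide-response ln-sd 1.0; technical CV 0.25 (a typical run-to-run
technical variability for label-free XIC areas; the within-condition
log2 signal variance ≈ 4.7 against a per-protein noise variance ≈ 0.04
then predicts replicate correlations ≈ 0.99, inside the ≥ 0.95 range
such experiments report); run scale biases drawn log-uniform in
[0.5, 2]; missing rate 0.05; two substrate spikes at the literature
filamin fold changes, FLNA-like at 7.10-fold and FLNB-like at 5.90-fold
(KO over WT); one ASB2α-like marker with no signal in the KO arm. The
within-condition variance of the emulated cell system is not published,
so the CV is a modelling constant, not a measured value.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: correlated biological replicate variation,
shared-peptide/razor protein inference, intensity-dependent (MNAR)
missingness by default, retention-time drift and misalignment,
interference/co-elution, and digestion or charge-state chemistry.

## Numerical and design choices

* Reference-run choice, tie-breaks and median conventions are fixed and
  deterministic, so all outputs are bit-reproducible from a seed.
* The pairwise LFQ solver uses `numpy.linalg.lstsq` on the
  pair-difference incidence system; the gauge freedom is removed by
  mean-centering before anchoring to the summed intensity. It agrees
  with brute-force minimization of the pairwise objective to < 1e-6 on
  small instances and with the 2-run closed form exactly.
* The PAI branch consumes median-of-ratios-normalized intensities
  (normalization precedes roll-up); the LFQ branch additionally applies
  its own median equalization on the protein table.
* When a reference peptide is missing in some run, the PAI for that run
  averages the remaining references; with widely differing peptide
  responses this inflates the apparent between-run variance of a protein.
  This is a faithful property of Top-N indices under missingness, and is
  the main reason the PAI branch occasionally loses a true spike at
  p < 0.05 (≈ 3–5% of seeds at the default conditions); the LFQ branch,
  whose pairwise ratios cancel peptide responses, is tighter.
* Welch's t-test at 3 vs 3 is conservative: its true type-I error at
  p < 0.05 under a Gaussian homoscedastic null is ≈ 0.033 (cross-checked
  against an independent R `t.test` oracle), not the nominal 0.05,
  because the Welch–Satterthwaite degrees of freedom are estimated and
  ≤ 4. The pooled-variance option attains ≈ 0.049 under equal variances.
  Welch remains the default as the safer choice under variance
  heterogeneity between genotypes.
* Cross-run ion matching is key-based (identities travel with exported
  tables); an m/z-ppm + retention-time window mode (defaults 5 ppm,
  0.5 min) merges keyless same-protein ions. Raw-data re-alignment and
  predicted-RT transfer are upstream concerns and out of scope, as are
  spectrum processing, database search and FDR control.

## Problem sizes used in the shipped checks

The end-to-end Monte-Carlo suites run the full default-condition pipeline
over 100 seeds (recovery and effect-size checks), 10 seeds for the
replicate-correlation QC, 10,000 simulated null proteins for test
calibration, and 1,000 random proteins for the Top-3 oracle comparison —
sizes at which the Monte-Carlo error is small relative to every asserted
margin while a full run stays in the minutes range on a single core.

## Known limitations

* Protein inference from shared peptides is not performed; every peptide
  is assumed unique to its protein, which holds for the synthetic data
  but not for real search results.
* The completeness filter (`quantitative data in all experiments`)
  discards proteins with any missing run, which biases the tested set
  toward abundant proteins; the absent-marker detector exists precisely
  to surface the most extreme such exclusions.
* No moderated variance estimation or permutation FDR; candidate calling
  uses raw p-values by design, inheriting that convention's liberality
  at small n (counterbalanced by the dual-branch intersection and the
  fold-change floor).
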