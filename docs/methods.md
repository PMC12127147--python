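# Methods

## Differential probe calling

For each probe the reference is the mean beta over non-missing matched
normals (probes with no observed normal are excluded). A tumor cell is
called hypermethylated when `beta − normal_mean ≥ 0.2` **and**
`normal_mean < 0.3`, hypomethylated when `normal_mean − beta ≥ 0.2` **and**
`normal_mean > 0.7`. The deviation threshold is inclusive (`≥ 0.2`); the
recurrence filter is strict (a probe keeps its calls only when flagged in
`> min_frac` of tumors, default 0.05 for array cohorts and 0.10 for
cell-line panels). The recurrence rule is motivated for hypermethylated
probes; we apply it symmetrically to hypomethylated probes
(`apply_to=("hyper",)` disables that) because the same atypical-sample
argument holds. Missing tumor betas are never imputed and never produce a
call. Burdens `N_hyper` / `N_hypo` are the per-sample counts of surviving
flags.

Under the linear purity-mixing model
`observed = purity·pure + (1 − purity)·normal + ε`, a planted pure-tumor
shift `e` produces an observed deviation `purity·e`, so it is callable iff
`purity·e ≥ 0.2` at ε = 0 — the attenuation law the tests verify on a
purity grid.

## Purity-confounding simulation

Patterns are generated in quadrant I with `ΔV1 ~ U(0, range)`:

* **POS** — `ΔV2 = ΔV1 + U(−0.1, 0.1)·range`, clipped at 0;
* **N1** — `ΔV2 = range − ΔV1 + residue`, clipped at 0. The negative rule
  needs an intercept to stay in quadrant I; we use the upper bound of the
  ΔV1 range (anti-diagonal), which keeps both variables spanning the same
  positive range;
* **N2 / N3** — 70% / 30% of points follow the N1 rule; the rest draw both
  coordinates independently from a truncated normal at ≥ 0 with mean
  `0.1·range` and SD `0.05·range` (small changes near the origin; the
  moments of this component are a design choice exposed in `SimConfig`).

A shared purity `U(0.1, 1)` is drawn per point and multiplies both
variables; the purity stream is seeded independently of the latent stream so
changing purity bounds never changes the latent draw. All quantities scale
with `range`, making every correlation scale-invariant (tested at ×10).

With n = 100 and 25–50 seeds, the mean correlations are: POS latent 0.981,
POS observed 0.988, N1 latent −0.981, N1 observed −0.290, N1 window-filtered
−0.70 ± 0.03, N2 window-filtered −0.16. The N1 observed value has the
closed form −0.293 under this generative model
(`corr(p·u, p·(1−u))` with `u ~ U(0,1)`, `p ~ U(0.1,1)`); its seed-to-seed
SD at n = 100 is 0.08, so single-realization values between −0.45 and −0.15
are routine. The N2 filtered value depends strongly on the admixture
component's moments, which are open parameters here.

## Narrowest purity window

A variable-width window slides over [0, 1] on a 0.01 grid; the smallest
closed interval containing at least `⌈coverage·n⌉` samples (default
coverage 0.5) wins, and among equal-width candidates the one with the larger
lower bound is chosen. Windows are closed on both ends; endpoints lie on the
grid while the purity values themselves are not rounded; missing purities
are dropped before counting. The implementation is checked against an
exhaustive enumeration over all grid pairs. Downstream correlation uses
in-window samples by default; `mode="above_lo"` additionally keeps all
higher-purity samples, since the survival exclusion removes only samples
*below* the window's lower bound.

## Burden stratification and survival

Burden counts span orders of magnitude, so the two-component 1-D Gaussian EM
runs on `log10(count + 1)` with deterministic initialisation (means at the
25th/75th percentiles, shared overall variance, equal weights), a variance
floor of 1e−6 and a relative log-likelihood tolerance of 1e−8. The trace is
non-decreasing by construction: the loop stops rather than record a decrease
that a floored variance could otherwise cause. Zero-variance input yields a
degenerate single-label fit flagged `converged=False`. The component with
the larger mean is "high"; hard labels take the larger responsibility.

Two independent EM fits map to four categories: (high, low) → hyper,
(low, high) → hypo, (high, high) → intermediate, (low, low) → control.
Pattern labels per cancer type come from the HighEpiMut fraction: N1 at
≥ 0.8, N2 at ≥ 0.4, N3 below (both boundaries inclusive upward). LowEpiMut
selection for N2/N3 cohorts takes the bottom 70% / 30% by the score
`N_hyper + k·N_hypo` (k = 4 for N2, 2 for N3), ties broken by smaller score
then lexicographic sample id so the selection is deterministic; samples with
purity strictly below the window's lower bound are removed from the
LowEpiMut set (not relabelled). Kaplan–Meier estimation and the two-group
log-rank test are delegated to `lifelines`; the tests validate them against
hand-computed product-limit and hypergeometric O/E/V tables.

## Epi-allele analysis (RIN-hyper)

Reads come from Bismark-dialect SAM: only `Z`/`z` symbols of the `XM` string
count (CpG context); calls are projected to reference coordinates through
the CIGAR (M/I/D/S/=/X supported), so calls inside soft clips or insertions
never count, and a call at reference position p belongs to a region iff
`start ≤ p < end`. Reads with fewer than `min_cpg` in-region CpGs are
dropped; the default `min_cpg = 4` is the smallest count for which the open
interval (0.5, 0.9) used below is populatable at all read compositions, and
it is configurable: there is no canonical value for this cutoff.

Per-read methylation `m = n_meth / n_cpg` is binned into width-0.1 bins,
left-closed with the last bin closed. RIN-hyper is
`#{0.5 < m < 0.9} / #{m > 0.9}` with strict bounds exactly as defined —
m = 0.5 and m = 0.9 belong to neither class — and is *undefined* (a value
state, not an exception) when no read exceeds 0.9. The sample-level
aggregate defaults to pooling all reads over the listed hypermethylated
regions; a per-region-median mode is provided as a robust alternative when
region coverage is very uneven.

Under the read generator's mechanism (fully methylated alleles whose CpGs
flip independently with probability λ), the flip count is Binomial(k, λ),
giving the exact prediction RIN-hyper = P(2 ≤ flips ≤ 4)/P(0 flips) at
k = 10 — e.g. 5.51 at λ = 0.2 — which the chain from SAM emission through
parsing to the statistic reproduces within sampling error.

## Association and biomarker machinery

Correlations are Pearson (t-distributed p, n − 2 df) or Spearman (average
ranks, t approximation) with pairwise-complete missing handling; zero
variance yields a flagged undefined result. No multiple-testing correction
is applied by default because the affected/not-affected rule is stated on
raw P < .05. Partial R² is `(SSE_reduced − SSE_full)/SSE_reduced` from
intercept-including least squares, equal to the squared partial correlation
(tested to 1e−8) and to a normal-equations oracle (1e−10). Marker classes:
affected iff `r < −0.3` and `p < .05`; not affected iff `r > −0.1`; else
intermediate. Panel scores are pairwise-missing-aware row means; AUC is the
Mann–Whitney statistic with ties counted 1/2. The combined cfDNA score is
`mean(hyper panel) − mean(hypo panel)` so both signals point the same way;
evaluating panels jointly is this package's choice.

## Synthetic-data generators

`synth_cohort` draws bimodal normal means (hyperable probes U(0.05, 0.25),
hypoable U(0.75, 0.95), the rest U(0.05, 0.95)), latent burden multipliers
`b ∈ [0.3, 1]` for high-burden samples coupled through a Gaussian copula
(coupling −1 makes them exactly antitone), and a low-burden subpopulation
(30% for pattern N2, 70% for N3) with multipliers from a truncated normal at
10% of the high-burden mean (SD 5% of it). A planted probe is active in a
sample with probability `b`, so `b` scales the *fraction* of the planted set
the sample carries; a multiplier on the effect size alone would make called
counts a step function of `b` and could not produce graded burdens or the
triangle pattern. Observation noise is truncated Gaussian on the beta scale
(clip to [0, 1]) rather than beta-distributed: the calling rule is a scale
threshold, so the noise family is not critical and a controllable SD is
worth more. The truth table records latent multipliers, purity, subtype and
the noise-free expected call matrix.

`synth_reads` plants `cpgs_per_read` CpGs at 10-bp spacing per region and
emits every read spanning all of them, with correct XM strings, so the SAM
parser can be validated against the exact per-read truth. `synth_survival`
uses exponential event and censoring clocks (hazard ratio on the HighEpiMut
group). `synth_cfdna` couples each cancer sample's maintenance-loss level to
its marker shifts: hyper-marker shifts scale with `1 − 0.8·loss`, hypo
shifts with `loss` itself (baseline loss 0.2 for maintenance-intact tumors),
so each panel is blind to the tumors the other detects — the scenario in
which combining panels pays.

What these generators do **not** emulate: probe-level covariance and batch
structure, realistic genomic composition or copy number, read-quality
artifacts, non-exponential hazards, and purity-estimation error (purity is
known exactly to the generator). Passing tests therefore demonstrate
correctness of the algorithms under the stated generative models, not
performance on any particular clinical cohort.

## Problem sizes

The test suite uses cohorts of 10–120 tumors over 200–2000 probes, 2,000–
24,000 reads per RIN-hyper experiment, and 20–500 seeds per Monte-Carlo
check; the simulation study itself runs 100-point patterns over 25–50
seeds. These sizes put every Monte-Carlo standard error well inside the
asserted tolerances while keeping the whole suite under a minute.

## Known limitations

* The EM is univariate with exactly two components; multi-modal burden
  distributions get a best two-way split.
* The log-rank implementation handles exactly two groups.
* `read_bismark_sam` supports SAM text only (no BAM/CRAM) and rejects
  spliced (N) or hard-clipped CIGARs.
* The N2/N3 admixture moments and the per-sample HighEpiMut definition are
  genuinely open modelling choices; the defaults are documented above and
  exposed in configuration.
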