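# methet

Analysis toolkit for the heterogeneity of CpG-island (CGI) hypermethylation
in tumors, and for the question of whether impaired DNA-methylation
maintenance attenuates it.

## The problem

CGI hypermethylation and genome-wide hypomethylation are both hallmarks of
cancer. If hypomethylation reflects failing methylation maintenance, tumors
with severe maintenance loss should also show *eroded* CGI hypermethylation —
a negative correlation between the per-sample hypermethylation burden and the
hypomethylation burden. Detecting that association in bulk tumor data is
confounded twice:

1. **Tumor purity.** A bulk sample is a mix of cancer and non-cancer cells,
   so every methylation change is scaled by the same purity factor. A shared
   multiplicative factor barely disturbs positive correlations but collapses
   negative ones into a "lower-left triangle" scatter.
2. **Low-epi-mutation subpopulations.** Cancer types that mix
   high-epi-mutation tumors with near-normal tumors add a mass of points at
   the origin that masks, or even flips, the within-subtype association.

`methet` implements the full workflow for studying this on methylation-array
cohorts and bisulfite reads, plus synthetic-data generators with ground
truth for every stage.

## What it computes

* **Differential probes and burdens** (`diffmeth`): a tumor probe is
  hypermethylated when `beta − mean(normals) ≥ 0.2` with `mean(normals) < 0.3`
  (hypomethylated symmetrically with `mean > 0.7`); a recurrence filter keeps
  only probes flagged in `> 5%` of tumors (`> 10%` for cell-line panels).
  Per-sample burdens are the call counts `N_hyper`, `N_hypo`.
* **Purity-confounding simulation** (`confound_sim`): paired changes
  `(ΔV1, ΔV2)` in quadrant I under positive, negative (N1), or admixture
  (N2/N3) rules, multiplied by a shared purity `U(0.1, 1)`, with Pearson
  correlations of the latent, observed and purity-filtered pairs.
* **Narrowest purity window** (`purity_window`): the smallest closed interval
  on a 0.01 grid containing at least half the samples (ties resolved toward
  higher purity), used to filter samples instead of regressing purity out.
* **Burden stratification and survival** (`stratify`): deterministic 1-D
  two-component Gaussian EM on `log10(count + 1)`; four patient categories
  (hyper / hypo / intermediate / control) from two independent EM fits;
  pattern N1/N2/N3 per cancer type from the HighEpiMut fraction (thresholds
  0.8 / 0.4); LowEpiMut selection by the weighted score
  `N_hyper + 4·N_hypo` (N2) or `N_hyper + 2·N_hypo` (N3); Kaplan–Meier
  curves and the two-group log-rank test.
* **Epi-allele heterogeneity** (`mehist`): per-read mean CpG methylation `m`
  from Bismark `XM` strings projected through the CIGAR, per-CGI histograms,
  and **RIN-hyper** = (#reads with 0.5 < m < 0.9) / (#reads with m > 0.9) —
  the ratio of incompletely to fully methylated epi-alleles.
* **Biomarker assessment** (`assoc`): markers whose betas correlate with
  global hypomethylation at Pearson `r < −0.3, P < .05` are *affected* by
  maintenance loss (`r > −0.1` = not affected); panel means and Mann–Whitney
  AUC for cfDNA cancer-vs-control discrimination; partial R² by nested OLS;
  mean-Z gene-signature scores.

## Worked example

A synthetic pattern-N1 cohort (120 tumors, purity ~ U(0.3, 1), 500 planted
hyper and 500 planted hypo probes, perfectly anticorrelated latent burdens):

```python
from methet import (CohortSpec, synth_cohort, normal_reference, call_probes,
                    recurrence_filter, burden, correlate, narrowest_window,
                    select_samples, classify_epimut, synth_survival, logrank)

spec = CohortSpec(n_tumor=120, n_normal=20, n_probes=2000,
                  effect_hyper=0.5, effect_hypo=0.5,
                  burden_pattern="N1", purity_dist=(0.3, 1.0), seed=7)
tumors, normals, samples, truth = synth_cohort(spec)

calls = recurrence_filter(call_probes(tumors, normal_reference(normals)), 0.05)
burdens = burden(calls)
print(correlate(burdens["N_hyper"], burdens["N_hypo"]).r)     # -0.145

w = narrowest_window(samples["purity"])                       # [0.68, 1.0]
inside = select_samples(samples, w)
print(correlate(burdens.loc[inside, "N_hyper"],
                burdens.loc[inside, "N_hypo"]).r)             # -0.991

labels = classify_epimut(burdens, method="em_total")
surv = synth_survival(labels, hazard_ratio=2.0, censor_rate=2.5e-4, seed=7)
print(logrank(surv["time"], surv["event"], labels.to_numpy()))
# (5.78, 0.0162)
```

Across all samples the truly perfect negative coupling is invisible
(r = −0.145) because purity scales both burdens together; restricting to the
61 samples inside the narrowest half-coverage purity window recovers it
almost exactly (r = −0.991). The log-rank test then confirms the planted
survival difference between the high- and low-burden groups
(χ² = 5.78, p = 0.016).

The same operations are available from the shell:

```bash
methet simulate --pattern N1 --seeds 20
methet call --tumors T.tsv --normals N.tsv --min-frac 0.05 --out calls
methet purity-window --samples samples.tsv
methet mehist --sam reads.sam --regions cgi.bed --min-cpg 4
```

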