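# genestrat

Genetically stratified survival analysis: estimating the frequency and
clinical phenotype of a latent disease subgroup by polygenic stratification
and subtraction.

## The problem

Type 1 diabetes presenting in middle age is routinely misdiagnosed as type 2
diabetes: after age 30 it is a small minority of new diabetes, and antibody
or C-peptide testing at that prevalence yields as many false positives as
true ones. `genestrat` implements a population-level answer for
epidemiologists and statistical geneticists working with biobank-scale
cohorts. Because type 1 genetic susceptibility does not predispose to type 2
diabetes, splitting a cohort at the median of a type 1 genetic risk score
(GRS) leaves type 2 cases equally distributed across the halves, while
nearly all type 1 cases land in the high half. The number of type 1 cases is
then the **excess**:

    n_T1D = n_H − n_L

where n_H and n_L are diabetes case counts in the high- and low-score halves
(from Kaplan-Meier comparison on the age timescale, censored at study entry
and at age 60). The clinical characteristics of this latent group — which is
never identified individual-by-individual — follow by moment subtraction:

    x̄_T1D = (n_H x̄_H − n_L x̄_L) / n_T1D

with SDs recovered the same way from second moments, and categorical
characteristics as per-category count excesses.

The package provides: GRS computation (additive ln-OR weights plus a
non-additive HLA diplotype term from two tag SNPs) with Hardy-Weinberg QC;
median stratification; product-limit survival with the censoring rules
above; the excess estimator overall, by age band, cumulatively, and by
decade; derived clinical summaries with bootstrap CIs and Welch/chi-square
comparisons; and a seeded synthetic-cohort generator with truth labels,
since real biobank data is access-restricted. See `docs/methods.md` for the
model, assumptions, and defaults.

## Worked example

```python
import numpy as np
from genestrat import (SimulationConfig, simulate_cohort, compute_grs,
                       split_by_median, excess_estimate)
from genestrat.characteristics import derive_group

synth = simulate_cohort(SimulationConfig(n_individuals=100_000, rng_seed=42))
scores = compute_grs(synth.genotypes, synth.weights)
strat = split_by_median(scores, synth.cohort)
est = excess_estimate(strat, rng=np.random.default_rng(42))
```

Printing the fields of `est` (and the derived 31–60-band BMI from
`derive_group`) gives:

```
groups: high n=50000, low n=50000, median cutoff 5.440
cases: high 1883, low 1580, total 3463
excess (genetically defined type 1): 303
share of all diabetes: 8.7% (95% CI 5.6-12.2)
 band  excess  total  share_of_excess_pct  share_of_band_total_pct
 0-30     182    582                 60.1                     31.3
31-60     121   2881                 39.9                      4.2
truth: 344 type 1, expected excess 316
derived BMI, onset 31-60: 26.0 kg/m2 (95% CI 20.3-31.0); configured type 1 mean 27.4
```

Reading this: the cohort truly contains 344 type 1 individuals; with 4% of
them scoring below the median, the subtraction's expected yield is
(1 − 2×0.04) × 344 ≈ 316, and the estimate 303 (8.7% of all diabetes) is
within sampling noise of that. The band rows show most type 1 diagnosed by
30 but a substantial minority at 31–60, where it is only ~4% of all
diabetes — the hard-to-spot group the method exists to count. The derived
BMI of that group recovers the simulated type 1 class mean rather than the
much higher type 2 mean.

Command-line equivalents:

```sh
genestrat simulate --seed 42 --n 100000 --out-dir sim/
genestrat run --weights sim/weights.tsv --genotypes sim/genotypes.tsv \
              --cohort sim/cohort.csv --out results/ --seed 42
genestrat figures results/
```

`run` writes `scores.csv`, `hwe.csv`, `lifetable.csv`, `excess_overall.csv`,
`excess_by_band.csv`, `cumulative_excess.csv`, `incidence_by_decade.csv`,
`table1.csv`, `table2.csv`, and `manifest.json`; reruns with the same inputs
and seed are byte-identical.

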