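# m6asig

N6-methyladenosine (m6A) is the most abundant internal modification of
eukaryotic mRNA. It is deposited by *writer* methyltransferases (METTL3,
METTL14), recognized by *reader* proteins (YTHDF1/2/3), and removed by
*eraser* demethylases (ALKBH5, FTO). In gastric cancer, the balance of
these regulators carries prognostic information: patients whose tumors
express low writers/readers or high erasers — i.e. tumors with a low
expected m6A level — show more driver-gene mutations, more diffuse
histology, and worse overall survival.

`m6asig` implements this signature analysis as a tested, reusable Python
pipeline for anyone working with tumor expression cohorts (protein
intensities or normalized RNA quantities) plus clinical and mutation
tables. It covers:

- **Signatures** — per-patient W/R/E values as geometric means of each
  regulator group: `W = (METTL3 · METTL14)^{1/2}`,
  `R = (YTHDF1 · YTHDF2 · YTHDF3)^{1/3}`, `E = (ALKBH5 · FTO)^{1/2}`.
- **Stratification** — median dichotomization into seven schemes: single
  (`W`, `R`, `E`), double 2×2 crosses (`WE`, `RE`, `WR`), and the
  six-group triple scheme `WRE` keyed by how many of W/R are high
  (double-low `dL`, single-high `sH`, double-high `dH`) crossed with the E
  level. Each stratum maps to an m6A *indication*: exactly seven labels
  (W^L, R^L, E^H, W^L E^H, R^L E^H, W^L R^L, WR^dL E^H) indicate low m6A,
  their seven mirror images indicate high m6A, all others are
  intermediate. A minimum-log-rank-P cutoff scan is provided as an
  alternative to the median split.
- **Survival** — Kaplan–Meier curves and the k-group log-rank test with
  per-group observed/expected events.
- **Association** — smoothed mutation-frequency fold changes (low- vs
  high-indication) with cross-cohort UP/DN consensus calls, exact-variant
  frequencies (e.g. CDH1 p.D254Y), Fisher/chi-square/Monte-Carlo exact
  contingency tests for clinical indexes, and Welch t comparisons for TMB.
- **Enrichment** — per-gene differential expression, Venn overlap counts,
  and a self-contained phenotype-permutation GSEA engine (signal-to-noise
  ranking, weighted-KS enrichment score, NES, nominal P, signed-pool FDR).
- **Synthetic cohorts** — a seeded generator in which one latent m6A level
  drives regulator expression (writers/readers load positively, erasers
  negatively), exponential survival (hazard ratio for the low-m6A
  tertile), driver-mutation odds, clinical covariates and an
  anti-correlated "oncogenic" gene set — so the whole pipeline is testable
  end to end with known ground truth.

## Worked example

```python
from m6asig import (SimulationParams, generate_cohort, compute_wre,
                    stratify_all, compare_strata_survival)

cohort = generate_cohort(SimulationParams(seed=1))   # n = 600 patients
sig = compute_wre(cohort.expression)
print(sig.data.corr().round(2))
#       W     R     E
# W  1.00  0.52 -0.46
# R  0.52  1.00 -0.48
# E -0.46 -0.48  1.00

wre = stratify_all(sig)["WRE"]
res, curves = compare_strata_survival(
    cohort.clinical, wre, pair=("WR^dL E^H", "WR^dH E^L"))
print(f"log-rank P = {res.p_value:.2e}")
# log-rank P = 9.48e-08
print({k: round(c.median, 1) for k, c in curves.items()})
# {'WR^dH E^L': 23.0, 'WR^dL E^H': 10.7}
```

Writers and readers correlate positively with each other and negatively
with erasers, as built into the simulated cohort; the
writer/reader-double-high eraser-low corner (highest expected m6A) roughly
doubles the median overall survival of the opposite corner, and the
two-group log-rank test is decisively significant.

The same stages run from the shell:

```sh
m6asig simulate --seed 1 --out cohort/
m6asig run-all --seed 1 --n-perm 1000 --out results/
```

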