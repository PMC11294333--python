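# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` implements a complete bidirectional two-sample Mendelian
randomization (MR) workflow for epidemiologists working from GWAS summary
statistics: instrument selection, effect-allele harmonization, six causal
estimators, heterogeneity and pleiotropy diagnostics, MR-PRESSO outlier
detection, multivariable MR with conditional instrument strength, and
analytic power for binary outcomes. A synthetic-data generator with known
ground truth makes every stage testable without access to any GWAS
database.

## The model

Each SNP *j* provides an estimated effect on the exposure
(β̂<sub>Xj</sub>, σ<sub>Xj</sub>) and on the outcome
(β̂<sub>Yj</sub>, σ<sub>Yj</sub>), measured in two non-overlapping
samples. If the SNP is a valid instrument, β<sub>Yj</sub> = θ·β<sub>Xj</sub>
for the causal effect θ (a log odds ratio for binary outcomes). The
estimators differ in how they pool the per-SNP Wald ratios
β̂<sub>Yj</sub>/β̂<sub>Xj</sub> and in which violations they tolerate:

* **IVW** — inverse-variance-weighted mean with weights
  w<sub>j</sub> = β̂²<sub>Xj</sub>/σ²<sub>Yj</sub>; equivalent to weighted
  least squares of β̂<sub>Y</sub> on β̂<sub>X</sub> through the origin.
  Cochran's Q drives the fixed- vs multiplicative-random-effects choice
  (fixed iff the Q p-value exceeds 0.05).
* **MR-Egger** — the same regression with an intercept, which estimates
  average directional pleiotropy; inference uses t(k−2) with the residual
  dispersion floored at 1.
* **Weighted / simple median** — the ratio at 50% cumulative weight,
  consistent when at least half the weight comes from valid instruments;
  SE by seeded parametric bootstrap.
* **Simple / weighted mode** — the peak of a normal-kernel density over
  the ratios; consistent when the largest group of instruments is valid.
* **MR-PRESSO** — a leave-one-out residual-sum-of-squares test with a
  parametric simulated null: a global pleiotropy p-value, Bonferroni
  per-SNP outlier flags, and a distortion test for the estimate shift
  after outlier removal.

Instrument strength is reported per SNP as F = β²/σ² and in aggregate as
F = ((N−K−1)/K)·R²/(1−R²) with R² = Σ<sub>j</sub> 2·eaf<sub>j</sub>(1−eaf<sub>j</sub>)β²<sub>j</sub>.
Multivariable MR regresses outcome effects jointly on several exposures'
effects to adjust for measured pleiotropic pathways; instrument strength
there is conditional (each exposure residualised on the others).

## Worked example

Simulate a study-scale dataset (80 genome-wide-significant instruments,
true OR 1.41, exposure N = 602,604, outcome N = 97,173, 17.5% palindromic
SNPs) and run the full pipeline:

```python
from tsmr import SimulationConfig, simulate_pair, analyze_pair, PowerSpec

config = SimulationConfig(seed=7)          # study-scale defaults
exposure, outcome, truth = simulate_pair(config)
bundle = analyze_pair(
    exposure, outcome,
    power=PowerSpec(n_cases=22_350, n_controls=74_823),
    presso_nb=1000, n_boot=500, seed=7,
)
print(bundle.report.to_string())
cols = ["method", "nsnp", "or", "or_ci_low", "or_ci_high", "pval", "model"]
print(bundle.estimates_frame[cols].round(3).to_string(index=False))
```

prints

```
shared                    80
flipped                   38
palindromic               15
dropped_palindromic       15
excluded_outcome_assoc    13
excluded_outlier           0
incompatible_alleles       0
kept                      52

         method  nsnp    or  or_ci_low  or_ci_high  pval model
            ivw    52 1.384      1.342       1.427   0.0 fixed
       mr_egger    52 1.434      1.335       1.539   0.0  None
weighted_median    52 1.382      1.324       1.443   0.0  None
    simple_mode    52 1.378      1.275       1.489   0.0  None
  weighted_mode    52 1.379      1.304       1.459   0.0  None

Cochran's Q = 40.45 (df 51, p = 0.855) -> fixed effects
Egger intercept = -0.0019 (p = 0.29) -> no-pleiotropy-evidence
total R^2 = 0.0416, total F = 502.8
power at the fitted OR: 100.0%
```

Of the 80 shared SNPs, 15 palindromic SNPs are dropped and 13 SNPs that
are themselves genome-wide outcome hits are excluded (they violate the
exclusion restriction), leaving 52 instruments. Every estimator recovers
an OR close to the simulated 1.41; the homogeneous Q selects fixed
effects and the Egger intercept shows no pleiotropy — which is correct,
since none was simulated.

The same workflow is available from the shell:

```sh
tsmr simulate --seed 7 --out-dir sim/
tsmr run --config analysis.yaml
tsmr power --n 97173 --r2 0.0282 --or 1.41 --case-frac 0.23
```

(`tsmr --help` lists all verbs: convert, select, harmonize, estimate,
sensitivity, presso, run, bidirectional, mvmr, simulate, power. Exit
codes: 0 success, 2 configuration error, 3 insufficient instruments.)

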