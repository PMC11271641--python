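# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of one trait (an *exposure*, e.g. a
psychiatric disorder) on another (an *outcome*, e.g. a digestive-tract
cancer) using only published GWAS summary statistics, the setting known as
two-sample Mendelian randomization (MR). Genetic variants (SNPs) strongly
associated with the exposure serve as instrumental variables: because
alleles are assigned at meiosis, their downstream associations with the
outcome are protected from confounding and reverse causation, provided the
instruments are valid.

It is aimed at genetic epidemiologists who have exposure and outcome
summary tables (one row per SNP: alleles, effect-allele frequency, beta,
SE, p, n) and want the full analysis battery reproducibly: instrument
selection, harmonization, estimation, sensitivity diagnostics and
multiple-testing correction — plus a ground-truth simulator so every step
is testable without downloading any GWAS data.

## Model

For SNP *j*, let β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) be its effect on the
exposure and β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) its effect on the outcome,
both expressed per copy of the same effect allele after harmonization. Each
SNP yields a Wald ratio θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub> with
first-order SE σ<sub>Yj</sub>/|β̂<sub>Xj</sub>|.

- **IVW**: β̂ = Σw<sub>j</sub>θ̂<sub>j</sub> / Σw<sub>j</sub> with
  w<sub>j</sub> = 1/se(θ̂<sub>j</sub>)²; fixed-effect SE 1/√Σw<sub>j</sub>,
  inflated multiplicatively by √(Q/(k−1)) when Cochran's Q indicates
  heterogeneity (the fixed/random switch at Q-test p = 0.05).
- **MR-Egger**: weighted regression β̂<sub>Yj</sub> = α + β·β̂<sub>Xj</sub>
  (weights 1/σ<sub>Yj</sub>²) after orienting every SNP to β̂<sub>Xj</sub> ≥ 0.
  The intercept α estimates average directional pleiotropy; the slope is a
  pleiotropy-robust causal estimate under the InSIDE assumption.
- **Weighted median**: the interpolated 50th percentile of the weighted
  empirical distribution of the θ̂<sub>j</sub>; consistent while valid
  instruments carry > 50 % of the weight. SE by seeded parametric bootstrap.

Instrument quality uses R² = 2·EAF·(1−EAF)·β² and
F = R²(n−k−1)/[k(1−R²)], with F > 10 marking a strong instrument.
Diagnostics: Cochran's Q, the Egger intercept test, leave-one-out
re-estimation, funnel-plot data with a weighted-skewness asymmetry summary,
and an MR-PRESSO-style residual-sum-of-squares global/outlier test with
Monte-Carlo p-values. Effects are reported as odds ratios with 95 % CIs;
IVW p-values are adjusted across each hypothesis family by
Benjamini-Hochberg FDR and Bonferroni.

## Worked example

Simulate a panic-disorder-sized exposure (13 instruments, effective
n ≈ 7,000) against a colorectal-cancer-sized outcome (effective n ≈ 2,500)
with a protective causal effect of −0.25 log-odds (true OR 0.78), then
estimate:

```sh
mr simulate --n-snps 13 --causal-beta -0.25 --seed 7 \
   --out-exposure pd.tsv --out-outcome crc.tsv
mr estimate --exposure pd.tsv --outcome crc.tsv --p-threshold 5e-6 --n-boot 1000 --seed 1
```

prints

```
method           n_snps      OR          95% CI       P
ivw_fixed             9    0.80   0.69-0.92      0.0026
egger                 9    1.61   0.76-3.41        0.26
weighted_median       9    0.80   0.65-0.97       0.027
```

Nine of the 13 simulated SNPs pass the relaxed significance threshold
(p < 5×10⁻⁶) used for small exposure GWAS. IVW and the weighted median both
recover the protective effect (true OR 0.78) with CIs excluding 1; MR-Egger,
which spends one degree of freedom on its intercept, is far less precise
here — exactly the behaviour expected with few instruments of similar
strength. A multi-pair study (many exposures × outcomes, exclusion lists,
LD tables, correction families) runs from a YAML config via `mr run
--config study.yaml`; see `python -m tsmr.cli --help` and the
`tsmr.pipeline` module docstring for the schema.

The same API is available in Python (`tsmr.read_summary_stats`,
`tsmr.harmonize`, `tsmr.ivw`, `tsmr.mr_egger`, `tsmr.weighted_median`,
`tsmr.sensitivity_report`, …).

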