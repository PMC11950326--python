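# socthresh

Threshold meta-analysis of nitrogen-fertilization effects on soil organic
carbon fractions, with site-level functional-carbon indices.

## The problem

Nitrogen fertilization changes soil organic carbon (SOC) unpredictably
because its two functional pools respond differently: particulate organic
carbon (POC, plant-derived, >53 µm) and mineral-associated organic carbon
(MAOC, microbially derived, <53 µm). Whether fertilization builds POC or
MAOC appears to be governed by the soil's *initial* SOC content, with an
abrupt regime change around 13–15 g C/kg. `socthresh` implements the full
statistical machinery needed to detect and test such a threshold in a
multi-study dataset, for meta-analysts and soil scientists who want a
reproducible, scriptable version of the analysis.

## What it computes

**Effect sizes.** For each treatment/control pair the log response ratio
and its sampling variance

    lnRR = ln(X̄_t / X̄_c),     v = s_t²/(n_t X̄_t²) + s_c²/(n_c X̄_c²),

with inverse-variance weights, CI-based classification of each observation
as negative/neutral/positive, and a random-effects pooled estimate
(DerSimonian–Laird τ²) whose 95% CI comes from a 999-iteration percentile
bootstrap resampling whole studies.

**Threshold detection.** lnRR is regressed on initial SOC under eight
families — linear, quadratic, penalized-spline GAM, and five breakpoint
families (step, segmented, stegmented, hinge-12, hinge-22) — by weighted
least squares with the breakpoint profiled over the observed SOC values.
A linear-vs-nonlinear prefit (AIC) gates the analysis; the six nonlinear
models are then compared by AIC/BIC and the winning family's breakpoint is
the estimated SOC threshold.

**Threshold inference.** Bootstrapped linear regressions on each side of
the threshold yield slope and predicted-value distributions compared with
a Mann-Whitney U test; the between-side heterogeneity statistic Q_M
(χ²-distributed under homogeneity) tests whether the pooled response
differs across the threshold.

**Bias diagnostics.** Egger's regression, Rosenthal's fail-safe N against
the 5n+10 criterion, leave-one-study-out jackknife, and a weighted
meta-regression of lnRR on publication year.

**Soil indices.** Closed-form site-level indices: enzymatic vector length
√(x²+y²), resource limitation (SOC:TN)/(MBC:MBN), bacterial necromass C
(muramic acid × 45), fungal necromass C ((GluN − 2 MurA) × 179.17 × 9),
aggregate mean weight diameter Σ XᵢWᵢ, ¹³C-NMR aliphaticity and
recalcitrance, metabolic quotient qCO₂, and partial-correlation screening
of POC/MAOC drivers.

**Synthetic data.** A generator that emulates the structure of the global
dataset (studies contributing several observations, initial SOC spanning
0.79–46.1 g/kg, a planted piecewise effect-size curve, delta-method
sampling noise) so every stage is testable without downloads.

## Worked example

Simulate a particulate-fraction dataset with a threshold planted at
15 g/kg, then run the full analysis:

```
$ socthresh simulate --preset poc --seed 42 --out obs.csv
wrote 492 observations to obs.csv

$ socthresh run --input obs.csv --fraction POC --n-boot 999 --seed 42 --out out/
pooled lnRR +0.1783 [+0.1589, +0.1985]
threshold: 15.0 g/kg (stegmented)
```

The JSON report in `out/report.json` carries the detail. For this run:
the pooled effect is lnRR = 0.178 (95% bootstrap CI 0.159–0.199), i.e.
fertilization raises POC by ~19% on average; 39% of observations are
individually positive, 60% neutral, 1% negative. The stegmented family
(slope and intercept both change at the breakpoint) wins the BIC
comparison and puts the threshold at 15.0 g/kg — the planted value. Below
the threshold the bootstrapped slope of lnRR against initial SOC has
median +0.038 per g/kg, above it −0.004 (Mann-Whitney p < 0.001), and the
between-side heterogeneity is decisive (Q_M = 58.0, p < 10⁻¹³). The
fail-safe number (249,140) dwarfs the 5n+10 criterion (2,470), the Egger
intercept is not significant (p = 0.34) and the jackknife is robust, as
expected for unbiased synthetic data.

Site-level indices work the same way:

```
$ socthresh indices --input site.csv --out indices.csv
```

All of this is available as a library (`socthresh.effect_sizes`,
`socthresh.compare_families`, `socthresh.bootstrap_side_slopes`, …); the
CLI is a thin layer over it.

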