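# Methods

## Effect sizes and pooling

The meta-analytic unit is one treatment/control pair of carbon-fraction
measurements. The effect size is the log response ratio
lnRR = ln(X̄_t/X̄_c); its sampling variance is the delta-method variance of
the two log sample means, v = s_t²/(n_t X̄_t²) + s_c²/(n_c X̄_c²). Both
assume positive means and approximately normal sampling of the group
means; lnRR is undefined (and the record rejected) when a mean is
nonpositive.

Observations are weighted 1/v. Missing SDs are imputed by the mean
coefficient of variation of complete cases within the same fraction
(opt-out to exclusion), because dropping them would discard otherwise
informative studies; imputed rows are flagged in every output.
Zero-variance observations (both SDs zero, common when replicate scatter
is unreported as exactly zero) would get infinite weight; their weight is
capped at the 99th percentile of the finite weights so a single "exact"
observation cannot dominate, and the rows are flagged.

Pooling defaults to a random-effects inverse-variance average with the
DerSimonian–Laird moment estimator of the between-study variance τ² —
the standard default for lnRR meta-analyses — with a fixed-effect mode
available. The 95% CI is a percentile bootstrap (999 iterations, explicit
seed) that resamples *studies* with replacement, so multiple observations
from one study move together; within-study dependence is otherwise
ignored in the point estimate (multiple observations per study are
treated as independent), a deliberate simplification recorded here
because three-level models are out of scope. Per-observation response
classes use the 1.96·√v normal interval: positive if the lower bound
exceeds zero, negative if the upper bound is below zero, neutral
otherwise.

## Threshold detection

The effect-size curve g(x) = E[lnRR | initial SOC = x] is fitted by
weighted least squares under eight families. Writing (x−e)₊ for the
positive part and I for the indicator:

| family     | basis                                   | continuous at e |
|------------|-----------------------------------------|-----------------|
| linear     | 1, x                                    | —               |
| quadratic  | 1, x, x²                                | —               |
| step       | 1, I(x>e)                               | no              |
| segmented  | 1, x, (x−e)₊                            | yes             |
| stegmented | 1, x, I(x>e), (x−e)₊                    | no              |
| hinge-12   | 1, x, (x−e)₊, (x−e)₊²                   | yes             |
| hinge-22   | 1, x, x², (x−e)₊, (x−e)₊²               | yes             |
| gam        | cubic P-spline, 10 basis functions      | smooth          |

Continuity conventions follow the verbal family definitions: the hinge
families are built from truncated-power bases and are therefore
continuous at the breakpoint; step and stegmented are not. Whether the
original hinge formulations were continuity-constrained is ambiguous;
the truncated-power convention is the natural reading and is what this
package implements.

The breakpoint e is profiled: candidates are the observed SOC values
between the 10th and 90th percentiles (optionally refined to a uniform
0.1 g/kg lattice), subject to at least `min_side = 5` observations
strictly on each side, and the candidate minimizing the weighted RSS
wins (ties break toward the smaller e). Restricting to the central 80%
of the data stabilizes the side fits, as is common change-point
practice. Thresholds are reported to 0.1 g/kg.

The GAM is a P-spline: cubic B-splines on uniform knots extended beyond
the data range (so straight lines lie in the penalty's null space), a
second-difference coefficient penalty, and the smoothing parameter chosen
by GCV over a log-spaced grid (10⁻⁴…10⁸). Its effective degrees of
freedom (trace of the hat matrix) serve as its parameter count. With
fewer observations than basis functions it falls back to a quadratic
with a warning.

Families are compared on a common Gaussian profile-likelihood scale,
AIC = n ln(RSS/n) + 2k and BIC = n ln(RSS/n) + k ln n, where k counts
the coefficients plus one for a profiled breakpoint. Counting the
breakpoint as a single parameter under-penalizes the grid search
slightly; the BIC's heavier penalty and the prefit gate (below)
compensate in practice. The lowest BIC selects the family; when AIC and
BIC disagree, BIC wins and a flag is raised. A RSS floor of 1e-300 keeps
both criteria finite on exact fits.

Detection is gated twice: a linear/quadratic/GAM prefit must prefer a
nonlinear shape (AIC), and the subsequent six-model comparison must pick
a breakpoint family. Only then is a threshold reported. The gate is what
controls the procedure's false-positive rate: under a linear truth the
prefit rarely prefers a nonlinear shape, so the anti-conservative
downstream comparison is rarely reached (measured rejection ≈ 2% at
nominal 5% in the calibration run of `scripts/acceptance.py`).

Weighting the regressions by 1/v mirrors the meta-analytic weights; an
unweighted mode is exposed because the original weighting convention for
such threshold fits is not standardized, and the report records which
mode was used.

## Threshold inference

Either side of the estimated threshold, observations are resampled with
replacement 999 times (observation-level within a side; a study-level
option exists); each replicate yields a weighted straight-line slope and
the predicted lnRR at the threshold. Replicates whose resampled SOC
values are all identical cannot support a slope and are discarded
(logged; more than 20% discards aborts with an error). The left/right
slope and value distributions are compared with a Mann-Whitney U test:
U from midranks, the exact null distribution (counting recurrence) when
n_a·n_b ≤ 400 without ties, otherwise the tie-corrected normal
approximation without continuity correction. Observations exactly at the
threshold belong to the left side (closed-left convention).

The Mann-Whitney p-value treats the two bootstrap distributions as
samples of size n_boot, which overstates evidence for any fixed
difference between side estimates; it must be read jointly with the
selection gate (see above), not as a standalone test. The between-side
Q_M uses fixed-effect subgroup means: Q_M = Σ_g W_g(μ̂_g − μ̂)², χ² with
G−1 degrees of freedom under homogeneity. Q_M scales with the weights;
its p-value is the invariant quantity.

## Bias diagnostics

Egger's test regresses the standard normal deviate lnRR/SE on precision
1/SE by OLS and t-tests the intercept (the classical form; the weighted
variant is not implemented). The fail-safe number is Rosenthal's,
N_fs = ⌊(Σz)²/z_α² − n⌋ clipped at zero with one-tailed α = 0.05, judged
against 5n+10 — chosen over Rosenberg/Orwin because it is the variant
that pairs with that classic criterion. The jackknife removes whole
studies, re-pools, and uses analytic (normal-theory) CIs so the table is
deterministic; the robustness flag requires every leave-one-out estimate
to preserve the full-data sign and significance. The temporal trend is a
1/v-weighted meta-regression of lnRR on publication year. An effect-size
histogram is exported as binned counts for funnel-free distribution
inspection.

## Soil functional-carbon indices

All indices are pure closed forms. The enzymatic vector length uses the
proportion convention x = C/(C+P), y = C/(C+N) with C = BG+CBH,
N = NAG+LAP and P the site-appropriate phosphatase; "relative ratio" is
ambiguous and the proportion (Moorhead-style) convention is adopted and
documented. Amino-sugar inputs are treated as molar amounts so the
molecular-weight multiplication in the fungal-necromass formula is
dimensionally coherent; a mass-input mode applying the conventional
mass-based correction (dividing by the respective molecular weights) is
available behind a flag, because the printed molar form omits the
muramic-acid weight normalization found in the conventional formula —
the printed form is implemented as the default rather than silently
"corrected". Negative net fungal glucosamine is clipped to zero with a
warning. Aggregate mass proportions must sum to 1 within [0.98, 1.02]
and are renormalized with a warning otherwise. Partial correlations are
Pearson correlations of OLS residuals after projecting out the controls
(pseudo-inverse with a warning under collinearity).

## Synthetic-data generator

The meta-dataset generator draws 120 studies of 2–6 observations each
(~480 observations), initial SOC ~ Uniform(0.79, 46.1) g/kg, replicate
counts 3–6, per-group CVs ~ Uniform(0.05, 0.30), and a shared study-level
N(0, 0.08) deviation. Reported group means carry lognormal sampling noise
with log-scale SD cv/√n — exactly the dispersion their reported variance
claims — so computed effect sizes scatter around the planted curve with
the correct variance structure.

The default planted curve is stegmented (the shape class the pipeline is
designed to detect): for the particulate scenario, lnRR = −0.10 + 0.04·x
below the 15 g/kg threshold and 0.22 − 0.004·(x − 15) above it; for the
mineral-associated scenario, 0.55 − 0.045·x below 13.2 g/kg and
0.10 − 0.002·(x − 13.2) above. The discontinuity at the threshold is
deliberately large relative to the observation noise: change-point
localization error grows like σ²/(density·jump²), and a planted jump
much below ~0.1 would make the threshold unidentifiable at this sample
size regardless of estimator — the generator's purpose is a recoverable
ground truth, so identifiability takes precedence over matching any
particular pooled mean. Step, segmented, linear and smooth alternatives
are available for power studies. One `numpy.random.default_rng` stream
per dataset, seeded explicitly; no global state.

The site-level generator plants multiplicative fertilization effects per
carbon class (POC ×2.05 and aggregate stability up in carbon-poor soil;
MAOC ×1.15, necromass ×1.10, qCO₂ ×0.86 and NMR stability indices up in
carbon-rich soil) over lognormal plot noise (CV 8%), with Dirichlet
aggregate fractions that sum to one.

What the generator does *not* emulate: correlated moderators (texture,
climate and SOC are independent draws), heteroscedastic study quality,
selective reporting, digitization error, or any spatial structure.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under the assumed noise model, not performance on real
compiled literature data.

## Problem sizes and numerics

Recovery and calibration studies use 20 seeds (recovery) and 200
simulated datasets (null calibration) at the generator's default sizes;
bootstraps use 999 iterations; the Mann-Whitney exact/asymptotic switch
is at n_a·n_b = 400. WLS solves use `lstsq` on the √w-scaled system with
a rank check (rank-deficient bases raise rather than silently
pseudo-inverting). Reports are JSON with sorted keys and no wall-clock
content, so a rerun with the same input, configuration and seed is
byte-identical.

## Known limitations

- No multivariate or robust variance estimation; no three-level models;
  dependence between observations of a study enters only through the
  bootstrap.
- Single-breakpoint search only; no Bayesian change-point inference and
  no permutation test of threshold existence beyond the gated procedure.
- The side-contrast Mann-Whitney p-value is anti-conservative in
  isolation (see above).
- No trim-and-fill or selection-model bias correction.
- The breakpoint parameter count in AIC/BIC is a convention, not an
  exact accounting of the profiling search.
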