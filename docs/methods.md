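# Methods

## Curve models and fitting

Both sigmoids are parametrised by capacity *A* > 0, maximum rate *μ* > 0
(the slope at the inflection point) and lag *λ* (h, the time-axis intercept
of the inflection tangent; finite, may be negative):

* logistic `y(t) = A / (1 + exp(4μ/A (λ − t) + 2))`
* Gompertz `y(t) = A exp(−exp(μe/A (λ − t) + 1))`

The Gompertz inner term follows the standard three-parameter
re-parametrisation, `(μe/A)(λ − t) + 1`, the form consistent with its use
in the mirrored decline phase.

Fitting is bounded trust-region least squares (`scipy.optimize.least_squares`,
tolerances 1e-13) on values normalised by their maximum; both models are
equivariant under uniform value rescaling (fitting c·y returns (cA, cμ, λ)),
so viable counts at 1e9 CFU/mL and ammonia at 0.3 mg/mL are equally well
conditioned. The start is the classical tangent construction — A₀ = max(y),
μ₀ = steepest forward-difference slope, λ₀ = t* − y(t*)/μ₀ at the steepest
segment's midpoint — plus four deterministic jittered restarts (fixed
internal seed; the fit is a pure function of the data). Bounds:
A ∈ (0, 10·max(y)], μ > 0, λ ∈ [−t_end, t_end]. Negative fitted lags are
allowed and flagged, since the mirrored decline phase interprets them.
Constant or shorter-than-4-point series raise a degenerate-series error.
Residuals are unweighted; viable counts may optionally be fitted on log10
values (off by default — counts are fitted on the natural scale).

Model choice uses the Gaussian-likelihood AIC
`n ln(2π·rss/n) + n + 2(k+1)`, lower better, ties broken toward logistic.
Both candidates have k = 3, so any consistent AIC convention produces the
same ranking; a perfect fit (rss = 0) scores −inf with a warning and wins.
Both models' scores are recorded on the selected fit.

## Additive growth–decline model

Viable-count patterns rise, peak and decline. The additive summary keeps
the two-sigmoid vocabulary: the tipping point tx is the **earliest** time
attaining the series maximum ("immediate maximum" read as first
attainment); values after tx are held at the peak and the padded series
fitted as growth; values before tx are held at the peak, time is mirrored
(t → t_end − t, default t_end = 205 h), and the re-sorted series fitted
again, so the decline reads as a growth curve. Model selection runs
independently per branch. Exactly seven scalars are reported: MaxCFU,
GroRate, Lag, tx, DeclineMaxCFU, DeclineRate, DeclineLag.

Choices where the procedure is genuinely open:

* tx is found per replicate; each replicate gets its own additive fit and
  parameters are summarised as replicate mean ± sample sd, keeping the sd
  semantics of the metabolite parameter tables.
* At t == tx exactly, `evaluate_additive` reports the mean of the two
  branch values; the model is piecewise and need not be continuous at tx.
  No bridging function is fitted.
* Plateau padding duplicates the peak value at sampled times only; no
  interpolation. The padded points are included in each branch's residuals
  by default (`exclude_padding=True` drops them, keeping the tx point).
* `sustainability = t_end − DeclineLag`; DeclineLag < 0 yields a value
  beyond the window and flags the fit "not fully declined within
  observation window".

**Accuracy of the plateau construction.** The procedure recovers branch
parameters exactly (round trips at ≤1e-6 relative error) when each branch
has saturated by tx, because then the padding coincides with the model's
own plateau. When the pattern peaks *before* saturation — a sharply peaked
curve — the padding disagrees with the continuing sigmoid and biases branch
parameters at the few-percent level. Conversely, a pattern that saturates
long before declining has a flat top, and under measurement noise the
argmax (hence tx) wanders across the plateau. Identifiable tipping points
and exactly recoverable branch parameters are therefore in tension; the
test suite checks exact recovery in the saturated regime and tx
identifiability on the peaked default simulations.

## SCFAs/NH₃ indicator

Total SCFA is the sum of acetate, propionate and butyrate (valerate and
caproate excluded as negligible). Dissolved ammonia from the enzymatic
microplate assay is `(sample ΔA/standard ΔA) × 0.04 mg/mL` with
ΔA = A1 − A2 at 340 nm; a non-positive standard ΔA is an assay failure, a
negative sample ΔA is flagged. The assay formula is implemented as stated;
an optional `dilution_factor` multiplier (default 1) is exposed for
protocols whose standard does not absorb the sample dilution.

Min–max scaling maps each indicator into (a, b) = (1, 10): the floor of 1
keeps the subsequent quotient defined, and the ratio is bounded in
[0.1, 10]. Scaling defaults to **per time-point across candidates** — the
indicator is compared across candidates at fixed times, which requires
per-time comparability — with a `global` option over the whole experiment.
Inputs to scaling are replicate means. A time-point where all candidates
coincide leaves the scale undefined and is an error, not a silent constant.
Negative-control series are ordinary candidates; their inclusion in the
scaling domain is left to the caller's candidate selection.

## Robustness battery

Ten statistics per indicator on paired 24 h/48 h candidate profiles
(n ≥ 3): dispersion sd(|slope|)/mean(|slope|) with slope = Δvalue/Δt
(Δt cancels); two-sided paired t; Wilcoxon signed-rank (the only *paired*
Wilcoxon — exact for n ≤ 25 with no zero or tied differences, normal
approximation otherwise); Pearson r with p from t = r√(n−2)/√(1−r²);
Spearman rho (Pearson on ranks) with the same t-approximation, an
exact-permutation option for n ≤ 10; and similarities of sample-sd
z-scored profiles: 1/(1+d) for Euclidean and Manhattan distance, plus the
raw cosine. Sample sd (n−1) is the package-wide convention; with it,
d²_euclidean = 2(n−1)(1−r) and cosine = r exactly, so the Euclidean and
cosine rows are determined by the Pearson row — the identity behind
`scripts/acceptance.py`. The cosine can be negative and is reported raw
with a warning, since similarity is nominally in [0, 1]. Degenerate cases:
all differences zero gives p = 1 (flagged); identical nonzero shifts give
a diverging t statistic, reported as p = 0 with a "degenerate large
effect" flag. Best-performer flags per statistic (lower dispersion and
correlation p; higher everything else) allow joint ties. No
multiple-testing correction is applied across the battery.

## Exploratory outputs

The candidate × parameter matrix holds replicate means (three parameters
per metabolite analyte, seven for the viable-count pattern; DeclineLag can
be displayed as sustainability). Pairwise Pearson correlations are starred
at p < 0.05/0.01/0.001; zero-variance columns yield NaN, not errors. PCA
centres and unit-scales columns (parameters mix h, mM/h and CFU) and
decomposes by SVD with a deterministic sign convention; loadings are the
right singular vectors unscaled by singular values. Heatmap data is column
z-scored with Euclidean/complete-linkage agglomerative ordering (a common
heatmap default; the choice is configurable). Plot rendering is left to
the caller; the numeric tables are the tested surface.

## Synthetic screens

The generator emulates the reference design: 13 carbohydrate candidates,
the fixed 19-point schedule over 205 h (4 samplings on day 1, 3 on days
2–4, 2 on day 5, 1 on days 6–9), biological triplicates, six measured
patterns (counts, three SCFAs, their sum, ammonia) — 4446 data cells.
Noise is additive Gaussian with sd = 5% of the curve's capacity by
default, truncated at zero (concentrations and counts are non-negative);
a multiplicative lognormal option exists for counts. Every stochastic
output derives from a per-series `SeedSequence(seed, spawn_key)`, so
screens are bit-for-bit reproducible and replicates share truth but not
noise. The total-SCFA series is the sum of the three simulated component
series, so its noise is the propagated component noise.

Default truths span the qualitative regimes of such screens — simple
sugars: fast fermentation, early tipping point, prompt decline;
oligosaccharides intermediate; polymeric beta-glucans and inulin: slow
rates, late tipping points, declines extending past the window (negative
DeclineLag). The numbers are the package's own realistic choices.
Viable-count truths are specified as (A, tx, growth rise time r_g, decline
rise time r_d) with branch lags at 1.35 rise times before the respective
end, placing each branch just shy of capacity at tx: the noiseless pattern
then peaks exactly at tx (exact noiseless recovery of tx), and under 5%
noise the tipping point stays identifiable (recovered within one schedule
step in ≈97% of replicate series; the two sustained, slow-declining
candidates account for most misses — their peaks are intrinsically broad).
At t == tx the generator emits the larger branch value, making tx the
literal maximum; the fitted model's evaluator uses the mean convention,
a difference confined to the single point tx.

What the generator does **not** emulate: substrate depletion or any
mechanistic community dynamics, diauxic (multi-peak) growth,
heteroscedastic or autocorrelated assay error, inter-replicate biological
drift, or missing samples. Passing recovery tests therefore shows the
estimation machinery is correct under the stated noise model, not that
real screens meet these assumptions.

## Problem sizes in tests

The suite validates noisy parameter recovery with 200 seeded replicates of
the 19-point design per model (median errors: A and μ within 10%, λ within
2 h), tx identifiability across the default screen, and statistical
p-values against brute-force oracles (exact sign-flip enumeration for the
signed-rank test, closed-form t mappings for the rest) at 1e-6 agreement.

## Known limitations

* Single tipping point only; diauxic patterns are out of scope.
* The plateau construction's parameter bias for sharply peaked patterns
  (see above) is inherent to the procedure, not the optimizer.
* The Spearman p uses the t-approximation by default; exact permutation is
  limited to n ≤ 10.
* The ammonia formula ignores the reaction-volume dilution unless
  `dilution_factor` is supplied.
* Indicator scaling makes values panel-relative: ratios are not comparable
  across screens scaled separately.
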