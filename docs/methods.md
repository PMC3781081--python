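# Methods

## Model structure

The observational unit is a plot-year count Ω_t of occupied sample units out
of N_max, treated as beta-binomial: a beta-distributed latent cover
probability (shapes a, b; mean μ = a/(a+b); overdispersion φ = a+b) followed
by a binomial draw over the N_max units. The beta mean/variance relation is
σ²_beta = μ(1−μ)/(φ+1), so a variance never exceeds the bound μ(1−μ).
Probability mass is computed exclusively through log-gamma differences
(`gammaln`/`betaln`), never factorials, so N_max = 484 is handled without
overflow.

Four pluggable pieces define a model variant (`ModelSpec`):

* **Mean map.** Modified Ricker,
  μ_t = I(1−p_{t−1}) + p_{t−1}·exp(r + Σ_x [α_x p_{t−x} + β_x p_{t−x}^{c_x}]),
  up to fourth order. Immigration acts only on unoccupied space, so an empty
  plot expects cover I the next year, and the map is the identity under
  neutral parameters. A modified Hassell map (density dependence in a
  denominator (1 + Σ α_x p_{t−x})^g instead of the exponent) is provided as a
  robustness alternative; the two families give qualitatively identical
  stable skeletons in the fitted region.
* **Variance law.** All variances are *relative*: fractions of the beta
  bound, σ²_rel = σ²_abs/(μ(1−μ)) = 1/(φ+1). The constant law fixes σ²_rel;
  the density-linked law is σ²(p) = exp(x + y p^z), evaluated at the lagged
  density p_{t−1}. With y < 0 and large z (the fitted regime) the relative
  variance is moderate at low cover — where recruitment from the plankton
  dominates and is erratic — and collapses near full cover, where undisturbed
  beds change little. The exponential-of-power form can also be flat (y = 0,
  recovering the constant law exactly, which makes the constant model a
  nested special case), monotone increasing, or threshold-like. Working on
  the relative scale keeps every parameter proposal inside the beta-feasible
  region whenever the fraction is below one, which is what makes ML
  estimation under the variance constraint cheap.
* **Disturbance mixture.** With probability Ψ_d(p) = logistic(j + k p) the
  next census comes from a post-disturbance beta-binomial with mean μ_d and
  relative variance σ²_d instead of the growth model. The logistic keeps
  Ψ_d in [0,1] for any (j, k); the fitted k > 0 encodes wave disturbance
  spreading through crowded beds. The disturbed beta component is
  constrained to be strictly unimodal (a > 1 and b > 1): crashes land around
  μ_d, not at the lattice edges. The per-row log-likelihood is
  LL = log((1−Ψ_d)·L + Ψ_d·L_d), computed with `logaddexp`.
* **Fixed-parameter masks.** Linear variants fix β_x = 0, c_x = 1 a priori;
  fixed parameters stay in the parameter dictionary but are excluded from
  the free-parameter count k used by AIC, so the standard variant ladder has
  k = 4 (first-order linear constant), 6 (+β₁, c₁), 10 (linear DLS mixture),
  12, and 15 (fourth-order non-linear constant).

## Functional-form provenance

The published account of this model family presents its defining equations
as display figures, and the printed parameter tables are the firmest record
of the forms. The implementations here were fixed by requiring that the
printed estimates reproduce the printed behaviour: the first-order linear
mean map has a unique attracting fixed point at 82.9% cover; an empty plot
expects cover I; the non-linear term (β₁ = 0.005, c₁ ≈ 131) acts only above
~95% cover; the variance law declines with abundance at the fitted (x, y, z)
and the constant-variance simulations show modest fluctuation around the
attractor; the disturbance probability increases with density at the fitted
(j, k); and the disturbed state at (μ_d = 0.393, σ²_d = 0.090) is unimodal
on the relative-variance scale (a = 3.97, b = 6.14). Simulated trajectories
under the fitted DLS parameters then show the characteristic multi-year
build-up punctuated by crashes to the vicinity of μ_d.

## Estimation

`fit_ml` maximises the pooled transition likelihood over all plots.
Constraints are enforced by reparameterization, not penalties: logit for I
and μ_d; scaled logistic bounding c_x in (0, 200] (fitted exponents reach
~131, so the bound is generous) and z in (0, 100]; logit for the constant
relative variance; and the disturbed-state overdispersion parameterised as
its unimodality bound max(1/μ_d, 1/(1−μ_d)) plus a log-scale gap, so the
constraint is structurally satisfied. The mixture surface is multimodal, so
optimization runs L-BFGS-B from a heuristic start plus seeded Sobol scatter
points (default 20 starts; reproducible under the seed) and keeps the best
optimum. Refitting from a previous optimum is idempotent to 1e−6.

Numerical guards: expected proportions are clipped to [1e−9, 1−1e−9] before
beta construction; inside the optimizer the overdispersion is clamped to
[0.05, 1e8] — the floor avoids the degenerate two-point beta as the variance
approaches its bound, and the ceiling avoids catastrophic cancellation in
the log-gamma differences (beyond ~1e8 the pmf loses all precision, which
otherwise opens a spurious "perfect-fit" sink); and any negative
log-likelihood (impossible for discrete data) is rejected as numerical
failure. Outside the optimizer, strict evaluation raises a feasibility error
naming the offending density instead of clamping.

Model comparison follows the AIC = 2k + 2(−LL) convention with Akaike
weights w_i = exp(−ΔAIC_i/2)/Σ and evidence ratios w_best/w_i. A model is
flagged *supported* when ΔAIC < 6 **and** no simpler nested model (nesting
declared structurally: linear ⊂ non-linear, constant ⊂ density-linked,
non-mixture ⊂ mixture, lower ⊂ higher order, same mean family) achieves a
lower AIC. Ties in the minimum AIC break toward smaller k, then
lexicographic label, so reports are deterministic. Model averaging weights
each parameter by w_i over the models whose universe contains it (weights
renormalized within that subset), with fixed-a-priori values contributing
their fixed 0/1.

## Order of density dependence

`odd` diagnoses how many lagged densities are needed to predict the next
census, nonparametrically: a Nadaraya–Watson (Gaussian-kernel local-mean)
autoregression of order d, scored by leave-one-out cross-validation, with
the bandwidth chosen per (series, order) by minimising the same criterion
over a fixed geometric grid (0.02–1.0 in cover units). Leave-one-out rather
than block CV is used because the series are only 17–18 censuses long.
Per-plot scores are standardised by subtracting the plot's minimum across
orders, then averaged over plots; embedding windows touching a missing
census are excluded. The contract is behavioural — correct order
identification on synthetic data — not replication of any particular kernel
variant.

## Diagnostics

* **Attractors.** `find_attractor` iterates the noise-free map and reports a
  fixed point (successive-iterate tolerance 1e−10) or a cycle of period ≤ 50
  within 1e5 iterations, verifying the detected period is minimal.
* **Ensembles.** `simulate` draws each annual step from the transition
  mixture on the plot's own count lattice; reproducible under a seed.
* **Prediction envelopes.** For each starting cover on a grid (default
  increment 0.002), the model is iterated one step many times (default 1e6,
  matching the study protocol; the test suite uses 1e4 to stay fast) and the
  envelope is the smallest set of outcome bins, accumulated in decreasing
  probability, whose mass first reaches 95%. Working on the discrete count
  lattice keeps the region honest when the outcome distribution is
  multimodal — at high cover the envelope splits into a "persist" island and
  a "crash" island — where a central interval would bridge the gap.
* **Spectra.** One-sided periodogram of the mean-removed series, no taper or
  padding, normalised so the powers sum to the series variance (Parseval is
  the testable contract); ensemble spectra average replicates and report the
  standard error per frequency. Series are analysed raw (not detrended).

## Synthetic studies

`generate_study` emulates the field design: 16 plots (14 started 1993, two
1994), annual censuses through 2010, ten plots on a 484-unit lattice and six
on 100 points, initial covers uniform on [0.02, 0.25] (plots were sited at
low cover; exact values are unpublished, so a uniform low-cover draw is
used), and plot 1 missing its 1994 census — the underlying population keeps
evolving through the gap, only the record is withheld. Measurement error is
modelled as symmetric independent per-unit flips (the study reports a single
0.48% repeat-sampling figure with no direction); default 0. Presets wire the
published parameter columns: `constant_table1` (I=0.242, r=0.122,
α₁=−0.209, σ²=0.036), `dls_table2` (I=0.053, r=0.522, α₁=−0.524, x=−2.959,
y=−2.023, z=13.133, μ_d=0.393, σ²_d=0.090, j=−3.143, k=2.225), and
`deterministic_table1` (the noise-free skeleton, for attractor work only).

What the generator does *not* emulate: spatial structure within and among
plots (disturbance transmission is only implicit in the fitted mixture),
covariate species that facilitate recruitment, observation timing within the
season, and any secular environmental trend. Passing recovery tests
therefore show that the estimation machinery is consistent under the model's
own assumptions at the study's size and noise level — not that the model is
correct for any particular field system.

## Problem sizes and tolerances in the test suite

Recovery experiments use 50 replicate studies at the design size (16 × 18)
with 3 optimizer starts each; ODD and spectral-contrast checks use 100
seeded replicates; envelope calibration uses 1e4 iterations per grid point
and 1e4 fresh transitions. Oracle comparisons are tight (quadrature 1e−8
relative; brute-force likelihood 1e−8 absolute; Parseval 1e−10); behavioural
thresholds (e.g. the generating model winning by AIC in ≥ 80% of replicates)
are deliberately below the observed rates, which are near 100%.

## Known limitations

Fourth-order variants are implemented and tested structurally, but their
recovery properties at 17-point series lengths are weak (the data barely
identify 10 parameters, and `fit_ml` warns below 3k rows). The Hassell
family's higher-order extension is a design choice (shared denominator
across lags) rather than a published form. Confidence intervals for
parameters are out of scope; comparisons rest on AIC. The measurement-error
model is symmetric Bernoulli per unit, which cannot represent systematic
observer bias.
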