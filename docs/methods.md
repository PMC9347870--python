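# Methods

## The renewal model and its two summary statistics

Daily incidence I_t (new cases on day t, t = 1..T) is modelled by the renewal
equation

    E[I_t] = Λ_t R_t,    Λ_t = Σ_{j=1}^{min(t−1, L)} I_{t−j} w_j ,

where w_j is the probability that a secondary case occurs j days after its
primary case (the generation-time distribution, approximated in practice by
the serial-interval distribution) and R_t is the instantaneous reproduction
number. Counts are Poisson about that mean (a negative-binomial option with
dispersion k covers overdispersion in simulation only). The instantaneous
growth rate r_t is the derivative of log-smoothed incidence. Under sustained
exponential growth at rate r the two are linked by the moment generating
function of the generation time, R · M_w(−r) = 1, with
M_w(s) = Σ_j w_j e^{sj}.

Assumptions worth keeping in view: cases and infections are treated as
equivalent (no reporting delay or under-ascertainment model); the
generation-time distribution is known, fixed in time, and non-negative; the
population is homogeneous (no superspreading, spatial or age structure).

## Generation-time distributions

Gamma(shape a, rate b) densities are discretized onto integer days by the
midpoint rule: w_j = F(j + 1/2) − F(j − 1/2) for the gamma CDF F, with day 1
absorbing [0, 1/2) (no same-day transmission mass), truncated at the smallest
L with F(L + 1/2) ≥ 1 − tail_cutoff (default 1e−4) and renormalised. Centred
bins were chosen over right-endpoint bins (w_j = F(j) − F(j−1)) because the
latter inflate the discrete mean by half a day, which propagates into a
several-percent bias between the discretized MGF root and the continuous
closed form r = b(R^{1/a} − 1); with centred bins the two agree to ~0.25%
over R ∈ [0.3, 4] for the default generation time.

The default generation time is gamma with mean 8 days (a = 3, b = 0.375/day),
an Ebola-like serial interval; the exact parameters behind that convention
are not standardised, so the mean is the committed quantity. Deliberate
misspecification holds the shape fixed and scales the rate
(b′ = b / factor), isolating the effect of a wrong mean; factor 0.67 is the
canonical "mean a third too small" scenario.

`discretize_gamma` accepts a sub-daily `step_days` so the empirical MGF can
be checked against its continuous limit; the renewal machinery itself
requires daily bins.

## Simulator

Seasonal truth: R_t = baseline + amplitude · sin(2πt / period), defaults
T = 300 days, baseline 1.0, amplitude 0.75, period 120 days, 50 seed cases —
two growing and two declining seasons with incidence spanning tens to a few
hundred cases/day. The first max(7, L/2) days are constant imports of the
seed count so the convolution is well defined early; Λ_1 = 0 by convention.
Extinction (no case within the final generation-time window) is flagged, not
raised. A deterministic mode propagates means exactly; with constant R its
log-incidence slope equals the root of R·M_w(−r) = 1 to machine precision,
which ties the simulator to the transform layer and is used as a
cross-check in the tests.

## Grid filter/smoother for R_t

The posterior over R_t lives on a uniform grid (default [0.01, 10], 2000
points). The state model is a Gaussian random walk with daily standard
deviation η√R (default η = 0.1); the row-normalised transition kernel is
shared by the forward filter and the backward (fixed-interval) smoother.
Likelihoods are Poisson with mean Λ_t R, computed in the log domain with
max-subtraction; probabilities are floored at e^−700. Estimation starts at
t = 2 (the first day with defined Λ_t); day 1 reports the uniform prior. The
headline estimate is the smoothed posterior mean — the smoother conditions on
the entire series and has uniformly lower mean-squared error than the filter
in paired-replicate tests.

Equal-tailed credible intervals invert the posterior CDF with each grid
point's mass spread uniformly over its cell. The discrete inverse-CDF would
collapse to zero-width intervals whenever incidence is large enough that the
daily likelihood is narrower than one grid cell; cell-uniform interpolation
is the standard remedy and keeps interval coverage meaningful across the full
range of epidemic sizes.

One-step-ahead predictions use the day-t prior (the day-(t−1) posterior
pushed through the kernel) only, so each prediction sees strictly past data.
The predictive distribution of I_t is the Poisson mixture across the grid
with means Λ_t R; its 2.5%/97.5% quantiles are found by bisection on the
mixture CDF, with negligible-weight grid points (< 1e−12) dropped for speed.

Replicate studies (interval calibration, smoother-vs-filter comparisons)
run through an internal batched core that propagates all replicates as one
matrix through the shared kernel; the public per-series functions wrap it.

## Savitzky–Golay growth rates

SG weights come from the least-squares polynomial fit at the window centre
(scipy's coefficients, centre-indexed so Σ a_j = 1 for smoothing and
Σ a_j = 0, Σ j·a_j = 1 for first derivatives; polynomial order ≤ 1 with
derivative 0 reduces exactly to the moving average 1/m). Defaults: window
15 days, order 2 — the window spans roughly two mean generation times of the
default serial interval. Edges are reported as NaN, never padded: padding
would be an unstated modelling assumption.

The incidence-based estimator smooths counts (derivative 0), floors at 0.5
cases, takes logs, then applies the derivative-1 filter. Staging avoids
log(0) on raw counts; all-zero windows yield zero growth, flagged only by the
floor. The Λ-based estimator differentiates log Λ_t directly (the
generation-time kernel already smooths); its first L days use a truncated
kernel and are reported undefined. Both estimators are exact (to ~1e−14) on
noiseless exponentials because any linear time-invariant smoother scales an
exponential by a constant that the log-derivative removes. No credible
intervals accompany the SG estimates; they are deliberately assumption-light
point estimates.

Shift convention: the Λ-based kernel's centroid sits E[w] days in the past,
so that series is advanced by round(E[w]/2) days by default and the smoothed
incidence series is (by convention, when compared against the model-based
estimate) delayed by the other half; the relative lag between the unshifted
model-agnostic estimates is therefore ≈ E[w], which `align_lag` recovers by
maximising Pearson correlation over integer shifts (ties toward smaller
|lag|). The half/half split reconciles the two framings of this lag — each
series moved by τ/2 toward a common centre versus Λ shifted by the full τ
against the smoothed incidence — which differ only in the chosen reference
frame.

## Transforms and interval propagation

Three R ↔ r maps: the gamma closed form r = b(R^{1/a} − 1) (inverse
R = (1 + r/b)^a, domain r > −b), bracketed Brent root finding on the
discretized empirical MGF (tolerance 1e−12; decay rates below −min(5, b) are
outside the numerically stable range of the discretized MGF and reported
undefined), and the linearised-SIR form r = (R − 1)/E[w], tangent to the
gamma curve at R = 1. All are strictly increasing, so posterior quantile
bounds are propagated by mapping them directly — valid for monotone maps and
cheaper than resampling, which is why it was chosen. Whether the model-based
growth rate uses the closed form or the numeric root is configurable; both
are provided because they answer to slightly different notions of the
generation time (continuous density vs its daily discretization).

## Experiments and metrics

Summary metrics are computed on days where all compared estimators are
defined and incidence exceeds a floor (default 10 cases; estimation at very
low incidence is known to be unstable and noisy); the floor is recorded in
the metrics file. Prediction-interval coverage excludes the seeding period,
whose counts are deterministic imports rather than renewal draws. For the
same reason, interval-calibration studies in the test suite score coverage on
post-seeding days: during seeding, the data genuinely carry no information
about the true R.

Misspecification metrics: relative errors are used for R (truth is bounded
away from zero) and absolute errors for r (truth crosses zero, where relative
error is undefined); each quantity's error inflation is the ratio of its
median error under the misspecified generation time to that under the true
one, so the scales cancel within each ratio before the two are compared.

## Problem sizes

Defaults were chosen so that every study runs comfortably on a single CPU:
the seasonal scenario uses 300 days at the full 2000-point grid;
interval-calibration studies use 201 constant-R epidemics (67 each at
R = 0.8, 1.5, 2.0; T = 150) through the batched core; paired
smoother-vs-filter comparisons use 100 replicates on a 500-point grid (the
grid-refinement tests show the posterior mean moves < 0.01% between 1000 and
2000 points, so coarser grids are adequate where only means are compared).

## Known limitations

- No reporting-delay, weekday, or under-ascertainment corrections: the
  package analyses true infection incidence, which real surveillance streams
  only approximate.
- The synthetic epidemics are homogeneous Poisson renewal processes; real
  outbreaks show superspreading (heavier-tailed offspring distributions),
  importation bursts, and time-varying generation times, none of which the
  generator emulates. Passing tests demonstrate correctness of the estimators
  under the renewal model's own assumptions, not robustness to these
  violations (except the generation-time-mean misspecification studied
  explicitly).
- The grid filter assumes R ∈ [0.01, 10]; pathogens or data outside that
  range need a wider grid.
- The Λ-based growth estimator discards its first L days (truncated kernel)
  and both SG estimators lose (m−1)/2 days at each boundary — real-time use
  at the series end therefore relies on the model-based estimate.
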