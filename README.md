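# epigrowth

Reproduction numbers and growth rates from epidemic incidence curves — and
the machinery to convert between them.

Public-health surveillance tracks two headline statistics of an unfolding
epidemic. The **instantaneous reproduction number** R_t is the average number
of secondary infections per effective primary case at time t; R_t > 1 means
the epidemic is growing. The **instantaneous growth rate** r_t is the time
derivative of log-smoothed incidence, in 1/day; r_t > 0 means the same thing,
but with a speed attached (doubling time = ln 2 / r_t). This package
implements both estimators side by side, for epidemiologists and modellers
who want to compare them on the same data:

- **Renewal-model simulation.** Daily counts follow
  `E[I_t] = Λ_t R_t` with total infectiousness
  `Λ_t = Σ_{j≥1} I_{t−j} w_j`, where w_j is the generation-time (serial
  interval) distribution. The simulator provides exact ground truth for every
  estimator, including seasonally varying R_t profiles.
- **Bayesian R_t estimation.** A grid filter/smoother (EpiFilter-style):
  R_t performs a Gaussian random walk with daily standard deviation η√R_t,
  each day's Poisson likelihood with mean Λ_t R is absorbed by exact discrete
  Bayes updates, and a backward pass conditions every day on the full series.
  Outputs: posterior mean, equal-tailed 95% credible intervals, and
  one-step-ahead predictive intervals for validation.
- **Model-agnostic r_t estimation.** Savitzky–Golay (SG) filters — local
  least-squares polynomial smoothing as a fixed convolution — applied to log
  incidence; the moving average is the special case a_j = 1/m. A second
  estimator differentiates log Λ_t directly, exploiting the package's central
  observation: the generation-time convolution is itself an implicit SG
  filter whose centroid sits E[w] days in the past, so the Λ-based estimate
  trails the incidence-based one by one mean generation time.
- **Transforms.** Under exponential growth the two statistics are linked
  through the moment generating function M_w of the generation time:
  `R · M_w(−r) = 1`. For a gamma(a, b) generation time this is
  `r = b (R^{1/a} − 1)` with exact inverse `R = (1 + r/b)^a`; a linearised
  SIR model gives `r = (R − 1)/E[w]`. All maps are monotone and send R = 1 to
  r = 0, so threshold crossings coincide. Credible intervals are propagated
  through the monotone map.
- **Experiments.** End-to-end seasonal-epidemic comparison of all three r_t
  estimates, and a robustness study estimating with a generation time whose
  mean is 33% too small — which biases R_t substantially more than r_t.

## Worked example

```python
import epigrowth as eg

# Ebola-like serial interval: gamma, mean 8 days (shape 3, rate 0.375/day)
gt = eg.discretize_gamma(3.0, 0.375)

# R = 2 corresponds to ~0.097/day growth: a 7.1-day doubling time
eg.growth_from_R_gamma(2.0, 3.0, 0.375)   # 0.09747
eg.growth_from_R_numeric(2.0, gt)         # 0.097516 (discretized MGF root)
eg.growth_from_R_sir(2.0, gt.mean_days)   # 0.125029 (first-order SIR)
eg.critical_prevention_fraction(2.0)      # 0.5 — half of transmissions

# Full seasonal experiment: simulate, estimate, compare
result = eg.run_seasonal_experiment()
result.metrics["recovered_lag_days"]      # 8  (~ E[w]: the implicit-filter lag)
result.metrics["prediction_coverage"]     # 0.9858 (one-step-ahead 95% PIs)
result.metrics["sign_agreement_sg_vs_truth"]  # 0.9154 on days with >10 cases
```

The gamma and numeric values agree to 0.05% — the daily discretization is
that close to the continuous closed form — while the SIR linearisation
overstates growth away from R = 1. In the seasonal run, the growth-rate
estimate built from the total infectiousness lags the SG-smoothed-incidence
estimate by 8 days, the mean generation time, confirming that Λ_t acts as an
epidemiologically informed smoothing filter.

The same functionality is exposed on the command line:

```bash
epigrowth transform --R 1 --kind gamma --shape 3 --rate 0.375   # prints 0
epigrowth simulate --out epidemic.csv
epigrowth estimate-rt --incidence epidemic.csv --out rt.csv
epigrowth experiment seasonal --seed 1 --out runs/seasonal/
```

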