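# Methods

## The problem

Health-technology assessments need survival extrapolated far beyond a
trial's follow-up. For a single-arm trial with ~2 years of data, the seven
standard parametric families (exponential, Weibull, Gompertz, lognormal,
log-logistic, gamma, generalized gamma) agree inside the observed window and
then diverge wildly in the tail, because the data carry almost no
information there. `survelicit` constrains that tail with structured expert
opinion: clinicians state, for each horizon t_E (3, 5, 10 years), a most
likely value (MLV) and lower/upper plausible limits (LPL, UPL) for the
survival probability, and those judgments enter the model as additional
likelihood terms.

## Model

For subjects i = 1..N with follow-up time T_i and death indicator
delta_i, and elicited horizons j = 1..M, the joint posterior is

    p(theta | T, delta, Y) ∝ prod_i f(T_i|theta)^{delta_i} S(T_i|theta)^{1-delta_i}
                            * prod_j d(Y_j | theta) * p(theta)

The first product is the ordinary right-censored likelihood. The second is
the expert term: Y_j (the consensus MLV) is treated as an observation of a
normal distribution truncated to [0, 1] whose mean is tied to the model,
mu_j = S(t_Ej, theta), and whose standard deviation comes from the plausible
interval, sigma_j = (UPL_j - LPL_j) / (2 z_0.99), reading the limits as the
1st/99th percentiles of the pre-truncation normal. Tight intervals give
strong constraints; as sigma_j grows the constraint switches off and the fit
reverts to the data-only posterior.

Three deliberate choices in the expert density:

- **Closed truncation interval.** The truncated normal is evaluated on the
  closed interval [0, 1] so an elicited MLV of exactly 0 (10-year survival
  judged implausible) retains positive density. An open interval would
  assign it zero likelihood and make the stated boundary case unusable.
- **Truncation constant included.** The normalization
  Phi((1-mu)/sigma) - Phi(-mu/sigma) depends on mu, hence on theta, and is
  part of the likelihood. `include_truncation_constant=False` (CLI
  `--no-truncation-constant`) exposes the unnormalized kernel for
  sensitivity analysis.
- **Untruncated-percentile convention for sigma.** Solving for the
  truncated distribution's own percentiles would need an iterative solver
  and changes sigma only in boundary-adjacent cases; the closed form
  matches the simple normal fit of standard elicitation tooling.

## Parameterizations

All on the natural scale, time in years (month inputs divided by exactly 12):

| family       | parameters            | survival function                      |
|--------------|------------------------|----------------------------------------|
| exponential  | rate λ                 | exp(-λt)                               |
| weibull      | shape v, rate λ        | exp(-λ t^v)                            |
| gompertz     | shape a (real), rate b | exp(-(b/a)(e^{at}-1))                  |
| lognormal    | meanlog μ, sdlog σ     | 1 - Φ((log t - μ)/σ)                   |
| loglogistic  | shape β, scale α       | 1/(1 + (t/α)^β)                        |
| gamma        | shape k, rate r        | Γ_u(k, rt)/Γ(k)                        |
| gengamma     | shape r, rate λ, power b | Γ_u(r, (λt)^b)/Γ(r)  (Stacy form)   |

Nesting identities used as correctness oracles: Weibull(shape 1) =
exponential; gengamma(power 1) = gamma; gengamma(shape 1, rate λ, power b) =
Weibull(shape b, rate λ^b). A Gompertz with negative shape is allowed and
implies a survival plateau ("cure fraction") exp(b/a); the sampler of event
times then returns `inf` for never-event subjects (or draws conditionally on
the event, per option).

Numerical details worth knowing:

- Gompertz cumulative hazard uses the series t(1 + at/2 + (at)²/6) for
  |a| < 1e-6, avoiding 0/0 at the exponential limit.
- Generalized-gamma log-survival switches to the leading-series bound
  log1p(-exp(r·log x - log Γ(r+1))) when log x = b·log(λt) < -34. Without
  this branch, (λt)^b underflows to zero for large b, the survival of every
  censored subject evaluates to exactly 1, and the posterior collapses into
  a spurious corner (r → 0, b → thousands) that wins ~150 deviance units by
  floating-point accident.
- The truncation normalization uses log Φ differences computed in the left
  tail (log_ndtr with interval reflection), stable for sigma down to ~1e-3.

## Priors

By domain, following the approximately non-informative convention: strictly
positive parameters get Gamma(1e-3, 1e-3); real-valued parameters (only the
Gompertz shape) get Normal(0, precision 1e-3). The lognormal sdlog is
positive-domain and therefore receives the gamma prior on sigma itself;
`PriorSpec.overrides` swaps in any other (kind, p1, p2) per parameter.
These priors are genuinely diffuse: for 3-parameter families on immature
data they leave long, nearly-flat posterior ridges (see Limitations).

## Sampling

Component-wise adaptive random-walk Metropolis on the unconstrained scale
(positive parameters log-transformed; the log-Jacobian Σ u_k over
log-mapped components is added to the target). Defaults mirror the
reference schedule: 20,000 burn-in, 50,000 kept, 2 chains. Chains start at
an approximate posterior mode (Nelder-Mead from sufficient-statistic
heuristics) with distinct per-chain Gaussian jitter (sd 0.5), giving
over-dispersed starts for the convergence diagnostic.

Burn-in adaptation is phased:

1. Each chain adapts per-axis step sizes in windows of 50 iterations,
   targeting 0.44 acceptance with diminishing batch adjustments.
2. At half burn-in, the states of *all* chains are pooled and the Cholesky
   factor of their covariance becomes the shared proposal basis; steps then
   re-adapt along those directions. Pooling is repeated once more mid-way
   through the second half (axis-aligned exploration underestimates the
   extent of correlated ridges; the second estimate corrects the scale).
   A multivariate-t independence proposal (mean/1.5-sd-inflated covariance
   of the pooled states, 4 df) is also fitted and mixed in at rate 0.1,
   letting chains hop between separated posterior branches.
3. After burn-in the kernel is frozen (valid Metropolis throughout the
   sampling phase).

Each iteration additionally performs, with probability `slice_fraction`,
one rejection-free stepping-out/shrinkage slice move along a random
direction in the whitened metric (default: every iteration for families
with 3+ parameters, 30% of iterations otherwise). On the long flat ridges
of weakly identified families these travel much further per evaluation than
a random walk. Proposals per component also mix in occasional 5x kicks.

Families with three or more parameters — in practice the generalized gamma,
whose posterior under the diffuse priors has separated branches — also run
a tempered companion state per chain, targeting the posterior raised to
1/T (default T = 3, `hot_temperature`), updated by the same kernel and
coupled to the cold state by replica-exchange swaps each iteration. The hot
state crosses density barriers freely and hands branch-switching states to
the cold chain; only cold-state draws are recorded. The hot states' burn-in
history also feeds the independence-proposal fit, so branches discovered
only at high temperature are still covered by the mode-hopping proposal.

Acceptance rates after adaptation are recorded per component; the expected
band is [0.15, 0.6]. If an entire adaptation window passes with zero
acceptances the run aborts with a `StepSizeFailure` carrying the step sizes
and state. Fits with any PSRF above 1.05 are flagged in the CLI log; above
1.2 they are marked not converged (flagged in output, never silently
dropped).

## Diagnostics and model comparison

**Gelman-Rubin.** Classic potential scale reduction factor on the
unconstrained scale: W = mean within-chain variance, B/n = variance of chain
means, Vhat = (n-1)/n W + (1+1/m) B/n, Rhat = sqrt(Vhat/W). Byte-identical
chains give sqrt((n-1)/n) < 1, the textbook degenerate case.

**DIC.** Per-draw deviance is -2x the *fitted* log likelihood — IPD terms
plus, when constraints are present, the expert terms (DIC must score the
likelihood actually being fitted; `deviance_includes_experts=False` exposes
the IPD-only variant for sensitivity). The penalty p_D = Dbar - D(theta_hat)
uses the posterior mean on the unconstrained scale, back-transformed — the
mean of a constrained parameter can fall outside its domain, the
back-transformed unconstrained mean cannot. DIC = Dbar + p_D; lower is
better; on well-identified data p_D lands near the parameter count.

## Outputs

Survival curves are summarized pointwise (mean, median, equal-tailed 95%
credible band) over pooled draws on a monthly grid to 10 years, with exact
evaluations at the elicitation horizons. Bands are pointwise, not
simultaneous — the standard display convention. The 10-year restricted mean
survival (AUC) is the per-draw trapezoid integral of S(t) on the monthly
grid, then summarized across draws; halving the grid step moves it by less
than 0.005 years for all seven families at typical parameters
(refinement-checked in the suite), and the AUC-of-the-mean-curve variant is
available on request. Kaplan-Meier overlays use the product-limit estimate
with Greenwood variance and a 99% log-log band (range-respecting), via
lifelines.

## Synthetic data

No individual-patient data ship with the package; the generator emulates
the observable design of the motivating phase-2 study. `simulate_trial`
draws event times from a chosen truth, enrolls subjects over an accrual
window (randomly uniform, or evenly spaced so the first subject's
administrative censoring time equals the full data cutoff), censors at
min(cutoff - enrollment, exponential dropout), and flags events.
`simulate_expert_consensus` fabricates (LPL, MLV, UPL) triplets from the
true curve: MLV rounded to a 0.05 grid, plausible intervals of width
0.10/0.10/0.05 at 3/5/10 years that shift (never shrink) at the [0, 1]
boundary, preserving the MLV = LPL = 0 boundary case at 10 years.

`karmma_like_fixture` packages a calibrated scenario: n = 140, 12-month
accrual, 22.6-month cutoff, truth Weibull(shape 0.98, rate 0.41013) —
chosen so true survival at 3/5/10 years (0.300, 0.137, 0.020) sits inside
the published consensus ranges (25-35%, 5-20%, 0-5%) and realized median
follow-up lands in 10-14 months with a 35-65% event fraction. Realizations
violating those targets are discarded and redrawn from deterministic
sub-seeds (typically 0-2 retries).

What the generator does **not** emulate: patient covariates, response/PFS
outcomes, inter-expert disagreement (it fabricates one consensus, not six
expert opinions), correlation of judgments across horizons, and informative
dropout. Passing tests therefore demonstrate correctness of the machinery
and the qualitative expert-constraint behavior, not agreement with any
real trial's numbers.

## Problem sizes in the test suite

The suite exercises the pipeline at reduced scale, chosen as the smallest
sizes at which each property is sharply testable: fixture fits use 2 chains
x 5,000 kept after 2,000 burn-in; the conjugacy check uses n = 200 subjects
(~175 events); recovery studies use 20 replicates per family at n = 500
with ~25% administrative censoring, 2 x 1,600 kept after 800 burn-in
(2 x 3,000 after 1,500 for the generalized gamma, whose posterior needs
longer exploration), with a coverage threshold of 17/20 — the binomial
2.5th percentile of nominal 95% coverage at 20 draws.

## Known limitations

- The generalized gamma under the diffuse gamma priors is only weakly
  identified by immature censored data: its posterior is a long curved
  ridge (corr(log shape, log power) ≈ -0.998 on the fixture) with a
  second, rarely-visited branch. The tempered companion state and slice
  moves exist for exactly this geometry; without them, parameter-space
  PSRF exceeds 1.05 in a sizeable fraction of reduced-length runs.
  Functionals (S(t), AUC, DIC) are far more stable than the raw
  parameters.
- Expert uncertainty is not linked to trial size: a larger trial outweighs
  the same constraints, but nothing calibrates sigma_j to N.
- No covariates, treatment effects, relative-survival adjustment, or
  flexible (spline/mixture/fractional-polynomial) baselines; one
  truncated-normal consensus per horizon, independent across horizons.
- Month-to-year conversion is exactly 1/12; calendar subtleties are out of
  scope.
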