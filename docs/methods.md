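# Methods

## Chained model specification

A chain is `M >= 3` submodels `p_m(phi_m, psi_m, Y_m)` in which only
adjacent submodels share parameters: `phi_{m∩m+1}` is common to submodels
`m` and `m+1`, `phi_m` collects the (one or two) overlap blocks of
submodel `m`, and `psi_m` is everything else. The package identifies
shared quantities by *named slots with declared dimensions*
(`PhiLayout`); the concatenated `phi` layout is canonicalised once at
chain construction so that pooled priors, replacement ratios and samplers
can never silently misalign coordinates. `validate_chain` enforces the
contract: adjacency-only sharing, matching slot dimensions across each
overlap, unique overlap names.

Marginal replacement modifies submodel `m` so its `phi`-marginal equals a
common pooled prior:

    p_repl,m(phi, psi_m, Y_m) = p_pool(phi) p_m(phi_m, psi_m, Y_m) / p_m(phi_m),

the KL-closest such modification. The Markov combination of the replaced
submodels is the chained melded model whose posterior all samplers target.
Two structural assumptions matter in practice:

- each submodel must supply its `phi`-marginal analytically (or as a
  user-fitted parametric form). The library never estimates a marginal
  from draws — density estimation of marginals is fragile, especially for
  mixed discrete/continuous quantities — and interior-joint
  marginalisation is either the caller's closed form or explicit 1-D
  quadrature (`marginal_via_quadrature`) on a declared support;
- when a shared quantity is a deterministic function of a submodel's
  parameters, that submodel exposes the pushforward marginal directly; no
  inversion is attempted.

If `p_m(phi_m) = 0` somewhere the pooled prior is positive, the
replacement ratio is undefined; this raises a support-mismatch error
rather than returning `-inf`, deliberately conservative because a
measure-zero mismatch cannot be distinguished from a modelling error at
evaluation time.

## Pooling operators

All four operators work in log space and return unnormalised densities:
normalising constants cancel in every Metropolis–Hastings ratio, so they
are never computed for sampling. A Simpson-quadrature normaliser and
moment/correlation diagnostics exist for problems of dimension <= 2
(grids default to 201 points per axis over the mean +- 8 marginal
standard deviations; at that truncation the omitted Gaussian mass is
~1e-15 and the quadrature error is far below the 1e-6 agreement the
tests demand).

Logarithmic pooling enforces nonnegative weights and warns — rather than
errors — when `sum(lam) < 1`, because whether the pooled prior remains
proper then depends on tail behaviour the library cannot verify
generically. Linear pooling takes per-overlap weight pairs
`(lam_{m,1}, lam_{m,2})`; the flat weight-vector notation sometimes used
for presentations is not part of the API. For Gaussian marginals,
logarithmic pooling has the exact closed form of weighted precision
addition (`gaussian_pool_closed_form`), which doubles as the oracle for
the generic grid implementation; the middle weight `lam_2` controls the
pooled cross-overlap correlation monotonically (zero at `lam_2 = 0`,
rising toward the middle prior's own correlation).

Partial dictatorial pooling keeps one submodel's joint prior verbatim and
pools the remaining components with a standard operator per side. The
admissible argument sets for the side operators are not constrained:
either standard operator may be used on either side, with the side
factors built from the available submodel marginals over the remaining
overlaps. For `M = 3` with the middle submodel authoritative both sides
are vacuous, which is the configuration anything downstream relies on.

## Two-stage sampler

The sampler assumes the decomposition
`p_pool(phi) = p_pool,1(phi_{1∩2}) p_pool,2(phi_{1∩2}, phi_{2∩3}) p_pool,3(phi_{2∩3})`.
`decompose_pooled` offers *flat sides* (sides improper/flat, middle
carries everything) and *subprior sides*
(`p_pool,1 = p_1(phi_{1∩2})`, `p_pool,3 = p_3(phi_{2∩3})`), under which
the stage-one targets reduce to the ordinary subposteriors — the default
for the owls fit, because it lets existing submodel samplers be reused
unchanged.

Stage one uses an adaptive random-walk Metropolis sampler (global step
size by Robbins–Monro toward acceptance 0.234, proposal covariance from
the running chain covariance, both frozen after warmup) unless a submodel
carries a direct subposterior sampler. Draws may be thinned when
within-chain correlation is high.

Stage two sweeps three blocks in the fixed order side-1, side-3, psi_2
(a deterministic-scan Gibbs justification is assumed; random scan is
available behind a flag). Index proposals are drawn uniformly *with*
replacement from the stage-one pools — ties between equal rows need no
tie-breaking since their ratios are identical — and the acceptance
ratios contain only the middle submodel and middle pooled factor, whose
current log-values are cached and refreshed on acceptance. The default
psi_2 kernel is a componentwise Gaussian random walk whose per-component
scales adapt (toward 0.44 acceptance) only during warmup — 10% of sweeps
by default, discarded — and are frozen afterwards, preserving the
stationary distribution. A side whose pool has a single row is degenerate
but valid (it is logged, and the other blocks still move); a block with
no acceptances over a configurable window triggers a mixing warning, not
an error.

Seed policy: one root seed; the stage-one side streams and each stage-two
chain derive their generators deterministically from it, so stages are
independently re-runnable and whole runs reproduce bit-for-bit.

### Monte-Carlo error of two-stage estimates

A two-stage posterior mean carries two error sources: the stage-two chain
and the finite stage-one pool it recycles (the long-run distribution is
proportional to the *empirical* pool density times the melded weight).
Wherever the package's validation compares two-stage means against an
oracle "within k standard errors", the standard error is the combination
`sqrt(mcse_stage2^2 + sd_pool^2 / ESS_pool)`; for side quantities the
pool term usually dominates. ESS and split-R̂ come from ArviZ.

## Normal-approximation melding

When the outer subposteriors are well approximated by Gaussians and
`psi_1, psi_3` are not of interest, the side information collapses into a
single Gaussian correction factor with

    Sigma = (Sigma_nu^{-1} - Sigma_de^{-1})^{-1},
    mu    = Sigma (Sigma_nu^{-1} mu_nu - Sigma_de^{-1} mu_de),

where the numerator stacks the two subposterior summaries
block-diagonally and the denominator the two prior summaries (under PoE
pooling the denominator terms vanish and the correction is the numerator
itself). The default Gaussian fit is moment matching of draws — what a
normal approximation of MCMC output conventionally means in multi-stage
practice — with a Laplace-at-mode fit available as an option. The
precision difference must be positive definite (eigenvalue floor 1e-10);
failure is fatal, because a subposterior no tighter than its prior in
some direction makes the correction non-integrable. Because `psi_1` and
`psi_3` are integrated out by assumption, the approximate posterior
simply omits them; their uncertainty is not reported.

## The owls integrated population model

Three submodels observe one owl population over `T` years (0-based
internally; recapture column `T` means "never recaptured"):

- **capture-recapture**: releases per age class (J/A), sex (M/F) and year
  follow multinomials over recapture years with cell probabilities
  `Q[t, u] = delta_t pi_u prod_{r=t+1}^{u-1} delta_r (1 - pi_r)` and a
  complement column that makes each row sum to exactly one;
- **counts**: observed female counts are Poisson around the latent total
  `x_t = x_{J,t} + x_{A,t}`, with Poisson recruitment at rate
  `x_{t-1} (rho/2) delta_{J,F,t-1}` (half of fledglings are female — the
  reading made explicit here because the rate is sometimes typeset
  ambiguously), binomial adult survival `sur_t ~ Bin(x_{t-1}, delta_{A,F,t-1})`
  and Poisson immigration at rate `x_{t-1} eta_t`; a zero population
  forces point masses at zero;
- **fecundity**: fledgling totals `n_t ~ Poisson(N_t rho)` given observed
  breeding females `N_t`.

Rates come from linear predictors
`logit(delta_{a,s,t}) = alpha0 + alpha1 1(s=M) + alpha2 1(a=A)`,
`log(eta_t) = alpha6`, `logit(pi_{s,u}) = alpha4 1(s=M) + alpha5_u`
(`u = 2..T`; `alpha5_u` is shared across sexes with the male offset
`alpha4`; `pi` at the post-study year is never needed, being absorbed in
the complement column). `delta` is constant over `t` under this
parameterisation but stored per-(a, s, t) to keep the multinomial
machinery general. Priors: every `alpha` component Normal(0, 2^2)
truncated to [-10, 10]; `rho ~ Uniform(0, 10)`; initial populations
discrete uniform on {0, ..., 50}.

The shared quantities are `phi_{1∩2} = (alpha0, alpha2)` and
`phi_{2∩3} = rho` (`alpha1` is male-specific and absent from the count
submodel, so it stays idiosyncratic). Because all submodels place the
same independent priors on the shared quantities, logarithmic pooling at
weights (1/2, 1/2, 1/2) reproduces those priors exactly and the melded
model *is* the monolithic joint model — the property the validation
exploits by comparing the two-stage fit with direct MCMC on the joint
model. PoE pooling squares and renormalises the shared priors
(concentrating them around zero); equal-weight linear pooling mixes
identical densities and changes nothing.

Latent integer states (`x_{J,t}`, initial adult count, `sur_t`, `imm_t`)
are updated by single-site symmetric integer random walks (steps
+-1, +-2) inside the psi_2 block; marginalisation is not attempted. The
fecundity subposterior is conjugate (truncated Gamma) and sampled
directly in stage one; the capture-recapture side uses the adaptive RWMH.
The count-process log-pmf and the `Q`-table construction are JIT-compiled
(numba) on the sampler hot path, with pure-numpy reference
implementations retained and tested for agreement.

### What the simulator emulates — and what it does not

`simulate_ipm` draws data from exactly the likelihoods above, with
defaults chosen as a plausible small monitoring scheme: `T = 15` years,
50 releases per age/sex/year stratum, initial juvenile/adult female
populations of 20, juvenile female survival ~0.26 (`alpha0 = -1.05`),
adult ~0.56 (`alpha2 = 1.3`), female recapture probability ~0.62
(`alpha5 = 0.5`), immigration rate ~0.20 (`alpha6 = -1.6`) and
`rho = 2.6` fledglings per breeding female — a slowly growing population.
Breeding females are taken to be the whole female population
(`N_t = x_t`). Real monitoring data differ in ways the simulator does not
emulate: unmodelled heterogeneity in survival and recapture (trap
response, year effects), breeding-female counts that are neither exact
nor equal to the total population, and model misspecification generally.
Passing the recovery study therefore demonstrates correctness of the
melding machinery and samplers *under the assumed model*, not robustness
of the owl model itself to field data.

Desk-scale study sizes used by the validation: stage one 28k–40k RWMH
iterations (thinned pools of 5k–10k rows), stage two 2 chains x 3k–6k
sweeps, 10 simulation replicates for the coverage study, and 12k-sweep
componentwise MCMC for the monolithic benchmark; the discrete-chain
stationarity check uses 10^6 sweeps against a 2x10^5-row exact iid pool.

## Numerical choices and degenerate inputs

- Truncated-normal and multinomial constants are precomputed once per
  dataset; multinomial coefficients are data constants and only nonzero
  cells contribute, so a capture-recapture likelihood evaluation is
  O(nonzero cells) after the O(T^2) `Q` build.
- Poisson/binomial pmfs treat a zero mean/size as a point mass at zero;
  `sur_t > x_{t-1}` and positive counts in zero-probability cells yield
  `-inf` (not exceptions), so samplers reject rather than crash.
- Latent values are carried as floats holding exact integers; likelihood
  code rounds via `rint` before validating, and the discrete-uniform
  prior rejects non-integers.
- Quantile convention for interval summaries: type 7 (linear
  interpolation), numpy's default.
- Interval tables default to 50/80/95/99% central intervals.

## Known limitations

- The two-stage sampler covers `M = 3`; longer chains can be specified
  and evaluated (`melded_log_density`) but need a generic sampler.
- Recycling a finite stage-one pool biases the stationary distribution by
  the pool's empirical error, vanishing as the pool grows; the validation
  accounts for it explicitly (see above).
- Joint proposals between the latent states and the survival parameters
  are not implemented, so the melded (and joint) owl posteriors mix
  slowly in `alpha0` (bulk ESS of order 10-100 per thousand sweeps);
  runs should be sized accordingly.
- Mixed discrete/continuous shared quantities, copula-based dependent
  linear pooling, and weight elicitation are out of scope.
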