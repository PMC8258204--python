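# Methods

`postrepro` estimates age-specific survival from yearly photo-identification
sighting histories, converts the fitted survival into life tables, quantifies
the postreproductive life stage with the postreproductive representation (PrR)
statistic and a simulation-based significance test, and predicts age-specific
local relatedness ("kinship dynamics") under alternative dispersal and mating
regimes.  This note records the models, conventions and design choices.

## Mortality laws

Four baseline hazards are supported — constant (Exponential), exponentially
increasing (Gompertz), power-law (Weibull) and plateauing (Logistic) — each
optionally extended with a Makeham constant `c` or a full bathtub (Siler-type)
shape with a declining juvenile term:

    mu(x) = exp(a0 - a1*x) + c + mu_baseline(x)

Conventions where more than one parameterisation is in circulation:

* Gompertz/Logistic use a log-scale level, `mu_b(x) = exp(b0 + b1*x)`.
* Weibull uses shape `b0 > 0` and rate `b1 > 0`: `mu_b(x) = b0*b1*(b1*x)^(b0-1)`.
* The Logistic hazard is `exp(b0 + b1*x) / (1 + exp(b0)(exp(b1*x)-1)/b1)`,
  the one-parameter-family member of the Vaupel logistic with unit
  heterogeneity, which rises like a Gompertz and plateaus at `b1`.  Only the
  law's qualitative character (a late-life plateau) matters downstream; the
  headline analyses use the bathtub Gompertz.

All cumulative hazards are closed-form; survivorship is `S(x) = exp(-H(x))`.
Life expectancy integrates `S` by adaptive quadrature with an age cap of 150
years (survivorship there is < 1e-12 for any plausible parameters); life-span
quantiles invert `H` by bracketed root finding; random ages at death invert
the CDF by vectorised bisection.  The canonical set of ten fitted laws is the
constant hazard plus the three age-dependent baselines under each of the
three shapes; a Makeham or bathtub Exponential would duplicate members of
that set and is rejected at construction.

## Capture–mark–recapture likelihood

The data are a yearly 0/1 detection matrix over a study window plus
per-individual metadata (sex, birth year, death year; 0 = unknown).  Given
birth year `b` and death year `d`:

* death in year `d` contributes the age-at-death density evaluated at the
  midpoint of the death year, `mu(x+1/2) S(x+1/2)` with `x = d - b` (the
  midpoint convention also removes the age-0 singularity of Weibull-type
  hazards);
* an animal alive at the study end contributes `S(end + 1 - b)`;
* detection contributes a Bernoulli term per alive year inside the window,
  with a recapture probability per fixed 10-year calendar block from the
  study start (partial final block allowed);
* a known-birth animal born before the study start enters conditionally on
  survival to the start (division by `S(start - b)`).

Unknown birth and death years are latent integer variables.  Latent death
years range over [last sighting, end + 1], where `end + 1` is the censored
state.  Latent birth years range over [first sighting − 100, min(first
sighting, start)] and carry a *normalised stable-population prior*,
`pi(b) = S(entry age) / Z(theta)` with `Z(theta) = sum_e S(e)` over the
individual's admissible entry ages — the probability that a birth-cohort
member is alive at the study start at all.  The `S(entry)` factor exactly
cancels the left-truncation division, so an unknown-birth animal contributes
the full age-at-death density, and the normaliser enters the parameter
updates as `-log Z` per unknown-birth animal (it cancels in latent moves and
is recomputed only on parameter proposals).  Both pieces matter, and both
failure modes were observed in simulation before settling on this form:
a flat latent-birth prior kept *with* the truncation division lets
flat-hazard laws integrate over a wide range of entry ages and spuriously
dominate (the senescence slope collapsed towards zero), while dropping the
division *without* the `1/Z` normaliser hands every unknown-birth animal as
spurious evidence for low-senescence laws (estimated female life span
doubled).  With the normalised prior, parameter recovery is unbiased (see
the acceptance suite) and the posterior mean latent birth years sit within
a year of truth.

Sex enters by full stratification: separate mortality parameters per sex,
shared recapture probabilities.  Unknown-sex individuals are handled by the
permutation wrapper, which assigns F/M independently with probability 1/2 and
refits, once per permutation.

### Sampler

A Metropolis-within-Gibbs sampler advances all chains simultaneously through
array operations:

* per-sex blocked random-walk updates of the mortality parameters with an
  adaptive proposal covariance (Haario-style: estimated from the chain
  history during burn-in, scaled by 2.38²/k, plus a scalar factor tuned to a
  0.2–0.5 acceptance rate; both frozen after burn-in);
* conjugate Beta draws of the per-block recapture probabilities under a
  uniform prior (detections and misses over latent alive-years are binomial);
* element-wise integer random-walk updates of the latent years (individuals
  are conditionally independent given the parameters); proposals mix local
  (±1–3) and long-range (±4–12) moves, and birth- and death-year sweeps
  alternate between iterations.

Priors on mortality parameters are independent normals, truncated at zero
for rate-like parameters.  The defaults for the bathtub Gompertz are the
published whale-informed values — a0(−3, 1), a1(0.2, 0.05), c(0.001, 0.001),
b0(−4, 1), b1(0.05, 0.01) — and other laws get weakly informative analogues.
Simulation studies in the test suite deliberately widen the rate priors
(e.g. b1 sd 0.1) because their synthetic truths are not killer-whale-like;
a recovery study run under a sharply conflicting prior would measure prior
dominance, not estimator quality.

Convergence is summarised by split-R̂ (via ArviZ) for every mortality and
recapture parameter; `passed` means all R̂ < 1.1, and a failed check warns
but still returns the draws.  Two MCMC presets exist: `paper`
(4 chains × 1,000,000 iterations, 200,001 burn-in, 10,001 thinning — the
published protocol) and `desk` (4 × 20,000, 5,000, 10) for interactive work;
the desk preset converges comfortably on datasets of a few hundred
individuals.

DIC is `D̄ + pD` with `pD = D̄ − D̂`: the mean deviance over retained draws
(each with its own latent years) minus the deviance at the posterior means
of the mortality/recapture parameters with latent years at their posterior
medians.  The sex covariate is assessed by the symmetrised Kullback–Leibler
divergence between moment-matched normal approximations of the two sexes'
marginal posteriors, calibrated onto (0.5, 1] via
`q = (1 + sqrt(1 − e^{−2k}))/2` (0.5 = identical posteriors).

## Life tables and fecundity

Ages are integer years, age 0 = year of birth.  Survivorship envelopes are
pointwise quantiles (2.5/50/97.5%) of posterior survivorship curves, pooled
across permutations when several fits are supplied.  Discrete remaining
expectancy uses trapezoid person-years, `e_x = sum_{y>=x}(l_y+l_{y+1})/2 /
l_x`, and `T_x = l_x e_x`; it agrees with continuous quadrature within 0.5
years for all ten laws (acceptance check).  The average life span is `e_0`;
the 90% life span is the age where `l_x` crosses 0.1, interpolated within
the year.

Fecundity `m_x` is births to females of age x divided by female-years at age
x with known birth status; a female-year is status-unknown when the female
was not detected that year, and such years are excluded from numerator and
denominator alike.  Ages `B` and `M` are the smallest integer ages at which
the cumulative share of `sum m_x` reaches 5% and 95% — the unweighted `m_x`
schedule, not `l_x m_x` (an `l_x`-weighted variant would conflate survival
and fertility declines; the statistic is defined on the fecundity schedule
itself).

## PrR and its null test

`PrR = T_M / T_B`: the fraction of adult female person-years lived after
reproductive cessation.  The null hypothesis is that fecundity declines at
the same rate as survivorship, operationalised as *reproduction until
death*: each of `n` simulated females draws her age at death from the fitted
survival curve and reproduces with a constant yearly probability (default
0.2 from maturity at 10) until she dies.  Each null cohort's own empirical
life table and fecundity schedule give its own `B`, `M` and PrR — under this
construction per-capita fecundity never declines, so `M` is dragged to the
oldest observed ages and the null PrR concentrates at 0 (median ≈ 4e-4 for
999 cohorts of 1,000).  The p-value is the +1/+1-corrected exceedance count,
`p = (#{null PrR >= observed} + 1)/(n_null + 1)`; with several observed
values (one per sex permutation) each gets its own p-value.

## Synthetic data generator

The generator emulates the structure the inference assumes: yearly time
steps; births from an age-specific fecundity schedule (default: onset 11,
plateau 0.11 births/female-year over 15–35, cessation by 43 — the plateau is
set so R0 ≈ 1 and the age structure is stationary); sex 1:1 at birth;
deaths from sex-specific bathtub hazards (defaults give female expectancy
33.8 y and 90% life span 56.6 y, male 17.7/32.4 y); founders with ages from
the survivorship-weighted stationary distribution and a 40-year burn-in;
decade-blocked detection (default 0.9); and the masking rules of real
photo-identification datasets — animals dead before the study are absent,
birth years of animals born before the study start are unknown (0), animals
alive at the study end are right-censored, animals never detected are
dropped, and sexes of animals last seen below age 15 are masked to unknown
with configurable probability.  Each individual consumes its own
counter-based random stream keyed by (master seed, individual index), so
regeneration is bit-identical and added individuals do not perturb existing
histories.

What the generator does *not* emulate: social/matriline structure in
detection (heterogeneous, correlated sighting probabilities), birth-year
estimation error of ±1 year, immigration/emigration, and time-varying
mortality.  Passing recovery tests therefore show the estimator is correct
under its own assumptions, not that those assumptions hold in any particular
field dataset.

## Kinship dynamics

A pedigree-explicit simulation of a maternal group of constant size `n`:
each member dies with probability `1/mu` per year and is replaced by a
newborn of a surviving mature group female, sired within-group with
probability `m` (else by an unrelated outsider); maturing females (age 10)
disperse with probability `d` and are replaced by unrelated immigrants of
the same age, with an optional switch to let males disperse too.
Relatedness follows `r(child, x) = (r(mother, x) + r(father, x))/2` from
unrelated founders, ignoring inbreeding corrections.  A female's mean
relatedness to co-members is recorded against her age after a burn-in of
10·mu years and averaged across replicate groups; the Monte Carlo SE is
taken across replicates.  The three standard scenarios are resident
(d=0, m=0.01, µ=50, n=4) and low/high-dispersal Bigg's variants (d=0.5/0.8,
m=0.2, µ=38, n=4).  Under full dispersal (d=1, both sexes) a small residual
relatedness (~0.07) remains because a female's own offspring stay in the
group until maturity; this is a property of the replacement-birth model, not
a bug.  The published figure's qualitative ordering — relatedness rising
with female age, more steeply for residents than for high-dispersal
Bigg's — is reproduced beyond Monte Carlo error.

## Numerical and scale choices

* Test-suite simulation sizes (hundreds of individuals, the desk MCMC
  preset, 199–999 null cohorts) are chosen so the full suite runs on one
  CPU in well under half an hour while keeping every statistical conclusion
  unambiguous; the `paper` preset reproduces the published protocol when
  the archived data are available.
* The calibration study reuses each simulated null set for 20 of its 200
  replicates (10 independent sets in total); the rejection-rate estimate is
  unaffected in expectation.
* Degenerate inputs fail loudly: empty datasets, all-unknown birth
  statuses, all-zero fecundity schedules, zero survivorship at `B`,
  single-member kinship groups and non-mixing chains all raise or warn
  explicitly rather than returning silent numbers.

## Known limitations

* Recapture probabilities are shared between sexes and homogeneous within a
  decade block; individual sighting heterogeneity is not modelled.
* The latent birth-year prior assumes an approximately stationary age
  structure at study entry; strong population growth would tilt entry ages
  younger than the prior implies.
* DIC uses the conditional (latents-in) deviance; alternatives (WAIC,
  marginal DIC) would penalise latent dimensionality differently.
* The kinship module is a simulation predictor, not the analytic recursion
  behind the original theory; it reproduces orderings and shapes, not
  closed-form values.
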