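# postrepro

Demographic analysis of postreproductive life span in long-lived social
mammals, built around yearly photo-identification sighting data of the kind
collected for killer whale (*Orcinus orca*) populations.

Individual-based field studies of long-lived species face three chronic
problems: animals born before the study have unknown birth years, animals
alive at its end have unknown death years, and imperfect yearly detection
leaves gaps.  `postrepro` provides the full analysis chain that handles all
three:

* **Bayesian capture–mark–recapture survival estimation** under parametric
  mortality laws (Exponential, Gompertz, Weibull, Logistic, each with simple,
  Makeham or bathtub/Siler shape), with unknown birth and death years as
  latent variables, sex-stratified parameters, decade-blocked recapture
  probabilities, split-R̂ convergence checks, DIC model ranking and a
  Kullback–Leibler assessment of the sex covariate.  The headline model is
  the bathtub Gompertz, μ(x) = e^(a₀−a₁x) + c + e^(b₀+b₁x).
* **Sex permutations**: individuals of unknown sex are assigned F/M at 1:1
  and the model refit per permutation, propagating that uncertainty into
  every downstream quantity.
* **Life tables and fecundity schedules**: survivorship l_x with credible
  envelopes, remaining expectancy e_x, person-years T_x = l_x·e_x, and
  age-specific fecundity m_x estimated with a known-birth-status filter;
  ages B and M mark 5% and 95% of cumulative fecundity.
* **Postreproductive representation**: PrR = T_M/T_B, the fraction of adult
  female years lived after reproductive cessation, with a significance test
  against simulated null populations in which fecundity declines at the same
  rate as survivorship (each female reproducing until her own death) and the
  +1/+1 permutation p-value p = (#{null ≥ observed}+1)/(n_null+1).
* **Kinship dynamics**: an individual-based pedigree model predicting how a
  female's mean relatedness to her group changes with age under given
  dispersal (d), within-group mating (m), life span (µ) and group size (n).
* **A synthetic-data generator** reproducing the full statistical structure
  of such studies (age-specific fecundity with cessation, bathtub mortality,
  1:1 sex ratio with masking of young animals' sexes, left truncation, right
  censoring, blocked detection), so every stage is testable without any
  data download.

## Worked example

Simulate a resident-like population, fit the bathtub Gompertz with the desk
MCMC preset, and test for a postreproductive life span:

```python
import numpy as np
from postrepro import SimConfig, simulate_population, lifespan_summaries
from postrepro import cmr, lifetable, prr
from postrepro.simulate import make_birth_records_from_dataset

cfg = SimConfig(seed=42, n_initial=300)          # defaults: female e0 ~33 y
truth, data = simulate_population(cfg)

# one 1:1 sex assignment for the unknown-sex individuals
rng = np.random.default_rng(42)
assign = {i: ("F" if rng.random() < 0.5 else "M")
          for i in data.meta.loc[data.meta["sex"] == "U", "id"]}

priors = (cmr.PriorSpec.default("gompertz", "bathtub")
          .with_param("b0", -5.5, 1.0).with_param("b1", 0.07, 0.03))
draws, report = cmr.fit(data.with_sexes(assign), "gompertz", "bathtub",
                        priors=priors, mcmc=cmr.MCMCConfig.desk_preset(seed=1))

ages = np.arange(101)
table = lifetable.LifeTable.from_lx(
    ages, lifetable.lx_from_draws(draws, "F", ages)["median"])
sched = lifetable.estimate_mx(make_birth_records_from_dataset(data))
B, M = lifetable.ages_B_M(sched)
value = prr.compute_prr(table, B, M)
res = prr.prr_significance(value, draws.posterior_median_params("F"),
                           n_null=999, n_pop=1000,
                           rng=np.random.default_rng(2))
```

Output (about a minute on one CPU):

```
observed individuals: 600
converged: True (max R-hat 1.008)
female average life span: 33.1 y, 90% life span: 58.2 y
male   average life span: 18.0 y, 90% life span: 31.9 y
reproductive span: B = 12, M = 36
PrR = 0.608, p = 0.0010 (median null PrR 0.0003)
```

Reading the numbers: the sampler converged (all split-R̂ < 1.1); estimated
female survival matches the generator's truth (32.6 / 57.8 y); 5% of
lifetime fecundity is realised by age 12 and 95% by age 36; 61% of adult
female person-years are lived after age M, and none of 999 null cohorts —
in which reproduction continues until death — reached that value, so the
postreproductive life span is significant at the smallest attainable
p-value, 1/1000.

The same pipeline runs from the command line:

```bash
postrepro simulate --seed 42 --n-initial 300 --outdir simdata
postrepro run --metadata simdata/metadata.csv --sightings simdata/sightings.csv \
              --outdir results --seed 1
```

The `paper` preset (`RunConfig(preset="paper")`) switches every setting to
the full published protocol — 4 chains of 1,000,000 MCMC iterations,
1,000 sex permutations, 9,999 null populations — for use with the real
archived sighting datasets.

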