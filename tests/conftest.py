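import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from postrepro import cmr
from postrepro.mortality import MortalityParams
from postrepro.simulate import SimConfig, simulate_population

#: short-lived Gompertz-bathtub truth used by the shared fixtures; most
#: individuals die inside a 40-year window, so fits are well informed
SHORT_LIVED = MortalityParams("gompertz", "bathtub", a0=-3.0, a1=0.2,
                              c=0.001, b0=-4.5, b1=0.1)

#: weakly informative priors for simulation studies at the truth above
WIDE_PRIORS = (
    cmr.PriorSpec.default("gompertz", "bathtub")
    .with_param("a1", 0.2, 0.1)
    .with_param("c", 0.001, 0.01)
    .with_param("b0", -4.0, 2.0)
    .with_param("b1", 0.05, 0.1)
)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated study with unknown sexes/births (shared)."""
    cfg = SimConfig(seed=7, n_initial=150, mortality_female=SHORT_LIVED,
                    mortality_male=SHORT_LIVED,
                    fecundity_mx=SimConfig().fecundity_mx * 2.2,
                    p_sex_unknown=0.35)
    truth, data = simulate_population(cfg)
    return cfg, truth, data


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A quick (non-desk) fit of the shared dataset, sexes assigned 1:1."""
    _, _, data = small_sim
    rng = np.random.default_rng(0)
    assign = {i: ("F" if rng.random() < 0.5 else "M")
              for i in data.meta.loc[data.meta["sex"] == "U", "id"]}
    data = data.with_sexes(assign)
    mcmc = cmr.MCMCConfig(n_chains=4, n_iterations=4000, burn_in=1500,
                          thinning=10, seed=11)
    draws, report = cmr.fit(data, "gompertz", "bathtub",
                            priors=WIDE_PRIORS, mcmc=mcmc)
    return data, draws, report
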