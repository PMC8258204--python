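import math

import numpy as np
import pandas as pd
import pytest

from postrepro import cmr
from postrepro.io import SightingDataset
from postrepro.mortality import MortalityParams
from postrepro.simulate import simulate_known_age_cohort


def one_individual(birth=2000, death=2010, start=1995, end=2015, det_years=None):
    years = np.arange(start, end + 1)
    det = np.zeros(len(years), int)
    if det_years is None:
        det_years = range(max(birth, start), min(death, end) + 1)
    for y in det_years:
        det[y - start] = 1
    meta = pd.DataFrame({"id": ["w1"], "sex": ["F"], "birth_year": [birth],
                         "death_year": [death]})
    mat = pd.DataFrame(det[None, :], index=pd.Index(["w1"], name="id"),
                       columns=years)
    return SightingDataset(meta, mat, start, end)


class TestLogLikelihood:
    def test_exponential_death_density_closed_form(self):
        data = one_individual()
        c = 0.07
        ll = cmr.log_likelihood(data, {"F": MortalityParams("exponential", c=c)},
                                recapture=[1.0, 1.0, 1.0])
        # death at age 10, evaluated mid-year; certain detection adds 0
        x = 10.5
        assert ll == pytest.approx(math.log(c) - c * x, rel=1e-10)

    def test_certain_detection_contributes_zero(self):
        data = one_individual()
        params = {"F": MortalityParams("gompertz", "simple", b0=-4, b1=0.06)}
        ll_p1 = cmr.log_likelihood(data, params, recapture=[1.0] * 3)
        ll_p8 = cmr.log_likelihood(data, params, recapture=[0.8] * 3)
        # 11 alive years all detected: p=0.8 costs 11*log(0.8)
        assert ll_p8 - ll_p1 == pytest.approx(11 * math.log(0.8))

    def test_doubling_the_dataset_doubles_the_loglik(self):
        d1 = one_individual()
        meta = pd.concat([d1.meta, d1.meta.assign(id="w2")], ignore_index=True)
        mat = pd.concat([d1.matrix,
                         d1.matrix.set_axis(["w2"], axis=0)])
        mat.index.name = "id"
        d2 = SightingDataset(meta, mat, 1995, 2015)
        params = {"F": MortalityParams("gompertz", "simple", b0=-4, b1=0.06)}
        assert cmr.log_likelihood(d2, params, [0.9] * 3) == pytest.approx(
            2 * cmr.log_likelihood(d1, params, [0.9] * 3))

    def test_missed_year_with_certain_detection_is_log_zero(self):
        data = one_individual(det_years=[2000, 2002, 2010])
        params = {"F": MortalityParams("exponential", c=0.1)}
        assert cmr.log_likelihood(data, params, [1.0] * 3) == -np.inf

    def test_left_truncation_conditioning(self):
        # born before the study: density is conditioned on survival to entry
        data = one_individual(birth=1990, death=2010)
        c = 0.05
        ll = cmr.log_likelihood(data, {"F": MortalityParams("exponential", c=c)},
                                recapture=[1.0] * 3)
        x, entry = 20.5, 5.0
        assert ll == pytest.approx(math.log(c) - c * x + c * entry)

    def test_censored_individual_contributes_survival_only(self):
        data = one_individual(birth=2000, death=0,
                              det_years=range(2000, 2016))
        c = 0.05
        ll = cmr.log_likelihood(data, {"F": MortalityParams("exponential", c=c)},
                                recapture=[1.0] * 3)
        assert ll == pytest.approx(-c * 16.0)  # S(end + 1 - birth)


def _fake_draws(f_draws, m_draws, names=("b0", "b1")):
    C, T, k = f_draws.shape
    return cmr.PosteriorDraws(
        model="gompertz", shape="simple", param_names=tuple(names),
        theta={"F": f_draws, "M": m_draws},
        recapture=np.full((C, T, 1), 0.9),
        latent_birth=np.empty((C, T, 0)), latent_death=np.empty((C, T, 0)),
        unknown_birth_ids=np.array([]), unknown_death_ids=np.array([]),
        loglik=np.zeros((C, T)),
    )


class TestDiagnostics:
    def test_rhat_of_identical_chains_is_one(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 400, 2))
        draws = _fake_draws(np.tile(one, (4, 1, 1)), np.tile(one, (4, 1, 1)))
        report = cmr._convergence(draws, include_p=False)
        assert report.passed
        assert max(report.rhat.values()) < 1.02

    def test_diverged_chains_flagged(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(4, 200, 2))
        f[0] += 10.0  # one chain in a different mode
        draws = _fake_draws(f, f.copy())
        report = cmr._convergence(draws, include_p=False)
        assert not report.passed

    def test_kl_identical_posteriors(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(2, 500, 2))
        out = cmr.kl_covariate_discrepancy(_fake_draws(f, f.copy()))
        for v in out.values():
            assert v["kl_sym"] == pytest.approx(0.0, abs=1e-12)
            assert v["calibration"] == pytest.approx(0.5, abs=1e-6)

    def test_kl_unit_normals_one_apart(self):
        assert cmr._kl_normal(0, 1, 1, 1) == pytest.approx(0.5)
        assert cmr._kl_normal(1, 1, 0, 1) == pytest.approx(0.5)

    def test_kl_separated_posteriors_calibrate_near_one(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0.0, 0.05, size=(2, 500, 2))
        m = rng.normal(1.0, 0.05, size=(2, 500, 2))
        out = cmr.kl_covariate_discrepancy(_fake_draws(f, m))
        assert all(v["calibration"] > 0.99 for v in out.values())

    def test_kl_degenerate_posterior_fails(self):
        f = np.zeros((2, 100, 2))
        with pytest.raises(ValueError):
            cmr.kl_covariate_discrepancy(_fake_draws(f, f))


@pytest.fixture(scope="module")
def cohort_fit():
    """Known-age single-sex Gompertz cohort and a quick fit."""
    truth = MortalityParams("gompertz", "simple", b0=-4.2, b1=0.1)
    rng = np.random.default_rng(42)
    data = simulate_known_age_cohort(truth, 600, rng=rng)
    mcmc = cmr.MCMCConfig(n_chains=4, n_iterations=4000, burn_in=1500,
                          thinning=10, seed=8)
    priors = cmr.PriorSpec.default("gompertz", "simple") \
        .with_param("b0", -4, 2).with_param("b1", 0.05, 0.1)
    draws, report = cmr.fit(data, "gompertz", "simple", priors=priors,
                            mcmc=mcmc, fix_recapture=1.0)
    return truth, data, draws, report


class TestFit:
    def test_posterior_matches_truth_on_clean_cohort(self, cohort_fit):
        truth, _, draws, report = cohort_fit
        assert report.passed
        for sex in ("F",):
            lo, hi = np.percentile(draws.flat(sex), [1, 99], axis=0)
            med = np.median(draws.flat(sex), axis=0)
            i0 = draws.param_names.index("b0")
            i1 = draws.param_names.index("b1")
            assert lo[i0] <= truth.b0 <= hi[i0]
            assert lo[i1] <= truth.b1 <= hi[i1]

    def test_exponential_posterior_matches_analytic_mle(self):
        truth = MortalityParams("exponential", c=0.08)
        rng = np.random.default_rng(11)
        data = simulate_known_age_cohort(truth, 500, rng=rng)
        meta = data.meta
        event = meta["death_year"] > 0
        exposure = np.where(event,
                            meta["death_year"] - meta["birth_year"] + 0.5,
                            data.study_end + 1 - meta["birth_year"])
        mle = event.sum() / exposure.sum()
        mcmc = cmr.MCMCConfig(n_chains=4, n_iterations=3000, burn_in=1000,
                              thinning=5, seed=13)
        priors = cmr.PriorSpec.default("exponential", "simple") \
            .with_param("c", 0.05, 0.1)
        draws, _ = cmr.fit(data, "exponential", "simple", priors=priors,
                           mcmc=mcmc, fix_recapture=1.0)
        post_c = draws.flat("F")[:, 0]
        se = mle / np.sqrt(event.sum())
        assert abs(post_c.mean() - mle) < 2 * se

    def test_latent_years_respect_detection_bounds(self, small_fit):
        data, draws, _ = small_fit
        det = data.detection_years()
        first = det.loc[draws.unknown_birth_ids, "first"].to_numpy()
        last = det.loc[draws.unknown_death_ids, "last"].to_numpy()
        assert (draws.latent_birth <= first[None, None, :]).all()
        assert (draws.latent_death >= last[None, None, :]).all()
        assert (draws.recapture >= 0).all() and (draws.recapture <= 1).all()

    def test_unknown_sexes_rejected_with_guidance(self, small_sim):
        _, _, data = small_sim
        with pytest.raises(ValueError, match="permute"):
            cmr.fit(data, mcmc=cmr.MCMCConfig.desk_preset(0))


class TestDic:
    def test_true_model_beats_constant_hazard(self, cohort_fit):
        truth, data, draws_g, _ = cohort_fit
        mcmc = cmr.MCMCConfig(n_chains=4, n_iterations=3000, burn_in=1000,
                              thinning=5, seed=14)
        priors = cmr.PriorSpec.default("exponential", "simple") \
            .with_param("c", 0.05, 0.1)
        draws_e, _ = cmr.fit(data, "exponential", "simple", priors=priors,
                             mcmc=mcmc, fix_recapture=1.0)
        dic_g, pd_g = cmr.compute_dic(draws_g, data)
        dic_e, pd_e = cmr.compute_dic(draws_e, data)
        assert dic_g < dic_e
        assert pd_g > 0

    def test_ranking_sorted_ascending(self):
        comp = cmr.ModelComparison()
        comp.add("exponential", "simple", 120.0, 1.1)
        comp.add("gompertz", "simple", 100.0, 2.2)
        assert list(comp.ranking["DIC"]) == [100.0, 120.0]


class TestPermutations:
    def test_output_length_and_assignments(self, small_sim):
        _, _, data = small_sim
        mcmc = cmr.MCMCConfig(n_chains=2, n_iterations=400, burn_in=100,
                              thinning=5, seed=21)
        from conftest import WIDE_PRIORS

        results = cmr.permute_unknown_sexes(data, n_perm=3, mcmc=mcmc,
                                            priors=WIDE_PRIORS)
        assert len(results) == 3
        assert all(d is not None for d, _ in results)

    def test_random_assignment_is_balanced(self):
        # the 1:1 assignment rule, isolated from the MCMC
        rng_counts = []
        for j in range(500):
            rng = np.random.default_rng(np.random.SeedSequence(9, spawn_key=(j,)))
            rng_counts.append(sum(rng.random() < 0.5 for _ in range(100)))
        mean_f = np.mean(rng_counts)
        se = np.sqrt(0.25 * 100) / np.sqrt(500)
        assert abs(mean_f - 50) < 3 * se + 0.5


class TestObservedVsEstimated:
    def test_km_properties_and_agreement(self, cohort_fit):
        _, data, draws, _ = cohort_fit
        curves = cmr.observed_vs_estimated_survival(data, draws)
        assert curves["observed"].iloc[0] == pytest.approx(1.0)
        assert (np.diff(curves["observed"]) <= 1e-12).all()
        assert np.max(np.abs(curves["observed"] - curves["estimated_female"])) \
            < 0.05

    def test_requires_known_ages(self, cohort_fit):
        _, data, draws, _ = cohort_fit
        meta = data.meta.copy()
        meta["birth_year"] = 0
        anon = SightingDataset(meta, data.matrix, data.study_start,
                               data.study_end)
        with pytest.raises(ValueError):
            cmr.observed_vs_estimated_survival(anon, draws)
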