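import numpy as np
import pandas as pd
import pytest

from postrepro import lifetable as lt
from postrepro import mortality as mt
from postrepro.mortality import MortalityParams


def records(rows):
    return pd.DataFrame(rows, columns=["id", "year", "age", "status"])


class TestEstimateMx:
    def test_direct_ratio(self):
        rec = records([("a", 2000, 20, "birth"), ("b", 2000, 20, "no_birth"),
                       ("c", 2000, 20, "no_birth")])
        sched = lt.estimate_mx(rec)
        assert sched.mx[sched.ages == 20][0] == pytest.approx(1 / 3)

    def test_unknown_status_excluded_from_both_sides(self):
        rec = records([("a", 2000, 20, "birth"), ("b", 2000, 20, "no_birth"),
                       ("c", 2000, 20, "unknown")])
        sched = lt.estimate_mx(rec)
        assert sched.mx[sched.ages == 20][0] == pytest.approx(0.5)
        assert sched.unknown[sched.ages == 20][0] == 1

    def test_age_without_known_years_is_undefined(self):
        rec = records([("a", 2000, 20, "birth"), ("b", 2001, 21, "unknown")])
        sched = lt.estimate_mx(rec)
        assert np.isnan(sched.mx[sched.ages == 21][0])

    def test_all_unknown_fails(self):
        rec = records([("a", 2000, 20, "unknown")])
        with pytest.raises(ValueError):
            lt.estimate_mx(rec)


class TestAgesBM:
    def test_uniform_mass_over_11_to_30(self):
        ages = np.arange(0, 41)
        mx = np.where((ages >= 11) & (ages <= 30), 1.0, 0.0)
        B, M = lt.ages_B_M(lt.FecunditySchedule(ages=ages, mx=mx))
        assert (B, M) == (11, 29)

    def test_point_mass(self):
        ages = np.arange(0, 41)
        mx = np.where(ages == 17, 0.3, 0.0)
        assert lt.ages_B_M(lt.FecunditySchedule(ages=ages, mx=mx)) == (17, 17)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        ages = np.arange(0, 50)
        mx = np.where((ages >= 10) & (ages <= 42), rng.random(50), 0.0)
        s1 = lt.ages_B_M(lt.FecunditySchedule(ages=ages, mx=mx))
        s2 = lt.ages_B_M(lt.FecunditySchedule(ages=ages, mx=7.3 * mx))
        assert s1 == s2

    def test_all_zero_schedule_fails(self):
        with pytest.raises(ValueError):
            lt.ages_B_M(lt.FecunditySchedule(ages=np.arange(5),
                                             mx=np.zeros(5)))

    def test_undefined_ages_excluded_from_cumulative(self):
        ages = np.arange(0, 30)
        mx = np.where((ages >= 10) & (ages <= 20), 1.0, 0.0)
        mx[5] = np.nan
        B, M = lt.ages_B_M(lt.FecunditySchedule(ages=ages, mx=mx))
        assert (B, M) == (10, 20)


class TestLifeTable:
    def test_lifespan_summaries_hand_example(self):
        table = lt.LifeTable.from_lx([0, 1, 2], [1.0, 0.5, 0.0])
        avg, p90 = lt.lifespan_summaries(table)
        assert avg == pytest.approx(1.0)

    def test_90pct_lifespan_exponential(self):
        p = MortalityParams("exponential", c=0.1)
        ages = np.arange(0, 121)
        table = lt.LifeTable.from_lx(ages, mt.survivorship(p, ages * 1.0))
        avg, p90 = lt.lifespan_summaries(table)
        assert p90 == pytest.approx(23.03, abs=0.2)
        assert avg == pytest.approx(10.0, abs=0.5)

    def test_degenerate_rectangular_survival(self):
        A = 30
        lx = np.where(np.arange(61) <= A, 1.0, 0.0)
        table = lt.LifeTable.from_lx(np.arange(61), lx)
        avg, p90 = lt.lifespan_summaries(table)
        assert avg == pytest.approx(A, abs=1.0)
        assert p90 == pytest.approx(A, abs=1.0)

    def test_warns_when_lx_never_reaches_10pct(self):
        table = lt.LifeTable.from_lx([0, 1, 2], [1.0, 0.9, 0.8])
        with pytest.warns(UserWarning):
            _, p90 = lt.lifespan_summaries(table)
        assert p90 == 2.0

    def test_Tx_identity_and_monotone(self):
        p = MortalityParams("gompertz", "bathtub", a0=-3, a1=0.2, c=0.001,
                            b0=-5, b1=0.07)
        ages = np.arange(0, 121)
        table = lt.LifeTable.from_lx(ages, mt.survivorship(p, ages * 1.0))
        ok = table.lx > 0
        assert np.allclose(table.Tx[ok], (table.lx * table.ex)[ok])
        assert np.all(np.diff(table.Tx) <= 1e-12)

    def test_discrete_ex_close_to_continuous(self):
        p = MortalityParams("gompertz", "bathtub", a0=-3, a1=0.2, c=0.001,
                            b0=-5, b1=0.07)
        table = lt.LifeTable.from_params(p, max_age=150)
        for age in (0, 10, 30, 50):
            cont = mt.remaining_expectancy(p, float(age))
            assert table.at(age)[1] == pytest.approx(cont, abs=0.5)

    def test_nonincreasing_enforced(self):
        with pytest.raises(ValueError):
            lt.LifeTable.from_lx([0, 1, 2], [1.0, 0.5, 0.6])


class TestLxFromDraws:
    class _FakeDraws:
        def __init__(self, curves):
            self.curves = np.asarray(curves)

        def survivorship(self, sex, ages):
            return self.curves

    def test_single_draw_is_its_own_median(self):
        ages = np.arange(5)
        curve = np.exp(-0.1 * ages)
        env = lt.lx_from_draws(self._FakeDraws(curve[None, :]), "F", ages)
        assert np.allclose(env["median"], curve)

    def test_envelope_contains_median(self):
        rng = np.random.default_rng(0)
        ages = np.arange(20)
        curves = np.exp(-rng.uniform(0.02, 0.2, 50)[:, None] * ages)
        env = lt.lx_from_draws(self._FakeDraws(curves), "F", ages)
        assert np.all(env["lo"] <= env["median"] + 1e-12)
        assert np.all(env["median"] <= env["hi"] + 1e-12)

    def test_pooling_over_list(self):
        ages = np.arange(10)
        d1 = self._FakeDraws(np.exp(-0.05 * ages)[None, :])
        d2 = self._FakeDraws(np.exp(-0.15 * ages)[None, :])
        env = lt.lx_from_draws([d1, d2], "F", ages)
        expect = 0.5 * (np.exp(-0.05 * ages) + np.exp(-0.15 * ages))
        assert np.allclose(env["median"], expect)

    def test_empty_draws_fail(self):
        with pytest.raises(ValueError):
            lt.lx_from_draws([], "F", np.arange(5))


def test_estimated_mx_matches_configured_fecundity(small_sim):
    """With certain detection, m-hat_x is binomial around the true rates."""
    from postrepro.simulate import SimConfig, make_birth_records, \
        simulate_population

    cfg0, _, _ = small_sim
    cfg = SimConfig(seed=21, n_initial=150,
                    mortality_female=cfg0.mortality_female,
                    mortality_male=cfg0.mortality_male,
                    fecundity_mx=cfg0.fecundity_mx,
                    recapture_by_block=1.0, p_sex_unknown=0.0)
    truth, data = simulate_population(cfg)
    sched = lt.estimate_mx(make_birth_records(truth, data))
    checked = 0
    for age, m_hat, n_at_risk in zip(sched.ages, sched.mx, sched.at_risk):
        true_m = cfg.fecundity_at(int(age))
        if n_at_risk >= 30 and np.isfinite(m_hat):
            se = np.sqrt(max(true_m * (1 - true_m), 1e-4) / n_at_risk)
            assert abs(m_hat - true_m) <= 3.5 * se + 1e-9
            checked += 1
    assert checked >= 10
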