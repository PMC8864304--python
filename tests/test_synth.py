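"""Generator determinism, the softmax surface, and sampling laws."""

import numpy as np
import pytest

from csmf519.synth import (
    ScenarioConfig,
    make_truth,
    modelled_cause_order,
    simulate_envelopes,
    simulate_scenario,
    simulate_studies,
    true_csmf,
)
from csmf519.taxonomy import AgeSexGroup

G = AgeSexGroup.AGE_10_14
CFG = ScenarioConfig(
    n_countries=8, n_hqvr=1, n_lmm=3, n_study_countries=4, groups=(G,),
    n_envelope_draws=100,
)


class TestMakeTruth:
    def test_same_seed_identical_truth(self):
        a = make_truth(seed=3, config=CFG)
        b = make_truth(seed=3, config=CFG)
        assert np.array_equal(a.group_truth[G].beta, b.group_truth[G].beta)
        assert np.array_equal(a.group_truth[G].u, b.group_truth[G].u)
        assert a.covariates.equals(b.covariates)
        assert a.countries == b.countries

    def test_full_sparsity_zeroes_every_covariate_effect(self):
        t = make_truth(sparsity=1.0, seed=0, config=CFG)
        assert np.all(t.group_truth[G].beta[:, 1:] == 0)
        assert not t.group_truth[G].support.any()

    def test_half_sparsity_with_ten_covariates_gives_five_effects_per_cause(self):
        t = make_truth(P=10, sparsity=0.5, seed=0, config=CFG)
        gt = t.group_truth[G]
        assert np.all(gt.support.sum(axis=1) == 5)
        assert np.all((gt.beta[:, 1:] != 0) == gt.support)

    def test_random_effect_sd_matches_configuration(self):
        t = make_truth(seed=0, config=ScenarioConfig(n_countries=300, groups=(G,)))
        u = t.group_truth[G].u
        assert np.std(u) == pytest.approx(0.07, rel=0.15)


class TestTrueCsmf:
    def test_no_signal_gives_uniform_fractions(self):
        t = make_truth(sparsity=1.0, seed=0, config=CFG)
        gt = t.group_truth[G]
        gt.beta[:, 0] = 0.0
        gt.u[:] = 0.0
        C = len(gt.taxonomy.modelled_causes)
        p = true_csmf(t, G, np.zeros(CFG.n_covariates), 0)
        assert np.allclose(p, 1.0 / C)

    def test_intercept_bump_raises_that_cause(self):
        t = make_truth(seed=1, config=CFG)
        x = np.zeros(CFG.n_covariates)
        before = true_csmf(t, G, x, 0)
        t.group_truth[G].beta[2, 0] += 0.5
        after = true_csmf(t, G, x, 0)
        assert after[2] > before[2]

    def test_matches_independent_softmax_computation(self, rng):
        t = make_truth(seed=2, config=CFG)
        gt = t.group_truth[G]
        x = rng.standard_normal(CFG.n_covariates)
        j = 3
        # independent recomputation with explicit loops
        eta = [
            gt.beta[c, 0] + sum(gt.beta[c, 1 + p] * x[p] for p in range(len(x)))
            + gt.u[j, c]
            for c in range(gt.beta.shape[0])
        ] + [0.0]
        ex = np.exp(eta)
        assert np.allclose(true_csmf(t, G, x, j), ex / ex.sum(), atol=1e-12)


class TestSimulateStudies:
    def test_fixed_seed_reproducible(self):
        t = make_truth(seed=4, config=CFG)
        assert simulate_studies(t, seed=9) == simulate_studies(t, seed=9)

    def test_single_death_study_has_one_nonzero_cause(self):
        cfg = ScenarioConfig(
            n_countries=4, n_hqvr=0, n_lmm=0, n_study_countries=2,
            studies_per_country_group=2, mean_study_deaths=1e-9, groups=(G,),
        )
        t = make_truth(seed=5, config=cfg)
        for s in simulate_studies(t, seed=5):
            assert s.total_deaths == 1
            assert sum(v > 0 for v in s.deaths_by_cause.values()) == 1

    def test_mean_fractions_converge_to_truth(self):
        cfg = ScenarioConfig(
            n_countries=1, n_hqvr=0, n_lmm=0, n_study_countries=1,
            studies_per_country_group=400, mean_study_deaths=185,
            groups=(G,), ar1_rho=0.0,
        )
        t = make_truth(seed=6, config=cfg)
        studies = simulate_studies(t, seed=6)
        order = modelled_cause_order(t.group_truth[G].taxonomy)
        tot = np.zeros(len(order))
        n = 0
        expect = np.zeros(len(order))
        for s in studies:
            x = t.covariates.loc[(s.iso_code, s.year_mid)].to_numpy()
            expect += s.total_deaths * true_csmf(t, G, x, s.iso_code)
            tot += [s.deaths_by_cause[c] for c in order]
            n += s.total_deaths
        se = np.sqrt(np.maximum(expect / n * (1 - expect / n) / n, 1e-12))
        assert np.all(np.abs(tot / n - expect / n) <= 3 * se + 1e-3)


class TestSimulateEnvelopes:
    def test_zero_decline_zero_noise_constant_series(self):
        cfg = ScenarioConfig(
            n_countries=2, n_hqvr=0, n_lmm=0, envelope_decline=0.0,
            envelope_cv=0.0, groups=(G,),
        )
        t = make_truth(seed=7, config=cfg)
        env = simulate_envelopes(t, seed=7)
        per_country = {}
        for e in env:
            per_country.setdefault(e.iso_code, set()).add(round(e.deaths, 9))
        assert all(len(v) == 1 for v in per_country.values())

    def test_draw_mean_near_point_value(self):
        t = make_truth(seed=8, config=CFG)
        e = simulate_envelopes(t, seed=8)[0]
        draws = np.array(e.deaths_draws)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - e.deaths) <= 3 * se + 1e-9 * e.deaths
        assert min(e.deaths_draws) <= e.deaths <= max(e.deaths_draws)


class TestScenario:
    def test_crisis_exceeding_cap_present_by_construction(self):
        cfg = ScenarioConfig(
            n_countries=6, n_hqvr=1, n_lmm=2, crisis_rate=0.5, groups=(G,),
        )
        b = simulate_scenario(9, cfg)
        env = {(e.iso_code, e.year, e.group): e.deaths for e in b.envelopes}
        crises = [s for s in b.single_causes if s.cause == "crisis"]
        assert crises
        assert any(
            s.deaths / env[(s.iso_code, s.year, s.group)] > s.ghe_max_fraction
            for s in crises
        )

    def test_hqvr_pass_through_fractions_are_simplexes(self, small_bundle):
        vr = small_bundle.vr_csmfs
        sums = vr.groupby(["iso_code", "year", "group"])["fraction"].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)
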