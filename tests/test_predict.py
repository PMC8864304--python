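"""CSMF prediction, malaria structural rules, envelope application."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csmf519.predict import (
    CSMFDraws,
    MalariaConstraints,
    apply_envelope,
    apply_malaria_rules,
    predict_csmf,
)
from csmf519.model import ModelSpec, build_likelihood, fit
from csmf519.synth import ScenarioConfig, make_truth, simulate_studies
from csmf519.taxonomy import AgeSexGroup, default_taxonomy
from csmf519.types import Envelope, ValidationError

G59 = AgeSexGroup.AGE_5_9


def _draws(fractions, iso="X", year=2010, group=G59, causes=("malaria", "diarrhoea", "other_cmpn")):
    arr = np.atleast_2d(np.asarray(fractions, dtype=float))
    return CSMFDraws(iso, year, group, tuple(causes), arr)


def _constraints(caps=None, zero=()):
    return MalariaConstraints(
        incidence_zero=frozenset(zero), under5_fraction=caps or {}
    )


class TestMalariaRules:
    def test_cap_binds_and_excess_spreads_pro_rata(self):
        out = apply_malaria_rules(
            _draws([0.5, 0.3, 0.2]), _constraints({("X", 2010): 0.2})
        )
        np.testing.assert_allclose(out.draws[0], [0.2, 0.48, 0.32], atol=1e-12)

    def test_cap_not_binding_leaves_fractions_unchanged(self):
        out = apply_malaria_rules(
            _draws([0.1, 0.5, 0.4]), _constraints({("X", 2010): 0.2})
        )
        np.testing.assert_allclose(out.draws[0], [0.1, 0.5, 0.4], atol=1e-15)

    def test_zero_incidence_renormalizes_remaining_causes(self):
        out = apply_malaria_rules(
            _draws([0.5, 0.3, 0.2]), _constraints(zero={("X", 2010)})
        )
        # oracle: p_c / (1 - m) for the remaining causes
        np.testing.assert_allclose(out.draws[0], [0.0, 0.6, 0.4], atol=1e-12)

    def test_group_without_malaria_cause_passes_through(self):
        d = CSMFDraws(
            "X", 2010, AgeSexGroup.AGE_15_19_F,
            ("self_harm", "other_cmpn"), np.array([[0.3, 0.7]]),
        )
        assert apply_malaria_rules(d, _constraints({("X", 2010): 0.0})) is d

    def test_all_malaria_degenerate_case_spreads_uniformly(self):
        out = apply_malaria_rules(
            _draws([1.0, 0.0, 0.0]), _constraints({("X", 2010): 0.4})
        )
        np.testing.assert_allclose(out.draws[0], [0.4, 0.3, 0.3], atol=1e-12)

    def test_invalid_cap_is_an_error(self):
        with pytest.raises(ValidationError):
            _constraints({("X", 2010): 1.5})

    @given(
        fracs=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=3, max_size=6
        ),
        cap=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_simplex_and_ratios_preserved(self, fracs, cap):
        p = np.array(fracs) / np.sum(fracs)
        out = apply_malaria_rules(
            _draws(p, causes=("malaria",) + tuple(f"c{i}" for i in range(len(p) - 1))),
            _constraints({("X", 2010): cap}),
        )
        q = out.draws[0]
        assert abs(q.sum() - 1.0) < 1e-9
        assert q[0] <= cap + 1e-12 or q[0] == pytest.approx(p[0])
        # unchanged causes keep their ratios
        if p[1] > 1e-9 and p[2] > 1e-9:
            assert q[1] / q[2] == pytest.approx(p[1] / p[2], rel=1e-6)


class TestApplyEnvelope:
    def _env(self, deaths=1000.0, rate=2.0, draws=()):
        return Envelope(
            "X", 2010, G59, deaths, rate,
            deaths_draws=tuple(draws),
            rate_draws=tuple(d * rate / deaths for d in draws),
        )

    def test_quarter_three_quarter_split_of_thousand(self):
        d, r = apply_envelope(
            _draws([0.25, 0.75], causes=("a", "b")), self._env()
        )
        np.testing.assert_allclose(d[0], [250.0, 750.0])

    def test_cause_deaths_sum_to_envelope_each_draw(self, rng):
        p = rng.dirichlet(np.ones(5), size=40)
        env_draws = rng.uniform(800, 1200, size=40)
        d, r = apply_envelope(
            CSMFDraws("X", 2010, G59, tuple("abcde"), p),
            self._env(1000.0, 2.0, env_draws),
        )
        np.testing.assert_allclose(d.sum(axis=1), env_draws, rtol=1e-12)

    def test_envelope_spread_scales_with_fixed_fractions(self, rng):
        # SD(deaths_c) = fraction_c * SD(envelope) when fractions are fixed
        env_draws = rng.uniform(500, 1500, size=200)
        p = np.tile([0.2, 0.8], (200, 1))
        d, _ = apply_envelope(
            CSMFDraws("X", 2010, G59, ("a", "b"), p),
            self._env(1000.0, 2.0, env_draws),
        )
        assert d[:, 0].std() == pytest.approx(0.2 * env_draws.std(), rel=1e-9)


@pytest.fixture(scope="module")
def fitted():
    cfg = ScenarioConfig(
        n_countries=4, n_hqvr=0, n_lmm=0, n_study_countries=2,
        studies_per_country_group=3, n_covariates=2,
        groups=(AgeSexGroup.AGE_10_14,),
    )
    truth = make_truth(seed=41, config=cfg)
    studies = simulate_studies(truth, seed=42)
    spec = ModelSpec(
        taxonomy=default_taxonomy(AgeSexGroup.AGE_10_14),
        covariate_names=tuple(truth.covariates.columns),
        chains=2, warmup=200, samples=200,
    )
    return truth, fit(build_likelihood(studies, truth.covariates, spec), seed=43)


class TestPredictCsmf:
    def test_draws_are_simplexes_for_every_year(self, fitted):
        truth, post = fitted
        per_year = predict_csmf(post, truth.covariates, truth.countries[0].iso_code)
        assert len(per_year) == 20
        for d in per_year.values():
            np.testing.assert_allclose(d.draws.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(d.draws >= 0)

    def test_missing_country_is_an_error(self, fitted):
        truth, post = fitted
        with pytest.raises(ValidationError, match="missing"):
            predict_csmf(post, truth.covariates, "ZZZ")

    def test_identical_covariates_without_random_effects_predict_identically(
        self, fitted
    ):
        truth, post = fitted
        panel = truth.covariates.copy()
        row = panel.iloc[[0]].to_numpy()
        untrained = [c.iso_code for c in truth.countries
                     if c.iso_code not in post.countries][:2]
        preds = []
        for iso in untrained:
            x = panel.loc[(iso, 2000)].to_numpy() * 0 + row[0]
            preds.append(post.predict_fractions(x, country=iso))
        np.testing.assert_array_equal(preds[0], preds[1])
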