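"""Likelihood assembly, shrinkage behaviour, RMSE arithmetic, penalty selection."""

import numpy as np
import pandas as pd
import pytest

from csmf519.model import (
    ModelSpec,
    PosteriorSample,
    Standardizer,
    _study_folds,
    build_likelihood,
    fit,
    oos_rmse,
    select_lambda,
)
from csmf519.synth import ScenarioConfig, make_truth, modelled_cause_order, simulate_studies
from csmf519.taxonomy import AgeSexGroup, default_taxonomy
from csmf519.types import StudyRecord, ValidationError

G = AgeSexGroup.AGE_10_14
CFG = ScenarioConfig(
    n_countries=6, n_hqvr=0, n_lmm=0, n_study_countries=6,
    studies_per_country_group=3, n_covariates=3, groups=(G,),
)
FAST = dict(chains=2, warmup=300, samples=300)


@pytest.fixture(scope="module")
def synth_fit():
    truth = make_truth(seed=21, config=CFG)
    studies = simulate_studies(truth, seed=22)
    spec = ModelSpec(
        taxonomy=default_taxonomy(G),
        covariate_names=tuple(truth.covariates.columns),
        lam=1.0,
        **FAST,
    )
    model = build_likelihood(studies, truth.covariates, spec)
    return truth, studies, model, fit(model, seed=23)


def _panel(iso="A", years=(2010,), names=()):
    rows = [
        {"iso_code": iso, "year": y, **{n: 0.0 for n in names}} for y in years
    ]
    df = pd.DataFrame(rows)
    if not names:
        df["_dummy"] = 0.0
    df = df.set_index(["iso_code", "year"])
    return df[[c for c in df.columns if c in names]] if names else df[[]]


class TestBuildLikelihood:
    def test_missing_covariate_row_is_an_error(self, tax1014):
        spec = ModelSpec(taxonomy=tax1014, covariate_names=("x0",))
        s = StudyRecord("s", "B", G, 2010, {"malaria": 10, "diarrhoea": 10})
        panel = pd.DataFrame(
            {"iso_code": ["A"], "year": [2010], "x0": [0.0]}
        ).set_index(["iso_code", "year"])
        with pytest.raises(ValidationError, match="missing covariate"):
            build_likelihood([s], panel, spec)

    def test_cause_outside_taxonomy_is_an_error(self, tax1014):
        spec = ModelSpec(taxonomy=tax1014, covariate_names=())
        s = StudyRecord("s", "A", G, 2010, {"measles": 5, "malaria": 10})
        with pytest.raises(ValidationError, match="outside taxonomy"):
            build_likelihood([s], _panel(), spec)

    def test_empty_study_list_is_an_error(self, tax1014):
        spec = ModelSpec(taxonomy=tax1014, covariate_names=())
        with pytest.raises(ValidationError):
            build_likelihood([], _panel(), spec)

    def test_two_cause_no_covariate_model_reduces_to_logit_intercept(self):
        # one study, two causes, no covariates: the log posterior must equal
        # a binomial logit with one intercept and one random effect
        from csmf519.taxonomy import CauseTaxonomy

        tax = CauseTaxonomy(
            group=G,
            causes=("malaria", "other_cmpn"),
            broad_group={"malaria": "CMPN", "other_cmpn": "CMPN"},
            source={"malaria": "modelled", "other_cmpn": "modelled"},
        )
        spec = ModelSpec(taxonomy=tax, covariate_names=(), sigma_u=0.07)
        s = StudyRecord("s", "A", G, 2010, {"malaria": 7, "other_cmpn": 3})
        model = build_likelihood([s], _panel(), spec)
        assert model.n_params == 2  # one intercept, one random effect
        b0, u = 0.4, -0.05
        lp, grad = model.logp_grad(np.array([b0, u]))
        eta = b0 + u
        p = np.exp(eta) / (1 + np.exp(eta))
        expected = (
            7 * np.log(p) + 3 * np.log(1 - p)
            - 0.5 * b0**2 / spec.intercept_sd**2
            - 0.5 * u**2 / spec.sigma_u**2
        )
        assert lp == pytest.approx(expected, rel=1e-12)
        # gradient of the logit: y - n p (plus prior terms)
        assert grad[0] == pytest.approx(7 - 10 * p - b0 / spec.intercept_sd**2)
        assert grad[1] == pytest.approx(7 - 10 * p - u / spec.sigma_u**2)

    def test_intercept_only_posterior_matches_pooled_proportions(self):
        # pooled multinomial MLE is the observed proportion vector; the
        # intercept-only posterior mean CSMF must sit within 0.02 of it
        tax = default_taxonomy(G)
        order = modelled_cause_order(tax)
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(len(order)) * 5)
        counts = rng.multinomial(5000, p)
        s = StudyRecord("s", "A", G, 2010, dict(zip(order, (int(v) for v in counts))))
        spec = ModelSpec(taxonomy=tax, covariate_names=(), **FAST)
        post = fit(build_likelihood([s], _panel(), spec), seed=1)
        pred = post.predict_fractions(np.zeros(0), country="A").mean(axis=0)
        np.testing.assert_allclose(pred, counts / counts.sum(), atol=0.02)


class TestShrinkage:
    def test_l1_norm_of_coefficients_decreases_with_lambda(self):
        truth = make_truth(seed=31, config=CFG)
        studies = simulate_studies(truth, seed=32)
        norms = []
        for lam in (0.1, 10.0, 1000.0):
            spec = ModelSpec(
                taxonomy=default_taxonomy(G),
                covariate_names=tuple(truth.covariates.columns),
                lam=lam,
                **FAST,
            )
            post = fit(build_likelihood(studies, truth.covariates, spec), seed=33)
            norms.append(np.abs(post.beta[:, :, 1:].mean(axis=0)).sum())
        assert norms[0] > norms[1] > norms[2]


class TestFit:
    def test_same_seed_identical_summaries(self, synth_fit):
        truth, studies, model, post = synth_fit
        again = fit(model, seed=23)
        assert np.array_equal(post.beta, again.beta)
        assert np.array_equal(post.u, again.u)

    def test_predictions_live_on_the_simplex(self, synth_fit):
        truth, studies, model, post = synth_fit
        x = truth.covariates.iloc[0].to_numpy()
        draws = post.predict_fractions(x, country=studies[0].iso_code)
        assert np.all(draws >= 0)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_random_effects_only_for_training_countries(self, synth_fit):
        truth, studies, model, post = synth_fit
        assert set(post.countries) == {s.iso_code for s in studies}
        assert post.u.shape[1] == len(post.countries)


class TestOosRmse:
    def _posterior_with_uniform_prediction(self, n_causes):
        tax = default_taxonomy(G)
        order = modelled_cause_order(tax)[:n_causes]
        S = 8
        return PosteriorSample(
            spec=ModelSpec(taxonomy=tax, covariate_names=()),
            cause_order=order,
            countries=(),
            standardizer=Standardizer((), np.zeros(0), np.ones(0)),
            beta=np.zeros((S, n_causes - 1, 1)),
            u=np.zeros((S, 0, n_causes - 1)),
            rhat=np.ones(1),
            accept_rate=np.ones(1),
        )

    def test_uniform_prediction_against_point_mass_gives_half(self):
        post = self._posterior_with_uniform_prediction(2)
        s = StudyRecord("s", "A", G, 2010, {post.cause_order[0]: 20})
        assert oos_rmse(post, [s], _panel()) == pytest.approx(0.5)

    def test_matches_direct_formula_on_random_case(self, rng):
        post = self._posterior_with_uniform_prediction(4)
        counts = {c: int(v) for c, v in zip(post.cause_order, rng.integers(1, 30, 4))}
        s = StudyRecord("s", "A", G, 2010, counts)
        total = sum(counts.values())
        expected = np.sqrt(
            np.mean([(0.25 - counts[c] / total) ** 2 for c in post.cause_order])
        )
        assert oos_rmse(post, [s], _panel()) == pytest.approx(expected, abs=1e-12)

    def test_empty_heldout_set_is_an_error(self):
        post = self._posterior_with_uniform_prediction(2)
        with pytest.raises(ValidationError):
            oos_rmse(post, [], _panel())


class TestSelectLambda:
    def test_empty_grid_is_an_error(self, synth_fit, tax1014):
        truth, studies, model, _ = synth_fit
        spec = ModelSpec(taxonomy=tax1014, covariate_names=tuple(truth.covariates.columns))
        with pytest.raises(ValidationError):
            select_lambda(studies, truth.covariates, spec, ())

    def test_single_value_grid_returns_it(self, synth_fit):
        truth, studies, model, _ = synth_fit
        spec = ModelSpec(
            taxonomy=default_taxonomy(G),
            covariate_names=tuple(truth.covariates.columns),
            chains=2, warmup=150, samples=150,
        )
        best, table = select_lambda(
            studies, truth.covariates, spec, (2.5,), n_folds=3, seed=5
        )
        assert best == 2.5
        assert set(table["lam"]) == {2.5} and len(table) == 3

    def test_fold_assignment_reproducible_by_seed(self, synth_fit):
        _, studies, _, _ = synth_fit
        a = _study_folds(studies, 4, seed=7)
        b = _study_folds(studies, 4, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = _study_folds(studies, 4, seed=8)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))
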