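"""Simulation-based validation harnesses.

Each function runs a replicate study on synthetic scenarios with known
ground truth and returns the measured operating characteristic:

* :func:`coefficient_coverage` -- how often 95% credible intervals cover
  the true nonzero covariate coefficients (on the training-standardized
  scale, where the model's coefficients live);
* :func:`csmf_error_vs_size` -- mean absolute CSMF error at two study
  sizes, to confirm error shrinks as data grow;
* :func:`ui_coverage` -- how often the 95% uncertainty intervals of
  predicted CSMFs cover the generating truth;
* :func:`lambda_contract` -- the cross-validation selection rule's
  guarantee that the chosen penalty is no worse (in mean out-of-fold RMSE)
  than the smallest grid value.

Scenario and sampler sizes here are deliberately small -- a handful of
countries, a few dozen studies, two short chains -- chosen so a full
replicate study runs in minutes on one CPU while leaving the estimand
(coverage, error ordering) unbiased.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import ModelSpec, build_likelihood, fit, oos_rmse, select_lambda
from .synth import ScenarioConfig, make_truth, simulate_studies, true_csmf
from .taxonomy import AgeSexGroup, default_taxonomy

#: compact scenario used by the replicate studies
SMALL_SCENARIO = ScenarioConfig(
    n_countries=8,
    n_hqvr=0,
    n_lmm=0,
    n_study_countries=8,
    studies_per_country_group=4,
    n_covariates=4,
    sparsity=0.5,
    groups=(AgeSexGroup.AGE_10_14,),
)

#: reduced sampler settings for replicate fits
FAST_MCMC = {"chains": 2, "warmup": 400, "samples": 400}


def _fit_replicate(seed: int, config: ScenarioConfig, mcmc: dict):
    truth = make_truth(seed=seed, config=config)
    group = config.groups[0]
    studies = simulate_studies(truth, seed=seed + 1)
    spec = ModelSpec(
        taxonomy=default_taxonomy(group),
        covariate_names=tuple(truth.covariates.columns),
        lam=1.0,
        sigma_u=config.sigma_u,
        **mcmc,
    )
    model = build_likelihood(studies, truth.covariates, spec)
    return truth, studies, fit(model, seed=seed + 2)


def coefficient_coverage(
    n_replicates: int = 20,
    seed: int = 0,
    config: ScenarioConfig = SMALL_SCENARIO,
    mcmc: dict = FAST_MCMC,
) -> dict:
    """Coverage of 95% credible intervals for the true nonzero coefficients.

    The generator's coefficients apply to its covariates directly; the model
    fits on training-standardized covariates, so the true value of the
    fitted coefficient is ``beta_p * sd_p``.  Returns the pooled coverage
    over every (cause, nonzero covariate) cell of every replicate.
    """
    covered = total = 0
    group = config.groups[0]
    for r in range(n_replicates):
        truth, _, post = _fit_replicate(seed + 1000 * r, config, mcmc)
        gt = truth.group_truth[group]
        sd = post.standardizer.sd
        lo = np.percentile(post.beta[:, :, 1:], 2.5, axis=0)
        hi = np.percentile(post.beta[:, :, 1:], 97.5, axis=0)
        target = gt.beta[:, 1:] * sd[None, :]
        mask = gt.support
        covered += int(np.sum((lo <= target) & (target <= hi) & mask))
        total += int(mask.sum())
    return {"coverage": covered / total, "n_cells": total}


def _mean_csmf_error(seed: int, config: ScenarioConfig, mcmc: dict) -> float:
    truth, studies, post = _fit_replicate(seed, config, mcmc)
    group = config.groups[0]
    errs = []
    for s in studies:
        x = truth.covariates.loc[(s.iso_code, s.year_mid)].to_numpy()
        pred = np.median(post.predict_fractions(x, country=s.iso_code), axis=0)
        errs.append(np.abs(pred - true_csmf(truth, group, x, s.iso_code)).mean())
    return float(np.mean(errs))


def csmf_error_vs_size(
    seed: int = 0,
    size_factor: float = 10.0,
    config: ScenarioConfig = SMALL_SCENARIO,
    mcmc: dict = FAST_MCMC,
    n_replicates: int = 3,
) -> dict:
    """Mean absolute CSMF error at baseline and enlarged study sizes."""
    small, large = [], []
    big = replace(config, mean_study_deaths=config.mean_study_deaths * size_factor)
    for r in range(n_replicates):
        small.append(_mean_csmf_error(seed + 1000 * r, config, mcmc))
        large.append(_mean_csmf_error(seed + 1000 * r, big, mcmc))
    return {"mae_small": float(np.mean(small)), "mae_large": float(np.mean(large))}


#: lighter settings for the many-replicate coverage study
TINY_SCENARIO = replace(
    SMALL_SCENARIO, n_countries=6, n_study_countries=6, studies_per_country_group=3
)
TINY_MCMC = {"chains": 2, "warmup": 300, "samples": 300}


def ui_coverage(
    n_replicates: int = 200,
    seed: int = 0,
    config: ScenarioConfig = TINY_SCENARIO,
    mcmc: dict = TINY_MCMC,
) -> dict:
    """Coverage of predicted-CSMF 95% uncertainty intervals.

    Each replicate draws a fresh truth and data, fits the model, predicts
    the CSMF for one country-year, and checks every cause's 95% interval
    against the generating truth; results are pooled across replicates.
    """
    group = config.groups[0]
    covered = total = 0
    for r in range(n_replicates):
        rep_seed = seed + 1000 * r
        truth, studies, post = _fit_replicate(rep_seed, config, mcmc)
        rng = np.random.default_rng(rep_seed + 17)
        s = studies[int(rng.integers(len(studies)))]
        x = truth.covariates.loc[(s.iso_code, s.year_mid)].to_numpy()
        draws = post.predict_fractions(x, country=s.iso_code)
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)
        p = true_csmf(truth, group, x, s.iso_code)
        covered += int(np.sum((lo <= p) & (p <= hi)))
        total += p.size
    return {"coverage": covered / total, "n_cells": total}


def lambda_contract(
    seed: int = 0,
    lambda_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    n_folds: int = 3,
    config: ScenarioConfig = SMALL_SCENARIO,
    mcmc: dict = TINY_MCMC,
) -> dict:
    """Cross-validated penalty selection on one sparse-truth scenario.

    Returns the selected penalty, the per-penalty mean out-of-fold RMSE,
    and whether the selected penalty's RMSE is no worse than the smallest
    grid value's (true by construction of the argmin rule; verified
    numerically here).
    """
    truth = make_truth(seed=seed, config=config)
    group = config.groups[0]
    studies = simulate_studies(truth, seed=seed + 1)
    spec = ModelSpec(
        taxonomy=default_taxonomy(group),
        covariate_names=tuple(truth.covariates.columns),
        sigma_u=config.sigma_u,
        **mcmc,
    )
    best, table = select_lambda(
        studies, truth.covariates, spec, lambda_grid, n_folds=n_folds, seed=seed
    )
    means = table.groupby("lam")["rmse"].mean()
    return {
        "selected_lambda": best,
        "rmse_by_lambda": {float(k): float(v) for k, v in means.items()},
        "selected_rmse": float(means[best]),
        "smallest_lambda_rmse": float(means[min(lambda_grid)]),
    }
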