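"""End-to-end estimation pipeline.

Order of operations per country-year-group (configurable in principle,
logged always): model prediction -> malaria structural rules -> other-CMPN
squeeze -> LRI squeeze -> crisis capping -> envelope application ->
aggregation.  Separate models are fitted per age-sex group and per country
stratum (low-mortality-modelled vs high-mortality-modelled input data);
high-quality vital-registration countries bypass the model and their
observed CSMFs go straight to the envelopes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    RunConfig,
    read_countries,
    read_envelopes,
    read_panel,
    read_single_causes,
    read_studies,
)
from .model import ModelSpec, PosteriorSample, build_likelihood, fit, select_lambda
from .predict import CSMFDraws, MalariaConstraints, apply_malaria_rules, predict_csmf
from .squeeze import (
    ResidualFractions,
    apply_crisis,
    residuals_from_vr,
    single_cause_fraction,
    squeeze_lri,
    squeeze_other_cmpn,
)
from .synth import ScenarioBundle
from .taxonomy import AgeSexGroup, default_taxonomy
from .types import (
    CountryMeta,
    Envelope,
    SingleCauseSeries,
    StudyRecord,
    filter_studies,
)
from .uncertainty import (
    CellEstimates,
    EstimateCube,
    aggregate,
    propagate,
    sample_single_cause,
)

MODELLED_STRATA = ("LMM", "HMM")


@dataclass
class InputBundle:
    """All input streams for one pipeline run."""

    studies: list[StudyRecord]
    panel: pd.DataFrame
    envelopes: list[Envelope]
    single_causes: list[SingleCauseSeries]
    countries: list[CountryMeta]
    malaria: MalariaConstraints
    vr_csmfs: pd.DataFrame

    @classmethod
    def from_dir(cls, indir: str | Path) -> "InputBundle":
        indir = Path(indir)
        return cls(
            studies=read_studies(indir / "studies.csv"),
            panel=read_panel(indir / "covariates.csv"),
            envelopes=read_envelopes(
                indir / "envelopes.csv",
                (indir / "envelope_draws.csv")
                if (indir / "envelope_draws.csv").exists()
                else None,
            ),
            single_causes=read_single_causes(indir / "single_causes.csv"),
            countries=read_countries(indir / "countries.csv"),
            malaria=MalariaConstraints.from_frame(
                pd.read_csv(indir / "malaria_constraints.csv")
            ),
            vr_csmfs=pd.read_csv(indir / "vr_csmfs.csv"),
        )

    @classmethod
    def from_scenario(cls, bundle: ScenarioBundle) -> "InputBundle":
        return cls(
            studies=bundle.studies,
            panel=bundle.truth.covariates,
            envelopes=bundle.envelopes,
            single_causes=bundle.single_causes,
            countries=list(bundle.truth.countries),
            malaria=MalariaConstraints.from_frame(bundle.malaria_constraints),
            vr_csmfs=bundle.vr_csmfs,
        )


@dataclass
class PipelineResult:
    cube: EstimateCube                 # country level
    aggregated: EstimateCube           # regional + global
    posteriors: dict[tuple[AgeSexGroup, str], PosteriorSample]
    residuals: dict[AgeSexGroup, ResidualFractions]
    run_log: dict = field(default_factory=dict)


def _cell_seed(seed: int, *key: object) -> int:
    """Stable per-cell seed independent of iteration order (< 2**31)."""
    return (seed * 2654435761 + zlib.crc32("|".join(map(str, key)).encode())) % (2**31)


def _single_lookup(
    series: list[SingleCauseSeries],
) -> tuple[dict, dict]:
    singles: dict[tuple, SingleCauseSeries] = {}
    crises: dict[tuple, list[SingleCauseSeries]] = {}
    for s in series:
        if s.cause == "crisis":
            crises.setdefault((s.iso_code, s.year, s.group), []).append(s)
        else:
            singles[(s.iso_code, s.year, s.group, s.cause)] = s
    return singles, crises


def _fraction_draws(
    series: SingleCauseSeries | None, env_deaths: float, K: int, seed: int
) -> np.ndarray:
    if series is None or env_deaths <= 0:
        return np.zeros(K)
    return single_cause_fraction(sample_single_cause(series, K, seed), env_deaths)


def run_pipeline(
    inputs: InputBundle,
    config: RunConfig | None = None,
    groups: tuple[AgeSexGroup, ...] | None = None,
    select_penalty: bool = False,
    lam: float = 1.0,
) -> PipelineResult:
    """Fit, predict, squeeze, propagate and aggregate.

    ``lam`` is the LASSO penalty used when ``select_penalty`` is off;
    otherwise each (group, stratum) fit picks its own penalty from the
    configured grid by cross-validation.
    """
    cfg = config or RunConfig()
    seed = cfg.seed
    K = cfg.n_draws
    category = {c.iso_code: c.category for c in inputs.countries}
    region_map = {c.iso_code: c.region for c in inputs.countries}
    env = {(e.iso_code, e.year, e.group): e for e in inputs.envelopes}
    singles, crises = _single_lookup(inputs.single_causes)
    if groups is None:
        groups = tuple(sorted({e.group for e in inputs.envelopes}, key=lambda g: g.value))
    years = tuple(sorted({e.year for e in inputs.envelopes}))

    cube = EstimateCube()
    posteriors: dict[tuple[AgeSexGroup, str], PosteriorSample] = {}
    residuals: dict[AgeSexGroup, ResidualFractions] = {}
    log: dict = {
        "seed": seed, "n_draws": K, "sigma_u": cfg.sigma_u, "lambda": {},
        "rejected_studies": [], "warnings": [], "events": {
            "malaria_zeroed": 0, "malaria_capped": 0,
            "squeeze_scaled": 0, "crisis_capped": 0,
        },
    }

    for gi, group in enumerate(groups):
        tax = default_taxonomy(group)
        accepted, rejected = filter_studies(
            [s for s in inputs.studies if s.group == group], tax
        )
        log["rejected_studies"] += [(r.study_id, r.rule) for r in rejected]

        if inputs.vr_csmfs.empty:
            residuals[group] = ResidualFractions(group, 0.0, 0.0)
            log["warnings"].append(
                f"{group}: no vital-registration input; residual floors set to 0"
            )
        else:
            residuals[group] = residuals_from_vr(inputs.vr_csmfs, group)

        for si, stratum in enumerate(MODELLED_STRATA):
            studs = [s for s in accepted if category.get(s.iso_code) == stratum]
            if not studs:
                continue
            spec = ModelSpec(
                taxonomy=tax,
                covariate_names=tuple(inputs.panel.columns),
                lam=lam,
                sigma_u=cfg.sigma_u,
                chains=cfg.chains,
                warmup=cfg.warmup,
                samples=cfg.samples,
            )
            if select_penalty:
                best, _ = select_lambda(
                    studs, inputs.panel, spec, cfg.lambda_grid,
                    n_folds=min(cfg.n_folds, len(studs)),
                    seed=_cell_seed(seed, "cv", group, stratum),
                )
                spec = ModelSpec(**{**spec.__dict__, "lam": best})
            log["lambda"][f"{group.value}/{stratum}"] = spec.lam
            post = fit(
                build_likelihood(studs, inputs.panel, spec),
                seed=_cell_seed(seed, "fit", group, stratum),
            )
            log["warnings"] += [f"{group.value}/{stratum}: {w}" for w in post.warnings]
            posteriors[(group, stratum)] = post

        # ---- modelled countries: predict, squeeze, propagate
        res = residuals[group]
        for c in inputs.countries:
            if c.category == "HQVR":
                continue
            post = posteriors.get((group, c.category))
            if post is None:  # no studies in this stratum: borrow the other
                other = "HMM" if c.category == "LMM" else "LMM"
                post = posteriors.get((group, other))
            if post is None:
                log["warnings"].append(f"{group.value}: no fitted model for {c.iso_code}")
                continue
            per_year = predict_csmf(post, inputs.panel, c.iso_code, years)
            S = post.n_draws
            idx = np.arange(K) % S
            for year in years:
                e = env.get((c.iso_code, year, group))
                if e is None:
                    continue
                modelled = per_year[year]
                modelled = CSMFDraws(
                    c.iso_code, year, group, modelled.causes, modelled.draws[idx]
                )
                before = modelled.draws.copy()
                modelled = apply_malaria_rules(modelled, inputs.malaria)
                if "malaria" in modelled.causes:
                    k = modelled.cause_index("malaria")
                    if (c.iso_code, year) in inputs.malaria.incidence_zero:
                        log["events"]["malaria_zeroed"] += 1
                    elif np.any(modelled.draws[:, k] < before[:, k]):
                        log["events"]["malaria_capped"] += 1
                cell = _integrate_cell(
                    modelled, tax, e, res, singles, crises, cfg, seed, log
                )
                cube.add(c.iso_code, year, group, cell)

        # ---- HQVR countries: pass-through fractions
        if not inputs.vr_csmfs.empty:
            sub = inputs.vr_csmfs[inputs.vr_csmfs["group"] == group.value]
            for (iso, year), rows in sub.groupby(["iso_code", "year"]):
                e = env.get((iso, int(year), group))
                if e is None:
                    continue
                frac = rows.set_index("cause")["fraction"]
                point = np.array([frac.get(cz, 0.0) for cz in tax.causes])
                total = point.sum()
                if total > 0:
                    point = point / total
                draws = np.tile(point, (K, 1))
                env_d, env_r = _envelope_draws(e, K)
                cube.add(
                    iso, int(year), group,
                    propagate(iso, int(year), group, tax.causes, draws, env_d, env_r),
                )

    aggregated = aggregate(cube, region_map)
    return PipelineResult(cube, aggregated, posteriors, residuals, log)


def _envelope_draws(e: Envelope, K: int) -> tuple[np.ndarray, np.ndarray]:
    if e.deaths_draws:
        i = np.arange(K) % len(e.deaths_draws)
        return np.asarray(e.deaths_draws)[i], np.asarray(e.rate_draws)[i]
    return np.full(K, e.deaths), np.full(K, e.rate)


def _integrate_cell(
    modelled: CSMFDraws,
    tax,
    e: Envelope,
    res: ResidualFractions,
    singles: dict,
    crises: dict,
    cfg: RunConfig,
    seed: int,
    log: dict,
) -> CellEstimates:
    """Squeeze single causes into one cell's modelled draws and propagate."""
    K = modelled.draws.shape[0]
    iso, year, group = modelled.iso_code, modelled.year, modelled.group
    key = (iso, year, group)

    def frac(kind: str) -> np.ndarray:
        return _fraction_draws(
            singles.get((*key, kind)), e.deaths, K, _cell_seed(seed, kind, *key)
        )

    hiv = frac("hiv")
    tb_p, tb_e = frac("tb_pulmonary"), frac("tb_extrapulmonary")
    measles = frac("measles_endemic") if "measles" in tax.causes else np.zeros(K)

    m_oc = modelled.draws[:, modelled.cause_index("other_cmpn")]
    if tax.has_lri:
        part_oc = squeeze_other_cmpn(m_oc, hiv, measles, tb_e, res.residual_other_cmpn)
        m_lri = modelled.draws[:, modelled.cause_index("lri")]
        part_lri = squeeze_lri(m_lri, tb_p, res.residual_lri)
        tb_total = part_oc["tb_extrapulmonary"] + part_lri["tb_pulmonary"]
        lri_final = part_lri["lri_final"]
    else:
        # no LRI cause at these ages: pulmonary TB joins the other-CMPN squeeze
        part_oc = squeeze_other_cmpn(
            m_oc, hiv, measles, tb_e + tb_p, res.residual_other_cmpn
        )
        tb_total = part_oc["tb_extrapulmonary"]
        lri_final = None
    if np.any(part_oc["hiv"] < hiv - 1e-15):
        log["events"]["squeeze_scaled"] += 1

    full = np.zeros((K, len(tax.causes)))
    for k, cause in enumerate(tax.causes):
        if cause == "other_cmpn":
            full[:, k] = part_oc["other_cmpn_final"]
        elif cause == "lri":
            full[:, k] = lri_final
        elif cause == "hiv":
            full[:, k] = part_oc["hiv"]
        elif cause == "tuberculosis":
            full[:, k] = tb_total
        elif cause == "measles":
            full[:, k] = part_oc["measles_endemic"]
        elif cause in ("collective_violence", "natural_disasters"):
            full[:, k] = 0.0
        else:
            full[:, k] = modelled.draws[:, modelled.cause_index(cause)]

    cell = CSMFDraws(iso, year, group, tax.causes, full)
    env_scale = np.ones(K)
    for cr in crises.get(key, []):
        raw = _fraction_draws(cr, e.deaths, K, _cell_seed(seed, "crisis", *key))
        if np.any(raw > cr.ghe_max_fraction):
            log["events"]["crisis_capped"] += 1
        cell, scale = apply_crisis(
            cell, raw, cr.ghe_max_fraction, cr.crisis_nature or "collective_violence",
            in_envelope=cr.in_envelope, crisis_targets=cfg.crisis_targets,
        )
        env_scale *= scale

    env_d, env_r = _envelope_draws(e, K)
    return propagate(
        iso, year, group, tax.causes, cell.draws, env_d * env_scale, env_r * env_scale
    )
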