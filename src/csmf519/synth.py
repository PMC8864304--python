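"""Synthetic input streams with known ground truth.

The generator emulates the five data streams the estimation pipeline
consumes -- sparse small-count multinomial studies, a smooth covariate-driven
CSMF surface with country random deviations, all-cause envelopes with
sampling uncertainty, single-cause series (including cases engineered to
exceed plausible shares, to exercise squeezing and capping), and a country
classification table -- so every downstream stage can be tested against the
generating truth without any external download.

The CSMF surface is exactly the model the estimator assumes: for modelled
cause c in country j with standardized covariates x,

    p_c = softmax(eta)_c,   eta_c = beta_{0,c} + x . beta_c + u_{j,c},

with the reference cause's linear predictor fixed at 0 and country random
effects u_{j,c} ~ Normal(0, sigma_u), sigma_u = 0.07 by default.  Study
counts are multinomial draws from that surface; study sizes follow the
sparse-data regime of verbal-autopsy compilations (a mean of about 185
deaths per study).

Covariates evolve as stationary AR(1) series over years (rho = 0.9,
standard-normal marginals) to mimic slowly varying country indicators; no
attempt is made to mimic real covariate semantics or real country
identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    write_countries,
    write_envelopes,
    write_panel,
    write_single_causes,
    write_studies,
)
from .taxonomy import AgeSexGroup, CauseTaxonomy, default_taxonomy
from .types import (
    REGIONS,
    CountryMeta,
    Envelope,
    SingleCauseSeries,
    StudyRecord,
    classify_country,
)

YEARS = tuple(range(2000, 2020))


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_countries: int = 30
    n_hqvr: int = 6
    n_lmm: int = 10
    n_study_countries: int = 12       # modelled countries contributing studies
    studies_per_country_group: int = 4
    mean_study_deaths: float = 185.0  # mean deaths per study (sparse-data regime)
    n_covariates: int = 6
    sparsity: float = 0.5             # fraction of covariate effects that are zero
    beta_scale: float = 0.6           # magnitude of nonzero covariate effects
    intercept_scale: float = 0.5
    sigma_u: float = 0.07
    ar1_rho: float = 0.9
    envelope_decline: float = 0.02    # annual proportional decline
    envelope_cv: float = 0.05         # coefficient of variation of envelope draws
    n_envelope_draws: int = 200
    groups: tuple[AgeSexGroup, ...] = tuple(AgeSexGroup)
    years: tuple[int, ...] = YEARS
    # single-cause injection rates (fractions of the envelope)
    hiv_fraction_max: float = 0.05
    tb_fraction_max: float = 0.04
    measles_fraction_max: float = 0.03
    crisis_rate: float = 0.05         # share of country-years with a crisis
    crisis_excess_fraction: float = 0.9   # injected raw crisis share (above cap)
    crisis_cap: float = 0.3               # cap fraction recorded for those cells
    malaria_excess_rate: float = 0.2  # share of HMM country-years with a binding cap


@dataclass(frozen=True)
class GroupTruth:
    """True model parameters for one age-sex group."""

    taxonomy: CauseTaxonomy
    beta: np.ndarray        # (C-1, P+1): column 0 = intercept
    support: np.ndarray     # (C-1, P) boolean: declared nonzero covariate effects
    u: np.ndarray           # (n_countries, C-1) country random effects


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for a full synthetic scenario."""

    config: ScenarioConfig
    seed: int
    countries: tuple[CountryMeta, ...]
    study_countries: tuple[str, ...]
    group_truth: dict[AgeSexGroup, GroupTruth] = field(hash=False)
    covariates: pd.DataFrame = field(hash=False)   # (iso, year) x P, standardized
    populations: dict[tuple[str, AgeSexGroup], float] = field(hash=False)
    envelope_level: dict[tuple[str, AgeSexGroup], float] = field(hash=False)

    @property
    def sigma_u(self) -> float:
        return self.config.sigma_u

    def country_index(self, iso_code: str) -> int:
        return next(
            i for i, c in enumerate(self.countries) if c.iso_code == iso_code
        )


def _softmax_with_reference(eta: np.ndarray) -> np.ndarray:
    """Softmax over causes with an implicit reference linear predictor of 0.

    ``eta`` has shape (..., C-1); returns (..., C) with the reference cause
    appended last.
    """
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=-1, keepdims=True)


def make_truth(
    P: int | None = None,
    n_countries: int | None = None,
    sparsity: float | None = None,
    seed: int = 0,
    config: ScenarioConfig | None = None,
) -> TruthSpec:
    """Draw a reproducible ground truth for one scenario.

    The number of nonzero covariate effects per cause is
    ``round(P * (1 - sparsity))``; the chosen support is recorded so recovery
    tests can check it.
    """
    cfg = config or ScenarioConfig()
    if P is not None:
        cfg = replace(cfg, n_covariates=P)
    if n_countries is not None:
        cfg = replace(cfg, n_countries=n_countries)
    if sparsity is not None:
        cfg = replace(cfg, sparsity=sparsity)
    if cfg.n_covariates < 1:
        raise ValueError("P must be >= 1")
    if not 0.0 <= cfg.sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    if cfg.n_hqvr + cfg.n_lmm > cfg.n_countries:
        raise ValueError("strata sizes exceed n_countries")
    rng = np.random.default_rng(seed)
    P = cfg.n_covariates

    # --- countries: HQVR and LMM draw low mortality, HMM high
    countries = []
    populations: dict[tuple[str, AgeSexGroup], float] = {}
    envelope_level: dict[tuple[str, AgeSexGroup], float] = {}
    n_hmm = cfg.n_countries - cfg.n_hqvr - cfg.n_lmm
    strata = ["HQVR"] * cfg.n_hqvr + ["LMM"] * cfg.n_lmm + ["HMM"] * n_hmm
    for i, stratum in enumerate(strata):
        iso = f"S{i:03d}"
        if stratum == "HMM":
            rate0 = rng.uniform(0.7, 1.5)     # per 1000 person-years
        else:
            rate0 = rng.uniform(0.2, 0.6)
        prob = 15.0 * rate0                    # approx 15-year cumulative risk
        category = classify_country(prob, hqvr_flag=(stratum == "HQVR"))
        countries.append(
            CountryMeta(
                iso_code=iso,
                region=REGIONS[i % len(REGIONS)],
                category=category,
                prob_death_5_19=prob,
            )
        )
        for g in cfg.groups:
            pop = float(np.exp(rng.uniform(np.log(2e5), np.log(5e6))))
            populations[(iso, g)] = pop
            envelope_level[(iso, g)] = pop * rate0 / 1000.0

    modelled = [c.iso_code for c in countries if c.category != "HQVR"]
    k = min(cfg.n_study_countries, len(modelled))
    study_countries = tuple(
        sorted(rng.choice(modelled, size=k, replace=False).tolist())
    )

    # --- covariates: AR(1) with standard-normal marginals
    rows = []
    for c in countries:
        x = rng.standard_normal(P)
        for year in cfg.years:
            rows.append({"iso_code": c.iso_code, "year": year, **{
                f"x{p}": x[p] for p in range(P)
            }})
            x = cfg.ar1_rho * x + np.sqrt(1 - cfg.ar1_rho**2) * rng.standard_normal(P)
    covariates = pd.DataFrame(rows).set_index(["iso_code", "year"]).sort_index()

    # --- per-group coefficients with declared sparse support
    n_nonzero = int(round(P * (1.0 - cfg.sparsity)))
    group_truth = {}
    for g in cfg.groups:
        tax = default_taxonomy(g)
        C = len(tax.modelled_causes)
        beta = np.zeros((C - 1, P + 1))
        support = np.zeros((C - 1, P), dtype=bool)
        beta[:, 0] = rng.normal(0.0, cfg.intercept_scale, size=C - 1)
        for c in range(C - 1):
            idx = rng.choice(P, size=n_nonzero, replace=False)
            support[c, idx] = True
            signs = rng.choice([-1.0, 1.0], size=n_nonzero)
            beta[c, 1 + idx] = signs * rng.uniform(
                0.5 * cfg.beta_scale, 1.5 * cfg.beta_scale, size=n_nonzero
            )
        u = rng.normal(0.0, cfg.sigma_u, size=(cfg.n_countries, C - 1))
        group_truth[g] = GroupTruth(taxonomy=tax, beta=beta, support=support, u=u)

    return TruthSpec(
        config=cfg,
        seed=seed,
        countries=tuple(countries),
        study_countries=study_countries,
        group_truth=group_truth,
        covariates=covariates,
        populations=populations,
        envelope_level=envelope_level,
    )


def true_csmf(
    truth: TruthSpec,
    group: AgeSexGroup,
    x: np.ndarray,
    country: str | int | None = None,
) -> np.ndarray:
    """True modelled-cause CSMF for covariate row ``x`` (standardized).

    The reference cause occupies the LAST position of the modelled-cause
    ordering used throughout (``modelled_nonref + [reference]``).  With
    ``country=None`` the random effect is zero (a new, unobserved country).
    """
    gt = truth.group_truth[group]
    x = np.asarray(x, dtype=float)
    eta = gt.beta[:, 0] + gt.beta[:, 1:] @ x
    if country is not None:
        j = truth.country_index(country) if isinstance(country, str) else country
        eta = eta + gt.u[j]
    return _softmax_with_reference(eta)


def modelled_cause_order(taxonomy: CauseTaxonomy) -> tuple[str, ...]:
    """Modelled causes with the reference cause moved to the end.

    This is the column order of every modelled-CSMF array in the package.
    """
    nonref = [c for c in taxonomy.modelled_causes if c != taxonomy.reference_cause]
    return tuple(nonref) + (taxonomy.reference_cause,)


def simulate_studies(
    truth: TruthSpec,
    seed: int,
    groups: tuple[AgeSexGroup, ...] | None = None,
) -> list[StudyRecord]:
    """Multinomial study counts from the true CSMF surface.

    Each study country contributes ``studies_per_country_group`` studies per
    age-sex group at random years; totals are Poisson with the configured
    mean (at least 1 death).
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    records = []
    for g in groups or cfg.groups:
        order = modelled_cause_order(truth.group_truth[g].taxonomy)
        for iso in truth.study_countries:
            for r in range(cfg.studies_per_country_group):
                year = int(rng.choice(cfg.years))
                x = truth.covariates.loc[(iso, year)].to_numpy()
                p = true_csmf(truth, g, x, iso)
                total = max(1, int(rng.poisson(cfg.mean_study_deaths)))
                counts = rng.multinomial(total, p)
                records.append(
                    StudyRecord(
                        study_id=f"{iso}-{g.value}-{r}",
                        iso_code=iso,
                        group=g,
                        year_mid=year,
                        deaths_by_cause={
                            c: int(n) for c, n in zip(order, counts)
                        },
                    )
                )
    return records


def simulate_envelopes(truth: TruthSpec, seed: int) -> list[Envelope]:
    """Smoothly declining all-cause envelopes with lognormal draw noise.

    Point values decline exponentially at the configured annual rate; draws
    are centred on the point value (unit-mean lognormal noise) and the point
    is guaranteed to lie inside the draw range.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cfg.envelope_cv**2))
    out = []
    for c in truth.countries:
        for g in cfg.groups:
            level = truth.envelope_level[(c.iso_code, g)]
            pop = truth.populations[(c.iso_code, g)]
            for year in cfg.years:
                deaths = level * np.exp(-cfg.envelope_decline * (year - cfg.years[0]))
                rate = deaths / pop * 1000.0
                if cfg.envelope_cv > 0:
                    noise = np.exp(
                        rng.normal(-0.5 * sigma**2, sigma, size=cfg.n_envelope_draws)
                    )
                    # keep the point estimate inside the draw range
                    noise[0] = min(noise.min(), 1.0)
                    noise[1] = max(noise.max(), 1.0)
                    ddraws = tuple(deaths * noise)
                    rdraws = tuple(rate * noise)
                else:
                    ddraws = (deaths,) * max(2, cfg.n_envelope_draws)
                    rdraws = (rate,) * max(2, cfg.n_envelope_draws)
                out.append(
                    Envelope(
                        iso_code=c.iso_code,
                        year=year,
                        group=g,
                        deaths=deaths,
                        rate=rate,
                        deaths_draws=ddraws,
                        rate_draws=rdraws,
                    )
                )
    return out


def simulate_single_causes(
    truth: TruthSpec, envelopes: list[Envelope], seed: int
) -> list[SingleCauseSeries]:
    """Single-cause series, including cases engineered to exceed caps.

    HIV, pulmonary/extrapulmonary TB and endemic measles are drawn as smooth
    per-country fractions of the envelope.  A configurable share of
    country-years receives a crisis whose raw fraction exceeds the recorded
    cap (default 0.9 raw vs 0.3 cap) so capping and redistribution are
    exercised by construction.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    env = {(e.iso_code, e.year, e.group): e for e in envelopes}
    out = []
    for c in truth.countries:
        frac_hiv = rng.uniform(0.0, cfg.hiv_fraction_max)
        frac_tbp = rng.uniform(0.0, cfg.tb_fraction_max)
        frac_tbe = rng.uniform(0.0, 0.5 * cfg.tb_fraction_max)
        frac_mea = rng.uniform(0.0, cfg.measles_fraction_max)
        for g in cfg.groups:
            for year in cfg.years:
                deaths = env[(c.iso_code, year, g)].deaths
                series = {
                    "hiv": frac_hiv,
                    "tb_pulmonary": frac_tbp,
                    "tb_extrapulmonary": frac_tbe,
                }
                if g is AgeSexGroup.AGE_5_9:
                    series["measles_endemic"] = frac_mea
                for kind, frac in series.items():
                    d = frac * deaths
                    out.append(
                        SingleCauseSeries(
                            cause=kind,
                            iso_code=c.iso_code,
                            year=year,
                            group=g,
                            deaths=d,
                            ui95=(0.8 * d, 1.25 * d),
                        )
                    )
                if rng.uniform() < cfg.crisis_rate:
                    d = cfg.crisis_excess_fraction * deaths
                    natures = ["collective_violence", "natural_disaster"]
                    if g is AgeSexGroup.AGE_5_9:  # measles lives in this group
                        natures.append("epidemic")
                    nature = rng.choice(natures)
                    out.append(
                        SingleCauseSeries(
                            cause="crisis",
                            iso_code=c.iso_code,
                            year=year,
                            group=g,
                            deaths=d,
                            ui95=(0.8 * d, 1.25 * d),
                            crisis_nature=str(nature),
                            in_envelope=bool(rng.uniform() < 0.8),
                            ghe_max_fraction=cfg.crisis_cap,
                        )
                    )
    return out


def simulate_malaria_constraints(truth: TruthSpec, seed: int) -> pd.DataFrame:
    """Under-5 malaria caps and zero-incidence flags per country-year.

    A configurable share of high-mortality country-years gets a cap below
    the typical modelled malaria share so the cap binds; HQVR/LMM countries
    are flagged zero-incidence.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    rows = []
    for c in truth.countries:
        zero = c.category != "HMM"
        for year in cfg.years:
            if zero:
                cap, inc0 = 0.0, True
            elif rng.uniform() < cfg.malaria_excess_rate:
                cap, inc0 = float(rng.uniform(0.01, 0.05)), False
            else:
                cap, inc0 = float(rng.uniform(0.2, 0.5)), False
            rows.append(
                {
                    "iso_code": c.iso_code,
                    "year": year,
                    "under5_fraction": cap,
                    "incidence_zero": inc0,
                }
            )
    return pd.DataFrame(rows)


def hqvr_csmfs(truth: TruthSpec, single_causes: list[SingleCauseSeries],
               envelopes: list[Envelope]) -> pd.DataFrame:
    """Observed full-taxonomy CSMFs for HQVR countries (pass-through input).

    The modelled-cause surface is scaled down by the country's single-cause
    shares, which occupy the corresponding single-cause labels; the result
    is an exact simplex per (country, year, group).
    """
    env = {(e.iso_code, e.year, e.group): e.deaths for e in envelopes}
    sc: dict[tuple, float] = {}
    for s in single_causes:
        key = (s.iso_code, s.year, s.group)
        d = env[key]
        if d > 0 and s.cause != "crisis":
            sc.setdefault((*key, s.cause), 0.0)
            sc[(*key, s.cause)] += s.deaths / d
    rows = []
    for c in truth.countries:
        if c.category != "HQVR":
            continue
        for g in truth.config.groups:
            tax = truth.group_truth[g].taxonomy
            order = modelled_cause_order(tax)
            for year in truth.config.years:
                x = truth.covariates.loc[(c.iso_code, year)].to_numpy()
                p = true_csmf(truth, g, x, c.iso_code)
                key = (c.iso_code, year, g)
                singles = {
                    "hiv": sc.get((*key, "hiv"), 0.0),
                    "tuberculosis": sc.get((*key, "tb_pulmonary"), 0.0)
                    + sc.get((*key, "tb_extrapulmonary"), 0.0),
                    "measles": sc.get((*key, "measles_endemic"), 0.0),
                }
                singles = {
                    k: v for k, v in singles.items() if k in tax.causes and v > 0
                }
                s = min(0.5, sum(singles.values()))
                scale = sum(singles.values())
                singles = {
                    k: (v * s / scale if scale > 0 else 0.0)
                    for k, v in singles.items()
                }
                frac = {cause: float(pc * (1.0 - s)) for cause, pc in zip(order, p)}
                for k, v in singles.items():
                    frac[k] = frac.get(k, 0.0) + v
                for cause in tax.causes:
                    rows.append(
                        {
                            "iso_code": c.iso_code,
                            "year": year,
                            "group": g.value,
                            "cause": cause,
                            "fraction": frac.get(cause, 0.0),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class ScenarioBundle:
    """Everything one synthetic scenario produces."""

    truth: TruthSpec
    studies: list[StudyRecord]
    envelopes: list[Envelope]
    single_causes: list[SingleCauseSeries]
    malaria_constraints: pd.DataFrame
    vr_csmfs: pd.DataFrame


def simulate_scenario(
    seed: int, config: ScenarioConfig | None = None
) -> ScenarioBundle:
    """Generate the full input bundle for one scenario (one seed)."""
    truth = make_truth(seed=seed, config=config)
    # independent substreams so each piece is reproducible on its own
    studies = simulate_studies(truth, seed=seed + 1)
    envelopes = simulate_envelopes(truth, seed=seed + 2)
    singles = simulate_single_causes(truth, envelopes, seed=seed + 3)
    malaria = simulate_malaria_constraints(truth, seed=seed + 4)
    vr = hqvr_csmfs(truth, singles, envelopes)
    return ScenarioBundle(truth, studies, envelopes, singles, malaria, vr)


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all input files (plus the truth needed by test harnesses)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "studies": outdir / "studies.csv",
        "covariates": outdir / "covariates.csv",
        "envelopes": outdir / "envelopes.csv",
        "envelope_draws": outdir / "envelope_draws.csv",
        "single_causes": outdir / "single_causes.csv",
        "countries": outdir / "countries.csv",
        "malaria_constraints": outdir / "malaria_constraints.csv",
        "vr_csmfs": outdir / "vr_csmfs.csv",
    }
    write_studies(bundle.studies, paths["studies"])
    write_panel(bundle.truth.covariates, paths["covariates"])
    write_envelopes(bundle.envelopes, paths["envelopes"], paths["envelope_draws"])
    write_single_causes(bundle.single_causes, paths["single_causes"])
    write_countries(list(bundle.truth.countries), paths["countries"])
    bundle.malaria_constraints.to_csv(paths["malaria_constraints"], index=False)
    bundle.vr_csmfs.to_csv(paths["vr_csmfs"], index=False)
    return paths
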