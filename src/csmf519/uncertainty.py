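"""Monte Carlo uncertainty propagation, aggregation and trend reporting.

Uncertainty flows from three sources -- the posterior of the CSMF model,
the all-cause envelope draws, and the uncertainty intervals of the
single-cause inputs -- and is propagated by draw alignment: draw k of every
output is computed from draw k of every input, so per-draw conservation
(cause deaths summing to the envelope) holds exactly and correlations
between quantities survive into the summaries.

Summaries are the median (point) and 2.5/97.5 percentiles (95% uncertainty
interval) of the draws, so the point always lies inside its interval.
Regional and global estimates sum country death draws per draw; regional
fractions are regional cause deaths over regional all-cause deaths, which
makes them the death-weighted mean of the country fractions.

Trends are summarised by the annual average rate of reduction

    AARR = 100 * ln(rate_t1 / rate_t2) / (t2 - t1)   [% per year],

positive when mortality declines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import AgeSexGroup, CauseTaxonomy
from .types import SingleCauseSeries, UISummary, ValidationError


def summarize_draws(draws: np.ndarray) -> UISummary:
    """Median and 95% interval of a draw vector."""
    x = np.asarray(draws, dtype=float)
    lo, mid, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return UISummary(point=float(mid), lower=float(lo), upper=float(hi))


def sample_single_cause(
    series: SingleCauseSeries, K: int, seed: int
) -> np.ndarray:
    """K Monte Carlo draws matched to a single-cause point and 95% interval.

    A lognormal matched to the interval endpoints is used when the lower
    bound is positive (mortality estimates are right-skewed and positive);
    when the interval touches zero a normal truncated at zero is used.
    A degenerate interval yields constant draws.
    """
    lo, hi = series.ui95
    if hi < lo:
        raise ValidationError("upper bound below lower bound")
    rng = np.random.default_rng(seed)
    if hi == lo:
        return np.full(K, series.deaths)
    z975 = float(stats.norm.ppf(0.975))
    if lo > 0 and series.deaths > 0:
        sigma = np.log(hi / lo) / (2 * z975)
        mu = np.log(series.deaths)  # point taken as the median
        return rng.lognormal(mu, sigma, size=K)
    # interval touches zero: normal anchored on (point, upper), truncated at 0
    sigma = max((hi - series.deaths) / z975, 1e-12)
    a = (0.0 - series.deaths) / sigma
    return stats.truncnorm.rvs(
        a, np.inf, loc=series.deaths, scale=sigma, size=K, random_state=rng
    )


@dataclass
class CellEstimates:
    """Aligned draws for one (location, year, group) cell."""

    causes: tuple[str, ...]
    fractions: np.ndarray  # (S, C)
    deaths: np.ndarray     # (S, C)
    rates: np.ndarray      # (S, C)


class EstimateCube:
    """Final deaths/rates/fractions with draws, keyed by (location, year, group)."""

    def __init__(self) -> None:
        self.cells: dict[tuple[str, int, AgeSexGroup], CellEstimates] = {}

    def add(
        self, iso_code: str, year: int, group: AgeSexGroup, cell: CellEstimates
    ) -> None:
        self.cells[(iso_code, year, group)] = cell

    def locations(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.cells}))

    def all_cause_deaths(self, iso_code: str, year: int, group: AgeSexGroup) -> np.ndarray:
        return self.cells[(iso_code, year, group)].deaths.sum(axis=1)

    def summary(self, include_all_cause: bool = True) -> pd.DataFrame:
        rows = []
        for (iso, year, group), cell in sorted(
            self.cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
        ):
            arrays = {
                cause: (cell.deaths[:, k], cell.rates[:, k], cell.fractions[:, k])
                for k, cause in enumerate(cell.causes)
            }
            if include_all_cause:
                arrays["all_cause"] = (
                    cell.deaths.sum(axis=1),
                    cell.rates.sum(axis=1),
                    cell.fractions.sum(axis=1),
                )
            for cause, (d, r, f) in arrays.items():
                ds, rs, fs = summarize_draws(d), summarize_draws(r), summarize_draws(f)
                rows.append(
                    {
                        "iso_code": iso,
                        "year": year,
                        "group": group.value,
                        "cause": cause,
                        "deaths": ds.point, "deaths_lower": ds.lower, "deaths_upper": ds.upper,
                        "rate": rs.point, "rate_lower": rs.lower, "rate_upper": rs.upper,
                        "fraction": fs.point, "fraction_lower": fs.lower, "fraction_upper": fs.upper,
                    }
                )
        return pd.DataFrame(rows)


def propagate(
    iso_code: str,
    year: int,
    group: AgeSexGroup,
    causes: tuple[str, ...],
    fraction_draws: np.ndarray,
    envelope_deaths_draws: np.ndarray,
    envelope_rate_draws: np.ndarray,
) -> CellEstimates:
    """Combine aligned fraction and envelope draws for one cell.

    All inputs must share the draw count K (resample upstream to align);
    draw k of the outputs uses draw k of every input.
    """
    f = np.asarray(fraction_draws, dtype=float)
    d = np.asarray(envelope_deaths_draws, dtype=float)
    r = np.asarray(envelope_rate_draws, dtype=float)
    if f.shape[0] != d.shape[0] or d.shape[0] != r.shape[0]:
        raise ValidationError(
            f"draw misalignment: {f.shape[0]} fraction vs {d.shape[0]}/{r.shape[0]} envelope draws"
        )
    return CellEstimates(
        causes=causes, fractions=f, deaths=f * d[:, None], rates=f * r[:, None]
    )


def aggregate(cube: EstimateCube, region_map: dict[str, str]) -> EstimateCube:
    """Sum country draws to regional and global estimates, per draw.

    Regional deaths are sums of country deaths; regional fractions divide
    by regional all-cause deaths; regional rates use summed person-years
    recovered from each country's deaths/rate pair.  The global estimate is
    the sum over regions.
    """
    for (iso, _, _) in cube.cells:
        if iso not in region_map:
            raise ValidationError(f"country {iso!r} not mapped to a region")
    out = EstimateCube()
    buckets: dict[tuple[str, int, AgeSexGroup], list[CellEstimates]] = {}
    for (iso, year, group), cell in cube.cells.items():
        for loc in (region_map[iso], "global"):
            buckets.setdefault((loc, year, group), []).append(cell)
    for (loc, year, group), cells in buckets.items():
        causes = cells[0].causes
        deaths = np.zeros_like(cells[0].deaths)
        py = np.zeros(cells[0].deaths.shape[0])  # person-years, thousands
        for cell in cells:
            if cell.causes != causes:
                raise ValidationError("inconsistent cause lists within a group")
            deaths += cell.deaths
            total_d = cell.deaths.sum(axis=1)
            total_r = cell.rates.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(total_r > 0, total_d / total_r, 0.0)
            py += p
        total = deaths.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fractions = np.where(total[:, None] > 0, deaths / total[:, None], 0.0)
            rates = np.where(py[:, None] > 0, deaths / py[:, None], 0.0)
        out.add(loc, year, group, CellEstimates(causes, fractions, deaths, rates))
    return out


def broad_group_totals(
    deaths_by_cause: dict[str, float],
    broad_map: dict[str, str] | CauseTaxonomy,
    total: float | None = None,
) -> pd.DataFrame:
    """CMPN / NCD / injury death totals and fractions of all-cause deaths."""
    if isinstance(broad_map, CauseTaxonomy):
        broad_map = dict(broad_map.broad_group)
    missing = [c for c in deaths_by_cause if c not in broad_map]
    if missing:
        raise ValidationError(f"cause(s) without a broad group: {missing}")
    if total is None:
        total = float(sum(deaths_by_cause.values()))
    sums = {"CMPN": 0.0, "NCD": 0.0, "injury": 0.0}
    for cause, d in deaths_by_cause.items():
        sums[broad_map[cause]] += d
    return pd.DataFrame(
        [
            {"broad_group": g, "deaths": d, "fraction": (d / total if total > 0 else 0.0)}
            for g, d in sums.items()
        ]
    )


def compute_aarr(
    rate_t1: float | np.ndarray,
    rate_t2: float | np.ndarray,
    t1: float,
    t2: float,
) -> np.ndarray:
    """Annual average rate of reduction, percent per year (positive = decline)."""
    r1 = np.asarray(rate_t1, dtype=float)
    r2 = np.asarray(rate_t2, dtype=float)
    if t2 <= t1:
        raise ValidationError("t2 must exceed t1")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValidationError("AARR requires positive rates")
    return 100.0 * np.log(r1 / r2) / (t2 - t1)


#: causes excluded from trend summaries because of idiosyncratic spikes
AARR_EXCLUDED_CAUSES = frozenset({"natural_disasters"})


def aarr_table(
    cube: EstimateCube, year_from: int = 2000, year_to: int = 2019
) -> pd.DataFrame:
    """Per (location, group, cause) AARR with 95% intervals from rate draws.

    Cells with nonpositive rates in either year, and causes with
    idiosyncratic series (natural disasters), are left out.
    """
    rows = []
    keys = {(loc, g) for (loc, y, g) in cube.cells}
    for loc, group in sorted(keys, key=lambda k: (k[0], k[1].value)):
        a = cube.cells.get((loc, year_from, group))
        b = cube.cells.get((loc, year_to, group))
        if a is None or b is None:
            continue
        for k, cause in enumerate(a.causes):
            if cause in AARR_EXCLUDED_CAUSES:
                continue
            r1, r2 = a.rates[:, k], b.rates[:, k]
            if np.any(r1 <= 0) or np.any(r2 <= 0):
                continue
            ui = summarize_draws(compute_aarr(r1, r2, year_from, year_to))
            rows.append(
                {
                    "iso_code": loc,
                    "group": group.value,
                    "cause": cause,
                    "aarr": ui.point,
                    "aarr_lower": ui.lower,
                    "aarr_upper": ui.upper,
                }
            )
    return pd.DataFrame(rows)


def source_share_table(
    cube: EstimateCube, categories: dict[str, str], year: int
) -> pd.DataFrame:
    """Share of global deaths by input-source stratum (HQVR/LMM/HMM/...)."""
    totals: dict[str, float] = {}
    grand = 0.0
    for (iso, y, group), cell in cube.cells.items():
        if y != year or iso not in categories:
            continue
        d = float(np.median(cell.deaths.sum(axis=1)))
        totals[categories[iso]] = totals.get(categories[iso], 0.0) + d
        grand += d
    return pd.DataFrame(
        [
            {"stratum": s, "deaths": d, "percent": 100.0 * d / grand if grand else 0.0}
            for s, d in sorted(totals.items())
        ]
    )
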