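"""Country-year CSMF prediction, malaria structural rules, envelopes.

The fitted model predicts a posterior draw of the modelled-cause CSMF for
every country-year from the covariate panel (complete 2000-2019 series).
Malaria then receives two structural corrections grounded in malaria
epidemiology: it is only modelled at ages 5-14 (the 15-19 taxonomies simply
carry no malaria cause), it is set to zero where programme estimates report
zero incidence, and elsewhere it is capped at the country-year's under-5
malaria share -- deaths due to malaria at 5-14 do not plausibly exceed the
1-59-month proportion -- with any excess redistributed pro rata across the
remaining causes.  Finally the fractions are multiplied into the all-cause
envelope to give cause-specific deaths and rates, draw by draw, so the
cause deaths sum exactly to the envelope in every draw.

High-quality vital-registration countries bypass the model entirely: their
observed CSMFs pass straight to envelope application.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorSample
from .taxonomy import AgeSexGroup
from .types import Envelope, ValidationError


@dataclass
class CSMFDraws:
    """Posterior/Monte-Carlo samples of a cause simplex for one cell."""

    iso_code: str
    year: int
    group: AgeSexGroup
    causes: tuple[str, ...]
    draws: np.ndarray  # (S, C), each row on the simplex

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.causes):
            raise ValidationError("draws must be (S, n_causes)")

    @property
    def point(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def cause_index(self, cause: str) -> int:
        return self.causes.index(cause)


@dataclass(frozen=True)
class MalariaConstraints:
    """Zero-incidence flags and under-5 malaria caps per (country, year)."""

    incidence_zero: frozenset[tuple[str, int]]
    under5_fraction: dict[tuple[str, int], float] = field(hash=False)

    def __post_init__(self) -> None:
        for key, v in self.under5_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"malaria cap outside [0,1] at {key}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MalariaConstraints":
        zero = frozenset(
            (str(r["iso_code"]), int(r["year"]))
            for _, r in df.iterrows()
            if bool(r["incidence_zero"])
        )
        caps = {
            (str(r["iso_code"]), int(r["year"])): float(r["under5_fraction"])
            for _, r in df.iterrows()
        }
        return cls(incidence_zero=zero, under5_fraction=caps)


def predict_csmf(
    posterior: PosteriorSample,
    panel: pd.DataFrame,
    country: str,
    years: tuple[int, ...] | None = None,
) -> dict[int, CSMFDraws]:
    """One modelled-cause simplex draw per posterior draw per year.

    Uses the country's random effect if it contributed training data, else
    u = 0.  ``panel`` must contain the country for every requested year.
    """
    if country not in panel.index.get_level_values(0):
        raise ValidationError(f"country {country!r} missing from covariate panel")
    sub = panel.loc[country]
    years = tuple(int(y) for y in (years or sub.index))
    out = {}
    group = posterior.spec.taxonomy.group
    for year in years:
        if year not in sub.index:
            raise ValidationError(f"({country}, {year}) missing from covariate panel")
        x = sub.loc[year][list(posterior.standardizer.names)].to_numpy(dtype=float)
        out[year] = CSMFDraws(
            iso_code=country,
            year=year,
            group=group,
            causes=posterior.cause_order,
            draws=posterior.predict_fractions(x, country=country),
        )
    return out


def _redistribute_excess(
    draws: np.ndarray, k: int, new_value: np.ndarray
) -> np.ndarray:
    """Set cause ``k`` to ``new_value`` per draw, spreading the freed mass
    pro rata over the remaining causes (uniformly when they hold no mass)."""
    out = draws.copy()
    m = draws[:, k]
    rest = 1.0 - m
    scale = np.where(rest > 0, (1.0 - new_value) / np.where(rest > 0, rest, 1.0), 0.0)
    out *= scale[:, None]
    # degenerate rows (all mass on cause k): spread uniformly
    degenerate = rest <= 0
    if np.any(degenerate):
        n_rest = draws.shape[1] - 1
        out[degenerate] = (1.0 - new_value[degenerate, None]) / n_rest
    out[:, k] = new_value
    return out


def apply_malaria_rules(
    csmf: CSMFDraws, constraints: MalariaConstraints
) -> CSMFDraws:
    """Apply the malaria structural rules to one cell's draws.

    Zero-incidence country-years get malaria = 0; otherwise malaria is
    capped at the under-5 share and the excess is redistributed pro rata.
    Groups without a malaria cause (ages 15-19) pass through unchanged.
    """
    if "malaria" not in csmf.causes:
        return csmf
    key = (csmf.iso_code, csmf.year)
    k = csmf.cause_index("malaria")
    m = csmf.draws[:, k]
    if key in constraints.incidence_zero:
        target = np.zeros_like(m)
    else:
        cap = constraints.under5_fraction.get(key)
        if cap is None:
            return csmf
        if not 0.0 <= cap <= 1.0:
            raise ValidationError(f"malaria cap outside [0,1] at {key}")
        target = np.minimum(m, cap)
    draws = _redistribute_excess(csmf.draws, k, target)
    return CSMFDraws(csmf.iso_code, csmf.year, csmf.group, csmf.causes, draws)


def apply_envelope(
    csmf: CSMFDraws, envelope: Envelope
) -> tuple[np.ndarray, np.ndarray]:
    """Convert fraction draws into (deaths, rate) draws by cause.

    CSMF draw k is paired with envelope draw k, recycling envelope draws
    when fewer are available; cause deaths sum to the envelope exactly in
    every draw.
    """
    if envelope.deaths < 0 or envelope.rate < 0:
        raise ValidationError("envelope must be nonnegative")
    S = csmf.draws.shape[0]
    if envelope.deaths_draws:
        idx = np.arange(S) % len(envelope.deaths_draws)
        d = np.asarray(envelope.deaths_draws)[idx]
        r = np.asarray(envelope.rate_draws)[idx]
    else:
        d = np.full(S, envelope.deaths)
        r = np.full(S, envelope.rate)
    return csmf.draws * d[:, None], csmf.draws * r[:, None]
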