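"""Single-cause integration: squeezing, residual floors, crisis capping.

Externally estimated single causes are carved out of the modelled composite
fractions:

* HIV/AIDS, endemic measles and extrapulmonary tuberculosis are squeezed
  *into* the modelled "other CMPN" fraction.  A residual other-CMPN floor --
  the median other-CMPN fraction across high-quality vital-registration
  country-years, taken as the minimum plausible share -- is reserved first;
  if the single causes exceed the remaining room they are scaled down pro
  rata so the partition always sums exactly to the modelled composite.
* Pulmonary tuberculosis is squeezed into the modelled lower-respiratory
  infection (LRI) fraction the same way, with a residual LRI floor.
  Age groups whose taxonomy carries no LRI cause route pulmonary TB through
  the other-CMPN squeeze instead.
* Crisis deaths (collective violence, natural disasters, epidemics) are
  capped at the country-year's maximum historically reported crisis share,
  assigned to the cause matching the crisis nature, and the other causes
  are rescaled; crises not already counted in the all-cause envelope
  increase the envelope instead of displacing other causes.

All operations work elementwise on scalars or draw vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predict import CSMFDraws
from .taxonomy import AgeSexGroup
from .types import ValidationError

#: default mapping from crisis nature to the reporting cause receiving it
DEFAULT_CRISIS_TARGETS = {
    "collective_violence": "collective_violence",
    "natural_disaster": "natural_disasters",
    "epidemic": "measles",
}


@dataclass(frozen=True)
class ResidualFractions:
    """Per-group residual floors derived from vital-registration data."""

    group: AgeSexGroup
    residual_lri: float
    residual_other_cmpn: float

    def __post_init__(self) -> None:
        for v in (self.residual_lri, self.residual_other_cmpn):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("residual fractions must lie in [0,1]")


def residuals_from_vr(vr_csmfs: pd.DataFrame, group: AgeSexGroup) -> ResidualFractions:
    """Median LRI and other-CMPN fractions over HQVR country-years.

    ``vr_csmfs`` is long format with columns (iso_code, year, group, cause,
    fraction).  HQVR countries are assumed to have the minimum plausible
    shares of these nonspecific causes, so their medians serve as floors.
    """
    if vr_csmfs.empty or "group" not in vr_csmfs.columns:
        raise ValidationError("vital-registration CSMF table is empty")
    sub = vr_csmfs[vr_csmfs["group"] == group.value]
    if sub.empty:
        raise ValidationError(f"no vital-registration rows for group {group}")

    def med(cause: str) -> float:
        vals = sub.loc[sub["cause"] == cause, "fraction"]
        return float(vals.median()) if len(vals) else 0.0

    return ResidualFractions(
        group=group, residual_lri=med("lri"), residual_other_cmpn=med("other_cmpn")
    )


def single_cause_fraction(
    deaths: float | np.ndarray, envelope_deaths: float
) -> np.ndarray:
    """Single-cause deaths as a fraction of the envelope, truncated to [0,1].

    A missing series is an input of 0 deaths.  A zero envelope with nonzero
    cause deaths is flagged as an error for that cell.
    """
    d = np.asarray(deaths, dtype=float)
    if np.any(d < 0):
        raise ValidationError("single-cause deaths must be nonnegative")
    if envelope_deaths == 0:
        if np.any(d > 0):
            raise ValidationError("zero envelope with nonzero single-cause deaths")
        return np.zeros_like(d)
    return np.clip(d / envelope_deaths, 0.0, 1.0)


def _check_unit(name: str, *vals: np.ndarray) -> None:
    for v in vals:
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError(f"{name}: inputs must lie in [0,1]")


def squeeze_other_cmpn(
    modelled_other_cmpn: float | np.ndarray,
    hiv: float | np.ndarray,
    measles_endemic: float | np.ndarray,
    tb_extrapulmonary: float | np.ndarray,
    residual_other_cmpn: float,
) -> dict[str, np.ndarray]:
    """Partition the modelled other-CMPN fraction.

    Room for the single causes is the modelled fraction minus the residual
    floor (the residual is clipped to the modelled fraction when larger);
    HIV, endemic measles and extrapulmonary TB are scaled down pro rata when
    they jointly exceed that room.  The partition sums exactly to the
    modelled fraction and the final other-CMPN never drops below the floor.
    """
    m = np.asarray(modelled_other_cmpn, dtype=float)
    parts = [np.asarray(v, dtype=float) for v in (hiv, measles_endemic, tb_extrapulmonary)]
    _check_unit("squeeze_other_cmpn", m, *parts, np.asarray(residual_other_cmpn))
    m, h, me, tb = np.broadcast_arrays(m, *parts)
    residual = np.minimum(residual_other_cmpn, m)
    available = m - residual
    s = h + me + tb
    scale = np.ones_like(s)
    np.divide(available, s, out=scale, where=s > available)
    h2, me2, tb2 = h * scale, me * scale, tb * scale
    final = m - (h2 + me2 + tb2)
    return {
        "hiv": h2,
        "measles_endemic": me2,
        "tb_extrapulmonary": tb2,
        "other_cmpn_final": final,
    }


def squeeze_lri(
    modelled_lri: float | np.ndarray,
    tb_pulmonary: float | np.ndarray,
    residual_lri: float,
) -> dict[str, np.ndarray]:
    """Partition the modelled LRI fraction into pulmonary TB and final LRI."""
    m = np.asarray(modelled_lri, dtype=float)
    tb = np.asarray(tb_pulmonary, dtype=float)
    _check_unit("squeeze_lri", m, tb, np.asarray(residual_lri))
    m, tb = np.broadcast_arrays(m, tb)
    residual = np.minimum(residual_lri, m)
    available = m - residual
    tb2 = np.minimum(tb, available)
    return {"tb_pulmonary": tb2, "lri_final": m - tb2}


def apply_crisis(
    csmf: CSMFDraws,
    crisis_fraction: float | np.ndarray,
    ghe_max_fraction: float,
    nature: str,
    in_envelope: bool = True,
    crisis_targets: dict[str, str] | None = None,
) -> tuple[CSMFDraws, np.ndarray]:
    """Fold capped crisis deaths into one cell's cause fractions.

    ``crisis_fraction`` is the raw crisis share of the (pre-crisis)
    envelope, per draw; it is capped at ``ghe_max_fraction``.  The capped
    share f goes to the cause matching the crisis nature.  Inside the
    envelope, every other cause scales by (1 - f); outside it, the envelope
    grows by the crisis deaths instead and all fractions are re-expressed
    against the enlarged envelope.  Returns the adjusted draws and the
    per-draw envelope scale factor (1 when the crisis is in the envelope).
    """
    targets = crisis_targets or DEFAULT_CRISIS_TARGETS
    if nature not in targets:
        raise ValidationError(f"unknown crisis nature {nature!r}")
    if not 0.0 <= ghe_max_fraction <= 1.0:
        raise ValidationError("crisis cap must lie in [0,1]")
    target = targets[nature]
    if target not in csmf.causes:
        raise ValidationError(
            f"crisis target cause {target!r} absent from taxonomy of {csmf.group}"
        )
    raw = np.broadcast_to(
        np.asarray(crisis_fraction, dtype=float), csmf.draws.shape[:1]
    ).copy()
    if np.any(raw < 0):
        raise ValidationError("crisis fraction must be nonnegative")
    f = np.minimum(raw, ghe_max_fraction)
    k = csmf.cause_index(target)
    out = csmf.draws.copy()
    if in_envelope:
        out *= (1.0 - f)[:, None]
        out[:, k] += f
        env_scale = np.ones_like(f)
    else:
        env_scale = 1.0 + f
        out /= env_scale[:, None]
        out[:, k] += f / env_scale
    return (
        CSMFDraws(csmf.iso_code, csmf.year, csmf.group, csmf.causes, out),
        env_scale,
    )
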