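"""Core domain types and validation rules.

Countries fall in three strata that determine how their cause-of-death
distribution is estimated:

* ``HQVR`` -- high-quality vital registration; empirical cause fractions are
  used directly (pass-through to the envelopes).
* ``LMM`` -- low-mortality modelled; vital-registration records feed the
  multinomial model as input studies.
* ``HMM`` -- high-mortality modelled; verbal-autopsy studies feed the model.

Without high-quality vital registration, the stratum is decided by the
probability of dying between ages 5 and 19: at or above 10 per 1000 the
country is HMM, below it LMM (the boundary itself is assigned to HMM so the
rule is deterministic).

Study inclusion rules: a study must report at least two causes of death and
at least 15 total deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .taxonomy import AgeSexGroup, CauseTaxonomy

#: the nine reporting regions used for aggregation
REGIONS = (
    "west and central Africa",
    "eastern and southern Africa",
    "Middle East and north Africa",
    "south Asia",
    "east Asia and Pacific",
    "Latin America and Caribbean",
    "North America",
    "western Europe",
    "eastern Europe and central Asia",
)

CATEGORIES = ("HQVR", "LMM", "HMM")

#: stratum cutoff: probability of death age 5-19, per 1000
HMM_CUTOFF_PER_1000 = 10.0

MIN_STUDY_DEATHS = 15
MIN_REPORTED_CAUSES = 2


class ValidationError(ValueError):
    """An input violated a structural rule (bad label, negative count...)."""


@dataclass(frozen=True)
class StudyRejection:
    """A study excluded by an inclusion rule, with the rule it violated."""

    study_id: str
    rule: str


@dataclass(frozen=True)
class CountryMeta:
    iso_code: str
    region: str
    category: str
    prob_death_5_19: float  # per 1000

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown country category {self.category!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.prob_death_5_19 < 0:
            raise ValidationError("prob_death_5_19 must be nonnegative")


@dataclass(frozen=True)
class StudyRecord:
    """One study's death counts by cause for a country-period-group.

    ``year_mid`` is the midpoint of the study period; multi-year studies
    carry a single covariate row evaluated at that midpoint.
    """

    study_id: str
    iso_code: str
    group: AgeSexGroup
    year_mid: int
    deaths_by_cause: Mapping[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        for cause, n in self.deaths_by_cause.items():
            if n < 0:
                raise ValidationError(
                    f"study {self.study_id}: negative count for {cause!r}"
                )

    @property
    def total_deaths(self) -> int:
        return int(sum(self.deaths_by_cause.values()))

    @property
    def reported_causes(self) -> tuple[str, ...]:
        return tuple(self.deaths_by_cause.keys())


@dataclass(frozen=True)
class Envelope:
    """All-cause deaths and mortality rate for one country-year-group.

    ``deaths_draws``/``rate_draws`` are samples from the envelope's
    uncertainty distribution; the point estimate must lie within their range.
    """

    iso_code: str
    year: int
    group: AgeSexGroup
    deaths: float
    rate: float  # deaths per 1000 person-years
    deaths_draws: tuple[float, ...] = ()
    rate_draws: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.deaths < 0 or self.rate < 0:
            raise ValidationError("envelope deaths and rate must be nonnegative")
        if any(d < 0 for d in self.deaths_draws) or any(r < 0 for r in self.rate_draws):
            raise ValidationError("envelope draws must be nonnegative")
        if self.deaths_draws and not (
            min(self.deaths_draws) <= self.deaths <= max(self.deaths_draws)
        ):
            raise ValidationError("envelope point estimate outside draw range")


SINGLE_CAUSE_KINDS = (
    "hiv",
    "tb_pulmonary",
    "tb_extrapulmonary",
    "measles_endemic",
    "measles_epidemic",
    "crisis",
)
CRISIS_NATURES = ("collective_violence", "natural_disaster", "epidemic")


@dataclass(frozen=True)
class SingleCauseSeries:
    """Externally estimated deaths for one single cause in one cell.

    A missing series is treated as zero deaths.  ``in_envelope`` says whether
    these deaths are already counted in the all-cause envelope (if not, they
    are added on top of it at integration time).
    """

    cause: str
    iso_code: str
    year: int
    group: AgeSexGroup
    deaths: float
    ui95: tuple[float, float]
    crisis_nature: str | None = None
    in_envelope: bool = True
    #: cap on the crisis share of the envelope (maximum historically
    #: reported crisis fraction for this country-year); crisis rows only
    ghe_max_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cause not in SINGLE_CAUSE_KINDS:
            raise ValidationError(f"unknown single-cause kind {self.cause!r}")
        lo, hi = self.ui95
        if not (lo <= self.deaths <= hi):
            raise ValidationError(
                f"{self.cause} {self.iso_code} {self.year}: point outside UI"
            )
        if lo < 0:
            raise ValidationError("single-cause bounds must be nonnegative")
        if self.crisis_nature is not None and self.crisis_nature not in CRISIS_NATURES:
            raise ValidationError(f"unknown crisis nature {self.crisis_nature!r}")
        if not 0.0 <= self.ghe_max_fraction <= 1.0:
            raise ValidationError("ghe_max_fraction must lie in [0,1]")


@dataclass(frozen=True)
class UISummary:
    """Point estimate (median of draws) with a 95% uncertainty interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValidationError("UI must satisfy lower <= point <= upper")


def classify_country(prob_death_5_19: float, hqvr_flag: bool) -> str:
    """Assign a country to the HQVR / LMM / HMM stratum.

    ``prob_death_5_19`` is the probability of dying between ages 5 and 19,
    per 1000.  A country with high-quality vital registration is HQVR
    regardless of mortality; otherwise the 10-per-1000 cutoff separates HMM
    (>= 10, boundary included) from LMM.
    """
    if prob_death_5_19 < 0:
        raise ValidationError("prob_death_5_19 must be nonnegative")
    if hqvr_flag:
        return "HQVR"
    return "HMM" if prob_death_5_19 >= HMM_CUTOFF_PER_1000 else "LMM"


def validate_study(
    record: StudyRecord, taxonomy: CauseTaxonomy
) -> StudyRecord | StudyRejection:
    """Apply the study inclusion rules.

    Returns the record unchanged when it reports at least two causes and at
    least 15 deaths; otherwise a :class:`StudyRejection` naming the violated
    rule.  Unknown cause labels and negative counts raise
    :class:`ValidationError` (they are data errors, not exclusions).
    """
    unknown = set(record.deaths_by_cause) - set(taxonomy.causes)
    if unknown:
        raise ValidationError(
            f"study {record.study_id}: unknown cause label(s) {sorted(unknown)}"
        )
    if len(record.reported_causes) < MIN_REPORTED_CAUSES:
        return StudyRejection(record.study_id, f">={MIN_REPORTED_CAUSES} causes")
    if record.total_deaths < MIN_STUDY_DEATHS:
        return StudyRejection(record.study_id, f"<{MIN_STUDY_DEATHS} deaths")
    return record


def filter_studies(
    records: list[StudyRecord], taxonomy: CauseTaxonomy
) -> tuple[list[StudyRecord], list[StudyRejection]]:
    """Split records into accepted studies and rejections (idempotent)."""
    accepted: list[StudyRecord] = []
    rejected: list[StudyRejection] = []
    for rec in records:
        out = validate_study(rec, taxonomy)
        (accepted if isinstance(out, StudyRecord) else rejected).append(out)
    return accepted, rejected


def csmf_from_counts(
    deaths_by_cause: Mapping[str, float],
    total: float | None = None,
    rtol: float = 1e-4,
) -> dict[str, float]:
    """Cause-specific mortality fractions from death counts.

    ``total`` defaults to the sum of the counts, in which case the fractions
    sum to 1 to within 1e-12.  An explicit ``total`` may differ from the sum
    by a relative ``rtol`` (published tables round cause rows and the
    all-cause total independently, so the two rarely agree to the last
    death); fractions then use ``total`` as the denominator, matching how
    published percentages are computed.
    """
    counts = dict(deaths_by_cause)
    if any(v < 0 for v in counts.values()):
        raise ValidationError("death counts must be nonnegative")
    s = float(sum(counts.values()))
    if total is None:
        total = s
    if total <= 0:
        raise ValidationError("total deaths must be positive")
    if abs(s - total) > rtol * max(1.0, total):
        raise ValidationError(f"counts sum to {s}, expected total {total}")
    return {c: v / total for c, v in counts.items()}
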