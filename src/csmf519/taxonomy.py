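"""Cause-of-death taxonomy for 5-19-year-old mortality estimation.

Estimation is carried out separately for four age-sex groups: 5-9-year-olds
(both sexes), 10-14-year-olds (both sexes), 15-19-year-old females and
15-19-year-old males.  Each group has its own ordered cause list: a cause is
included when it accounts for a non-trivial share (>= ~3%) of global deaths in
that group, which is why e.g. maternal causes appear only in 15-19-year-old
females, congenital disorders and measles only in 5-9-year-olds, and
cardiovascular disease and self-harm only in the 15-19 groups.

Causes carry two orthogonal labels:

* a *broad group* -- CMPN (communicable, maternal, perinatal and nutritional
  conditions), NCD (non-communicable diseases) or injury -- used for
  aggregate reporting;
* a *source* -- ``modelled`` causes are estimated jointly by the
  multinomial-logistic model, while ``single_cause`` causes (HIV/AIDS,
  tuberculosis, measles, and the crisis causes collective violence and
  natural disasters) come from external programme estimates and are squeezed
  into the modelled composites afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class AgeSexGroup(str, Enum):
    """The four age-sex strata estimated separately."""

    AGE_5_9 = "5-9"
    AGE_10_14 = "10-14"
    AGE_15_19_F = "15-19f"
    AGE_15_19_M = "15-19m"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


BROAD_GROUPS = ("CMPN", "NCD", "injury")
SOURCE_FLAGS = ("modelled", "single_cause", "residual")

#: broad-group membership, shared across age-sex groups
_BROAD: dict[str, str] = {
    "diarrhoea": "CMPN",
    "malaria": "CMPN",
    "lri": "CMPN",  # lower-respiratory tract infections
    "tuberculosis": "CMPN",
    "measles": "CMPN",
    "hiv": "CMPN",
    "maternal": "CMPN",
    "other_cmpn": "CMPN",
    "neoplasms": "NCD",
    "congenital": "NCD",
    "cardiovascular": "NCD",
    "digestive": "NCD",
    "other_ncd": "NCD",
    "road_traffic": "injury",
    "drowning": "injury",
    "self_harm": "injury",
    "interpersonal_violence": "injury",
    "collective_violence": "injury",
    "natural_disasters": "injury",
    "other_injuries": "injury",
}

#: causes supplied by external single-cause programme estimates rather than
#: the multinomial model (crisis causes included)
SINGLE_CAUSES = frozenset(
    {"hiv", "tuberculosis", "measles", "collective_violence", "natural_disasters"}
)

#: per-group reporting cause lists
_GROUP_CAUSES: dict[AgeSexGroup, tuple[str, ...]] = {
    AgeSexGroup.AGE_5_9: (
        "diarrhoea", "malaria", "lri", "drowning", "neoplasms", "road_traffic",
        "tuberculosis", "measles", "congenital", "digestive", "hiv",
        "collective_violence", "natural_disasters",
        "other_cmpn", "other_ncd", "other_injuries",
    ),
    AgeSexGroup.AGE_10_14: (
        "malaria", "neoplasms", "lri", "drowning", "road_traffic", "diarrhoea",
        "hiv", "digestive", "tuberculosis",
        "collective_violence", "natural_disasters",
        "other_cmpn", "other_ncd", "other_injuries",
    ),
    AgeSexGroup.AGE_15_19_F: (
        "self_harm", "neoplasms", "cardiovascular", "road_traffic",
        "tuberculosis", "digestive", "maternal", "interpersonal_violence",
        "hiv", "drowning", "collective_violence", "natural_disasters",
        "other_cmpn", "other_ncd", "other_injuries",
    ),
    AgeSexGroup.AGE_15_19_M: (
        "road_traffic", "interpersonal_violence", "self_harm", "tuberculosis",
        "neoplasms", "cardiovascular", "digestive", "drowning", "hiv",
        "collective_violence", "natural_disasters",
        "other_cmpn", "other_ncd", "other_injuries",
    ),
}

#: default synonym table applied when reading study files
DEFAULT_ALIASES: dict[str, str] = {
    "road traffic injuries": "road_traffic",
    "rti": "road_traffic",
    "lower-respiratory tract infections": "lri",
    "lower respiratory infections": "lri",
    "hiv/aids": "hiv",
    "tb": "tuberculosis",
    "self-harm": "self_harm",
    "interpersonal violence": "interpersonal_violence",
    "collective violence": "collective_violence",
    "natural disasters": "natural_disasters",
    "other cmpn": "other_cmpn",
    "other non-communicable diseases": "other_ncd",
    "other injuries": "other_injuries",
}


@dataclass(frozen=True)
class CauseTaxonomy:
    """Ordered cause list for one age-sex group with broad-group/source maps.

    Parameters
    ----------
    group
        Age-sex group the taxonomy applies to.
    causes
        Ordered reporting cause labels, unique within the group.
    broad_group
        Map cause -> {"CMPN", "NCD", "injury"}.
    source
        Map cause -> {"modelled", "single_cause", "residual"}.
    reference_cause
        Baseline category of the multinomial-logistic model; must be a
        modelled cause.  All model coefficients for this cause are fixed at 0.
    """

    group: AgeSexGroup
    causes: tuple[str, ...]
    broad_group: dict[str, str] = field(hash=False)
    source: dict[str, str] = field(hash=False)
    reference_cause: str = "other_cmpn"

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("cause labels must be unique within a group")
        for c in self.causes:
            if self.broad_group.get(c) not in BROAD_GROUPS:
                raise ValueError(f"cause {c!r} lacks a valid broad group")
            if self.source.get(c) not in SOURCE_FLAGS:
                raise ValueError(f"cause {c!r} lacks a valid source flag")
        if self.reference_cause not in self.causes:
            raise ValueError("reference cause must belong to the taxonomy")
        if self.source[self.reference_cause] != "modelled":
            raise ValueError("reference cause must be a modelled cause")

    @property
    def modelled_causes(self) -> tuple[str, ...]:
        """Causes estimated jointly by the multinomial model, in order."""
        return tuple(c for c in self.causes if self.source[c] == "modelled")

    @property
    def single_causes(self) -> tuple[str, ...]:
        return tuple(c for c in self.causes if self.source[c] == "single_cause")

    @property
    def has_malaria(self) -> bool:
        return "malaria" in self.causes

    @property
    def has_lri(self) -> bool:
        return "lri" in self.causes

    def broad_members(self, broad: str) -> tuple[str, ...]:
        if broad not in BROAD_GROUPS:
            raise ValueError(f"unknown broad group {broad!r}")
        return tuple(c for c in self.causes if self.broad_group[c] == broad)


def default_taxonomy(group: AgeSexGroup | str) -> CauseTaxonomy:
    """Standard taxonomy for one age-sex group.

    Modelled-cause counts are 11 / 10 / 11 / 10 for the 5-9, 10-14, 15-19
    female and 15-19 male groups respectively once the externally estimated
    single causes are set aside.
    """
    group = AgeSexGroup(group)
    causes = _GROUP_CAUSES[group]
    return CauseTaxonomy(
        group=group,
        causes=causes,
        broad_group={c: _BROAD[c] for c in causes},
        source={
            c: ("single_cause" if c in SINGLE_CAUSES else "modelled") for c in causes
        },
    )


def all_default_taxonomies() -> dict[AgeSexGroup, CauseTaxonomy]:
    return {g: default_taxonomy(g) for g in AgeSexGroup}


def resolve_cause(label: str, aliases: dict[str, str] | None = None) -> str:
    """Map a free-text cause label to the closed vocabulary."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    key = label.strip().lower()
    return table.get(key, key)
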