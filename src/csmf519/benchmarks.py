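"""Consistency arithmetic on published 2019 global estimates.

The package ships the published global cause-of-death counts for
5-19-year-olds in 2019 (overall and per age-sex group) and the death totals
by input-source stratum.  The functions here recompute, from those raw
counts, the derived quantities a reader checks first -- cause percentages,
broad-group totals, and input-source shares -- exercising
:func:`~csmf519.types.csmf_from_counts` and
:func:`~csmf519.uncertainty.broad_group_totals` on real published numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .taxonomy import _BROAD
from .types import csmf_from_counts
from .uncertainty import broad_group_totals


def _data(name: str) -> pd.DataFrame:
    with resources.files("csmf519.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_global_estimates_2019() -> pd.DataFrame:
    """Published 2019 global death counts by (group, cause); group 'all'
    spans 5-19 overall.  Each group includes an ``all_cause`` row."""
    return _data("global_estimates_2019.csv")


def load_input_source_2019() -> pd.DataFrame:
    """Published 2019 death totals by input-source stratum."""
    return _data("input_source_2019.csv")


def group_counts(group: str) -> tuple[dict[str, float], float]:
    """(cause -> deaths, all-cause total) for one group of the 2019 table."""
    df = load_global_estimates_2019()
    sub = df[df["group"] == group]
    if sub.empty:
        raise KeyError(f"no published counts for group {group!r}")
    counts = dict(zip(sub["cause"], sub["deaths"].astype(float)))
    total = counts.pop("all_cause")
    return counts, total


def cause_percentage(group: str, cause: str) -> float:
    """Percent of the group's all-cause deaths due to one cause (one decimal
    place is how such tables print)."""
    counts, total = group_counts(group)
    fractions = csmf_from_counts(counts, total)
    return 100.0 * fractions[cause]


def broad_group_summary() -> pd.DataFrame:
    """CMPN / NCD / injury deaths and percentages for all 5-19-year-olds."""
    counts, total = group_counts("all")
    out = broad_group_totals(counts, _BROAD, total)
    out["percent"] = 100.0 * out["fraction"]
    return out


def input_source_shares() -> dict[str, float]:
    """Percent of 2019 global deaths by input-source stratum."""
    df = load_input_source_2019()
    _, total = group_counts("all")
    return {
        str(r["stratum"]): 100.0 * float(r["deaths"]) / total
        for _, r in df.iterrows()
    }
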