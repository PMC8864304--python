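"""Delimited-text readers and writers for the five input streams.

All tables are UTF-8 CSV in long format, keyed by
``(iso_code, year, group[, cause])`` except the covariate panel, which is
wide (one column per covariate, keyed by ``(iso_code, year)``).  Readers
validate schemas, report offending rows with their file line numbers, and
reject duplicate keys; writers round-trip values bit-for-bit through
``repr``-precision floats.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .taxonomy import AgeSexGroup, resolve_cause
from .types import (
    CountryMeta,
    Envelope,
    SingleCauseSeries,
    StudyRecord,
    ValidationError,
)

PREDICTION_YEARS = tuple(range(2000, 2020))


class SchemaError(ValidationError):
    """A file did not match its declared header schema."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_duplicates(df: pd.DataFrame, keys: list[str], path: str | Path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        row = df.loc[dup.idxmax()]
        key = tuple(row[k] for k in keys)
        line = int(df.index[dup][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}: duplicate key {key} (first at line {line})")


# ---------------------------------------------------------------- studies

STUDY_COLUMNS = ("study_id", "iso_code", "group", "year_mid", "cause", "deaths")


def read_studies(
    path: str | Path, aliases: dict[str, str] | None = None
) -> list[StudyRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, STUDY_COLUMNS, path)
    df["cause"] = df["cause"].map(lambda c: resolve_cause(str(c), aliases))
    _check_duplicates(df, ["study_id", "cause"], path)
    bad = df["deaths"] < 0
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValidationError(f"{path}: negative death count at line {line}")
    records = []
    for sid, sub in df.groupby("study_id", sort=False):
        head = sub.iloc[0]
        records.append(
            StudyRecord(
                study_id=str(sid),
                iso_code=str(head["iso_code"]),
                group=AgeSexGroup(str(head["group"])),
                year_mid=int(head["year_mid"]),
                deaths_by_cause={
                    str(r["cause"]): int(r["deaths"]) for _, r in sub.iterrows()
                },
            )
        )
    return records


def write_studies(records: Sequence[StudyRecord], path: str | Path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "iso_code": r.iso_code,
            "group": r.group.value,
            "year_mid": r.year_mid,
            "cause": cause,
            "deaths": n,
        }
        for r in records
        for cause, n in r.deaths_by_cause.items()
    ]
    pd.DataFrame(rows, columns=list(STUDY_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------- covariates


def read_panel(
    path: str | Path,
    require_complete: bool = True,
    years: Sequence[int] = PREDICTION_YEARS,
) -> pd.DataFrame:
    """Read the country-year covariate panel (wide format).

    With ``require_complete`` the panel must provide every covariate for
    every (country, year) cell over ``years`` -- predictions need a complete
    time series from 2000 to 2019.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("iso_code", "year"), path)
    _check_duplicates(df, ["iso_code", "year"], path)
    df = df.set_index(["iso_code", "year"]).sort_index()
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no covariate columns")
    if require_complete:
        null = df.isna()
        if null.any().any():
            cell = null.stack()
            cell = cell[cell].index[0]
            raise ValidationError(
                f"{path}: missing covariate value at {cell} "
                "(complete 2000-2019 time series required)"
            )
        for iso in df.index.get_level_values(0).unique():
            have = set(df.loc[iso].index)
            gaps = [y for y in years if y not in have]
            if gaps:
                raise ValidationError(
                    f"{path}: country {iso} missing year(s) {gaps[:5]} "
                    "(complete 2000-2019 time series required)"
                )
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------- envelopes

ENVELOPE_COLUMNS = ("iso_code", "year", "group", "deaths", "rate")


def read_envelopes(
    path: str | Path, draws_path: str | Path | None = None
) -> list[Envelope]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ENVELOPE_COLUMNS, path)
    _check_duplicates(df, ["iso_code", "year", "group"], path)
    draws: dict[tuple, tuple[list[float], list[float]]] = {}
    if draws_path is not None:
        dd = pd.read_csv(draws_path, float_precision="round_trip")
        _require_columns(dd, ("iso_code", "year", "group", "draw", "deaths", "rate"), draws_path)
        for key, sub in dd.groupby(["iso_code", "year", "group"]):
            sub = sub.sort_values("draw")
            draws[key] = (sub["deaths"].tolist(), sub["rate"].tolist())
    out = []
    for _, r in df.iterrows():
        key = (r["iso_code"], r["year"], r["group"])
        d, rt = draws.get(key, ([], []))
        out.append(
            Envelope(
                iso_code=str(r["iso_code"]),
                year=int(r["year"]),
                group=AgeSexGroup(str(r["group"])),
                deaths=float(r["deaths"]),
                rate=float(r["rate"]),
                deaths_draws=tuple(d),
                rate_draws=tuple(rt),
            )
        )
    return out


def write_envelopes(
    envelopes: Sequence[Envelope],
    path: str | Path,
    draws_path: str | Path | None = None,
) -> None:
    pd.DataFrame(
        [
            {
                "iso_code": e.iso_code,
                "year": e.year,
                "group": e.group.value,
                "deaths": e.deaths,
                "rate": e.rate,
            }
            for e in envelopes
        ],
        columns=list(ENVELOPE_COLUMNS),
    ).to_csv(path, index=False)
    if draws_path is not None:
        rows = [
            {
                "iso_code": e.iso_code,
                "year": e.year,
                "group": e.group.value,
                "draw": k,
                "deaths": d,
                "rate": r,
            }
            for e in envelopes
            for k, (d, r) in enumerate(zip(e.deaths_draws, e.rate_draws))
        ]
        pd.DataFrame(
            rows, columns=["iso_code", "year", "group", "draw", "deaths", "rate"]
        ).to_csv(draws_path, index=False)


# ---------------------------------------------------------------- single causes

SINGLE_CAUSE_COLUMNS = (
    "cause", "iso_code", "year", "group", "deaths", "lower", "upper",
    "crisis_nature", "in_envelope", "ghe_max_fraction",
)


def read_single_causes(path: str | Path) -> list[SingleCauseSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SINGLE_CAUSE_COLUMNS, path)
    _check_duplicates(df, ["cause", "iso_code", "year", "group"], path)
    out = []
    for _, r in df.iterrows():
        nature = r["crisis_nature"]
        out.append(
            SingleCauseSeries(
                cause=str(r["cause"]),
                iso_code=str(r["iso_code"]),
                year=int(r["year"]),
                group=AgeSexGroup(str(r["group"])),
                deaths=float(r["deaths"]),
                ui95=(float(r["lower"]), float(r["upper"])),
                crisis_nature=None if pd.isna(nature) else str(nature),
                in_envelope=bool(r["in_envelope"]),
                ghe_max_fraction=float(r["ghe_max_fraction"]),
            )
        )
    return out


def write_single_causes(series: Sequence[SingleCauseSeries], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cause": s.cause,
                "iso_code": s.iso_code,
                "year": s.year,
                "group": s.group.value,
                "deaths": s.deaths,
                "lower": s.ui95[0],
                "upper": s.ui95[1],
                "crisis_nature": s.crisis_nature,
                "in_envelope": s.in_envelope,
                "ghe_max_fraction": s.ghe_max_fraction,
            }
            for s in series
        ],
        columns=list(SINGLE_CAUSE_COLUMNS),
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- countries

COUNTRY_COLUMNS = ("iso_code", "region", "category", "prob_death_5_19")


def read_countries(path: str | Path) -> list[CountryMeta]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COUNTRY_COLUMNS, path)
    _check_duplicates(df, ["iso_code"], path)
    return [
        CountryMeta(
            iso_code=str(r["iso_code"]),
            region=str(r["region"]),
            category=str(r["category"]),
            prob_death_5_19=float(r["prob_death_5_19"]),
        )
        for _, r in df.iterrows()
    ]


def write_countries(countries: Sequence[CountryMeta], path: str | Path) -> None:
    pd.DataFrame(
        [asdict(c) for c in countries], columns=list(COUNTRY_COLUMNS)
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- estimate cube

CUBE_COLUMNS = (
    "iso_code", "year", "group", "cause",
    "deaths", "deaths_lower", "deaths_upper",
    "rate", "rate_lower", "rate_upper",
    "fraction", "fraction_lower", "fraction_upper",
)


def write_cube(cube: pd.DataFrame, path: str | Path) -> None:
    _require_columns(cube, CUBE_COLUMNS, "estimate cube")
    cube.to_csv(path, index=False, columns=list(CUBE_COLUMNS))


def read_cube(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CUBE_COLUMNS, path)
    _check_duplicates(df, ["iso_code", "year", "group", "cause"], path)
    return df


# ---------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Structured run configuration (YAML/JSON on disk)."""

    seed: int = 0
    n_draws: int = 1000  # Monte Carlo draw count K
    lambda_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    n_folds: int = 10
    sigma_u: float = 0.07
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    crisis_targets: dict[str, str] = field(
        default_factory=lambda: {
            "collective_violence": "collective_violence",
            "natural_disaster": "natural_disasters",
            "epidemic": "measles",
        }
    )


def read_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    cfg = RunConfig()
    for key, value in (data or {}).items():
        if not hasattr(cfg, key):
            raise ValidationError(f"{path}: unknown configuration key {key!r}")
        if key == "lambda_grid":
            value = tuple(float(v) for v in value)
        setattr(cfg, key, value)
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["lambda_grid"] = list(data["lambda_grid"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
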