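"""Reading, validation and normalization of GBD-results-tool CSV exports.

The canonical in-memory representation of an epidemiological table
("EpiTable") is a :class:`pandas.DataFrame` in long format with one row per
(location, year, sex, age, measure, metric) and the fixed column order
:data:`EPI_COLUMNS`.  Rates are interpreted as per 100,000 population
throughout.  The GBD results tool exports carry verbose measure labels
("YLLs (Years of Life Lost)") and a ``val`` value column; this module maps
them onto short canonical names so every downstream stage can rely on one
vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataValidationError,
    DuplicateKeyError,
    MissingDataError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Canonical column order of an EpiTable.
EPI_COLUMNS = [
    "location",
    "location_level",
    "year",
    "sex",
    "age",
    "measure",
    "metric",
    "value",
    "lower",
    "upper",
]

#: Key columns whose combination must be unique.
KEY_COLUMNS = ["location", "year", "sex", "age", "measure", "metric"]

#: The six canonical burden measures.
MEASURES = ("incidence", "prevalence", "deaths", "YLLs", "YLDs", "DALYs")

LOCATION_LEVELS = ("country", "region", "global", "income_group", "sdi_quintile")

#: GHDx exports vary in label verbosity; this shipped mapping normalizes the
#: common variants.  Extend or override per-file via ``schema_map``.
MEASURE_ALIASES: Mapping[str, str] = {
    "incidence": "incidence",
    "prevalence": "prevalence",
    "deaths": "deaths",
    "death": "deaths",
    "ylls": "YLLs",
    "ylls (years of life lost)": "YLLs",
    "ylds": "YLDs",
    "ylds (years lived with disability)": "YLDs",
    "dalys": "DALYs",
    "dalys (disability-adjusted life years)": "DALYs",
}

METRIC_ALIASES: Mapping[str, str] = {
    "number": "number",
    "rate": "rate",
    "percent": "percent",
}

SEX_ALIASES: Mapping[str, str] = {
    "male": "male",
    "female": "female",
    "both": "both",
}


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights of a standard population.

    Weights must sum to 1 (tolerance 1e-9); they are used to collapse
    age-specific rates into a single age-standardized rate.
    """

    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"standard-population weights sum to {total!r}, expected 1.0"
            )
        for group, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise DataValidationError(
                    f"weight for age group {group!r} is {w!r}, outside [0, 1]"
                )


def _apply_aliases(series: pd.Series, aliases: Mapping[str, str]) -> pd.Series:
    lowered = series.astype(str).str.strip().str.lower()
    return lowered.map(aliases)


def read_gbd_csv(path, schema_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a GBD-results-tool CSV export into a validated EpiTable.

    Parameters
    ----------
    path
        CSV file with header.  Expected columns (possibly under different
        names, see ``schema_map``): measure, location, sex, age, metric,
        year, val/value, upper, lower.  A ``cause`` column is accepted and
        dropped; ``location_level`` is accepted and defaults to ``country``.
    schema_map
        Optional mapping from the file's column names to canonical ones,
        e.g. ``{"val": "value"}``.

    Rows whose measure or metric is not recognized are dropped with a
    logged warning count.  Duplicate keys raise; negative values raise.
    """
    raw = pd.read_csv(path)
    if schema_map:
        raw = raw.rename(columns=dict(schema_map))
    if "val" in raw.columns and "value" not in raw.columns:
        raw = raw.rename(columns={"val": "value"})

    required = ["measure", "location", "sex", "age", "metric", "year", "value"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    df = raw.copy()
    if "location_level" not in df.columns:
        df["location_level"] = "country"
    for col in ("lower", "upper"):
        if col not in df.columns:
            df[col] = np.nan

    df["measure"] = _apply_aliases(df["measure"], MEASURE_ALIASES)
    df["metric"] = _apply_aliases(df["metric"], METRIC_ALIASES)
    df["sex"] = _apply_aliases(df["sex"], SEX_ALIASES)

    unknown = df["measure"].isna() | df["metric"].isna() | df["sex"].isna()
    if unknown.any():
        logger.warning(
            "dropping %d rows with unrecognized measure/metric/sex labels",
            int(unknown.sum()),
        )
        df = df.loc[~unknown]

    df = df[EPI_COLUMNS].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    for col in ("value", "lower", "upper"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    validate_epi(df)
    return df


def validate_epi(table: pd.DataFrame) -> pd.DataFrame:
    """Check EpiTable invariants; return the table unchanged on success."""
    missing = [c for c in EPI_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"EpiTable missing columns: {missing}")

    negative = table.index[table["value"] < 0]
    if len(negative):
        raise DataValidationError(
            f"negative value at row index {int(negative[0])}"
        )
    has_bounds = table["lower"].notna() & table["upper"].notna()
    bad_bounds = table.index[
        has_bounds
        & ~(
            (table["lower"] <= table["value"] + 1e-12)
            & (table["value"] <= table["upper"] + 1e-12)
        )
    ]
    if len(bad_bounds):
        raise DataValidationError(
            f"bounds do not bracket value at row index {int(bad_bounds[0])}"
        )
    if table.duplicated(subset=KEY_COLUMNS).any():
        dup = table[table.duplicated(subset=KEY_COLUMNS, keep=False)]
        key = tuple(dup.iloc[0][KEY_COLUMNS])
        raise DuplicateKeyError(f"duplicate EpiTable key {key}")
    return table


def write_epi_csv(table: pd.DataFrame, path) -> None:
    """Write an EpiTable as canonical CSV (fixed column order, key-sorted).

    The canonical form is a fixed point: reading a canonical file and
    writing it again reproduces the bytes.
    """
    out = table[EPI_COLUMNS].sort_values(KEY_COLUMNS, kind="mergesort")
    out.to_csv(path, index=False)


def write_gbd_csv(table: pd.DataFrame, path, cause: str = "Orofacial clefts") -> None:
    """Write an EpiTable in the GBD results-tool dialect (``val`` column,
    verbose measure labels) so it can round-trip through :func:`read_gbd_csv`."""
    verbose = {
        "incidence": "Incidence",
        "prevalence": "Prevalence",
        "deaths": "Deaths",
        "YLLs": "YLLs (Years of Life Lost)",
        "YLDs": "YLDs (Years Lived with Disability)",
        "DALYs": "DALYs (Disability-Adjusted Life Years)",
    }
    out = table[EPI_COLUMNS].sort_values(KEY_COLUMNS, kind="mergesort").copy()
    out["measure"] = out["measure"].map(verbose)
    out["metric"] = out["metric"].str.capitalize()
    out["sex"] = out["sex"].str.capitalize()
    out["cause"] = cause
    out = out.rename(columns={"value": "val"})
    cols = [
        "measure", "location", "location_level", "sex", "age", "cause",
        "metric", "year", "val", "upper", "lower",
    ]
    out[cols].to_csv(path, index=False)


def filter_observations(
    table: pd.DataFrame,
    sexes: Iterable[str] | None = None,
    age_label: str | None = None,
    metric: str | None = None,
    years: tuple[int, int] | None = None,
    location_level: str | None = None,
) -> pd.DataFrame:
    """Subset an EpiTable; never fabricates rows, preserves key uniqueness.

    ``age_label`` entirely absent from the table raises, since that almost
    always means the caller asked for an age aggregation the extract does
    not carry.  An empty result for any other filter is allowed but logged.
    """
    out = table
    if age_label is not None:
        if age_label not in set(table["age"]):
            raise MissingDataError(f"age label {age_label!r} absent from table")
        out = out[out["age"] == age_label]
    if sexes is not None:
        out = out[out["sex"].isin(set(sexes))]
    if metric is not None:
        out = out[out["metric"] == metric]
    if years is not None:
        lo, hi = years
        out = out[(out["year"] >= lo) & (out["year"] <= hi)]
    if location_level is not None:
        out = out[out["location_level"] == location_level]
    if out.empty:
        logger.warning("filter_observations produced an empty table")
    return out.reset_index(drop=True)


def age_standardize(
    rates: Sequence[tuple[str, float]], std_pop: StandardPopulation
) -> float:
    """Collapse age-specific rates (per 100,000) into one standardized rate.

    Returns ``sum(weight_a * rate_a)`` over the supplied age groups; every
    supplied age group must have a weight.
    """
    total = 0.0
    for age_group, rate in rates:
        if age_group not in std_pop.weights:
            raise MissingDataError(
                f"age group {age_group!r} has no standard-population weight"
            )
        total += std_pop.weights[age_group] * float(rate)
    return total
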