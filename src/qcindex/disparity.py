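"""Gender disparity ratios, QCI quintiles, group summaries and changes.

The gender disparity ratio (GDR) is male QCI divided by female QCI per
location-year, banded into five categories; the band from 0.95 to 1.05 is
the "optimal" (parity) band.  Boundary convention, pinned: [0, 0.5),
[0.5, 0.95), [0.95, 1.05], (1.05, 1.5], (1.5, inf) — both 0.95 and 1.05
fall in the optimal band.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingDataError

logger = logging.getLogger(__name__)


class GDRBand(enum.Enum):
    """GDR bands; OPTIMAL is closed on both ends, lower bands close on the left."""

    B1 = "[0, 0.5)"
    B2 = "[0.5, 0.95)"
    OPTIMAL = "[0.95, 1.05]"
    B4 = "(1.05, 1.5]"
    B5 = "(1.5, inf)"


@dataclass(frozen=True)
class GroupingScheme:
    """Mapping from location to group label (World Bank income, SDI quintile, ...)."""

    mapping: Mapping[str, str]
    scheme_name: str = "custom"


def classify_band(gdr: float) -> GDRBand:
    """Assign a positive finite GDR to its band."""
    if not math.isfinite(gdr) or gdr <= 0:
        raise ValueError(f"GDR must be positive and finite, got {gdr!r}")
    if gdr < 0.5:
        return GDRBand.B1
    if gdr < 0.95:
        return GDRBand.B2
    if gdr <= 1.05:
        return GDRBand.OPTIMAL
    if gdr <= 1.5:
        return GDRBand.B4
    return GDRBand.B5


def compute_gdr(qci_scores: pd.DataFrame) -> pd.DataFrame:
    """Male/female QCI ratio per (location, year).

    Expects a scores frame with columns location, year, sex, qci.  Only
    location-years with both sexes scored appear in the output; a zero
    female QCI leaves the GDR undefined (NaN band, logged).
    """
    sexed = qci_scores[qci_scores["sex"].isin(["male", "female"])]
    wide = sexed.pivot_table(
        index=["location", "year"], columns="sex", values="qci", aggfunc="first"
    )
    if "male" not in wide.columns or "female" not in wide.columns:
        raise InsufficientDataError("need both male and female QCI rows")
    wide = wide.dropna(subset=["male", "female"]).reset_index()
    if wide.empty:
        raise InsufficientDataError("no location-years with both sexes scored")
    out = wide.rename(columns={"male": "qci_male", "female": "qci_female"})
    with np.errstate(divide="ignore", invalid="ignore"):
        gdr = out["qci_male"].to_numpy() / out["qci_female"].to_numpy()
    gdr = np.where(np.isfinite(gdr) & (gdr > 0), gdr, np.nan)
    n_undefined = int(np.isnan(gdr).sum())
    if n_undefined:
        logger.warning("GDR undefined for %d location-years (female QCI 0)", n_undefined)
    out["gdr"] = gdr
    out["band"] = [classify_band(g).name if np.isfinite(g) else None for g in gdr]
    return out[["location", "year", "qci_male", "qci_female", "gdr", "band"]]


def count_by_band(gdr_table: pd.DataFrame, year: int) -> dict[GDRBand, int]:
    """Number of locations per band in a year; partitions the defined GDRs."""
    sub = gdr_table[(gdr_table["year"] == year) & gdr_table["band"].notna()]
    if (gdr_table["year"] == year).sum() == 0:
        raise MissingDataError(f"year {year} absent from GDR table")
    counts = sub["band"].value_counts()
    return {GDRBand[name]: int(c) for name, c in counts.items()}


# Largest-remainder extras go to the extreme quintiles first.
_EXTRA_ORDER = (1, 5, 2, 4, 3)


def quintile_rank(
    qci_scores: pd.DataFrame, year: int, sex: str = "both"
) -> pd.Series:
    """Rank-based quintile (1 = lowest QCI, 5 = highest) per location.

    Locations are stably sorted by (QCI, location name) ascending and cut
    into five near-equal groups (sizes differ by at most one; extras are
    assigned to quintiles 1, 5, 2, 4, 3 in that order).
    """
    sub = qci_scores[
        (qci_scores["year"] == year)
        & (qci_scores["sex"] == sex)
        & qci_scores["qci"].notna()
    ]
    n = len(sub)
    if n < 5:
        raise InsufficientDataError(
            f"quintile_rank needs >= 5 locations, got {n} for year={year}, sex={sex}"
        )
    ordered = sub.sort_values(["qci", "location"], kind="mergesort")
    sizes = [n // 5] * 5
    for q in _EXTRA_ORDER[: n % 5]:
        sizes[q - 1] += 1
    labels = np.repeat(np.arange(1, 6), sizes)
    return pd.Series(labels, index=ordered["location"].to_numpy(), name="quintile")


def group_summary(
    qci_scores: pd.DataFrame,
    scheme: GroupingScheme,
    year: int,
    sex: str = "both",
) -> pd.DataFrame:
    """Summary QCI per group (World Bank income level, SDI quintile, ...).

    When the scored table carries a group-level observation (a row whose
    location equals the group label and whose location_level is not
    country), that QCI is used directly — GBD publishes aggregate rows and
    they are population-consistent.  Otherwise the group falls back to the
    unweighted mean of its member countries' QCIs, flagged in the ``mode``
    column.  Empty groups are omitted with a warning.
    """
    sub = qci_scores[
        (qci_scores["year"] == year) & (qci_scores["sex"] == sex) & qci_scores["qci"].notna()
    ]
    has_level = "location_level" in sub.columns
    rows = []
    for group in sorted(set(scheme.mapping.values())):
        direct = sub[sub["location"] == group]
        if has_level:
            direct = direct[direct["location_level"] != "country"]
        if len(direct):
            rows.append({"group": group, "qci": float(direct["qci"].iloc[0]), "mode": "group_row"})
            continue
        members = [loc for loc, g in scheme.mapping.items() if g == group]
        member_rows = sub[sub["location"].isin(members)]
        if member_rows.empty:
            logger.warning("group %r has no scored members in %d; omitted", group, year)
            continue
        rows.append(
            {"group": group, "qci": float(member_rows["qci"].mean()), "mode": "member_mean"}
        )
    return pd.DataFrame(rows, columns=["group", "qci", "mode"])


def change_between(value_a: float, value_b: float) -> float:
    """Signed change from year a to year b: ``value_b - value_a``.

    With (a, b) = (1990, 2019) this reproduces the sign convention of
    published change columns (a falling DALY rate gives a negative change).
    Missing endpoints propagate NaN.
    """
    if value_a is None or value_b is None:
        return float("nan")
    if not (math.isfinite(value_a) and math.isfinite(value_b)):
        return float("nan")
    return value_b - value_a


def change_table(
    values: pd.DataFrame, year_a: int = 1990, year_b: int = 2019, value_col: str = "qci"
) -> pd.DataFrame:
    """Per-location change ``value[year_b] - value[year_a]`` for one value column."""
    wide = values.pivot_table(
        index="location", columns="year", values=value_col, aggfunc="first"
    )
    for y in (year_a, year_b):
        if y not in wide.columns:
            raise MissingDataError(f"year {y} absent from table")
    out = wide[[year_a, year_b]].reset_index()
    out.columns = ["location", f"{value_col}_{year_a}", f"{value_col}_{year_b}"]
    out["change"] = out[f"{value_col}_{year_b}"] - out[f"{value_col}_{year_a}"]
    return out
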