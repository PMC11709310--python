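"""The four care-quality ratios computed per (location, year, sex).

For a condition like orofacial clefts the four ratios read off different
facets of care from routinely estimated burden measures:

* ``r_pi`` — prevalence / incidence: how long incident cases persist in the
  population (ambiguous on its own: longer survival or slower resolution).
* ``r_mi`` — deaths / incidence: case fatality proxy; lower is better care.
* ``r_dp`` — DALYs / prevalence: burden per prevalent case; lower is better.
* ``r_ly`` — YLLs / YLDs: fatal versus non-fatal burden; lower means deaths
  contribute less, i.e. better survival.

Division by zero and missing measures produce NaN and ``complete=False``;
no epsilon-padding is applied, so excluded observations stay auditable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MissingDataError

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["r_pi", "r_mi", "r_dp", "r_ly"]

_UNIT = ["location", "year", "sex"]


def compute_ratios(table: pd.DataFrame, reconstruct_dalys: bool = True) -> pd.DataFrame:
    """Compute the four quality-of-care ratios from an EpiTable.

    The table must already be filtered to a single metric and a single age
    label (e.g. age-standardized rates).  Output has one row per distinct
    (location, year, sex) unit with columns ``r_pi, r_mi, r_dp, r_ly`` and a
    ``complete`` flag that is True only when all four ratios are finite.

    DALYs missing for a unit are reconstructed as YLLs + YLDs (the GBD
    identity) when ``reconstruct_dalys`` is set; reconstruction is logged.

    Raises
    ------
    MissingDataError
        If no unit yields four finite ratios.
    """
    for col in ("metric", "age"):
        if table[col].nunique() > 1:
            raise MissingDataError(
                f"compute_ratios requires a single {col}; "
                f"found {sorted(table[col].unique())}"
            )

    wide = table.pivot_table(
        index=_UNIT + (["location_level"] if "location_level" in table.columns else []),
        columns="measure",
        values="value",
        aggfunc="first",
    ).reset_index()
    for m in ("incidence", "prevalence", "deaths", "YLLs", "YLDs", "DALYs"):
        if m not in wide.columns:
            wide[m] = np.nan

    if reconstruct_dalys:
        needs = wide["DALYs"].isna() & wide["YLLs"].notna() & wide["YLDs"].notna()
        if needs.any():
            logger.warning(
                "reconstructed DALYs = YLLs + YLDs for %d observation units",
                int(needs.sum()),
            )
            wide.loc[needs, "DALYs"] = wide.loc[needs, "YLLs"] + wide.loc[needs, "YLDs"]
        wide["dalys_reconstructed"] = needs
    else:
        wide["dalys_reconstructed"] = False

    def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num.to_numpy(float) / den.to_numpy(float)
        r[~np.isfinite(r)] = np.nan
        return pd.Series(r, index=num.index)

    out = wide[[c for c in wide.columns if c in _UNIT + ["location_level"]]].copy()
    out["r_pi"] = _ratio(wide["prevalence"], wide["incidence"])
    out["r_mi"] = _ratio(wide["deaths"], wide["incidence"])
    out["r_dp"] = _ratio(wide["DALYs"], wide["prevalence"])
    out["r_ly"] = _ratio(wide["YLLs"], wide["YLDs"])
    out["dalys_reconstructed"] = wide["dalys_reconstructed"]
    out["complete"] = out[RATIO_COLUMNS].notna().all(axis=1)

    if not out["complete"].any():
        raise MissingDataError("no usable observations: every unit has a missing ratio")
    n_dropped = int((~out["complete"]).sum())
    if n_dropped:
        logger.warning("%d observation units incomplete (zero denominator or missing measure)", n_dropped)
    return out.reset_index(drop=True)


def write_ratio_csv(ratios: pd.DataFrame, path) -> None:
    cols = _UNIT + RATIO_COLUMNS + ["complete"]
    ratios[cols].to_csv(path, index=False)
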