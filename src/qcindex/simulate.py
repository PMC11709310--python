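"""Synthetic GBD-shaped burden tables driven by a latent care-quality factor.

Each location carries a latent quality ``q`` in [0, 1] (1 = best care) that
drifts linearly over years and differs between sexes by a per-location
offset.  The six burden measures are built so that all four care-quality
ratios are monotone in ``q`` the way the index assumes:

* incidence rate ``I`` is a constant base rate (care does not change how
  many children are born with a cleft);
* mortality fraction ``m = m_max * (1 - q)``, deaths ``D = m * I``;
* prevalence ``P = I * L(q)`` with mean duration ``L = 20 + 40 q`` years —
  better care means affected people live longer, so prevalence rises;
* ``YLD = P * dw`` with disability weight ``dw = 0.05``;
* ``YLL = D * e(q)`` with residual life expectancy ``e = 60 - 20 q``
  (deaths under poor care happen earlier in life);
* ``DALY = YLL + YLD`` exactly (noise is applied to YLL and YLD first, the
  sum is taken after, so the GBD identity holds even in noisy tables).

Every measure receives independent multiplicative lognormal noise with
coefficient of variation ``noise_cv`` (unit mean).  Noise is drawn per
(location, year, measure) and shared between the sexes: sex-specific burden
estimates for one location-year come out of one shared estimation process,
so their errors are strongly correlated, and the latent sex offset is the
only systematic source of male-female asymmetry.  Both-sex rows are the
male/female average.  The latent truth is returned alongside the table so
recovery of ``q`` by the full pipeline can be tested.  Randomness comes
from a single ``numpy.random.default_rng`` (PCG64) stream per seed, drawn
in a fixed order, so generation is reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .io import EPI_COLUMNS

#: Structural constants of the generative model; arbitrary but fixed, chosen
#: so the ratios span realistic orders of magnitude for a congenital,
#: low-lethality condition.
DEFAULT_STRUCTURE = {
    "m_max": 0.2,         # mortality-to-incidence fraction at q = 0
    "duration_base": 20.0, # mean prevalent duration (years) at q = 0
    "duration_gain": 40.0, # additional duration at q = 1
    "disability_weight": 0.05,
    "yll_base": 60.0,      # residual life expectancy at death, q = 0
    "yll_gain": -20.0,     # change in residual life expectancy at q = 1
}


@dataclass
class SyntheticConfig:
    n_locations: int = 100
    years: tuple[int, int] = (1990, 2019)
    seed: int = 1
    quality_range: tuple[float, float] = (0.05, 0.75)
    sex_offset_sd: float = 0.05
    trend_per_year: float = 0.008
    base_incidence_rate: float = 10.0   # per 100,000
    noise_cv: float = 0.1
    structure: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE))

    def validate(self) -> None:
        problems = []
        if self.n_locations < 5:
            problems.append(f"n_locations={self.n_locations} (need >= 5)")
        if self.years[0] > self.years[1]:
            problems.append(f"years={self.years} (need start <= end)")
        if not (0 <= self.noise_cv < 1):
            problems.append(f"noise_cv={self.noise_cv} (need 0 <= cv < 1)")
        lo, hi = self.quality_range
        if not (0 <= lo < hi <= 1):
            problems.append(f"quality_range={self.quality_range} (need 0 <= lo < hi <= 1)")
        if self.sex_offset_sd < 0:
            problems.append(f"sex_offset_sd={self.sex_offset_sd} (need >= 0)")
        if self.base_incidence_rate <= 0:
            problems.append(f"base_incidence_rate={self.base_incidence_rate} (need > 0)")
        if problems:
            raise DataValidationError("invalid SyntheticConfig: " + "; ".join(problems))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an EpiTable of age-standardized rates plus its latent truth.

    Returns ``(epi, truth)``: the EpiTable covers every (location, year)
    for sexes male, female and both, six measures each, metric "rate", age
    "Age-standardized"; the truth table records the latent quality ``q``
    per (location, year, sex).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.structure
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n_loc, n_yr = config.n_locations, len(years)

    locations = np.array([f"Country_{i:03d}" for i in range(1, n_loc + 1)])
    lo, hi = config.quality_range
    q0 = rng.uniform(lo, hi, size=n_loc)
    sex_delta = rng.normal(0.0, config.sex_offset_sd, size=n_loc)

    # latent quality per (location, year, sex): shape (n_loc, n_yr, 2)
    drift = config.trend_per_year * (years - y0)
    base = q0[:, None] + drift[None, :]
    q_sex = np.stack(
        [base + sex_delta[:, None] / 2.0, base - sex_delta[:, None] / 2.0], axis=2
    )
    q_sex = np.clip(q_sex, 0.0, 1.0)

    I0 = np.full_like(q_sex, config.base_incidence_rate)
    D0 = s["m_max"] * (1.0 - q_sex) * I0
    P0 = I0 * (s["duration_base"] + s["duration_gain"] * q_sex)
    YLD0 = P0 * s["disability_weight"]
    YLL0 = D0 * (s["yll_base"] + s["yll_gain"] * q_sex)

    noisy = {}
    for name, clean in (("incidence", I0), ("deaths", D0), ("prevalence", P0),
                        ("YLLs", YLL0), ("YLDs", YLD0)):
        shared = _lognormal_noise(rng, config.noise_cv, (n_loc, n_yr, 1))
        noisy[name] = clean * shared  # broadcast: same draw for both sexes
    noisy["DALYs"] = noisy["YLLs"] + noisy["YLDs"]

    measures = ("incidence", "prevalence", "deaths", "YLLs", "YLDs", "DALYs")
    records = []
    truth_records = []
    for i, loc in enumerate(locations):
        for j, year in enumerate(years):
            per_sex = {
                "male": {m: noisy[m][i, j, 0] for m in measures},
                "female": {m: noisy[m][i, j, 1] for m in measures},
            }
            per_sex["both"] = {
                m: 0.5 * (per_sex["male"][m] + per_sex["female"][m]) for m in measures
            }
            q_by_sex = {
                "male": q_sex[i, j, 0],
                "female": q_sex[i, j, 1],
                "both": 0.5 * (q_sex[i, j, 0] + q_sex[i, j, 1]),
            }
            for sex in ("male", "female", "both"):
                truth_records.append(
                    {"location": loc, "year": int(year), "sex": sex, "q": q_by_sex[sex]}
                )
                for m in measures:
                    v = per_sex[sex][m]
                    records.append(
                        {
                            "location": loc,
                            "location_level": "country",
                            "year": int(year),
                            "sex": sex,
                            "age": "Age-standardized",
                            "measure": m,
                            "metric": "rate",
                            "value": v,
                            "lower": v * max(0.0, 1.0 - 1.96 * config.noise_cv),
                            "upper": v * (1.0 + 1.96 * config.noise_cv),
                        }
                    )
    epi = pd.DataFrame.from_records(records, columns=EPI_COLUMNS)
    truth = pd.DataFrame.from_records(truth_records, columns=["location", "year", "sex", "q"])
    return epi, truth


def inject_missingness(
    table: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Delete a uniform random fraction of measure cells (rows); deterministic per seed."""
    if not 0.0 <= fraction <= 1.0:
        raise DataValidationError(f"fraction={fraction} outside [0, 1]")
    if fraction == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    n_drop = int(round(fraction * len(table)))
    drop = rng.choice(len(table), size=n_drop, replace=False)
    return table.drop(table.index[drop]).reset_index(drop=True)
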