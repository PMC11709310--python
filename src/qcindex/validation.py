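"""External validation: correlation with a reference index and a
country-random-intercept regression of QCI on covariates.

The default mixed-model estimator is a transparent two-stage moment method:

1. within-country (demeaned) pooled OLS for the fixed slopes;
2. country intercepts from country means, with the between-country
   intercept variance estimated as the variance of those intercepts minus
   the expected sampling noise contribution.

It is exactly reproducible and dependency-light; ``method="reml"`` exposes
a full-likelihood fit (statsmodels MixedLM) behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError


@dataclass
class RandomInterceptResult:
    slopes: dict[str, float]          # fixed-effect coefficient per covariate
    intercept: float                  # grand fixed intercept
    country_intercepts: dict[str, float]
    sigma_u: float                    # between-country intercept sd
    sigma_e: float                    # residual sd
    n_countries: int
    n_obs: int
    method: str = "moment"


def correlate_with_reference(
    qci_scores: pd.DataFrame, panel: pd.DataFrame, sex: str = "both"
) -> tuple[float, int]:
    """Pearson correlation between QCI and an external reference index.

    Joins on (location, year); needs at least 3 overlapping pairs.
    Returns ``(r, n)``.
    """
    left = qci_scores[qci_scores["sex"] == sex] if "sex" in qci_scores.columns else qci_scores
    merged = left.merge(panel, on=["location", "year"], how="inner")
    merged = merged.dropna(subset=["qci", "reference_index"])
    n = len(merged)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 overlapping (location, year) pairs, got {n}")
    r, _ = stats.pearsonr(merged["qci"], merged["reference_index"])
    return float(r), n


def fit_random_intercept(
    qci_scores: pd.DataFrame,
    panel: pd.DataFrame,
    covariates: list[str] | None = None,
    sex: str = "both",
    method: str = "moment",
) -> RandomInterceptResult:
    """Random-intercept linear model of QCI on panel covariates.

    Requires >= 2 countries with >= 2 observations each.  Covariates that
    carry no within-country variation (e.g. identically zero) get slope 0;
    linear dependence among the remaining covariates raises, naming the
    collinear set.
    """
    left = qci_scores[qci_scores["sex"] == sex] if "sex" in qci_scores.columns else qci_scores
    data = left.merge(panel, on=["location", "year"], how="inner")
    if covariates is None:
        covariates = [
            c
            for c in panel.columns
            if c not in ("location", "year", "reference_index")
            and pd.api.types.is_numeric_dtype(panel[c])
        ]
    data = data.dropna(subset=["qci"] + covariates)
    counts = data.groupby("location").size()
    keep = counts[counts >= 2].index
    data = data[data["location"].isin(keep)]
    groups = data.groupby("location")
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 countries with >= 2 observations, got {len(groups)}"
        )

    if method == "reml":
        return _fit_reml(data, covariates)

    y = data["qci"].to_numpy(float)
    X = data[covariates].to_numpy(float)
    codes, uniques = pd.factorize(data["location"], sort=True)
    n_i = np.bincount(codes)
    ybar = np.bincount(codes, weights=y) / n_i
    y_w = y - ybar[codes]
    Xbar = np.vstack(
        [np.bincount(codes, weights=X[:, j]) / n_i for j in range(X.shape[1])]
    ).T
    X_w = X - Xbar[codes]

    # drop covariates with no within-country variation (slope 0 by convention)
    col_scale = np.sqrt((X_w**2).sum(axis=0))
    active = col_scale > 1e-12 * max(1.0, np.abs(X).max(initial=0.0))
    Xa = X_w[:, active]
    if Xa.shape[1]:
        rank = np.linalg.matrix_rank(Xa)
        if rank < Xa.shape[1]:
            names = [c for c, a in zip(covariates, active) if a]
            collinear = _collinear_set(Xa, names)
            raise DegenerateInputError(f"collinear covariates: {collinear}")
        beta_a, *_ = np.linalg.lstsq(Xa, y_w, rcond=None)
    else:
        beta_a = np.zeros(0)
    beta = np.zeros(X.shape[1])
    beta[active] = beta_a

    resid = y_w - X_w @ beta
    dof = max(1, len(y) - len(n_i) - int(active.sum()))
    sigma2_e = float(resid @ resid) / dof

    a_i = ybar - Xbar @ beta
    var_a = float(np.var(a_i, ddof=1)) if len(a_i) > 1 else 0.0
    sigma2_u = max(0.0, var_a - sigma2_e * float(np.mean(1.0 / n_i)))

    return RandomInterceptResult(
        slopes=dict(zip(covariates, beta.tolist())),
        intercept=float(a_i.mean()),
        country_intercepts=dict(zip(uniques.tolist(), a_i.tolist())),
        sigma_u=float(np.sqrt(sigma2_u)),
        sigma_e=float(np.sqrt(sigma2_e)),
        n_countries=len(n_i),
        n_obs=len(y),
        method="moment",
    )


def _fit_reml(data: pd.DataFrame, covariates: list[str]) -> RandomInterceptResult:
    import statsmodels.formula.api as smf

    d = data.rename(columns={c: f"x{i}" for i, c in enumerate(covariates)})
    rhs = " + ".join(f"x{i}" for i in range(len(covariates))) or "1"
    fit = smf.mixedlm(f"qci ~ {rhs}", d, groups=d["location"]).fit(reml=True)
    re = {k: float(v.iloc[0]) + float(fit.params["Intercept"]) for k, v in fit.random_effects.items()}
    return RandomInterceptResult(
        slopes={c: float(fit.params[f"x{i}"]) for i, c in enumerate(covariates)},
        intercept=float(fit.params["Intercept"]),
        country_intercepts=re,
        sigma_u=float(np.sqrt(fit.cov_re.iloc[0, 0])),
        sigma_e=float(np.sqrt(fit.scale)),
        n_countries=data["location"].nunique(),
        n_obs=len(data),
        method="reml",
    )


def _collinear_set(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy identification of a column subset causing rank deficiency."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            bad.append(names[j])
        else:
            kept.append(j)
    return bad
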