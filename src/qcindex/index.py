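"""Quality-of-Care Index: standardized ratios → PCA → oriented PC1 → 0–100.

The index is the first principal component of the four care-quality ratios,
computed on z-scored inputs (correlation-scale PCA), oriented so that larger
component scores mean *worse* care (anchored on the mortality-to-incidence
ratio, whose direction is unambiguous), and min-max rescaled so the pooled
worst observation scores 0 and the pooled best scores 100.

One single PCA is fitted over the full pool of observation units — all
locations, years and sex groups together — so scores are comparable across
years (a country's 1990 and 2019 values live on one scale) and across sexes
(male/female ratios are meaningful).  The fitted model, including the
min-max anchors, is a frozen :class:`PCAModel` that can re-score new
observations on the same scale (clamped to [0, 100] out of pool).

Conventions pinned for bit-reproducibility:

* population standard deviation (divide by n) in the z-scoring step;
* eigendecomposition of the 4x4 covariance of the standardized matrix;
* per-component deterministic sign: the largest-|loading| element of each
  column is made positive, before the semantic orientation step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, OrientationError
from .ratios import RATIO_COLUMNS

_ANCHOR = "r_mi"          # orientation anchor: higher mortality/incidence = worse care
_FALLBACK_ANCHOR = "r_dp"  # burden per prevalent case, same direction


@dataclass
class PCAModel:
    """Frozen PCA scoring model for the four care-quality ratios."""

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray            # 4x4, columns = components
    explained_variance: np.ndarray  # non-increasing eigenvalues
    orientation_sign: float = 1.0
    scale_min: float = field(default=np.nan)
    scale_max: float = field(default=np.nan)

    @property
    def pc1(self) -> np.ndarray:
        return self.loadings[:, 0]

    def to_dict(self) -> dict:
        return {
            "ratio_columns": RATIO_COLUMNS,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "orientation_sign": float(self.orientation_sign),
            "scale_min": float(self.scale_min),
            "scale_max": float(self.scale_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            loadings=np.asarray(d["loadings"], float),
            explained_variance=np.asarray(d["explained_variance"], float),
            orientation_sign=float(d["orientation_sign"]),
            scale_min=float(d["scale_min"]),
            scale_max=float(d["scale_max"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class QCIResult:
    """Fitted model plus per-observation scores.

    ``scores`` has one row per complete observation unit with columns
    location, year, sex, ``pc1_score`` (oriented, standardized space) and
    ``qci`` in [0, 100]; incomplete units keep NaN scores.
    """

    model: PCAModel
    scores: pd.DataFrame


def standardize(ratios: pd.DataFrame):
    """Z-score the four ratio columns of the complete rows.

    Returns ``(Z, means, sds, complete_index)`` where ``Z`` is an
    (n_complete x 4) ndarray with column means 0 and population sds 1.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 complete rows.
    DegenerateInputError
        A ratio column is constant (sd == 0), named in the message.
    """
    complete = ratios[ratios["complete"]] if "complete" in ratios.columns else ratios
    X = complete[RATIO_COLUMNS].to_numpy(float)
    if X.shape[0] < 2:
        raise InsufficientDataError(
            f"standardize needs >= 2 complete rows, got {X.shape[0]}"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    for name, sd in zip(RATIO_COLUMNS, sds):
        if sd == 0.0:
            raise DegenerateInputError(f"ratio column {name!r} is constant")
    Z = (X - means) / sds
    return Z, means, sds, complete.index


def fit_pca(Z: np.ndarray) -> PCAModel:
    """Eigendecompose the 4x4 covariance of a standardized matrix.

    Components are ordered by explained variance (non-increasing) and each
    loading column is signed so its largest-magnitude element is positive.
    """
    Z = np.asarray(Z, float)
    if not np.all(np.isfinite(Z)):
        raise DegenerateInputError("standardized matrix contains non-finite entries")
    n, p = Z.shape
    if n < p:
        raise InsufficientDataError(f"need rows >= columns, got {n} x {p}")
    cov = Z.T @ Z / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(p):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAModel(
        means=np.full(p, np.nan),
        sds=np.full(p, np.nan),
        loadings=eigvecs,
        explained_variance=eigvals,
    )


def orient_pc1(model: PCAModel, Z: np.ndarray) -> PCAModel:
    """Fix the sign of PC1 so larger oriented scores mean worse care.

    The oriented score must correlate positively with the standardized
    mortality-to-incidence column; if that correlation is exactly zero the
    DALYs-to-prevalence column is used instead.
    """
    Z = np.asarray(Z, float)
    score = Z @ model.pc1
    for anchor in (_ANCHOR, _FALLBACK_ANCHOR):
        col = Z[:, RATIO_COLUMNS.index(anchor)]
        cov = float(np.mean((score - score.mean()) * (col - col.mean())))
        if cov != 0.0:
            model.orientation_sign = 1.0 if cov > 0 else -1.0
            return model
    raise OrientationError(
        "PC1 is uncorrelated with both orientation anchors (r_mi, r_dp)"
    )


def score_qci(
    model: PCAModel, ratios: pd.DataFrame, rescale_pool: str = "provided"
) -> QCIResult:
    """Score observations with a fitted, oriented model.

    ``pc1_score = orientation_sign * (z-row . pc1 loadings)``;
    ``qci = 100 * (scale_max - pc1_score) / (scale_max - scale_min)``.

    With ``rescale_pool="fit_pool"`` the min-max anchors are (re)frozen from
    the scored rows themselves, so the pooled worst row gets 0 and the best
    100.  With ``"provided"`` the model's stored anchors are used and
    out-of-pool scores are clamped to [0, 100].  Incomplete rows propagate
    NaN, they are never silently dropped.
    """
    id_cols = [c for c in ("location", "location_level", "year", "sex") if c in ratios.columns]
    out = ratios[id_cols].copy()
    X = ratios[RATIO_COLUMNS].to_numpy(float)
    Z = (X - model.means) / model.sds
    raw = Z @ model.pc1
    score = model.orientation_sign * raw
    complete = (
        ratios["complete"].to_numpy(bool)
        if "complete" in ratios.columns
        else np.isfinite(score)
    )
    score = np.where(complete, score, np.nan)

    if rescale_pool == "fit_pool":
        model.scale_min = float(np.nanmin(score))
        model.scale_max = float(np.nanmax(score))
    if not model.scale_min < model.scale_max:
        raise DegenerateInputError(
            f"degenerate rescale anchors: min={model.scale_min}, max={model.scale_max}"
        )
    qci = 100.0 * (model.scale_max - score) / (model.scale_max - model.scale_min)
    qci = np.clip(qci, 0.0, 100.0)

    out["pc1_score"] = score
    out["qci"] = qci
    return QCIResult(model=model, scores=out)


def compute_qci(ratios: pd.DataFrame) -> QCIResult:
    """Full index construction on a pooled ratio table.

    Standardizes the complete rows, fits and orients the PCA, freezes the
    min-max anchors on the pool, and scores every input row (incomplete
    rows keep NaN).
    """
    Z, means, sds, _ = standardize(ratios)
    model = fit_pca(Z)
    model.means = means
    model.sds = sds
    model = orient_pc1(model, Z)
    return score_qci(model, ratios, rescale_pool="fit_pool")
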