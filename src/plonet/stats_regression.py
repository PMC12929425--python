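"""Univariate regressions of delta indices on predictors, and a residual
spatial-autocorrelation test.

Each predictor is regressed against each delta-standardized index by ordinary
least squares on the networks where that predictor is available, so the
sample size varies between predictors.  Alongside the slope the fit reports
the Pearson correlation r, the regression t statistic
``t = r * sqrt(n-2) / sqrt(1-r^2)`` and its two-sided p-value; the t
statistic doubles as the standardized effect ("beta") column of the summary
table.

Precipitation covariates are log transformed as ``ln(x + 1)`` (precipitation
of the warmest quarter can be zero) and network size as
``ln(n_plants + n_pollinators)``.

Spatial autocorrelation of model residuals is tested with Moran's I under
row-standardized inverse great-circle-distance weights, with the usual
normal approximation (expected value -1/(n-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .network_io import InteractionNetwork, NetworkCovariates
from .traits_and_filters import TraitFrequencies

EARTH_RADIUS_KM = 6371.0

#: analysis-table columns, in the documented output order
RECORD_COLUMNS = [
    "network_id",
    "delta_connectance", "delta_nestedness", "delta_modularity", "delta_robustness",
    "pct_pp", "pct_sc", "pct_restrictive",
    "bio4", "bio10", "log_bio15", "log_bio18",
    "log_network_size", "latitude", "longitude",
]

DELTA_INDICES = ["delta_connectance", "delta_nestedness",
                 "delta_modularity", "delta_robustness"]

PREDICTORS = ["pct_pp", "pct_sc", "pct_restrictive",
              "bio4", "bio10", "log_bio15", "log_bio18", "log_network_size"]


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    response: str
    n: int
    r: float
    t_stat: float
    p: float
    slope: float
    intercept: float


def make_record(network: InteractionNetwork,
                freqs: TraitFrequencies,
                covariates: NetworkCovariates,
                deltas: Mapping[str, float]) -> dict:
    """One analysis row for a network (deltas keyed by index name)."""
    row = covariates.get(network.network_id)
    if row is None:
        raise KeyError(f"{network.network_id}: no covariate row")
    return {
        "network_id": network.network_id,
        "delta_connectance": deltas["connectance"],
        "delta_nestedness": deltas["nestedness"],
        "delta_modularity": deltas["modularity"],
        "delta_robustness": deltas["robustness"],
        "pct_pp": np.nan if freqs.pct_pp is None else freqs.pct_pp,
        "pct_sc": np.nan if freqs.pct_sc is None else freqs.pct_sc,
        "pct_restrictive": (np.nan if freqs.pct_restrictive is None
                            else freqs.pct_restrictive),
        "bio4": row["bio4"],
        "bio10": row["bio10"],
        "log_bio15": math.log(row["bio15"] + 1.0),
        "log_bio18": math.log(row["bio18"] + 1.0),
        "log_network_size": math.log(network.size),
        "latitude": row["latitude"],
        "longitude": row["longitude"],
    }


def records_frame(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=RECORD_COLUMNS)


def univariate_fit(records: pd.DataFrame, predictor: str,
                   response: str) -> RegressionResult:
    """OLS of one delta index on one predictor, on its complete cases."""
    sub = records[[predictor, response]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"{response}~{predictor}: fewer than 3 complete cases")
    x = sub[predictor].to_numpy(float)
    y = sub[response].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"{response}~{predictor}: zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        predictor=predictor, response=response, n=n, r=r,
        t_stat=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
    )


def regression_table(records: pd.DataFrame,
                     predictors: Sequence[str] = tuple(PREDICTORS),
                     responses: Sequence[str] = tuple(DELTA_INDICES)) -> pd.DataFrame:
    """Summary matrix of (r, t, p, n) for every predictor x response pair."""
    rows = []
    for pred in predictors:
        for resp in responses:
            res = univariate_fit(records, pred, resp)
            rows.append({"predictor": pred, "response": resp, "n": res.n,
                         "r": res.r, "t": res.t_stat, "p": res.p,
                         "slope": res.slope, "intercept": res.intercept})
    return pd.DataFrame(rows)


def t_from_r(r: float, n: int) -> float:
    """Regression t statistic implied by a Pearson correlation at sample size n."""
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


# ---------------------------------------------------------------------------
# Moran's I


def _great_circle_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances in km."""
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(residuals: Sequence[float],
             coordinates: Sequence[tuple[float, float]],
             weight_scheme: str = "inverse_distance") -> tuple[float, float, float]:
    """Moran's I of residuals with row-standardized inverse-distance weights.

    Coordinates are (latitude, longitude) pairs in degrees.  Returns
    (I, expected I, two-sided normal-approximation p).  Pairs at identical
    locations get the largest finite inverse-distance weight.
    """
    if weight_scheme != "inverse_distance":
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 points")
    if np.ptp(z) == 0:
        raise ValueError("constant residuals: Moran's I undefined (zero variance)")
    lat, lon = coords[:, 0], coords[:, 1]
    d = _great_circle_km(lat, lon)
    np.fill_diagonal(d, np.inf)
    if not np.isfinite(d).any() or np.all(d == 0):
        raise ValueError("all points at the same location")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    finite = w[np.isfinite(w)]
    if np.isinf(w).any():  # coincident (but not all-identical) points
        w[np.isinf(w)] = finite.max() if finite.size else 1.0
    w = w / w.sum(axis=1, keepdims=True)  # row standardization

    z = z - z.mean()
    s0 = w.sum()
    i_obs = (n / s0) * float(z @ w @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = ((n * n * s1 - n * s2 + 3 * s0 * s0)
           / (s0 * s0 * (n * n - 1))) - e_i * e_i
    zscore = (i_obs - e_i) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return float(i_obs), float(e_i), float(p)
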