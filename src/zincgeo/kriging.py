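"""Ordinary kriging on great-circle distances.

Prediction at an unsampled location is the best linear unbiased combination
of the data: weights solve the bordered semivariance system with the
unbiasedness constraint (weights sum to one), and the minimised expected
squared error is the kriging variance sigma2_K = sum_i lambda_i
gamma(h_i0) + psi with psi the Lagrange multiplier.  The exact-interpolation
convention gamma(0) = 0 is used, so a prediction at a data site returns the
datum with zero variance and leave-one-out cross-validation is well posed.

Model validity is screened by the median standardized squared prediction
error (SSPE): each leave-one-out squared error divided by its kriging
variance is ~ chi-square with 1 df under a valid model, whose median is
0.455; a median outside (0.355, 0.575) flags a questionable variogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve, solve
from scipy.stats import norm

from .geostats import VariogramModel, pairwise_great_circle, great_circle_distance

__all__ = [
    "KrigingResult",
    "CrossValidationResult",
    "ModelSelection",
    "SSPE_EXPECTED",
    "SSPE_VALID_INTERVAL",
    "krige",
    "krige_many",
    "cross_validate",
    "select_model",
    "predict_grid",
    "exceedance_probability",
    "probability_phrase",
    "PHRASE_BINS",
]

#: Median of a chi-square(1) variable: the expected median SSPE under a
#: valid variogram model.
SSPE_EXPECTED = 0.455
#: Published 95% acceptance interval for the median SSPE at survey scale.
SSPE_VALID_INTERVAL = (0.355, 0.575)

#: IPCC calibrated-likelihood bins for the probability of an event, as
#: (lower, upper, phrase); membership is [lower, upper) except the last.
PHRASE_BINS = [
    (0.00, 0.01, "exceptionally unlikely"),
    (0.01, 0.10, "very unlikely"),
    (0.10, 0.33, "unlikely"),
    (0.33, 0.66, "about as likely as not"),
    (0.66, 0.90, "likely"),
    (0.90, 0.99, "very likely"),
    (0.99, 1.00 + 1e-12, "virtually certain"),
]


@dataclass(frozen=True)
class KrigingResult:
    lon: float
    lat: float
    prediction: float
    variance: float
    psi: float  # Lagrange multiplier, diagnostic only


@dataclass(frozen=True)
class CrossValidationResult:
    errors: np.ndarray            # z_i - Z_hat_(-i)
    theta: np.ndarray             # standardized squared errors e^2/sigma2_K
    median_sspe: float
    valid_interval: tuple[float, float] = SSPE_VALID_INTERVAL
    is_valid: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"error": self.errors, "theta": self.theta})


@dataclass(frozen=True)
class ModelSelection:
    chosen_estimator: str
    model: VariogramModel
    median_sspe: float
    is_valid: bool
    rationale: str
    all_sspe: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chosen_estimator": self.chosen_estimator,
            "model": {"c0": self.model.c0, "c1": self.model.c1, "a": self.model.a},
            "median_sspe": self.median_sspe,
            "is_valid": self.is_valid,
            "rationale": self.rationale,
            "all_sspe": self.all_sspe,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _check_no_duplicates(lon, lat) -> None:
    d = pairwise_great_circle(lon, lat)
    iu = np.triu_indices(len(lon), k=1)
    if len(lon) > 1 and np.min(d[iu]) <= 0.0:
        raise ValueError(
            "duplicate data locations make the kriging system singular; "
            "aggregate or deduplicate before kriging (no silent jitter)"
        )


def _bordered_matrix(lon, lat, model: VariogramModel) -> np.ndarray:
    n = len(lon)
    gam = np.asarray(model(pairwise_great_circle(lon, lat)))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gam
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    return A


def krige(
    target: tuple[float, float],
    aggregates: pd.DataFrame,
    model: VariogramModel,
    neighborhood: int | None = None,
) -> KrigingResult:
    """Ordinary kriging prediction at one (lon, lat) target.

    Global by default; ``neighborhood`` restricts the system to the k
    nearest data points.  A target coincident with a datum returns that
    datum with zero variance (exact interpolation).
    """
    lon = aggregates["mean_lon"].to_numpy(dtype=float)
    lat = aggregates["mean_lat"].to_numpy(dtype=float)
    z = aggregates["mean_zn"].to_numpy(dtype=float)
    tlon, tlat = float(target[0]), float(target[1])
    if not (-90.0 <= tlat <= 90.0):
        raise ValueError("invalid target coordinates")
    if len(z) < 1:
        raise ValueError("need at least one data point")

    h0 = np.asarray(great_circle_distance(lon, lat, tlon, tlat), dtype=float)
    h0 = np.atleast_1d(h0)
    if neighborhood is not None and neighborhood < len(z):
        keep = np.argsort(h0)[:neighborhood]
        lon, lat, z, h0 = lon[keep], lat[keep], z[keep], h0[keep]

    hit = np.flatnonzero(h0 == 0.0)
    if hit.size:
        return KrigingResult(tlon, tlat, float(z[hit[0]]), 0.0, 0.0)
    if len(z) == 1:
        # one-point system: lambda = 1, psi = gamma(h0); sigma2 = 2 gamma(h0)
        g = float(model(h0[0]))
        return KrigingResult(tlon, tlat, float(z[0]), 2.0 * g, g)

    _check_no_duplicates(lon, lat)
    A = _bordered_matrix(lon, lat, model)
    b = np.append(np.asarray(model(h0)), 1.0)
    try:
        sol = solve(A, b, assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system") from exc
    lam, psi = sol[:-1], sol[-1]
    pred = float(lam @ z)
    var = float(lam @ b[:-1] + psi)
    return KrigingResult(tlon, tlat, pred, max(var, 0.0), float(psi))


def krige_many(
    targets: np.ndarray,
    aggregates: pd.DataFrame,
    model: VariogramModel,
) -> pd.DataFrame:
    """Global kriging at many targets, factorising the system once.

    ``targets`` is an (m, 2) array of (lon, lat).  Returns a DataFrame with
    lon, lat, prediction, variance.
    """
    lon = aggregates["mean_lon"].to_numpy(dtype=float)
    lat = aggregates["mean_lat"].to_numpy(dtype=float)
    z = aggregates["mean_zn"].to_numpy(dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 data points")
    _check_no_duplicates(lon, lat)
    targets = np.asarray(targets, dtype=float)

    A = _bordered_matrix(lon, lat, model)
    piv = lu_factor(A)
    h0 = np.asarray(
        great_circle_distance(lon[:, None], lat[:, None],
                              targets[None, :, 0], targets[None, :, 1])
    )  # (n, m)
    B = np.vstack([np.asarray(model(h0)), np.ones(targets.shape[0])])
    S = lu_solve(piv, B)
    lam, psi = S[:-1, :], S[-1, :]

    pred = lam.T @ z
    var = np.einsum("ij,ij->j", lam, B[:-1, :]) + psi
    # exact interpolation at coincident nodes
    coincident = h0 == 0.0
    for jm in np.flatnonzero(coincident.any(axis=0)):
        i = np.flatnonzero(coincident[:, jm])[0]
        pred[jm], var[jm] = z[i], 0.0
    return pd.DataFrame(
        {
            "lon": targets[:, 0],
            "lat": targets[:, 1],
            "prediction": pred,
            "variance": np.maximum(var, 0.0),
        }
    )


def cross_validate(
    aggregates: pd.DataFrame, model: VariogramModel
) -> CrossValidationResult:
    """Leave-one-out ordinary kriging cross-validation.

    Each site is removed in turn and predicted from the rest with the given
    model; the squared error standardized by the kriging variance gives the
    SSPE, and the model is flagged valid iff the median SSPE lies in the
    published acceptance interval.
    """
    n = len(aggregates)
    if n < 10:
        raise ValueError("need at least 10 sites for a meaningful median SSPE")
    lon = aggregates["mean_lon"].to_numpy(dtype=float)
    lat = aggregates["mean_lat"].to_numpy(dtype=float)
    z = aggregates["mean_zn"].to_numpy(dtype=float)
    _check_no_duplicates(lon, lat)

    gam = np.asarray(model(pairwise_great_circle(lon, lat)))
    errors = np.empty(n)
    theta = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = n - 1
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = gam[np.ix_(keep, keep)]
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        A[m, m] = 0.0
        b = np.append(gam[keep, i], 1.0)
        sol = solve(A, b, assume_a="sym")
        lam, psi = sol[:-1], sol[-1]
        pred = lam @ z[keep]
        var = lam @ b[:-1] + psi
        if var <= 0.0:
            raise ValueError(
                f"non-positive kriging variance at site {i}; model or "
                "geometry is degenerate"
            )
        errors[i] = z[i] - pred
        theta[i] = errors[i] ** 2 / var
    med = float(np.median(theta))
    lo, hi = SSPE_VALID_INTERVAL
    return CrossValidationResult(
        errors=errors, theta=theta, median_sspe=med, is_valid=bool(lo < med < hi)
    )


def select_model(
    fits: dict[str, VariogramModel], aggregates: pd.DataFrame
) -> ModelSelection:
    """Pick a variogram model by the cross-validation SSPE criterion.

    The Matheron estimator is the most statistically efficient, so its fit
    is accepted outright when its median SSPE falls in the validity
    interval; otherwise the robust-estimator fits are cross-validated too
    and the model with median SSPE closest to 0.455 wins.  If nothing is
    valid the closest model is returned flagged invalid.
    """
    if "matheron" not in fits:
        raise ValueError("the Matheron fit is required for model selection")
    all_sspe: dict[str, float] = {}
    cv = cross_validate(aggregates, fits["matheron"])
    all_sspe["matheron"] = cv.median_sspe
    if cv.is_valid:
        return ModelSelection(
            chosen_estimator="matheron",
            model=fits["matheron"],
            median_sspe=cv.median_sspe,
            is_valid=True,
            rationale=(
                f"Matheron median SSPE {cv.median_sspe:.3f} within "
                f"{SSPE_VALID_INTERVAL}; robust alternatives not considered"
            ),
            all_sspe=all_sspe,
        )
    for name, model in fits.items():
        if name == "matheron":
            continue
        all_sspe[name] = cross_validate(aggregates, model).median_sspe
    best = min(all_sspe, key=lambda k: abs(all_sspe[k] - SSPE_EXPECTED))
    lo, hi = SSPE_VALID_INTERVAL
    valid = lo < all_sspe[best] < hi
    return ModelSelection(
        chosen_estimator=best,
        model=fits[best],
        median_sspe=all_sspe[best],
        is_valid=valid,
        rationale=(
            f"Matheron median SSPE {all_sspe['matheron']:.3f} outside "
            f"{SSPE_VALID_INTERVAL}; {best} closest to {SSPE_EXPECTED} "
            + ("" if valid else "(no candidate valid)")
        ),
        all_sspe=all_sspe,
    )


def predict_grid(
    aggregates: pd.DataFrame,
    model: VariogramModel,
    lon_range: tuple[float, float],
    lat_range: tuple[float, float],
    resolution_deg: float = 0.1,
    node_cap: int = 1_000_000,
) -> pd.DataFrame:
    """Kriging predictions and variances on a regular lon/lat grid.

    Any outliers withheld during variogram estimation should already have
    been reinstated in ``aggregates``.  Refuses grids above ``node_cap``
    nodes with guidance to coarsen the resolution.
    """
    lons = np.arange(lon_range[0], lon_range[1] + resolution_deg / 2, resolution_deg)
    lats = np.arange(lat_range[0], lat_range[1] + resolution_deg / 2, resolution_deg)
    n_nodes = len(lons) * len(lats)
    if n_nodes > node_cap:
        raise ValueError(
            f"grid of {n_nodes} nodes exceeds the cap of {node_cap}; "
            "coarsen resolution_deg or raise node_cap"
        )
    gg = np.meshgrid(lons, lats)
    targets = np.column_stack([gg[0].ravel(), gg[1].ravel()])
    return krige_many(targets, aggregates, model)


def probability_phrase(p: float) -> str:
    """IPCC calibrated-likelihood phrase for a probability in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    for lo, hi, phrase in PHRASE_BINS:
        if lo <= p < hi:
            return phrase
    return PHRASE_BINS[-1][2]


def exceedance_probability(
    prediction, variance, threshold: float = 70.0
) -> pd.DataFrame:
    """Probability that the true value falls below ``threshold``.

    Under the Gaussian prediction distribution,
    ``p = Phi((threshold - prediction) / sigma_K)``; a degenerate zero
    variance resolves to 0 or 1 by direct comparison.  Returns a DataFrame
    with ``p_below`` and the calibrated ``phrase``.
    """
    pred = np.atleast_1d(np.asarray(prediction, dtype=float))
    var = np.atleast_1d(np.asarray(variance, dtype=float))
    if np.any(var < -1e-8):
        raise ValueError("negative kriging variance beyond tolerance")
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = norm.cdf((threshold - pred) / sd)
    p = np.where(sd == 0.0, (pred < threshold).astype(float), p)
    return pd.DataFrame(
        {"p_below": p, "phrase": [probability_phrase(x) for x in p]}
    )
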