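"""Variography on the sphere.

Enumeration-area (EA) aggregation, great-circle lag computation, Tukey
outlier screening, empirical variogram estimation (Matheron, Cressie-Hawkins
and Dowd estimators, isotropic or by bearing sector) and weighted
least-squares fitting of the exponential model

    gamma(h) = c0 + c1 * (1 - exp(-h / a)),   h > 0,

the family that remains positive-definite when lags are great-circle
distances.  ``c0`` is the nugget, ``c1`` the spatially correlated (partial
sill) variance and ``a`` the distance parameter; spatial correlation is
practically exhausted at an effective range of about ``3 a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: Mean Earth radius (IUGG), km, used for all spherical distance work.
EARTH_RADIUS_KM = 6371.0088

VALID_ESTIMATORS = ("matheron", "cressie_hawkins", "dowd")

__all__ = [
    "EARTH_RADIUS_KM",
    "VALID_ESTIMATORS",
    "VariogramEstimate",
    "VariogramModel",
    "aggregate_by_ea",
    "bearing",
    "estimate_variogram",
    "exponential_semivariance",
    "fit_exponential_wls",
    "great_circle_distance",
    "make_lag_bins",
    "pairwise_great_circle",
    "tukey_outliers",
]


# ---------------------------------------------------------------------------
# distances and bearings
# ---------------------------------------------------------------------------

def _check_coords(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(lon < -180.0) or np.any(lon >= 360.0):
        raise ValueError("longitude outside [-180, 360)")


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a spherical Earth (haversine).

    Accepts scalars or broadcastable arrays of decimal degrees.  Symmetric,
    non-negative and zero only for coincident points.
    """
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    s = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))
    return d if np.ndim(d) else float(d)


def pairwise_great_circle(lon, lat) -> np.ndarray:
    """Full symmetric matrix of great-circle distances (km) among points."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return np.asarray(
        great_circle_distance(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    )


def bearing(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Final bearing, degrees clockwise from north in [0, 360).

    The bearing of the great-circle path from point 1 as it arrives at
    point 2 (the ``finalBearing`` convention), used only to assign pairs to
    direction sectors.  Undefined for coincident points.
    """
    d = great_circle_distance(lon1, lat1, lon2, lat2)
    if np.any(np.asarray(d) == 0.0):
        raise ValueError("bearing undefined for coincident points")
    # final bearing at p2 = reverse of the initial bearing of the path p2->p1
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat2, lon2, lat1, lon1))
    dlam = l2 - l1
    theta = np.arctan2(
        np.sin(dlam) * np.cos(p2),
        np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam),
    )
    out = (np.degrees(theta) + 180.0) % 360.0
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# EA aggregation and outlier screening
# ---------------------------------------------------------------------------

def aggregate_by_ea(
    records: pd.DataFrame,
    value_col: str = "zn_adjusted",
    sanity_radius_km: float = 25.0,
) -> pd.DataFrame:
    """Average a biomarker and coordinates within each enumeration area.

    Returns one row per EA with columns ``ea_id``, ``mean_zn``, ``mean_lon``,
    ``mean_lat`` and ``n_records``.  The mean is unweighted: the EA is the
    spatial support unit and design weights play no role in variography.
    A warning is issued for EAs whose member coordinates are spread wider
    than ``sanity_radius_km``.
    """
    needed = {"ea_id", "lon", "lat", value_col}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records lack required columns: {sorted(missing)}")
    ok = records.dropna(subset=["lon", "lat", value_col])
    if ok.empty:
        raise ValueError("no records with coordinates and values to aggregate")
    agg = (
        ok.groupby("ea_id", sort=True)
        .agg(
            mean_zn=(value_col, "mean"),
            mean_lon=("lon", "mean"),
            mean_lat=("lat", "mean"),
            n_records=(value_col, "size"),
        )
        .reset_index()
    )
    for ea, grp in ok.groupby("ea_id", sort=False):
        if len(grp) > 1:
            d = great_circle_distance(
                grp["lon"].to_numpy()[:, None], grp["lat"].to_numpy()[:, None],
                grp["lon"].to_numpy()[None, :], grp["lat"].to_numpy()[None, :],
            )
            if np.max(d) > sanity_radius_km:
                warnings.warn(
                    f"EA {ea!r}: coordinate spread {np.max(d):.1f} km exceeds "
                    f"{sanity_radius_km} km sanity radius",
                    stacklevel=2,
                )
    return agg


def tukey_outliers(values, k: float = 3.0) -> tuple[np.ndarray, tuple[float, float]]:
    """Flag probable outliers beyond Tukey's outer fences.

    Fences sit at ``Q1 - k*IQR`` and ``Q3 + k*IQR`` (``k=3`` gives the outer
    fences); values strictly outside are flagged.  Returns ``(mask, fences)``.
    Flagged values should be withheld from variogram estimation but restored
    for kriging prediction.  A degenerate IQR of zero flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for fence estimation")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    if iqr == 0.0:
        warnings.warn("IQR is zero; no finite outlier fences", stacklevel=2)
        return np.zeros(x.shape, dtype=bool), (-np.inf, np.inf)
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (x < lo) | (x > hi), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# empirical variograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariogramEstimate:
    """Binned semivariance estimates from one estimator.

    ``bins`` has columns lower/upper/mid (km), n_pairs and gamma; bins with
    no pairs carry ``gamma = NaN``.  ``sector`` is the bearing-sector centre
    in degrees for directional estimates, or ``None`` for isotropic ones.
    """

    estimator: str
    bins: pd.DataFrame
    sector: float | None = None

    @property
    def nonempty(self) -> pd.DataFrame:
        return self.bins[self.bins["n_pairs"] > 0].reset_index(drop=True)


@dataclass(frozen=True)
class VariogramModel:
    """Exponential variogram parameters.

    nugget ``c0`` and partial sill ``c1`` in squared concentration units,
    distance parameter ``a`` in km.  ``effective_range`` (~3a) is where the
    correlation has essentially decayed.
    """

    c0: float
    c1: float
    a: float
    converged: bool = True
    objective: float = float("nan")
    estimator: str | None = None

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.c1 < 0 or self.a <= 0:
            raise ValueError("require c0 >= 0, c1 >= 0, a > 0")

    @property
    def sill(self) -> float:
        return self.c0 + self.c1

    @property
    def effective_range(self) -> float:
        return 3.0 * self.a

    @property
    def spatially_dependent_fraction(self) -> float:
        """c1 / (c0 + c1): share of the sill that is spatially correlated."""
        return self.c1 / self.sill if self.sill > 0 else 0.0

    def __call__(self, h) -> np.ndarray | float:
        return exponential_semivariance(h, self.c0, self.c1, self.a)


def exponential_semivariance(h, c0: float, c1: float, a: float):
    """gamma(h) = c0 + c1(1 - exp(-h/a)) for h > 0; exactly 0 at h = 0."""
    h = np.asarray(h, dtype=float)
    g = np.where(h > 0.0, c0 + c1 * (1.0 - np.exp(-h / a)), 0.0)
    return g if g.ndim else float(g)


def make_lag_bins(width_km: float = 10.0, max_lag_km: float = 200.0) -> np.ndarray:
    """Half-open lag bin edges [0, w), [w, 2w), ... up to ``max_lag_km``."""
    if width_km <= 0 or max_lag_km <= width_km:
        raise ValueError("need 0 < width_km < max_lag_km")
    return np.arange(0.0, max_lag_km + width_km / 2.0, width_km)


def _bin_gamma(diffs: np.ndarray, estimator: str) -> float:
    n = diffs.size
    if estimator == "matheron":
        return float(np.sum(diffs**2) / (2.0 * n))
    if estimator == "cressie_hawkins":
        m = np.mean(np.sqrt(np.abs(diffs)))
        return float(m**4 / (2.0 * (0.457 + 0.494 / n)))
    if estimator == "dowd":
        # 2.198 = (1 / Phi^-1(0.75))^2 scales the MAD-type statistic to the
        # Gaussian semivariance
        return float(2.198 * np.median(np.abs(diffs)) ** 2 / 2.0)
    raise ValueError(f"unknown estimator {estimator!r}; choose from {VALID_ESTIMATORS}")


def estimate_variogram(
    aggregates: pd.DataFrame,
    bin_edges: np.ndarray | None = None,
    estimator: str = "matheron",
    directional: bool = False,
    sector_width_deg: float = 45.0,
) -> VariogramEstimate | list[VariogramEstimate]:
    """Binned empirical semivariances over great-circle lags.

    ``aggregates`` needs columns ``mean_zn``, ``mean_lon``, ``mean_lat`` (as
    produced by :func:`aggregate_by_ea`).  Pair lags at or beyond the last
    bin edge are discarded; membership is half-open ``[lower, upper)``.

    With ``directional=True`` pairs are first assigned to bearing sectors of
    ``sector_width_deg`` centred on 0, 45, 90 and 135 degrees with 180-degree
    folding (the variogram is symmetric under pair reversal), and a list of
    per-sector estimates is returned.
    """
    if estimator not in VALID_ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {VALID_ESTIMATORS}")
    if len(aggregates) < 2:
        raise ValueError("need at least 2 aggregates")
    if bin_edges is None:
        bin_edges = make_lag_bins()
    bin_edges = np.asarray(bin_edges, dtype=float)

    lon = aggregates["mean_lon"].to_numpy(dtype=float)
    lat = aggregates["mean_lat"].to_numpy(dtype=float)
    z = aggregates["mean_zn"].to_numpy(dtype=float)

    iu, ju = np.triu_indices(len(z), k=1)
    lags = pairwise_great_circle(lon, lat)[iu, ju]
    diffs = z[iu] - z[ju]

    if not directional:
        return _binned_estimate(lags, diffs, bin_edges, estimator)

    brg = np.asarray(
        bearing(lon[iu], lat[iu], lon[ju], lat[ju]), dtype=float
    ) % 180.0
    centres = np.arange(0.0, 180.0, sector_width_deg)
    out = []
    for c in centres:
        half = sector_width_deg / 2.0
        dev = np.minimum(np.abs(brg - c), 180.0 - np.abs(brg - c))
        sel = dev < half
        est = _binned_estimate(lags[sel], diffs[sel], bin_edges, estimator)
        out.append(VariogramEstimate(estimator=estimator, bins=est.bins, sector=float(c)))
    return out


def _binned_estimate(lags, diffs, bin_edges, estimator) -> VariogramEstimate:
    idx = np.digitize(lags, bin_edges) - 1  # [lower, upper) membership
    nbins = len(bin_edges) - 1
    rows = []
    for b in range(nbins):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        gamma = _bin_gamma(diffs[sel], estimator) if n else np.nan
        rows.append(
            {
                "lower": bin_edges[b],
                "upper": bin_edges[b + 1],
                "mid": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                "n_pairs": n,
                "gamma": gamma,
            }
        )
    bins = pd.DataFrame(rows)
    if int(bins["n_pairs"].sum()) == 0:
        raise ValueError("all lag bins are empty; widen the bins or the max lag")
    return VariogramEstimate(estimator=estimator, bins=bins)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_exponential_wls(
    estimate: VariogramEstimate,
    weighting: str = "cressie",
    a_grid: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0),
    max_reweights: int = 20,
    tol: float = 1e-10,
) -> VariogramModel:
    """Fit the exponential model to binned estimates by weighted least squares.

    Minimises ``sum_j w_j [gamma_hat_j - gamma(h_j; c0, c1, a)]**2`` with
    Cressie's weights ``w_j = N_j / gamma(h_j; theta)**2``, iteratively
    reweighted until the parameters settle (``weighting="npairs"`` uses the
    plain ``w_j = N_j``, a single pass).  The optimiser is a bounded
    quasi-Newton search on ``(c0, c1, ln a)`` multistarted over ``a_grid``;
    ties go to the lowest objective, then the smallest ``a``.
    """
    pts = estimate.nonempty
    if len(pts) < 3:
        raise ValueError("need at least 3 non-empty bins to fit 3 parameters")
    h = pts["mid"].to_numpy(dtype=float)
    g = pts["gamma"].to_numpy(dtype=float)
    npairs = pts["n_pairs"].to_numpy(dtype=float)
    if weighting not in ("cressie", "npairs"):
        raise ValueError("weighting must be 'cressie' or 'npairs'")

    gmax = max(np.max(g), 1e-12)
    c0_init = max(float(g[0]), 0.0)
    c1_init = max(float(gmax - c0_init), 1e-6 * gmax)

    def objective(params, w):
        c0, c1, loga = params
        resid = g - exponential_semivariance(h, c0, c1, np.exp(loga))
        return float(np.sum(w * resid**2))

    def solve(w, a0):
        return minimize(
            objective,
            x0=np.array([c0_init, c1_init, np.log(a0)]),
            args=(w,),
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (np.log(1e-3), np.log(1e5))],
        )

    best = None
    for a0 in a_grid:
        w = npairs.copy()
        res = solve(w, a0)
        if weighting == "cressie":
            for _ in range(max_reweights):
                c0, c1, loga = res.x
                gam = np.maximum(
                    exponential_semivariance(h, c0, c1, np.exp(loga)), 1e-8 * gmax
                )
                w = npairs / gam**2
                prev = res.x.copy()
                res = solve(w, np.exp(loga))
                if np.max(np.abs(res.x - prev)) < tol * (1.0 + np.max(np.abs(prev))):
                    break
        cand = (res.fun, np.exp(res.x[2]), res)
        if best is None or cand[:2] < best[:2]:
            best = cand

    obj, a_hat, res = best
    c0_hat, c1_hat = max(res.x[0], 0.0), max(res.x[1], 0.0)
    # a flat fit over the observed lags (c1 ~ 0, or a so short the model
    # plateaus before the first bin) is indistinguishable from pure nugget:
    # report it canonically as one
    rise = (exponential_semivariance(h[-1], c0_hat, c1_hat, a_hat)
            - exponential_semivariance(h[0], c0_hat, c1_hat, a_hat))
    if c1_hat <= 1e-4 * gmax or rise <= 1e-4 * gmax:
        warnings.warn(
            "fitted variogram is flat over the observed lags: pure nugget",
            stacklevel=2,
        )
        c0_hat, c1_hat = c0_hat + c1_hat, 0.0
    return VariogramModel(
        c0=float(c0_hat),
        c1=float(c1_hat),
        a=float(a_hat),
        converged=bool(res.success),
        objective=float(obj),
        estimator=estimate.estimator,
    )
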