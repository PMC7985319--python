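"""Survey ingestion, exclusion cascade, inflammation staging and summaries.

The working container is a pandas DataFrame with the documented survey
header (see :data:`zincgeo.synthetic.SURVEY_COLUMNS`); blank cells become
missing values on read.  Records are excluded, in order, for missing GPS
coordinates, missing meal/draw context, missing inflammation biomarkers,
missing socio-demographics, and flagged analytical outliers — each record
attributed to the first matching reason so the report is a partition of the
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "EXCLUSION_REASONS",
    "read_survey",
    "apply_exclusions",
    "stage_inflammation",
    "stage_inflammation_frame",
    "weighted_mean",
    "weighted_median",
    "weighted_summary",
    "spearman_correlations",
]

MANDATORY_COLUMNS = [
    "id", "ea_id", "lon", "lat", "region", "residence", "group", "age",
    "sex", "draw_time", "fasting", "zn", "crp", "agp", "weight",
]

EXCLUSION_REASONS = [
    "missing_gps",
    "missing_meal_time",
    "missing_inflammation",
    "missing_sociodemographic",
    "analytical_outlier",
]

#: Thurnham inflammation-stage thresholds.
CRP_CUTOFF_MG_L = 5.0
AGP_CUTOFF_G_L = 1.0

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


@dataclass
class ExclusionReport:
    """Disjoint per-reason exclusion counts; reasons + retained = input."""

    n_input: int
    counts: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input - sum(self.counts.values()) != self.n_retained:
            raise ValueError("exclusion counts do not reconcile with totals")

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _parse_bool(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _BOOL_MAP:
            return _BOOL_MAP[s]
        raise ValueError(f"cannot parse boolean value {v!r}")

    return series.map(conv)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV into typed records.

    Raises ``ValueError`` naming any mandatory column that is absent or any
    coordinate that cannot be parsed; blank cells become missing values.
    """
    df = pd.read_csv(path, dtype={"id": str, "ea_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file lacks mandatory columns: {missing}")
    for col in ("lon", "lat", "zn", "crp", "agp", "weight", "age"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} contains unparseable values") from exc
    for col in ("fasting", "head_educated", "diarrhea", "analytical_outlier"):
        if col in df.columns:
            df[col] = _parse_bool(df[col])
    if "analytical_outlier" not in df.columns:
        df["analytical_outlier"] = False
    df["analytical_outlier"] = df["analytical_outlier"].fillna(False).astype(bool)

    bad_lat = df["lat"].notna() & (df["lat"].abs() > 90.0)
    bad_lon = df["lon"].notna() & ((df["lon"] < -180.0) | (df["lon"] >= 180.0))
    if bad_lat.any() or bad_lon.any():
        raise ValueError(
            f"{int(bad_lat.sum())} latitude and {int(bad_lon.sum())} longitude "
            "values outside valid ranges"
        )
    if (df["weight"].dropna() <= 0).any():
        raise ValueError("sampling weights must be positive")
    if (df["zn"].dropna() <= 0).any():
        raise ValueError("serum zinc values must be positive")
    return df


def _reason_masks(df: pd.DataFrame) -> dict[str, pd.Series]:
    socio = df["region"].isna() | df["residence"].isna() | df["sex"].isna()
    if "head_educated" in df.columns:
        socio = socio | df["head_educated"].isna()
    return {
        "missing_gps": df["lon"].isna() | df["lat"].isna(),
        "missing_meal_time": df["draw_time"].isna() | df["fasting"].isna(),
        "missing_inflammation": df["crp"].isna() | df["agp"].isna(),
        "missing_sociodemographic": socio,
        "analytical_outlier": df["analytical_outlier"].astype(bool),
    }


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records per the exclusion cascade; report disjoint counts.

    Order: GPS, meal/draw context, inflammation biomarkers,
    socio-demographics, analytical outliers — with first-reason attribution,
    so a record missing both GPS and CRP counts only under GPS.
    """
    if df.empty:
        return df.copy(), ExclusionReport(0, dict.fromkeys(EXCLUSION_REASONS, 0), 0)
    masks = _reason_masks(df)
    counts: dict[str, int] = {}
    already = pd.Series(False, index=df.index)
    for reason in EXCLUSION_REASONS:
        hit = masks[reason] & ~already
        counts[reason] = int(hit.sum())
        already = already | hit
    retained = df[~already].reset_index(drop=True)
    return retained, ExclusionReport(len(df), counts, len(retained))


def stage_inflammation(crp: float, agp: float) -> str:
    """Thurnham stage from CRP (mg/L) and AGP (g/L).

    none: CRP <= 5 and AGP <= 1; incubation: CRP > 5, AGP <= 1;
    early_convalescence: CRP > 5, AGP > 1; late_convalescence: CRP <= 5,
    AGP > 1.  Putting AGP exactly at 1 with the low-AGP stages keeps the
    four cells an exhaustive partition of the marker plane.
    """
    if pd.isna(crp) or pd.isna(agp):
        raise ValueError("both CRP and AGP are required to stage inflammation")
    if crp < 0 or agp < 0:
        raise ValueError("marker concentrations must be non-negative")
    high_crp = crp > CRP_CUTOFF_MG_L
    high_agp = agp > AGP_CUTOFF_G_L
    if high_crp and high_agp:
        return "early_convalescence"
    if high_crp:
        return "incubation"
    if high_agp:
        return "late_convalescence"
    return "none"


def stage_inflammation_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``stage`` column; requires complete CRP/AGP."""
    out = df.copy()
    out["stage"] = [
        stage_inflammation(c, a) for c, a in zip(df["crp"], df["agp"])
    ]
    return out


def weighted_mean(values, weights) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * v) / np.sum(w))


def weighted_median(values, weights) -> float:
    """0.5 quantile of the weight CDF, interpolating between distinct values.

    The plotting position of sorted value i is ``(W_i - w_i/2) / W`` with
    ``W_i`` the cumulative weight; with equal weights this reduces to the
    ordinary sample median for both odd and even n.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, p, v))


def weighted_summary(
    df: pd.DataFrame,
    group_by: str,
    value_cols: tuple[str, ...] = ("zn",),
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Per-stratum n, share of records (%), and weighted mean/median.

    One row per level of ``group_by`` plus a ``National`` total row.  Strata
    that are empty after dropping missing values are reported with n=0 and
    no estimates.
    """
    if group_by not in df.columns:
        raise ValueError(f"no column {group_by!r} to stratify on")
    rows = []
    total = len(df)
    levels = [lvl for lvl in df[group_by].dropna().unique()]
    for lvl in sorted(levels, key=str):
        sub = df[df[group_by] == lvl]
        rows.append(_summary_row(group_by, lvl, sub, total, value_cols, weight_col))
    rows.append(_summary_row(group_by, "National", df, total, value_cols, weight_col))
    return pd.DataFrame(rows)


def _summary_row(group_by, label, sub, total, value_cols, weight_col):
    row = {
        group_by: label,
        "n": len(sub),
        "percent": round(100.0 * len(sub) / total, 10) if total else np.nan,
    }
    for col in value_cols:
        ok = sub.dropna(subset=[col, weight_col])
        if ok.empty:
            row[f"{col}_wmean"] = np.nan
            row[f"{col}_wmedian"] = np.nan
        else:
            row[f"{col}_wmean"] = weighted_mean(ok[col], ok[weight_col])
            row[f"{col}_wmedian"] = weighted_median(ok[col], ok[weight_col])
    return row


def spearman_correlations(df: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlation matrix (average ranks).

    Unweighted.  Raises if any variable pair has fewer than 3 complete
    observations.
    """
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in data: {missing}")
    sub = df[variables].astype(float)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            if int(sub[[a, b]].dropna().shape[0]) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
    return sub.corr(method="spearman")
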