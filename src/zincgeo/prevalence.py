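"""Serum-zinc deficiency classification and weighted prevalence.

Deficiency thresholds depend on age band, sex, time of blood draw and
fasting status (Hotz-style cutoffs, ug/dL, strict less-than): children
under 10 use 65 (morning) / 57 (afternoon) regardless of sex; from age 10,
morning non-fasting cutoffs are 70 (male) / 66 (female), afternoon
non-fasting 61 / 59, and morning fasting 74 / 70.  Combinations without a
published cutoff (e.g. afternoon fasting) raise an explicit error rather
than defaulting silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .survey import weighted_mean

__all__ = ["CutoffTable", "load_default_cutoffs", "classify_deficiency",
           "classify_frame", "estimate_prevalence"]


class NoCutoffError(LookupError):
    """No deficiency cutoff is defined for this draw-context combination."""


@dataclass(frozen=True)
class CutoffTable:
    """Deficiency cutoffs keyed by (age band, sex, draw time, fasting).

    ``rows`` columns: age_band in {"<10", ">=10"}, sex in
    {"male", "female", "any"}, draw_time in {"morning", "afternoon"},
    fasting boolean, cutoff in ug/dL (strict ``<``).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"age_band", "sex", "draw_time", "fasting", "cutoff"}
        if not needed <= set(self.rows.columns):
            raise ValueError(f"cutoff table needs columns {sorted(needed)}")
        if (self.rows["cutoff"] <= 0).any():
            raise ValueError("cutoffs must be positive")
        key = self.rows[["age_band", "sex", "draw_time", "fasting"]]
        if key.duplicated().any():
            raise ValueError("duplicate cutoff rows for the same combination")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CutoffTable":
        rows = pd.read_csv(path)
        rows["fasting"] = rows["fasting"].astype(str).str.lower().map(
            {"true": True, "false": False}
        )
        return cls(rows=rows)

    def lookup(self, age: float, sex: str, draw_time: str, fasting: bool) -> float:
        """Cutoff (ug/dL) for a draw context; age < 10 uses the child rows."""
        if pd.isna(age) or pd.isna(draw_time) or pd.isna(fasting):
            raise ValueError("age, draw_time and fasting must all be present")
        band = "<10" if age < 10.0 else ">=10"
        cand = self.rows[
            (self.rows["age_band"] == band)
            & (self.rows["draw_time"] == draw_time)
            & (self.rows["fasting"] == bool(fasting))
            & (self.rows["sex"].isin([sex, "any"]))
        ]
        if cand.empty:
            raise NoCutoffError(
                f"no cutoff defined for age={age}, sex={sex}, "
                f"draw_time={draw_time}, fasting={fasting}"
            )
        return float(cand["cutoff"].iloc[0])


def load_default_cutoffs() -> CutoffTable:
    """The version-controlled cutoff table shipped with the package."""
    with resources.as_file(
        resources.files("zincgeo").joinpath("data/zn_cutoffs.csv")
    ) as p:
        return CutoffTable.from_csv(p)


def classify_deficiency(
    zn: float, age: float, sex: str, draw_time: str, fasting: bool,
    cutoffs: CutoffTable | None = None,
) -> bool:
    """Deficient iff ``zn`` is strictly below the matching cutoff."""
    cutoffs = cutoffs or load_default_cutoffs()
    if pd.isna(zn):
        raise ValueError("zinc value is missing")
    return bool(zn < cutoffs.lookup(age, sex, draw_time, fasting))


def classify_frame(
    records: pd.DataFrame,
    cutoffs: CutoffTable | None = None,
    value_cols: tuple[str, ...] = ("zn", "zn_adjusted"),
) -> pd.DataFrame:
    """Add ``deficient_<col>`` boolean columns for each zinc column present."""
    cutoffs = cutoffs or load_default_cutoffs()
    out = records.copy()
    cuts = np.array([
        cutoffs.lookup(a, s, d, f)
        for a, s, d, f in zip(
            records["age"], records["sex"], records["draw_time"], records["fasting"]
        )
    ])
    for col in value_cols:
        if col in records.columns:
            out[f"deficient_{col}"] = records[col].to_numpy(dtype=float) < cuts
    return out


def estimate_prevalence(
    records: pd.DataFrame,
    group_by: str | None = None,
    weight_col: str = "weight",
    cutoffs: CutoffTable | None = None,
) -> pd.DataFrame:
    """Weighted prevalence (%) of deficiency per stratum plus a national row.

    Classifies against unadjusted and (when present) adjusted zinc.  The
    estimate is the weight share of deficient records, invariant to a
    positive rescaling of all weights; empty strata get n=0 and no
    estimate.  Point prevalences only — no design-based standard errors.
    """
    classified = classify_frame(records, cutoffs)
    dcols = [c for c in classified.columns if c.startswith("deficient_")]
    rows = []

    def prev_row(label, sub):
        row = {"stratum": label, "n": len(sub)}
        for c in dcols:
            name = c.replace("deficient_zn_adjusted", "prevalence_adjusted").replace(
                "deficient_zn", "prevalence_unadjusted"
            )
            row[name] = (
                100.0 * weighted_mean(sub[c].astype(float), sub[weight_col])
                if len(sub) else np.nan
            )
        return row

    if group_by is not None:
        for lvl in sorted(classified[group_by].dropna().unique(), key=str):
            rows.append(prev_row(lvl, classified[classified[group_by] == lvl]))
    rows.append(prev_row("National", classified))
    return pd.DataFrame(rows)
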