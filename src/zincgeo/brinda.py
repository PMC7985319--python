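"""BRINDA internal-regression correction of serum zinc for inflammation.

Acute inflammation redistributes zinc from plasma to the liver, so measured
serum zinc understates status in inflamed individuals.  The internal
regression approach fits, within the analysis sample itself,

    ln Zn = b0 + beta1 * ln CRP + beta2 * ln AGP + e

and then removes the marker contribution above decile-based reference
values:

    Zn_adj = exp[ ln Zn - beta1 (ln CRP - ref_CRP)+ - beta2 (ln AGP - ref_AGP)+ ]

where each term applies only when that marker's log value exceeds its
reference (the maximum of the lowest decile over the fitting sample) — the
subscript ``+`` above denotes that gating, applied independently per
marker.  With the usual negative slopes the adjustment can only raise zinc,
and it is the identity for records with both markers at or below reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from scipy import stats

__all__ = ["BrindaFit", "fit_brinda", "adjust_zn", "adjust_frame",
           "lowest_decile_max"]


@dataclass(frozen=True)
class BrindaFit:
    """Fitted slopes, decile references and residual diagnostics."""

    beta1: float              # slope of lnZn on lnCRP
    beta2: float              # slope of lnZn on lnAGP
    ref_lncrp: float          # max of the lowest decile of lnCRP
    ref_lnagp: float          # max of the lowest decile of lnAGP
    n_fit: int
    intercept: float
    diagnostics: dict

    def __post_init__(self) -> None:
        if self.n_fit < 3:
            raise ValueError("need at least 3 records to fit")
        for v in (self.beta1, self.beta2, self.ref_lncrp, self.ref_lnagp):
            if not math.isfinite(v):
                raise ValueError("fit produced non-finite parameters")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def lowest_decile_max(values: np.ndarray) -> float:
    """Largest value among the lowest 10% of the sample.

    The lowest decile is the first ``floor(n/10)`` order statistics (at
    least one), so the reference is the ``floor(n/10)``-th smallest value.
    """
    x = np.sort(np.asarray(values, dtype=float))
    k = max(1, int(math.floor(0.1 * x.size)))
    return float(x[k - 1])


def _safe_log(values: np.ndarray, name: str, shift: float | None) -> np.ndarray:
    """Natural log with below-detection handling.

    Non-positive concentrations (possible below assay detection) are
    replaced by ``shift`` before logging; the default is half the smallest
    positive observed value.  All-non-positive input is an error.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains missing values; exclude them first")
    bad = x <= 0.0
    if bad.any():
        pos = x[~bad]
        if pos.size == 0:
            raise ValueError(f"all {name} values are non-positive")
        repl = shift if shift is not None else 0.5 * float(np.min(pos))
        x = np.where(bad, repl, x)
    return np.log(x)


def fit_brinda(
    records: pd.DataFrame,
    detection_shift: float | None = None,
) -> BrindaFit:
    """OLS of ln(zinc) on ln(CRP) and ln(AGP) over the analysis sample.

    A single national fit (no per-group models); decile references are
    computed on the same sample.  Residual diagnostics (Jarque-Bera
    normality, Breusch-Pagan homoscedasticity) are attached so the model
    assumptions can be inspected.
    """
    needed = {"zn", "crp", "agp"}
    if not needed <= set(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    sub = records.dropna(subset=["zn", "crp", "agp"])
    if len(sub) < 3:
        raise ValueError("need at least 3 complete records to fit")
    if (sub["zn"] <= 0).any():
        raise ValueError("serum zinc must be positive")

    lnzn = np.log(sub["zn"].to_numpy(dtype=float))
    lncrp = _safe_log(sub["crp"].to_numpy(), "crp", detection_shift)
    lnagp = _safe_log(sub["agp"].to_numpy(), "agp", detection_shift)

    X = sm.add_constant(np.column_stack([lncrp, lnagp]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear predictors: lnCRP and lnAGP are degenerate")
    res = sm.OLS(lnzn, X).fit()

    jb_stat, jb_p = stats.jarque_bera(res.resid)[:2]
    bp_stat, bp_p = het_breuschpagan(res.resid, X)[:2]
    diagnostics = {
        "r_squared": float(res.rsquared),
        "resid_sd": float(np.std(res.resid, ddof=3)),
        "jarque_bera_stat": float(jb_stat),
        "jarque_bera_p": float(jb_p),
        "breusch_pagan_stat": float(bp_stat),
        "breusch_pagan_p": float(bp_p),
    }
    return BrindaFit(
        beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        ref_lncrp=lowest_decile_max(lncrp),
        ref_lnagp=lowest_decile_max(lnagp),
        n_fit=len(sub),
        intercept=float(res.params[0]),
        diagnostics=diagnostics,
    )


def adjust_zn(
    zn, crp, agp, fit: BrindaFit, detection_shift: float | None = None
) -> np.ndarray | float:
    """Inflammation-adjusted zinc for one record or arrays of records.

    Each marker term ``beta * (ln marker - ref)`` is subtracted from
    ln(zinc) only where that marker's log value exceeds its reference;
    slopes are applied with their fitted signs and the result is not
    truncated.  Missing markers are an error — the exclusion cascade must
    have removed such records.
    """
    scalar = np.ndim(zn) == 0
    zn = np.atleast_1d(np.asarray(zn, dtype=float))
    crp = np.atleast_1d(np.asarray(crp, dtype=float))
    agp = np.atleast_1d(np.asarray(agp, dtype=float))
    if np.any(~np.isfinite(crp)) or np.any(~np.isfinite(agp)):
        raise ValueError("markers missing: records must be excluded, not passed through")
    if np.any(zn <= 0):
        raise ValueError("serum zinc must be positive")
    lncrp = _safe_log(crp, "crp", detection_shift)
    lnagp = _safe_log(agp, "agp", detection_shift)
    term1 = np.where(lncrp > fit.ref_lncrp, fit.beta1 * (lncrp - fit.ref_lncrp), 0.0)
    term2 = np.where(lnagp > fit.ref_lnagp, fit.beta2 * (lnagp - fit.ref_lnagp), 0.0)
    out = np.exp(np.log(zn) - term1 - term2)
    return float(out[0]) if scalar else out


def adjust_frame(
    records: pd.DataFrame, fit: BrindaFit, detection_shift: float | None = None
) -> pd.DataFrame:
    """Add ``zn_adjusted`` and per-term applied flags to the working table."""
    out = records.copy()
    out["zn_adjusted"] = adjust_zn(
        records["zn"].to_numpy(), records["crp"].to_numpy(),
        records["agp"].to_numpy(), fit, detection_shift,
    )
    lncrp = _safe_log(records["crp"].to_numpy(), "crp", detection_shift)
    lnagp = _safe_log(records["agp"].to_numpy(), "agp", detection_shift)
    out["brinda_crp_applied"] = lncrp > fit.ref_lncrp
    out["brinda_agp_applied"] = lnagp > fit.ref_lnagp
    return out
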