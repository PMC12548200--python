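"""Method-agreement battery for paired regional perfusion measurements.

Paired measurements are rows (animal, timepoint, condition, roi, pp_flm,
pp_dect) where, per (animal, timepoint), each method's three ROI fractions
sum to 1.  The battery comprises ordinary least-squares regression of
pp_dect on pp_flm (slope S, intercept, adjusted R^2, slope p-value),
Bland-Altman bias and 1.96-sd limits of agreement, and quadrant concordance
of between-timepoint changes: the percentage of change pairs in which both
methods move in the same direction (quadrants I and III of the
dPP_dect-vs-dPP_flm plane).  A stratified report reproduces the standard
table layout over {TLV, OLV, cranial, caudal, right, all}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AgreementReport",
    "ConcordanceResult",
    "validate_pairs",
    "regress",
    "bland_altman",
    "concordance",
    "stratified_report",
]

PAIR_COLUMNS = ("animal", "timepoint", "condition", "roi", "pp_flm", "pp_dect")
ZERO_TOL = 1e-12  # changes rounded to this are exact ties and carry no direction


def validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"paired measurements are missing columns {missing}")
    for col in ("pp_flm", "pp_dect"):
        v = pairs[col].to_numpy(dtype=float)
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError(f"{col} values must be fractions in [0, 1]")
    return pairs


@dataclass
class ConcordanceResult:
    concordance_pct: float
    quadrant_counts: tuple[int, int, int, int]  # I, II, III, IV
    n_excluded_zero: int

    @property
    def ratio_pct(self) -> float:
        """Literal (I+III)/(II+IV) reading, as a percentage (inf if no discordance)."""
        n1, n2, n3, n4 = self.quadrant_counts
        if n2 + n4 == 0:
            return float("inf")
        return 100.0 * (n1 + n3) / (n2 + n4)


@dataclass
class AgreementReport:
    stratum: str
    n: int
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    concordance_pct: float
    quadrant_counts: tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self) -> None:
        if np.isfinite(self.loa_low) and not (self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the bias")


def regress(pairs: pd.DataFrame) -> tuple[float, float, float, float]:
    """OLS of pp_dect on pp_flm: slope, intercept, adjusted R^2, slope p-value."""
    validate_pairs(pairs)
    x = pairs["pp_flm"].to_numpy(dtype=float)
    y = pairs["pp_dect"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("pp_flm has zero variance; regression is degenerate")
    if np.ptp(y) == 0:
        # constant response: flat fit carries no association
        return 0.0, float(y[0]), 0.0, 1.0
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    # adjusted R^2 with a single predictor: 1 - (1 - R^2)(n-1)/(n-2)
    adj_r2 = float(model.rsquared_adj)
    p = float(model.pvalues[1])
    return float(slope), float(intercept), adj_r2, p


def bland_altman(pairs: pd.DataFrame) -> tuple[float, float, float]:
    """Bias and 1.96-sd limits of agreement of d = pp_dect - pp_flm."""
    validate_pairs(pairs)
    d = pairs["pp_dect"].to_numpy(dtype=float) - pairs["pp_flm"].to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _changes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Between-consecutive-timepoint changes per (animal, roi) series.

    Each change is labeled with the source timepoint's condition, so the
    TLV stratum holds the TLV->OLV transitions and the OLV stratum the
    within-OLV steps.
    """
    validate_pairs(pairs)
    rows = []
    for (animal, roi), g in pairs.groupby(["animal", "roi"], sort=False):
        g = g.sort_values("timepoint")
        if len(g) < 2:
            continue
        d_flm = np.diff(g["pp_flm"].to_numpy(dtype=float))
        d_dect = np.diff(g["pp_dect"].to_numpy(dtype=float))
        src_cond = g["condition"].to_numpy()[:-1]
        for df_, dd, cond in zip(d_flm, d_dect, src_cond):
            rows.append({"animal": animal, "roi": roi, "condition": cond,
                         "d_flm": df_, "d_dect": dd})
    if not rows:
        raise ValueError("need at least 2 timepoints per (animal, roi) series")
    return pd.DataFrame(rows)


def _quadrants(changes: pd.DataFrame) -> ConcordanceResult:
    d1 = np.round(changes["d_flm"].to_numpy(dtype=float) / ZERO_TOL) * ZERO_TOL
    d2 = np.round(changes["d_dect"].to_numpy(dtype=float) / ZERO_TOL) * ZERO_TOL
    nonzero = (d1 != 0) & (d2 != 0)
    n_excluded = int((~nonzero).sum())
    d1, d2 = d1[nonzero], d2[nonzero]
    q1 = int(((d1 > 0) & (d2 > 0)).sum())
    q2 = int(((d1 < 0) & (d2 > 0)).sum())
    q3 = int(((d1 < 0) & (d2 < 0)).sum())
    q4 = int(((d1 > 0) & (d2 < 0)).sum())
    total = q1 + q2 + q3 + q4
    if total == 0:
        raise ValueError("no nonzero change pairs; concordance is undefined")
    return ConcordanceResult(
        concordance_pct=100.0 * (q1 + q3) / total,
        quadrant_counts=(q1, q2, q3, q4),
        n_excluded_zero=n_excluded,
    )


def concordance(pairs: pd.DataFrame) -> ConcordanceResult:
    """Directional concordance of between-timepoint changes.

    Primary definition: 100 * (I + III) / (I + II + III + IV); change pairs
    in which either method's change is exactly zero are excluded and
    counted.  The literal (I+III)/(II+IV) ratio is exposed on the result.
    """
    return _quadrants(_changes(pairs))


_STRATA = [
    ("TLV", "all"),
    ("OLV", "all"),
    ("all", "cranial"),
    ("all", "caudal"),
    ("all", "right"),
    ("all", "all"),
]
_ROI_ALIASES = {"cranial": "left_cranial", "caudal": "left_caudal", "right": "right"}


def stratified_report(pairs: pd.DataFrame) -> pd.DataFrame:
    """Agreement battery per stratum, in the standard table layout.

    Rows: TLV, OLV (condition strata), cranial, caudal, right (ROI strata)
    and all.  Regression and Bland-Altman use the rows of each stratum;
    concordance uses the change pairs falling in it.
    """
    validate_pairs(pairs)
    changes = _changes(pairs)
    records = []
    for cond, roi in _STRATA:
        sub = pairs
        ch = changes
        if cond != "all":
            sub = sub[sub["condition"] == cond]
            ch = ch[ch["condition"] == cond]
        if roi != "all":
            roi_name = _ROI_ALIASES[roi]
            sub = sub[sub["roi"] == roi_name]
            ch = ch[ch["roi"] == roi_name]
        slope, intercept, adj_r2, p = regress(sub)
        bias, lo, hi = bland_altman(sub)
        conc = _quadrants(ch)
        rep = AgreementReport(
            stratum=f"{cond}/{roi}",
            n=len(sub),
            slope=slope,
            intercept=intercept,
            adj_r2=adj_r2,
            p_value=p,
            bias=bias,
            loa_low=lo,
            loa_high=hi,
            concordance_pct=conc.concordance_pct,
            quadrant_counts=conc.quadrant_counts,
        )
        records.append({
            "ventilated": cond, "roi": roi, "n": rep.n,
            "slope": rep.slope, "intercept": rep.intercept,
            "adj_r2": rep.adj_r2, "p": rep.p_value,
            "bias": rep.bias, "loa_low": rep.loa_low, "loa_high": rep.loa_high,
            "concordance_pct": rep.concordance_pct,
        })
    return pd.DataFrame(records)
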