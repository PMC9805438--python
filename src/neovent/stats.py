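"""Correlation and curve-fit analysis of sweep tables.

Spearman rank correlations (with t-approximation P-levels) between the
inhomogeneity index, impedance and the ventilation burden variables;
Fisher-z tests for differences between coefficients computed in different
strata; and low-degree polynomial characteristics with their coefficients of
determination.  Stratification by respiratory rate, or by the (RR, Cw/CL)
pair, mirrors how the dependencies are reported: pooled coefficients are
diluted by rate-driven offsets and rise once computed per stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CurveFit",
    "CorrelationReport",
    "spearman_with_p",
    "compare_correlations",
    "fit_polynomial",
    "choose_degree",
    "grouped_correlation_report",
    "DEFAULT_PAIRS",
]

#: fit domain for the characteristics: the hypothetical asymptote point
#: T1/T2 = 100 is excluded from fits (kept in correlations)
FIT_T1T2_MAX = 10.0


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation P-level.

    Ties receive average ranks; ``|Rs| = 1`` maps to ``p = 0``.  Constant
    input is rejected (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; Spearman correlation is undefined")
    rs, p = sps.spearmanr(x, y)
    if abs(rs) >= 1.0 - 1e-15:
        return float(np.sign(rs)), 0.0
    return float(rs), float(p)


def compare_correlations(rs1: float, n1: int, rs2: float, n2: int) -> tuple[float, float]:
    """Two-sample Fisher-z test for a difference between correlation coefficients.

    ``z = (atanh(rs1) - atanh(rs2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal P-value.  Requires ``|rs| < 1`` and ``n >= 4`` in each
    sample (independent samples assumed).
    """
    for name, rs, n in (("first", rs1, n1), ("second", rs2, n2)):
        if not abs(rs) < 1:
            raise ValueError(f"{name} coefficient must satisfy |rs| < 1, got {rs}")
        if n <= 3:
            raise ValueError(f"{name} sample must have n >= 4, got {n}")
    z = (math.atanh(rs1) - math.atanh(rs2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return z, float(p)


@dataclass(frozen=True)
class CurveFit:
    """Polynomial characteristic y = f(x) with its goodness of fit.

    ``coefficients`` are in descending powers (numpy ``polyval`` order);
    ``domain`` is the x range the fit was computed on.
    """

    name: str
    degree: int
    coefficients: tuple[float, ...]
    r2: float
    domain: tuple[float, float]
    stratum: dict = field(default_factory=dict)

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


def fit_polynomial(x, y, degree: int, name: str = "", stratum: dict | None = None) -> CurveFit:
    """Ordinary least-squares polynomial fit on raw (x, y) with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.size <= degree:
        raise ValueError(f"need more than degree={degree} points, got {x.size}")
    if np.unique(x).size <= degree:
        raise ValueError("degenerate design: fewer distinct x values than degree + 1")
    coefs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coefs, x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("degenerate response: y is constant")
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return CurveFit(name=name, degree=degree, coefficients=tuple(float(c) for c in coefs),
                    r2=r2, domain=(float(x.min()), float(x.max())),
                    stratum=dict(stratum or {}))


def choose_degree(x, y, r2_threshold: float = 0.99) -> int:
    """Smallest degree of {2, 3} reaching the R^2 threshold, else 3."""
    for degree in (2, 3):
        if np.unique(np.asarray(x, float)).size <= degree:
            return degree - 1 if degree > 2 else 2
        if fit_polynomial(x, y, degree).r2 >= r2_threshold:
            return degree
    return 3


#: (y, x) variable pairs reported on: ventilation burden vs inhomogeneity,
#: burden vs impedance, and work vs the pressures
DEFAULT_PAIRS = (
    ("Z", "T1T2"), ("WOB_vt", "T1T2"), ("PIP_meas", "T1T2"), ("MAP", "T1T2"),
    ("WOB_vt", "Z"), ("PIP_meas", "Z"), ("MAP", "Z"),
    ("WOB_vt", "PIP_meas"), ("WOB_vt", "MAP"),
)


@dataclass
class CorrelationReport:
    """Stratified Spearman analysis of a sweep table.

    ``table`` has one row per (pair, stratum) with columns
    ``pair, y, x, stratum_type, RR, CwCL, n, Rs, p``; ``summaries`` holds the
    per-pair mean +/- SD of the stratified coefficients; ``difference_tests``
    the Fisher-z comparisons of the pooled coefficient against each
    stratified one.
    """

    table: pd.DataFrame
    summaries: pd.DataFrame
    difference_tests: pd.DataFrame

    def pooled(self, y: str, x: str) -> tuple[float, float]:
        sel = self.table[(self.table.y == y) & (self.table.x == x)
                         & (self.table.stratum_type == "pooled")]
        row = sel.iloc[0]
        return float(row.Rs), float(row.p)


def grouped_correlation_report(table: pd.DataFrame,
                               pairs=DEFAULT_PAIRS) -> CorrelationReport:
    """Pooled, per-RR and per-(RR, Cw/CL) Spearman coefficients for each pair.

    Strata with fewer than 3 usable points, or with a constant variable, are
    skipped with a warning.  Failed sweep rows (NaN metrics) are dropped.
    """
    strata_specs = [("pooled", []), ("by RR", ["RR"]), ("by RR x CwCL", ["RR", "CwCL"])]
    records = []
    for y, x in pairs:
        df = table[[c for c in {x, y, "RR", "CwCL"}]].dropna()
        for stype, keys in strata_specs:
            groups = [((), df)] if not keys else list(df.groupby(keys, sort=True))
            if keys and df[keys].drop_duplicates().shape[0] < 2 and stype != "pooled":
                continue
            for gkey, gdf in groups:
                gkey = gkey if isinstance(gkey, tuple) else (gkey,)
                meta = dict(zip(keys, gkey))
                if len(gdf) < 3:
                    warnings.warn(f"stratum {meta} for {y} vs {x} has n < 3; skipped",
                                  stacklevel=2)
                    continue
                try:
                    rs, p = spearman_with_p(gdf[x], gdf[y])
                except ValueError as exc:
                    warnings.warn(f"stratum {meta} for {y} vs {x} skipped: {exc}",
                                  stacklevel=2)
                    continue
                records.append({
                    "pair": f"{y} vs {x}", "y": y, "x": x, "stratum_type": stype,
                    "RR": meta.get("RR", np.nan), "CwCL": meta.get("CwCL", np.nan),
                    "n": len(gdf), "Rs": rs, "p": p,
                })
    tab = pd.DataFrame.from_records(records)

    summaries = (
        tab[tab.stratum_type != "pooled"]
        .groupby(["pair", "y", "x", "stratum_type"], sort=False)["Rs"]
        .agg(mean_Rs="mean", sd_Rs="std", n_strata="count")
        .reset_index()
    )

    # noiseless sweeps produce perfect within-stratum coefficients; nudge them
    # inside the open interval so the Fisher transform stays finite
    def clamp(rs: float) -> float:
        return float(np.clip(rs, -0.9999, 0.9999))

    diffs = []
    for (y, x), sub in tab.groupby(["y", "x"], sort=False):
        pooled = sub[sub.stratum_type == "pooled"]
        if pooled.empty:
            continue
        prow = pooled.iloc[0]
        for _, srow in sub[sub.stratum_type != "pooled"].iterrows():
            if prow.n <= 3 or srow.n <= 3:
                continue
            z, p = compare_correlations(clamp(prow.Rs), int(prow.n),
                                        clamp(srow.Rs), int(srow.n))
            diffs.append({"pair": f"{y} vs {x}", "stratum_type": srow.stratum_type,
                          "RR": srow.RR, "CwCL": srow.CwCL,
                          "Rs_pooled": prow.Rs, "Rs_stratum": srow.Rs, "z": z, "p": p})
    return CorrelationReport(table=tab, summaries=summaries,
                             difference_tests=pd.DataFrame.from_records(diffs))
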