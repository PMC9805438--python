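"""Bedside inversion of the impedance characteristic.

The clinical workflow: read the monitor's dynamic R and C at the set
respiratory rate, compute the respiratory-system impedance Z, invert the
calibrated characteristic Z = f(T1/T2) to estimate the inhomogeneity index,
evaluate the PIP/MAP/WOB characteristics at that index to predict the
pressures a constant-MV strategy will require, and flag the case for an
early elective switch to high-frequency oscillation when the predicted PIP
exceeds the lung-protective limit.

Calibration curves come from a constant-MV sweep of a matching patient
class; they are polynomial characteristics per respiratory rate, fitted over
the physiological index range (the asymptote point is excluded), with the
Z curve required to be monotone so its inversion is well posed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .measurement import compute_impedance
from .stats import FIT_T1T2_MAX, CurveFit, choose_degree, fit_polynomial

__all__ = [
    "CalibrationSet",
    "BedsideInput",
    "BedsideReport",
    "InversionResult",
    "calibrate_characteristics",
    "invert_characteristic",
    "bedside_assess",
    "DEFAULT_PIP_LIMIT",
]

#: protective-ventilation peak-pressure ceiling, cmH2O (upper edge of the
#: recommended 25 +/- 2 window for CDH neonates)
DEFAULT_PIP_LIMIT = 27.0

#: accept a requested RR this far (bpm) from the nearest calibrated RR
RR_TOLERANCE = 2.5

_CURVES = ("Z", "PIP", "MAP", "WOB_vt")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CalibrationSet:
    """Per-RR polynomial characteristics of Z, PIP, MAP and WOB_vt vs T1/T2."""

    patient_class: dict
    fits: dict[float, dict[str, CurveFit]]
    domain: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    @property
    def rr_values(self) -> tuple[float, ...]:
        return tuple(sorted(self.fits))

    def to_json(self, path) -> None:
        payload = {
            "format": "neovent-calibration",
            "version": _FORMAT_VERSION,
            "patient_class": self.patient_class,
            "domain": list(self.domain),
            "provenance": self.provenance,
            "fits": {
                str(rr): {
                    name: {
                        "degree": cf.degree,
                        "coefficients": list(cf.coefficients),
                        "r2": cf.r2,
                        "domain": list(cf.domain),
                    }
                    for name, cf in curves.items()
                }
                for rr, curves in self.fits.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationSet":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "neovent-calibration":
            raise ValueError(f"{path} is not a calibration file")
        fits = {
            float(rr): {
                name: CurveFit(name=name, degree=d["degree"],
                               coefficients=tuple(d["coefficients"]),
                               r2=d["r2"], domain=tuple(d["domain"]))
                for name, d in curves.items()
            }
            for rr, curves in payload["fits"].items()
        }
        return cls(patient_class=payload["patient_class"], fits=fits,
                   domain=tuple(payload["domain"]),
                   provenance=payload.get("provenance", {}))


@dataclass(frozen=True)
class BedsideInput:
    """Monitor readouts: dynamic R (cmH2O*s/l), dynamic C (ml/cmH2O), set RR (bpm)."""

    R: float
    C: float
    RR: float

    def __post_init__(self) -> None:
        for name in ("R", "C", "RR"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class InversionResult:
    value: float
    flag: str = ""  # "", "below-domain", "extrapolated", "nearest-RR"


@dataclass(frozen=True)
class BedsideReport:
    Z: float
    T1T2_est: float
    T1T2_flag: str
    PIP_pred: float
    MAP_pred: float
    WOB_pred: float
    strategy: str  # "CMV-ok" | "consider-HFV"
    pip_limit: float

    def __str__(self) -> str:
        lines = [
            f"Z          = {self.Z:8.1f} cmH2O*s/l",
            f"T1/T2 est  = {self.T1T2_est:8.2f}" + (f"  [{self.T1T2_flag}]" if self.T1T2_flag else ""),
            f"PIP  pred  = {self.PIP_pred:8.1f} cmH2O (limit {self.pip_limit:g})",
            f"MAP  pred  = {self.MAP_pred:8.1f} cmH2O",
            f"WOB  pred  = {self.WOB_pred:8.2f} J/l",
            f"strategy   = {self.strategy}",
        ]
        return "\n".join(lines)


def _monotone_increasing(cf: CurveFit, domain: tuple[float, float]) -> bool:
    xs = np.linspace(domain[0], domain[1], 201)
    return bool(np.all(np.diff(cf(xs)) > 0))


def calibrate_characteristics(table: pd.DataFrame,
                              r2_threshold: float = 0.99) -> CalibrationSet:
    """Fit per-RR characteristics of Z, PIP, MAP and WOB_vt against T1/T2.

    The asymptote grid point (T1/T2 > 10) is excluded from the fits.  The
    polynomial degree per curve is the smallest of {2, 3} reaching the R^2
    threshold.  A Z fit that is non-monotone over the domain is refitted at
    successively lower degree; if even the linear fit is non-monotone the
    calibration fails and the caller must densify the sweep.
    """
    required = {"T1T2", "RR", "Z", "PIP_set", "MAP", "WOB_vt"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sweep table lacks columns {sorted(missing)}")
    if table["CwCL"].nunique() > 1:
        raise ValueError("sweep table mixes Cw/CL values; calibrate one patient class at a time")
    df = table[table["T1T2"] <= FIT_T1T2_MAX].dropna(subset=["Z", "PIP_set", "MAP", "WOB_vt"])
    source = {"Z": "Z", "PIP": "PIP_set", "MAP": "MAP", "WOB_vt": "WOB_vt"}

    fits: dict[float, dict[str, CurveFit]] = {}
    domain = (float(df["T1T2"].min()), float(df["T1T2"].max()))
    for rr, g in df.groupby("RR", sort=True):
        g = g.sort_values("T1T2")
        x = g["T1T2"].to_numpy()
        if np.unique(x).size < 4:
            raise ValueError(f"RR={rr}: need >= 4 distinct T1/T2 values, got {np.unique(x).size}")
        curves = {}
        for name, col in source.items():
            y = g[col].to_numpy()
            degree = choose_degree(x, y, r2_threshold)
            cf = fit_polynomial(x, y, degree, name=name, stratum={"RR": float(rr)})
            if name == "Z":
                while not _monotone_increasing(cf, domain) and degree > 1:
                    degree -= 1
                    cf = fit_polynomial(x, y, degree, name=name, stratum={"RR": float(rr)})
                if not _monotone_increasing(cf, domain):
                    raise ValueError(
                        f"RR={rr}: Z characteristic is non-monotone at every degree; "
                        "densify the sweep grid"
                    )
            curves[name] = cf
        fits[float(rr)] = curves

    patient_class = {
        key: table[key].iloc[0]
        for key in ("label", "CwCL", "PEEP", "IE_i", "IE_e", "MV_target")
        if key in table.columns
    }
    provenance = {"n_rows": int(len(table)),
                  "t1t2_grid": sorted(float(v) for v in table["T1T2"].unique())}
    return CalibrationSet(patient_class=patient_class, fits=fits,
                          domain=domain, provenance=provenance)


def _nearest_rr(cal: CalibrationSet, rr: float) -> tuple[float, str]:
    rrs = np.array(cal.rr_values)
    i = int(np.argmin(np.abs(rrs - rr)))
    if abs(rrs[i] - rr) > RR_TOLERANCE:
        raise ValueError(
            f"RR={rr} bpm is farther than {RR_TOLERANCE} bpm from any calibrated rate {tuple(rrs)}"
        )
    flag = "" if rrs[i] == rr else "nearest-RR"
    return float(rrs[i]), flag


def invert_characteristic(cal: CalibrationSet, rr: float, z: float) -> InversionResult:
    """Solve Z = f(T1/T2) for the index on the calibrated monotone branch.

    Z below the curve's value at the lower domain edge returns the edge with
    a ``below-domain`` flag; Z above the upper edge is clamped there and
    flagged ``extrapolated``.
    """
    rr_used, rr_flag = _nearest_rr(cal, rr)
    f = cal.fits[rr_used]["Z"]
    lo, hi = cal.domain
    flo, fhi = float(f(lo)), float(f(hi))

    def with_rr_flag(flag: str) -> str:
        return "; ".join(x for x in (flag, rr_flag) if x)

    if z <= flo:
        flag = "below-domain" if z < flo else ""
        return InversionResult(lo, with_rr_flag(flag))
    if z >= fhi:
        flag = "extrapolated" if z > fhi else ""
        return InversionResult(hi, with_rr_flag(flag))
    root = brentq(lambda x: f(x) - z, lo, hi, xtol=1e-10)
    return InversionResult(float(root), with_rr_flag(""))


def bedside_assess(inp: BedsideInput, cal: CalibrationSet,
                   pip_limit: float = DEFAULT_PIP_LIMIT) -> BedsideReport:
    """Full workflow: monitor R/C/RR -> Z -> T1/T2 -> predicted pressures -> strategy.

    The strategy flag is ``consider-HFV`` iff the predicted PIP strictly
    exceeds ``pip_limit``; any domain or nearest-rate flag from the inversion
    propagates into the report.
    """
    z = compute_impedance(inp.R, inp.C, inp.RR)
    est = invert_characteristic(cal, inp.RR, z)
    rr_used, _ = _nearest_rr(cal, inp.RR)
    curves = cal.fits[rr_used]
    pip = float(curves["PIP"](est.value))
    map_ = float(curves["MAP"](est.value))
    wob = float(curves["WOB_vt"](est.value))
    strategy = "consider-HFV" if pip > pip_limit else "CMV-ok"
    if est.flag:
        warnings.warn(f"bedside estimate flagged: {est.flag}", stacklevel=2)
    return BedsideReport(Z=z, T1T2_est=est.value, T1T2_flag=est.flag,
                         PIP_pred=pip, MAP_pred=map_, WOB_pred=wob,
                         strategy=strategy, pip_limit=pip_limit)
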