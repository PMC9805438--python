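"""Structured config files and delimited-text exports.

Patients, ventilator settings and sweep grids are described in YAML; traces,
sweep tables and statistical reports are written as plain CSV so they can be
inspected with any spreadsheet or fed back into the analysis commands.
Compliances in config files may carry an explicit unit tag (``ml/cmH2O`` or
``l/cmH2O``); untagged compliance numbers are read as ml/cmH2O, the unit a
ventilator monitor displays.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .mechanics import DEFAULT_RISE_TIME, BreathTrace, PatientParams, VentSettings, make_patient
from .protocol import SweepGrid, patient_presets
from .stats import CorrelationReport

__all__ = [
    "load_patient_config",
    "load_grid_config",
    "trace_to_csv",
    "sweep_to_csv",
    "read_sweep_csv",
    "correlation_report_to_csv",
    "curve_fits_to_csv",
]

TRACE_COLUMNS = ["t", "Pao", "Q", "Q1", "Q2", "V1", "V2", "P_A1", "P_A2", "P_pl"]


def _compliance_ml(entry) -> float:
    """Compliance in ml/cmH2O from a bare number or a {value, units} mapping."""
    if isinstance(entry, dict):
        value = float(entry["value"])
        units = str(entry.get("units", "ml/cmH2O")).replace(" ", "")
        if units.lower() in ("ml/cmh2o",):
            return value
        if units.lower() in ("l/cmh2o",):
            return value * 1000.0
        raise ValueError(f"unknown compliance units {entry.get('units')!r}")
    return float(entry)


def _vent_from_mapping(v: dict) -> VentSettings:
    ie = v.get("ie", (1, 2))
    return VentSettings(
        RR=float(v["rr"]),
        PIP=float(v.get("pip", v.get("peep", 5.0))),
        PEEP=float(v.get("peep", 5.0)),
        IE=(float(ie[0]), float(ie[1])),
        rise_time=float(v.get("rise_time", DEFAULT_RISE_TIME)),
        MV_target=float(v["mv_target"]) if "mv_target" in v else None,
    )


def load_patient_config(path) -> tuple[PatientParams, VentSettings | None]:
    """Read a patient (and optional ventilator block) from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    p = doc["patient"]
    params = make_patient(
        c_total=_compliance_ml(p["c_total"]),
        cw_over_cl=float(p["cw_over_cl"]),
        t1_over_t2=float(p.get("t1_over_t2", 1.0)),
        rc=float(p["rc"]),
        r_periph_each=float(p["r_periph_each"]),
        L=float(p.get("inertance", 0.0)),
        mode=p.get("mode", "compliance-split"),
        label=str(p.get("label", Path(path).stem)),
    )
    vent = _vent_from_mapping(doc["ventilator"]) if "ventilator" in doc else None
    return params, vent


def load_grid_config(path) -> SweepGrid:
    """Read a sweep grid from YAML; a ``patient: <preset>`` key pulls preset constants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    s = doc["sweep"]
    kwargs = {}
    if "patient" in s and isinstance(s["patient"], str):
        preset = patient_presets()[s["patient"]]
        kwargs = dict(label=preset.label, c_total=preset.c_total, rc=preset.rc,
                      r_periph_each=preset.r_periph_each,
                      cwcl_values=(preset.default_cw_over_cl,),
                      PEEP=preset.PEEP, IE=preset.IE)
    elif "patient" in s:
        p = s["patient"]
        kwargs = dict(label=str(p.get("label", "custom")),
                      c_total=_compliance_ml(p["c_total"]),
                      rc=float(p["rc"]), r_periph_each=float(p["r_periph_each"]))
    for key, conv in (("t1t2", lambda v: ("t1t2_values", tuple(map(float, v)))),
                      ("rr", lambda v: ("rr_values", tuple(map(float, v)))),
                      ("cw_over_cl", lambda v: ("cwcl_values", tuple(map(float, v)))),
                      ("peep", lambda v: ("PEEP", float(v))),
                      ("ie", lambda v: ("IE", (float(v[0]), float(v[1])))),
                      ("mv_target", lambda v: ("MV_target", float(v))),
                      ("rise_time", lambda v: ("rise_time", float(v))),
                      ("mode", lambda v: ("mode", str(v)))):
        if key in s:
            name, value = conv(s[key])
            kwargs[name] = value
    return SweepGrid(**kwargs)


def trace_to_csv(trace: BreathTrace, path) -> None:
    """One row per sample with the canonical column order."""
    trace.to_dataframe()[TRACE_COLUMNS].to_csv(path, index=False)


def sweep_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_sweep_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def correlation_report_to_csv(report: CorrelationReport, path) -> None:
    """Pair x stratum rows (Rs, p, n) followed by nothing else; summaries inline."""
    report.table.to_csv(path, index=False)


def curve_fits_to_csv(fits, path) -> None:
    """Serialise CurveFit records: one row per curve, coefficients in descending powers."""
    rows = []
    for cf in fits:
        row = {"name": cf.name, "degree": cf.degree, "r2": cf.r2,
               "domain_lo": cf.domain[0], "domain_hi": cf.domain[1]}
        row.update({f"stratum_{k}": v for k, v in cf.stratum.items()})
        row.update({f"c{len(cf.coefficients) - 1 - i}": c
                    for i, c in enumerate(cf.coefficients)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
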