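"""Simulation protocol: constant-minute-ventilation sweeps over the inhomogeneity grid.

The study design holds minute ventilation constant (the ventilated patient's
gas-exchange requirement) while the inhomogeneity index T1/T2, the
respiratory rate and the chest-wall/lung compliance ratio vary; the set
inspiratory pressure is re-solved at every grid point so that the steady
breath delivers the target MV.  The sweep output is a tidy table, one row
per grid point, carrying the solved PIP together with the full monitor
emulation (PIP, MAP, Vt, MV, WOB_vt, Rdyn, Cdyn, Z, auto-PEEP).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mechanics import (
    DEFAULT_RISE_TIME,
    PatientParams,
    SimConfig,
    VentSettings,
    make_patient,
    simulate_to_steady_cycle,
)
from .measurement import breath_metrics, with_dynamic_channels

__all__ = [
    "Preset",
    "SweepGrid",
    "patient_presets",
    "default_sweep_grid",
    "target_minute_ventilation",
    "run_sweep",
    "SWEEP_COLUMNS",
]

#: default inhomogeneity grid; 100 is the hypothetical asymptote point
DEFAULT_T1T2_GRID = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 100.0)
DEFAULT_RR_GRID = (35.0, 40.0, 45.0, 50.0, 55.0)

# P3's central/peripheral split (Rc = 131, R1 = R2 = 88 cmH2O*s/l at a
# printed monitor R of 205); the other presets have no printed split and are
# scaled proportionally.
_P3_R_PRINTED = 205.0
_P3_RC = 131.0
_P3_R_PERIPH = 88.0


@dataclass(frozen=True)
class Preset:
    """Clinical preset: printed monitor values plus the assumed circuit split."""

    label: str
    R_printed: float          # monitor (dynamic) total resistance, cmH2O*s/l
    c_total: float            # total static compliance, ml/cmH2O
    MV: float                 # clinical minute ventilation, l/min
    PEEP: float
    RR: float
    IE: tuple[float, float]
    cw_over_cl: tuple[float, ...]
    rc: float
    r_periph_each: float

    @property
    def default_cw_over_cl(self) -> float:
        return self.cw_over_cl[-1]


def patient_presets() -> dict[str, Preset]:
    """The three neonatal CDH presets used throughout the study."""

    def split(r_printed: float) -> tuple[float, float]:
        scale = r_printed / _P3_R_PRINTED
        return _P3_RC * scale, _P3_R_PERIPH * scale

    presets = {}
    for label, r, c, mv, peep, rr, cwcl in (
        ("P1", 244.0, 0.80, 0.69, 4.0, 45.0, (15.0,)),
        ("P2", 188.0, 1.26, 0.86, 6.0, 50.0, (12.0,)),
        ("P3", 205.0, 1.14, 0.90, 5.0, 45.0, (5.0, 8.0, 12.0)),
    ):
        rc, rp = split(r)
        presets[label] = Preset(label=label, R_printed=r, c_total=c, MV=mv,
                                PEEP=peep, RR=rr, IE=(1.0, 2.0),
                                cw_over_cl=cwcl, rc=rc, r_periph_each=rp)
    return presets


@dataclass(frozen=True)
class SweepGrid:
    """Factorial grid T1/T2 x RR x Cw/CL for one patient class.

    ``c_total``, the resistance split, PEEP, I:E, rise time and the MV target
    are held fixed across the grid; PIP is solved per point.
    """

    label: str
    c_total: float
    rc: float
    r_periph_each: float
    t1t2_values: tuple[float, ...] = DEFAULT_T1T2_GRID
    rr_values: tuple[float, ...] = DEFAULT_RR_GRID
    cwcl_values: tuple[float, ...] = (12.0,)
    PEEP: float = 5.0
    IE: tuple[float, float] = (1.0, 2.0)
    MV_target: float = 0.8
    rise_time: float = DEFAULT_RISE_TIME
    mode: str = "compliance-split"

    def __post_init__(self) -> None:
        for name in ("t1t2_values", "rr_values", "cwcl_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(not v > 0 for v in vals):
                raise ValueError(f"{name} must be non-empty and strictly positive")
        if not self.MV_target > 0:
            raise ValueError("MV_target must be positive")
        if not 0.7 <= self.MV_target <= 0.9:
            warnings.warn(
                f"MV_target={self.MV_target} l/min is outside the protocol band 0.8 +/- 0.1",
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return len(self.t1t2_values) * len(self.rr_values) * len(self.cwcl_values)


def default_sweep_grid(preset: str | Preset = "P3", **overrides) -> SweepGrid:
    """Default sweep for a clinical preset (MV held at the protocol's 0.8 l/min)."""
    if isinstance(preset, str):
        preset = patient_presets()[preset]
    kwargs = dict(
        label=preset.label,
        c_total=preset.c_total,
        rc=preset.rc,
        r_periph_each=preset.r_periph_each,
        cwcl_values=(preset.default_cw_over_cl,),
        PEEP=preset.PEEP,
        IE=preset.IE,
        MV_target=0.8,
    )
    kwargs.update(overrides)
    return SweepGrid(**kwargs)


def _solve_pip(
    params: PatientParams,
    settings: VentSettings,
    mv_target: float,
    cfg: SimConfig,
    tol: float = 0.005,
    dp_bracket: tuple[float, float] = (0.1, 80.0),
):
    """Driving pressure solve returning (pip, trace, metrics) at the root.

    The steady-cycle MV is linear in the driving pressure PIP - PEEP
    (superposition in a linear circuit), so a single proportional update from
    one probe normally lands on the root; a bracketed Brent solve is the
    fallback for any residual mismatch.
    """

    def evaluate(dp: float):
        st = replace(settings, PIP=settings.PEEP + dp, MV_target=mv_target)
        tr = simulate_to_steady_cycle(params, st, cfg)
        return st, tr, breath_metrics(tr, st)

    lo, hi = dp_bracket
    dp0 = min(max(10.0, lo), hi)
    _, _, m0 = evaluate(dp0)
    if m0.MV <= 0:
        raise RuntimeError("no tidal volume delivered at the probe driving pressure")
    dp = dp0 * mv_target / m0.MV
    if not lo <= dp <= hi:
        _, _, mlo = evaluate(lo)
        _, _, mhi = evaluate(hi)
        raise ValueError(
            f"MV_target={mv_target} l/min unreachable: achievable range "
            f"[{mlo.MV:.3f}, {mhi.MV:.3f}] l/min over PIP-PEEP in {dp_bracket}"
        )
    st, tr, m = evaluate(dp)
    if abs(m.MV - mv_target) > tol * mv_target:
        dp = brentq(lambda d: evaluate(d)[2].MV - mv_target, lo, hi, xtol=1e-6)
        st, tr, m = evaluate(dp)
        if abs(m.MV - mv_target) > tol * mv_target:
            raise RuntimeError(
                f"MV solve did not meet tolerance: achieved {m.MV:.4f} vs target {mv_target}"
            )
    return st.PIP, tr, m


def target_minute_ventilation(
    params: PatientParams,
    settings: VentSettings,
    mv_target: float,
    tol: float = 0.005,
    cfg: SimConfig | None = None,
) -> float:
    """Set PIP delivering ``mv_target`` l/min on the steady cycle.

    ``settings`` provides RR, I:E, PEEP and rise time; its PIP field is
    ignored.  MV is strictly increasing in PIP, so the root over
    ``PIP - PEEP`` in [0.1, 80] cmH2O is unique when bracketed.
    """
    if not mv_target > 0:
        raise ValueError("mv_target must be positive")
    pip, _, _ = _solve_pip(params, settings, mv_target, cfg or SimConfig(), tol=tol)
    return pip


SWEEP_COLUMNS = [
    "label", "T1T2", "RR", "CwCL", "PEEP", "IE_i", "IE_e", "MV_target",
    "PIP_set", "PIP_meas", "MAP", "Vt", "MV", "WOB_vt",
    "Rdyn", "Cdyn", "Z", "autoPEEP_1", "autoPEEP_2", "steady", "note",
]


def run_sweep(grid: SweepGrid, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Run the factorial sweep; one row per (T1/T2, RR, Cw/CL) grid point.

    Deterministic given the grid and configuration.  Per-point failures are
    recorded in the row's ``note`` column (with NaN metrics) and never abort
    the sweep.  Z is computed from the fitted dynamic R and C, as at the
    bedside.
    """
    cfg = cfg or SimConfig()
    rows = []
    for t1t2, rr, cwcl in itertools.product(grid.t1t2_values, grid.rr_values, grid.cwcl_values):
        row = {
            "label": grid.label, "T1T2": t1t2, "RR": rr, "CwCL": cwcl,
            "PEEP": grid.PEEP, "IE_i": grid.IE[0], "IE_e": grid.IE[1],
            "MV_target": grid.MV_target,
        }
        try:
            params = make_patient(grid.c_total, cwcl, t1t2, grid.rc,
                                  grid.r_periph_each, mode=grid.mode,
                                  label=grid.label)
            base = VentSettings(RR=rr, PIP=grid.PEEP, PEEP=grid.PEEP,
                                IE=grid.IE, rise_time=grid.rise_time)
            pip, trace, metrics = _solve_pip(params, base, grid.MV_target, cfg)
            metrics = with_dynamic_channels(metrics, trace)
            row.update({
                "PIP_set": pip, "PIP_meas": metrics.PIP_meas, "MAP": metrics.MAP,
                "Vt": metrics.Vt, "MV": metrics.MV, "WOB_vt": metrics.WOB_vt,
                "Rdyn": metrics.Rdyn, "Cdyn": metrics.Cdyn, "Z": metrics.Z,
                "autoPEEP_1": metrics.autoPEEP_1, "autoPEEP_2": metrics.autoPEEP_2,
                "steady": metrics.steady, "note": metrics.warning,
            })
        except (ValueError, RuntimeError) as exc:
            row.update({col: np.nan for col in SWEEP_COLUMNS if col not in row})
            row["steady"] = False
            row["note"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
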