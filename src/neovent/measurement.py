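"""Ventilator/monitor emulation: per-breath mechanics readouts.

Reconstructs the channels a bedside ventilator and respiratory-mechanics
monitor report from a simulated steady breath: peak and mean airway pressure,
tidal and minute volume, ventilator work of breathing per litre (WOB_vt),
dynamic resistance and compliance from an equation-of-motion regression, and
the respiratory-system impedance magnitude Z at the breathing frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mechanics import BreathTrace, VentSettings

__all__ = [
    "BreathMetrics",
    "breath_metrics",
    "fit_dynamic_rc",
    "compute_impedance",
    "CMH2O_L_TO_J",
]

#: 1 cmH2O * 1 l of volume displacement, in joules
CMH2O_L_TO_J = 0.0980665


@dataclass(frozen=True)
class BreathMetrics:
    """Per-breath monitor readouts.

    ``Vt`` is in ml and ``Cdyn`` in ml/cmH2O (monitor display units); work is
    J per litre of delivered volume.  ``Rdyn``/``Cdyn``/``Z`` are filled in by
    the protocol layer after the equation-of-motion fit and are ``None`` on
    the bare ``breath_metrics`` output.
    """

    PIP_meas: float
    MAP: float
    PEEP_set: float
    autoPEEP_1: float
    autoPEEP_2: float
    Vt: float
    MV: float
    WOB_vt: float
    Rdyn: float | None = None
    Cdyn: float | None = None
    Z: float | None = None
    steady: bool = True
    warning: str = ""


def breath_metrics(trace: BreathTrace, settings: VentSettings,
                   wob_reference: str = "above-peep") -> BreathMetrics:
    """Compute the monitor channels for one steady cycle.

    PIP is the cycle maximum of the airway-opening pressure and MAP its
    time average over the full cycle.  Tidal volume is the volume expired at
    the airway opening (integral of the expiratory flow), minute ventilation
    is ``Vt * RR``.  WOB_vt integrates the inspiratory airway pressure over
    inspired volume and normalises by Vt.  The default references pressure to
    set PEEP (work the ventilator performs above the expiratory baseline),
    which matches the magnitudes respiratory monitors report at neonatal
    settings; ``wob_reference="absolute"`` integrates absolute airway
    pressure instead and yields systematically higher values (by
    ``PEEP * 0.0980665`` J/l exactly).  Auto-PEEP of each compartment is its
    end-expiratory alveolar pressure in excess of set PEEP.
    """
    if wob_reference not in ("absolute", "above-peep"):
        raise ValueError(f"unknown wob_reference {wob_reference!r}")
    t, pao, q = trace.t, trace.Pao, trace.Q
    T = trace.Ti + trace.Te
    pip_meas = float(np.max(pao))
    map_ = float(np.trapezoid(pao, t) / T)

    insp = slice(0, trace.i_exp)
    exp_ = slice(trace.i_exp, None)
    vt_l = float(np.trapezoid(-q[exp_], t[exp_]))
    vt_l = max(vt_l, 0.0)

    warning = "" if trace.steady else "non-steady cycle"
    p_work = pao if wob_reference == "absolute" else pao - settings.PEEP
    pdv = float(np.trapezoid(p_work[insp] * q[insp], t[insp]))  # cmH2O*l
    if vt_l > 0:
        wob = pdv / vt_l * CMH2O_L_TO_J
    else:
        wob = 0.0
        warning = (warning + "; " if warning else "") + "zero tidal volume"

    return BreathMetrics(
        PIP_meas=pip_meas,
        MAP=map_,
        PEEP_set=settings.PEEP,
        autoPEEP_1=float(trace.P_A1[-1] - settings.PEEP),
        autoPEEP_2=float(trace.P_A2[-1] - settings.PEEP),
        Vt=vt_l * 1000.0,
        MV=vt_l * settings.RR,
        WOB_vt=wob,
        steady=trace.steady,
        warning=warning,
    )


def fit_dynamic_rc(trace: BreathTrace) -> tuple[float, float]:
    """Dynamic R and C by fitting the single-compartment equation of motion.

    Least-squares fit of ``Pao(t) = Rdyn*Q(t) + V(t)/Cdyn + P0`` over every
    sample of the cycle, with ``V = V1 + V2`` re-zeroed at the cycle start —
    the regression a respiratory monitor applies to the proximal pressure and
    flow signals.  For inhomogeneous lungs the fitted ``Cdyn`` falls below the
    static series compliance as the breathing frequency rises (the classic
    frequency dependence of dynamic compliance), and ``Rdyn`` exceeds the
    static resistance; both effects grow with T1/T2.

    Returns ``(Rdyn, Cdyn)`` with Cdyn in ml/cmH2O.
    """
    q = trace.Q
    v = (trace.V1 + trace.V2) - (trace.V1[0] + trace.V2[0])
    if float(np.std(q)) <= 1e-12 * max(1.0, float(np.max(np.abs(q)))) or np.allclose(q, 0.0):
        raise ValueError("degenerate regressor: flow Q is constant over the cycle")
    if float(np.std(v)) <= 1e-15:
        raise ValueError("degenerate regressor: volume V is constant over the cycle")
    design = np.column_stack([q, v, np.ones_like(q)])
    coef, _, rank, _ = np.linalg.lstsq(design, trace.Pao, rcond=None)
    if rank < 3:
        raise ValueError("degenerate regressor: rank-deficient equation-of-motion design")
    rdyn, elastance = float(coef[0]), float(coef[1])
    if elastance <= 0:
        raise ValueError("equation-of-motion fit produced non-positive elastance")
    cdyn_ml = 1000.0 / elastance
    return rdyn, cdyn_ml


def compute_impedance(R: float, C: float, RR: float) -> float:
    """Respiratory-system impedance magnitude at the breathing frequency.

    ``Z = sqrt(R^2 + (1/(2*pi*f*C))^2)`` with ``f = RR/60`` Hz and ``C`` given
    in ml/cmH2O (converted to l/cmH2O internally); inertance is omitted, a
    good approximation below 60 breaths/min (< 1 Hz).  Returned in cmH2O*s/l.
    """
    for name, v in (("R", R), ("C", C), ("RR", RR)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
    f = RR / 60.0
    c_l = C / 1000.0
    return math.hypot(R, 1.0 / (2.0 * math.pi * f * c_l))


def with_dynamic_channels(metrics: BreathMetrics, trace: BreathTrace) -> BreathMetrics:
    """Attach Rdyn, Cdyn and the Z derived from them to a metrics record."""
    rdyn, cdyn = fit_dynamic_rc(trace)
    z = compute_impedance(rdyn, cdyn, trace.RR)
    return replace(metrics, Rdyn=rdyn, Cdyn=cdyn, Z=z)
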