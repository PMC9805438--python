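"""Lumped-parameter mechanics of the passively ventilated neonatal respiratory system.

The model is a two-compartment electrical-analogue circuit: a common airway
(resistance ``Rc``, optional inertance ``L``) feeds two parallel lung
compartments, each a peripheral resistance ``Rk`` in series with a lung
compliance ``Ck``; both compartments empty into a shared chest-wall
compliance ``Cw`` that sets the pleural pressure.  Regional inhomogeneity is
quantified by the ratio of the compartment time constants
``T1/T2 = (R1*C1)/(R2*C2)`` — 1 for homogeneous lungs, larger values for
increasingly unequal gas-flow dynamics (in congenital diaphragmatic hernia
the ipsilateral lung is the more hypoplastic one).

Pressure-controlled ventilation (PCV) is imposed as an airway-opening
pressure waveform: a linear ramp from PEEP to the set inspiratory plateau
over ``rise_time``, a plateau at PIP for the rest of inspiration, and an
instantaneous release to PEEP for expiration.

Because the circuit is linear and the drive is piecewise linear in time, the
state (compartment volumes, and flow when inertance is enabled) admits an
exact per-phase solution.  ``simulate_to_steady_cycle`` propagates that
solution cycle by cycle from empty lungs until the breath is periodic, then
returns one densely sampled steady cycle.

Units follow bedside convention: pressures in cmH2O, flows in l/s,
volumes in l, resistances in cmH2O*s/l, compliances in l/cmH2O internally
(constructors accept ml/cmH2O where noted), inertance in cmH2O*s^2/l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PatientParams",
    "VentSettings",
    "SimConfig",
    "BreathTrace",
    "make_patient",
    "pcv_waveform",
    "simulate_to_steady_cycle",
]

#: default pressure rise time, s.  Calibrated so the minute-ventilation-
#: targeted PIP of the reference homogeneous-lung neonate (C = 1.14 ml/cmH2O,
#: Cw/CL = 5.3, Rc = 131, R1 = R2 = 88 cmH2O*s/l, RR = 50, I:E = 1:2,
#: PEEP = 5, MV = 0.8 l/min) lands on the clinically reported ~24.4 cmH2O;
#: also a realistic neonatal PCV pressure-slope setting.
DEFAULT_RISE_TIME = 0.25


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PatientParams:
    """Circuit constants of the two-compartment respiratory system.

    Compartment 1 is, by convention, the slower lung: instances are
    relabelled on construction so that ``T1 >= T2`` and the
    inhomogeneity index ``t1_over_t2`` is always >= 1.

    Compliances are stored in l/cmH2O.
    """

    Rc: float
    R1: float
    R2: float
    C1: float
    C2: float
    Cw: float
    L: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        _require_positive(Rc=self.Rc, R1=self.R1, R2=self.R2,
                          C1=self.C1, C2=self.C2, Cw=self.Cw)
        if self.L < 0 or not math.isfinite(self.L):
            raise ValueError(f"L must be non-negative and finite, got {self.L!r}")
        if self.R1 * self.C1 < self.R2 * self.C2:
            r1, c1 = self.R1, self.C1
            object.__setattr__(self, "R1", self.R2)
            object.__setattr__(self, "C1", self.C2)
            object.__setattr__(self, "R2", r1)
            object.__setattr__(self, "C2", c1)

    @property
    def CL(self) -> float:
        """Total lung compliance, l/cmH2O (parallel compartments)."""
        return self.C1 + self.C2

    @property
    def Cstat(self) -> float:
        """Total static respiratory-system compliance, l/cmH2O (lungs in series with chest wall)."""
        return self.CL * self.Cw / (self.CL + self.Cw)

    @property
    def Rstat(self) -> float:
        """Total static resistance, cmH2O*s/l: central plus parallel peripheral."""
        return self.Rc + self.R1 * self.R2 / (self.R1 + self.R2)

    @property
    def T1(self) -> float:
        """Time constant of the slow compartment, s."""
        return self.R1 * self.C1

    @property
    def T2(self) -> float:
        """Time constant of the fast compartment, s."""
        return self.R2 * self.C2

    @property
    def t1_over_t2(self) -> float:
        """Ventilation-inhomogeneity index T1/T2 (>= 1 by the relabelling convention)."""
        return self.T1 / self.T2


def make_patient(
    c_total: float,
    cw_over_cl: float,
    t1_over_t2: float,
    rc: float,
    r_periph_each: float,
    L: float = 0.0,
    mode: str = "compliance-split",
    label: str = "",
) -> PatientParams:
    """Build a patient from bedside-style totals.

    Parameters
    ----------
    c_total
        Total static respiratory-system compliance, **ml/cmH2O** (the number a
        ventilator monitor displays, e.g. 1.14 for a ~3.6 kg CDH neonate).
    cw_over_cl
        Chest-wall to total-lung compliance ratio ``k``.  The lung and wall
        compliances are recovered from the series relation:
        ``CL = c_total*(1+k)/k`` and ``Cw = c_total*(1+k)``.
    t1_over_t2
        Requested inhomogeneity index.
    rc, r_periph_each
        Central resistance and the common peripheral resistance
        (``R1 = R2 = r_periph_each`` in the default mode), cmH2O*s/l.
    mode
        ``"compliance-split"`` (default): impose the index through the
        compliance asymmetry ``C1/C2 = t1_over_t2`` at fixed ``CL`` and equal
        peripheral resistances.  ``"resistance-split"``: keep ``C1 = C2`` and
        vary ``R1/R2`` instead, preserving the parallel resistance
        ``r_periph_each/2`` (and hence the static total).
    """
    _require_positive(c_total=c_total, cw_over_cl=cw_over_cl,
                      t1_over_t2=t1_over_t2, rc=rc, r_periph_each=r_periph_each)
    k = cw_over_cl
    cl_ml = c_total * (1.0 + k) / k
    cw_ml = c_total * (1.0 + k)
    r = t1_over_t2
    if mode == "compliance-split":
        c1_ml = cl_ml * r / (1.0 + r)
        c2_ml = cl_ml / (1.0 + r)
        r1 = r2 = r_periph_each
    elif mode == "resistance-split":
        c1_ml = c2_ml = cl_ml / 2.0
        r2 = r_periph_each * (1.0 + r) / (2.0 * r)
        r1 = r * r2
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'compliance-split' or 'resistance-split')")
    return PatientParams(Rc=rc, R1=r1, R2=r2,
                         C1=c1_ml / 1000.0, C2=c2_ml / 1000.0, Cw=cw_ml / 1000.0,
                         L=L, label=label)


@dataclass(frozen=True)
class VentSettings:
    """Pressure-controlled ventilation settings.

    ``IE`` is the inspiratory:expiratory time ratio as an ``(i, e)`` pair,
    e.g. ``(1, 2)``; ``rise_time`` is the duration of the linear PEEP->PIP
    ramp at inspiration onset.
    """

    RR: float
    PIP: float
    PEEP: float = 5.0
    IE: tuple[float, float] = (1.0, 2.0)
    rise_time: float = DEFAULT_RISE_TIME
    MV_target: float | None = None

    def __post_init__(self) -> None:
        _require_positive(RR=self.RR)
        i, e = self.IE
        _require_positive(**{"IE inspiratory part": i, "IE expiratory part": e})
        if not (self.PIP >= self.PEEP >= 0):
            raise ValueError(f"need PIP >= PEEP >= 0, got PIP={self.PIP}, PEEP={self.PEEP}")
        if not (0 <= self.rise_time < self.Ti):
            raise ValueError(f"rise_time must satisfy 0 <= rise_time < Ti={self.Ti:.4f} s, got {self.rise_time}")
        if self.MV_target is not None and not self.MV_target > 0:
            raise ValueError(f"MV_target must be positive, got {self.MV_target!r}")

    @property
    def period(self) -> float:
        """Cycle period 60/RR, s."""
        return 60.0 / self.RR

    @property
    def Ti(self) -> float:
        """Inspiratory time, s."""
        i, e = self.IE
        return self.period * i / (i + e)

    @property
    def Te(self) -> float:
        """Expiratory time, s."""
        return self.period - self.Ti


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of the steady-cycle simulator."""

    dt: float = 1e-3
    max_cycles: int = 50
    steady_tol: float = 1e-6
    use_inertance: bool = False

    def __post_init__(self) -> None:
        _require_positive(dt=self.dt, steady_tol=self.steady_tol)
        if self.max_cycles < 2:
            raise ValueError(f"max_cycles must be >= 2, got {self.max_cycles}")


def pcv_waveform(settings: VentSettings, t):
    """Airway-opening pressure of the PCV waveform at time(s) ``t`` within one cycle.

    Defined for ``0 <= t < T`` (``t == T`` is tolerated and treated as
    end-expiration): a linear PEEP->PIP ramp on ``[0, rise_time)``, the PIP
    plateau on ``[rise_time, Ti)`` and PEEP on ``[Ti, T)``.
    """
    t_arr = np.asarray(t, dtype=float)
    T = settings.period
    if np.any((t_arr < 0) | (t_arr > T * (1 + 1e-12))):
        raise ValueError("t must lie within one cycle, 0 <= t <= 60/RR")
    if settings.rise_time > 0:
        ramp = settings.PEEP + (settings.PIP - settings.PEEP) * t_arr / settings.rise_time
    else:
        ramp = np.full_like(t_arr, settings.PIP)
    pao = np.where(
        t_arr < settings.rise_time, ramp,
        np.where(t_arr < settings.Ti, settings.PIP, settings.PEEP),
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(pao)
    return pao


@dataclass(eq=False)
class BreathTrace:
    """One steady PCV cycle, densely sampled.

    All arrays share the sample axis.  Phase boundaries (end of ramp, end of
    inspiration) are stored twice — once with the left-limit airway pressure
    and once with the right limit — so that trapezoidal integrals across the
    expiratory pressure release are exact.  ``i_exp`` is the index of the
    first expiratory sample.

    Volumes are referenced to zero transrespiratory pressure, so a positive
    end-expiratory volume reflects the PEEP (plus any intrinsic auto-PEEP)
    baseline.
    """

    t: np.ndarray
    Pao: np.ndarray
    Q: np.ndarray
    Q1: np.ndarray
    Q2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    P_A1: np.ndarray
    P_A2: np.ndarray
    P_pl: np.ndarray
    Ti: float
    Te: float
    RR: float
    i_exp: int
    steady: bool
    n_cycles: int
    params: PatientParams = field(repr=False)
    settings: VentSettings = field(repr=False)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "Pao": self.Pao, "Q": self.Q, "Q1": self.Q1,
            "Q2": self.Q2, "V1": self.V1, "V2": self.V2,
            "P_A1": self.P_A1, "P_A2": self.P_A2, "P_pl": self.P_pl,
        })


# ---------------------------------------------------------------------------
# linear-system assembly


def _system_matrices(p: PatientParams, use_inertance: bool):
    """State matrix A and drive vector b of dx/dt = A x + b * Pao(t).

    State is (V1, V2) for the resistive-compliant model, (V1, V2, Q) when
    the central inertance is included.
    """
    if use_inertance and p.L > 0:
        g = 1.0 / p.R1 + 1.0 / p.R2

        def rhs(x, pao):
            v1, v2, q = x
            p_pl = (v1 + v2) / p.Cw
            pa1 = v1 / p.C1 + p_pl
            pa2 = v2 / p.C2 + p_pl
            pj = (pa1 / p.R1 + pa2 / p.R2 + q) / g
            return np.array([
                (pj - pa1) / p.R1,
                (pj - pa2) / p.R2,
                (pao - p.Rc * q - pj) / p.L,
            ])

        n = 3
    else:
        m = np.array([[p.Rc + p.R1, p.Rc], [p.Rc, p.Rc + p.R2]])
        minv = np.linalg.inv(m)
        e = np.array([[1.0 / p.C1 + 1.0 / p.Cw, 1.0 / p.Cw],
                      [1.0 / p.Cw, 1.0 / p.C2 + 1.0 / p.Cw]])

        def rhs(x, pao):
            return minv @ (pao - e @ np.asarray(x, dtype=float))

        n = 2
    a = np.column_stack([rhs(np.eye(n)[i], 0.0) for i in range(n)])
    b = rhs(np.zeros(n), 1.0)
    return a, b


def _flows(p: PatientParams, use_inertance: bool, X: np.ndarray, pao: np.ndarray):
    """Per-sample flows and pressures from states X (n_state x n_samples)."""
    v1, v2 = X[0], X[1]
    p_pl = (v1 + v2) / p.Cw
    pa1 = v1 / p.C1 + p_pl
    pa2 = v2 / p.C2 + p_pl
    if use_inertance and p.L > 0:
        q = X[2]
        g = 1.0 / p.R1 + 1.0 / p.R2
        pj = (pa1 / p.R1 + pa2 / p.R2 + q) / g
        q1 = (pj - pa1) / p.R1
        q2 = (pj - pa2) / p.R2
    else:
        m = np.array([[p.Rc + p.R1, p.Rc], [p.Rc, p.Rc + p.R2]])
        minv = np.linalg.inv(m)
        q1, q2 = minv @ np.vstack([pao - pa1, pao - pa2])
        q = q1 + q2
    return q, q1, q2, pa1, pa2, p_pl


class _PhasePropagator:
    """Exact propagation of dx/dt = A x + b*(p0 + slope*s) over a phase.

    Uses the eigendecomposition of A with the closed-form particular
    solution for a ramp input; falls back to stepping with the matrix
    exponential of an augmented system when A is (near-)defective.
    """

    def __init__(self, a: np.ndarray, b: np.ndarray):
        self.a = a
        self.b = b
        self.n = a.shape[0]
        self.ainv = np.linalg.inv(a)
        w, vec = np.linalg.eig(a)
        ok = np.linalg.cond(vec) < 1e10
        if ok and self.n > 1:
            scale = np.max(np.abs(w))
            gaps = np.abs(w[:, None] - w[None, :])[~np.eye(self.n, dtype=bool)]
            ok = np.min(gaps) > 1e-9 * scale
        self._diagonalizable = bool(ok)
        if self._diagonalizable:
            self.w = w
            self.vec = vec
            self.vinv = np.linalg.inv(vec)

    def __call__(self, x0: np.ndarray, p0: float, slope: float, s: np.ndarray) -> np.ndarray:
        """States at offsets ``s`` (sorted, >= 0) from the phase start; shape (n, len(s))."""
        c1 = -self.ainv @ self.b * slope
        c0 = self.ainv @ (c1 - self.b * p0)
        if self._diagonalizable:
            coef = self.vinv @ (x0 - c0)
            modes = np.exp(np.outer(self.w, s)) * coef[:, None]
            x = (self.vec @ modes).real
        else:  # pragma: no cover - defective A only at contrived parameter sets
            naug = self.n + 2
            aaug = np.zeros((naug, naug))
            aaug[: self.n, : self.n] = self.a
            aaug[: self.n, self.n] = self.b
            aaug[self.n, self.n + 1] = slope
            z = np.concatenate([x0, [p0, 1.0]])
            cols = []
            prev = 0.0
            for si in s:
                z = expm(aaug * (si - prev)) @ z
                prev = si
                cols.append(z[: self.n])
            x = np.array(cols).T
        return x + c0[:, None] + c1[:, None] * s


def _phases(settings: VentSettings) -> list[tuple[float, float, float]]:
    """(duration, Pao at phase start, dPao/dt) for ramp, plateau, expiration."""
    out = []
    if settings.rise_time > 0:
        out.append((settings.rise_time, settings.PEEP,
                    (settings.PIP - settings.PEEP) / settings.rise_time))
    out.append((settings.Ti - settings.rise_time, settings.PIP, 0.0))
    out.append((settings.Te, settings.PEEP, 0.0))
    return out


def simulate_to_steady_cycle(
    params: PatientParams,
    settings: VentSettings,
    cfg: SimConfig | None = None,
) -> BreathTrace:
    """Integrate the circuit under PCV from empty lungs to a periodic breath.

    The run-in is propagated cycle by cycle using only the exact phase-end
    states (cheap); once the start/end compartment volumes of a cycle agree
    to ``cfg.steady_tol`` (relative to the cycle's volume excursion), that
    cycle is re-propagated with dense sampling at ``cfg.dt`` and returned.
    If ``max_cycles`` is exhausted the last cycle is returned with
    ``steady=False``.
    """
    cfg = cfg or SimConfig()
    use_l = cfg.use_inertance and params.L > 0
    a, b = _system_matrices(params, use_l)
    prop = _PhasePropagator(a, b)
    phases = _phases(settings)

    n = a.shape[0]
    x = np.zeros(n)
    steady = False
    n_cycles = 0
    x_cycle_start = x.copy()
    for cycle in range(cfg.max_cycles):
        x_cycle_start = x.copy()
        vmax = np.abs(x[:2])
        for dur, p0, slope in phases:
            x = prop(x, p0, slope, np.array([dur]))[:, 0]
            vmax = np.maximum(vmax, np.abs(x[:2]))
        n_cycles = cycle + 1
        mismatch = np.abs(x[:2] - x_cycle_start[:2]) / np.maximum(vmax, 1e-12)
        if np.all(mismatch <= cfg.steady_tol):
            steady = True
            break

    # dense resampling of the (near-)steady cycle from its recorded start state
    ts, paos, xs = [], [], []
    t0 = 0.0
    xi = x_cycle_start
    i_exp = None
    count = 0
    for k, (dur, p0, slope) in enumerate(phases):
        m = max(1, int(math.ceil(dur / cfg.dt - 1e-9)))
        s = np.linspace(0.0, dur, m + 1)
        X = prop(xi, p0, slope, s)
        ts.append(t0 + s)
        paos.append(p0 + slope * s)
        xs.append(X)
        xi = X[:, -1]
        t0 += dur
        if k == len(phases) - 2:  # next phase is expiration
            i_exp = count + len(s)
        count += len(s)

    t = np.concatenate(ts)
    pao = np.concatenate(paos)
    X = np.hstack(xs)
    q, q1, q2, pa1, pa2, p_pl = _flows(params, use_l, X, pao)

    return BreathTrace(
        t=t, Pao=pao, Q=q, Q1=q1, Q2=q2, V1=X[0], V2=X[1],
        P_A1=pa1, P_A2=pa2, P_pl=p_pl,
        Ti=settings.Ti, Te=settings.Te, RR=settings.RR,
        i_exp=int(i_exp), steady=steady, n_cycles=n_cycles,
        params=params, settings=settings,
    )
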