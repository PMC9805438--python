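# Methods

## Model

The respiratory system is a linear lumped-parameter circuit: airway-opening
pressure `Pao` drives a common airway with resistance `Rc` (and optional
inertance `L`), which branches into two parallel lung compartments, each a
peripheral resistance `Rk` in series with a lung compliance `Ck`. Both
compartment volumes displace a shared chest-wall compliance `Cw`, so the
pleural pressure is `P_pl = (V1+V2)/Cw` and each alveolar pressure is
`P_Ak = Vk/Ck + P_pl`. With `L = 0` the compartment flows solve the 2×2
node system

```
(Rc+R1)·Q1 + Rc·Q2 = Pao − P_A1
Rc·Q1 + (Rc+R2)·Q2 = Pao − P_A2
```

and the state is `(V1, V2)` with `dVk/dt = Qk`. With inertance the total
flow `Q` becomes a third state, `L·dQ/dt = Pao − Rc·Q − Pj` with `Pj` the
junction pressure. Assumptions: passive (paralysed/sedated) patient — no
spontaneous effort; constant compliances and resistances (no volume
dependence, no flow-dependent tube resistance); no gas exchange. Inertance
defaults to zero: below 60 breaths/min (< 1 Hz) its contribution to the
pressures is under 2% (verified by the sensitivity test with
`L = 0.1 cmH₂O·s²/l` at 55 bpm).

Inhomogeneity is parameterised by `T1/T2 = R1·C1/(R2·C2) ≥ 1` (compartment
1 is relabelled to be the slower lung on construction). `make_patient`
imposes the index through the compliance split `C1/C2 = T1/T2` at fixed
total lung compliance and equal peripheral resistances — the configuration
in which the clinical presets are stated — while a `resistance-split` mode
(`R1/R2` varied at `C1 = C2`, parallel resistance preserved) is available
for exploration. Bedside totals map to circuit values through the series
relation: given total compliance `C` and ratio `k = Cw/CL`,
`CL = C·(1+k)/k` and `Cw = C·(1+k)`.

## Ventilation waveform

PCV is an imposed airway-opening pressure: a linear ramp PEEP→PIP over
`rise_time`, a plateau at PIP until the end of inspiration
(`Ti = T·i/(i+e)`, `T = 60/RR`), and an instantaneous release to PEEP for
expiration. The ideal-source assumption means the set and measured PIP
coincide; a real ventilator's servo dynamics are not modelled.

`rise_time` defaults to 0.25 s. The value was calibrated once against the
clinically reported homogeneous-lung working point of the reference patient
(C = 1.14 ml/cmH₂O, Cw/CL = 5.3, Rc = 131, R1 = R2 = 88 cmH₂O·s/l, RR = 50,
I:E = 1:2, PEEP = 5, MV = 0.8 l/min), for which the solved PIP is then
24.50 cmH₂O against the reported ≈ 24.4; it is also a realistic neonatal
pressure-slope setting. It is configurable everywhere.

## Integration

The system is linear time-invariant within each waveform phase, with an
input affine in time, so each phase is solved exactly: eigendecomposition
of the state matrix plus the closed-form particular solution for a ramp
input, evaluated vectorised at all sample times (a matrix-exponential
stepping fallback covers near-defective matrices, which do not arise for
physiological parameters). There is no ODE-solver tolerance to tune and
stiffness is irrelevant.

Breaths start from `V = 0` (zero transrespiratory pressure) and are
propagated cycle by cycle using only phase-end states until the start/end
volumes of a cycle agree to `steady_tol = 1e−6` (relative to the cycle's
volume excursion); convergence takes < 10 cycles for neonatal time
constants (≤ ~0.5 s vs cycle ≥ 1.09 s), with `max_cycles = 50` as the
cap (a non-converged cycle is returned flagged, never silently). The steady
cycle is then resampled densely at `dt = 1 ms` per phase, *including both
one-sided samples at each phase boundary*, so trapezoidal integrals across
the expiratory pressure jump are exact and all reported integrals are
second-order accurate (halving `dt` moves PIP/MAP/WOB/Vt by < 0.2%).

## Monitor emulation

- **PIP**: cycle maximum of `Pao`. **MAP**: time average of `Pao` over the
  full cycle, expiration included (standard ventilator convention).
- **Vt**: volume expired at the airway opening (integral of expiratory
  flow), reported in ml; **MV = Vt·RR** in l/min. On steady cycles inspired
  and expired volumes agree to < 0.5%.
- **WOB_vt**: `∫ (Pao − PEEP) dV` over inspiration, normalised by Vt and
  converted with 1 cmH₂O·l = 0.0980665 J. Referencing to set PEEP (work
  done above the expiratory baseline) reproduces the magnitudes neonatal
  monitors report at these settings (~1.5–2 J/l); the absolute-pressure
  convention is available via `wob_reference="absolute"` and is exactly
  `PEEP × 0.0980665` J/l higher.
- **Dynamic R/C**: least-squares fit of the single-compartment equation of
  motion `Pao = Rdyn·Q + V/Cdyn + P0` over the whole sampled cycle (the
  regression respiratory monitors apply), V re-zeroed at the cycle start.
  For homogeneous lungs this recovers the static totals near-exactly; with
  inhomogeneity `Cdyn` falls below the static series compliance and `Rdyn`
  rises above the static resistance — the frequency dependence of dynamic
  compliance that makes the monitor-visible quantities informative about
  T1/T2 in the first place.
- **Impedance**: `Z = √(Rdyn² + (1/(2πf·Cdyn))²)` at the breathing
  frequency `f = RR/60`, inertance omitted (negligible below 1 Hz).
- **Auto-PEEP**: end-expiratory alveolar pressure of each compartment minus
  set PEEP; non-negative, and larger in the slow compartment for
  T1/T2 > 1 (gas trapping in the longer-time-constant lung).

## Protocol

Sweeps hold the patient's total compliance, resistance split, PEEP, I:E,
rise time and minute ventilation fixed and traverse the factorial grid
T1/T2 ∈ {1, 1.5, 2, 3, 4, 5, 7, 10, 100} × RR ∈ {35…55} × Cw/CL. The 100
point is a hypothetical asymptote used to anchor the saturation of the
characteristics; it enters correlations but is excluded from curve fits.
At every grid point the set PIP is re-solved so the steady-cycle MV meets
the target (default 0.8 l/min) to 0.5% — tighter than the ±0.1 l/min
clinical band, for determinism. MV is exactly linear in the driving
pressure in a linear circuit, so one proportional update from a single
probe normally lands on the root; a bracketed Brent solve over
PIP − PEEP ∈ [0.1, 80] cmH₂O is the verified fallback.

Clinical presets: P1 (R = 244 cmH₂O·s/l, C = 0.8 ml/cmH₂O, PEEP 4, RR 45,
Cw/CL 15), P2 (188, 1.26, PEEP 6, RR 50, Cw/CL 12), P3 (205, 1.14, PEEP 5,
RR 45, Cw/CL ∈ {5, 8, 12}), all I:E = 1:2. P3's central/peripheral split is
Rc = 131 with R1 = R2 = 88; P1/P2 splits are scaled proportionally from it
(no independent values are available). The printed monitor R (205) is a
*dynamic* quantity; the static circuit total is Rc + R1‖R2 = 175, and the
gap is an output of the measurement model, not a parameter to force.

## Statistics

Spearman coefficients use average ranks with the two-sided t-approximation
P-level (`scipy.stats.spearmanr`); constant inputs are rejected, and
|Rs| = 1 reports p = 0. Coefficient differences use the two-sample Fisher-z
test — the classical choice for independent correlation estimates; strata
from a noiseless simulation can be exactly ±1, which the grouped report
clamps to ±0.9999 before the transform. Polynomial characteristics are
ordinary least squares on raw (x, y), degree chosen as the smallest of
{2, 3} reaching R² ≥ 0.99 (else 3); P-values carry no multiple-testing
correction, mirroring how such screening analyses are reported.

## Bedside workflow

Calibration fits per-RR characteristics of Z, PIP, MAP and WOB_vt against
T1/T2 over [1, 10] from a constant-MV sweep of a matching patient class. A
Z fit that is non-monotone on the domain is refitted at successively lower
degree (monotonicity makes the inversion well posed); an irreducibly
non-monotone fit is an error. Inversion solves `f(x) = Z` by bracketed root
finding; out-of-domain impedances are clamped to the nearest domain edge
and flagged (`below-domain` / `extrapolated`) rather than extrapolated — a
deliberate conservative choice, as the characteristics are only validated
in-domain. A requested rate within 2.5 bpm (half the grid step) of a
calibrated rate uses that curve with a `nearest-RR` flag. The strategy flag
is `consider-HFV` iff the predicted PIP strictly exceeds the configurable
protective limit, default 27 cmH₂O (upper edge of the recommended
25 ± 2 cmH₂O ceiling for CDH neonates). The tool is a research
reproduction of the proposed procedure, not a clinical device.

## What the simulator does and does not emulate

The package replaces a hybrid (numerical-physical) bench: an ideal pressure
source plays the ventilator and the circuit is purely numerical.
Consequences worth knowing:

- Within-stratum correlations of the burden variables with T1/T2 are
  exactly 1 (deterministic monotone characteristics); reported minima ≥ 0.7
  / ≥ 0.8 are therefore met trivially, and passing them demonstrates the
  *structure* (stratification effect, signs, saturation) rather than
  measurement noise robustness.
- The sensitivity of PIP and WOB to the index is that of the ideal lumped
  circuit: ~7% PIP and ~10% WOB rise for T1/T2 1 → 10 at RR 50 under
  constant MV. Bench measurements with a real ventilator report roughly
  double these relative changes; servo/flow-limitation dynamics and
  hardware impedance are plausible contributors and are out of scope here.
- At the hypothetical asymptote T1/T2 = 100 the PIP-vs-RR trend reverses
  marginally (+0.06%) between 50 and 55 bpm — extreme gas trapping eroding
  the smaller-tidal-volume advantage of faster rates; over the
  physiological range 1–10 the anti-monotonicity is strict.
- For T1/T2 = 1 all outputs are invariant to the Cw/CL split at fixed total
  compliance (exact circuit reduction). Any apparent dependence in bench
  data at homogeneous settings is hardware-induced and is not reproduced.

## Problem sizes and runtime

A steady-cycle simulation costs ~0.5 ms; the default 9 × 5 sweep solves in
~0.1 s and the full 9 × 5 × 3 sweep with statistics in well under a minute.
The test suite and the acceptance script each run in a few seconds on one
CPU. All randomness-free; results are bit-reproducible across runs.
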