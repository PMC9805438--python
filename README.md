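# neovent

Lumped-parameter simulation of pressure-controlled ventilation (PCV) in
neonates with inhomogeneous lungs, and the **T₁/T₂ ventilation-inhomogeneity
index** workflow built on it.

In congenital diaphragmatic hernia (CDH) the two lungs are hypoplastic to
different degrees, so their regional time constants `T_k = R_k·C_k` differ
and ventilation becomes uneven: fast regions overdistend while slow regions
underventilate and trap gas. `neovent` models the ventilated respiratory
system as a two-compartment RLC circuit — a common airway (resistance `Rc`,
optional inertance `L`) feeding two parallel compartments (`R₁C₁`, `R₂C₂`)
behind a shared chest-wall compliance `C_w` — and quantifies inhomogeneity
by the index

```
T₁/T₂ = (R₁·C₁) / (R₂·C₂)   (≥ 1; 1 = homogeneous lungs)
```

The package answers two questions:

1. **Forward:** for a patient with given mechanics, how do the ventilation
   burden variables — peak and mean airway pressure (PIP, MAP), ventilator
   work of breathing per litre (WOB_vt) and respiratory-system impedance
   `Z = √(R² + (1/2πfC)²)` — grow with T₁/T₂ when minute ventilation is held
   constant?
2. **Inverse (bedside):** given only the monitor's dynamic R, C and the set
   rate, estimate T₁/T₂ by inverting the calibrated characteristic
   `Z = f(T₁/T₂)`, predict the PIP a constant-MV strategy will need, and
   flag the case for an early elective switch to high-frequency oscillation
   when that prediction exceeds the lung-protective ceiling (default
   27 cmH₂O).

The circuit is linear and the PCV drive piecewise linear, so breaths are
integrated *exactly* (per-phase eigendecomposition of the state matrix) to a
periodic steady cycle; monitor channels (PIP, MAP, Vt, MV, WOB_vt, dynamic
R/C by equation-of-motion regression, Z) are then emulated from the sampled
cycle. See `docs/methods.md` for the model, conventions and numerical
choices.

## Worked example

Solve the set PIP that delivers 0.8 l/min to the P3 preset (a 3.6 kg CDH
neonate: C = 1.14 ml/cmH₂O, R split Rc = 131, R₁ = R₂ = 88 cmH₂O·s/l) with
homogeneous lungs at RR = 50:

```
$ neovent simulate --patient P3 --t1t2 1 --rr 50 --mv 0.8
patient P3: T1/T2=1, RR=50 bpm, PEEP=5, PIP=24.50 cmH2O
  PIP                24.501 cmH2O
  MAP                 9.469 cmH2O
  Vt                 16.000 ml
  MV                  0.800 l/min
  WOB_vt              1.511 J/l
  Rdyn              175.000 cmH2O*s/l
  Cdyn                1.140 ml/cmH2O
  Z                 242.264 cmH2O*s/l
  autoPEEP slow       0.259 cmH2O
  autoPEEP fast       0.259 cmH2O
```

A 16 ml tidal volume at 24.5 cmH₂O is a typical protective-ventilation
working point for this weight; with homogeneous lungs the monitor's dynamic
R and C coincide with the static circuit totals (175 cmH₂O·s/l, 1.14
ml/cmH₂O). Raising the inhomogeneity to T₁/T₂ = 10 at the same minute
ventilation pushes the required PIP to 26.29 cmH₂O and WOB_vt to 1.66 J/l —
the pressure cost of inhomogeneity at constant CO₂ clearance.

The full study pipeline:

```sh
neovent sweep --patient P3 --out sweep.csv            # constant-MV grid: T1/T2 x RR
neovent analyze --sweep sweep.csv --out-corr corr.csv # stratified Spearman report
neovent calibrate --sweep sweep.csv --out cal.json    # per-RR characteristics
neovent bedside --calibration cal.json --r 205 --c 1.14 --rr 45
```

The bedside command prints the impedance, the estimated T₁/T₂, the
predicted PIP/MAP/WOB and a `CMV-ok` / `consider-HFV` strategy flag.

Everything is also available as a library (`neovent.make_patient`,
`simulate_to_steady_cycle`, `breath_metrics`, `run_sweep`,
`grouped_correlation_report`, `bedside_assess`, ...); sweeps come back as
pandas DataFrames.

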