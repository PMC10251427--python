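# ocuflow

A lumped-parameter (0D, electric-analog) steady-state model of aqueous humor
secretion, circulation, and drainage in the anterior segment of the human
eye. The model predicts intraocular pressure (IOP) under physiological and
pathological trabecular-meshwork (TM) resistance, with Hill-type saturation
laws for the two adaptive responses of the unconventional (uveoscleral)
outflow route: a pressure-dependent nonlinear conductance and a
drug-controlled flow source (topical prostaglandin-analog therapy).

The steady state of the full hydraulic circuit reduces to a scalar
fixed-point problem `x = T_m(x)` for the IOP, solved by Picard iteration
with a relative stopping rule (exact closed form in the linear regime), and
cross-checked by an independent bracketed root finder plus a numerical
contraction diagnostic.

## Layout

- `src/ocuflow/units_and_params.py` — unit conversions (mmHg/Pa, uL·min⁻¹ /
  m³·s⁻¹), baseline physiology record, Ohm's-law calibration of the four
  hydraulic conductances and all derived constants.
- `src/ocuflow/model_core.py` — Hill function, activation variable `Z(x)`,
  nonlinear unconventional conductance and drug source, the iteration map
  `T_m`, and full state recovery from a solved IOP.
- `src/ocuflow/solver.py` — fixed-point solver, closed-form linear solve,
  bracketed-root oracle, contraction diagnostic.
- `src/ocuflow/protocols.py` — the two-phase simulation protocol
  (resistance sweep; day-by-day drug therapy), analytic sensitivity
  `d(IOP)/d(eta)` for the linear regime, mass-conservation audit.
- `src/ocuflow/cli_io.py` — CLI, YAML/JSON configuration with strict
  validation, CSV + metadata-JSON serialization.

## CLI

```sh
# one steady state (baseline):
ocuflow single --eta 1 --day 0

# resistance sweep, nonlinear pressure route:
ocuflow phase1 --eta-max 3 --kappa-hyd 0.99 --out phase1.csv

# 14-day drug therapy at pathological resistance, linear route:
ocuflow phase2 --kappa-hyd 0 --out phase2.csv

# linear-regime sensitivity table and mass-conservation audit:
ocuflow sensitivity --out sensitivity.csv
ocuflow audit
```

All parameters can be overridden from a YAML/JSON file passed via
`--config`; unknown keys are rejected. Sweeps are written as
full-precision CSV plus a `.meta.json` with the complete effective
configuration (which round-trips into an identical run).

## Notes on regimes

- `kappa_hyd = 0`: the pressure-dependent route is a linear resistor; the
  map is constant in x and solved in closed form.
- `kappa_hyd = 0.99`: reference nonlinear regime; Picard converges in at
  most a couple dozen iterations everywhere in the protocol.
- `kappa_hyd = 10`: strong-gain regime; for some mid-course drug masses the
  map is locally repelling (|T'| > 1) and Picard cycles. The solver raises
  a non-convergence error carrying the contraction diagnostic; use
  `method="bracketed_root"` (or the root oracle directly) there.
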