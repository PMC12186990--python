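# cvsloppy

Which clinical measurements does a cardiovascular digital twin actually
need?  `cvsloppy` answers the off-line part of that question for a
closed-loop, four-chamber lumped-parameter (0D) circulation model: it
quantifies how the choice of experimental design — the set of discrete
metrics (blood-pressure ratio, ejection fractions, peak flows) and/or
continuous waveforms (flows, volumes, pressures) exposed to the analysis
— changes which of the model's 36 input parameters are identifiable, and
whether the system is *sloppy* (most parameter directions barely affect
the outputs) or *stiff* (a few directions dominate).

The pipeline:

1. **Simulate.**  Four time-varying-elastance chambers (Shi double-cosine
   activation), Ohmic diode valves, CRRCR systemic and pulmonary
   circulations; 8 ODEs in compartment volume, integrated with a
   numba-compiled adaptive Dormand–Prince 5(4) stepper at tolerances
   1e−6 over 30 cycles (period τ = 0.81 s).
2. **Measure.**  Evaluate an experimental design — one of 11 discrete,
   16 continuous or 26 mixed measurement sets that grow additively in
   clinical invasiveness — on the final, periodic cycle.
3. **Sensitivity.**  Total-order Sobol' indices over the ±50 % parameter
   box, estimated with the Jansen pick-and-freeze estimator on a
   scrambled Sobol' sequence (Saltelli A/B/AB_i construction, N(n+2)
   model solves), with bootstrap confidence intervals.
4. **Sloppiness & influence.**  Form the Fisher information matrix
   F = SᵀS from the m × 36 total-order matrix; the eigen-spectrum
   classifies sloppiness (log-uniform spread over ≥ 6 decades), and the
   eigenvalue-weighted influence score
   E_i = Σ_j |μ_j Q_ij| / Σ_j |μ_j| ∈ [0, 1] ranks parameters as
   biomarker candidates (reported when E > 0.01).

## Worked example

```python
import cvsloppy as cv

traj = cv.simulate(cv.table1())          # 30 cycles, baseline parameters
cyc = traj.extraction_slice()            # the final (periodic) cycle
p_sa = traj.signal("P_sa")[cyc]
print(f"arterial pressure {p_sa.min():.1f}..{p_sa.max():.1f} mmHg")
print(f"BP ratio {cv.blood_pressure_metric(p_sa):.3f}")
print(f"periodicity residual {cv.periodicity_residual(traj):.1e}")

result = cv.run_sweep(cv.SweepConfig(mode="discrete", sets=("1",),
                                     N=1024, seed=0))
for name, e in result.sets[0].ranking.ordered:
    print(f"{name:>10}  E = {e:.2f}")
```

prints

```
arterial pressure 62.2..126.1 mmHg
BP ratio 2.028
periodicity residual 3.3e-11
      C_sa  E = 0.79
     R_svb  E = 0.61
 tau_es_lv  E = 0.05
```

Read: the baseline model beats at a physiological 126/62 mmHg and is
periodic to 11 digits after 30 cycles.  With a cuff blood-pressure ratio
as the *only* measurement, just three parameters are influential
(E > 0.01): the systemic arterial compliance C_sa (E ≈ 0.8), the
systemic vascular-bed resistance R_svb (E ≈ 0.6) and, marginally, the
left-ventricular systolic timing.  Those are the biomarkers a BP-only
design could personalise; everything else is practically invisible to
it.  Adding waveform measurements (``mode="continuous"``) raises the
influential count to ~18+ and turns the eigen-spectrum into a
log-uniform ladder spanning 8–14 decades — a sloppy system.

A thin CLI mirrors the library:

```sh
cvsloppy simulate --out out/                      # trajectory CSV
cvsloppy designs list --mode mixed                # the measurement sets
cvsloppy sweep --mode discrete --samples 1024 --seed 0 --out out/
```

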