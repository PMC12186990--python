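# Methods

## The model

`cvsloppy` implements a closed-loop, zero-dimensional (lumped-parameter)
model of the human circulation with four actively contracting heart
chambers.  Each chamber k ∈ {lv, rv, la, ra} is a time-varying elastance
element

    P_k(t) = E_k(t) · (V_k(t) − V_{k,0}),
    E_k(t) = (E_max − E_min) · e(t̃) + E_min,
    t̃     = mod(t + (1 − E_shift) τ, τ),

with the double-cosine activation

    e(t̃) = ½(1 − cos(π t̃ / τ_es))                    0 ≤ t̃ < τ_es
           ½(1 + cos(π (t̃ − τ_es)/(τ_ep − τ_es)))     τ_es ≤ t̃ < τ_ep
           0                                           τ_ep ≤ t̃ < τ.

Valves are Ohmic diodes (flow (ΔP)/R when forward-biased, zero otherwise;
no regurgitation, no inertance).  Each circulation (systemic, pulmonary)
is a CRRCR chain: an arterial compliance node, arterial and vascular-bed
resistances in series, a venous compliance node, and a venous resistance
returning to the contralateral atrium.  The vascular-bed "compartments"
carry no compliance of their own; their pressures are the algebraic
mid-node values, e.g. P_svb = P_sa − Q_s R_sa.  Passive node pressures
follow the stressed-volume convention P = V/C, so the baseline initial
volumes produce physiological initial pressures (P_sa = 98.3/0.983 =
100 mmHg, P_sv ≈ 4, P_pa = 15, P_pv = 8 mmHg).  This convention fixes
only the pressure baseline; the dynamics are shift-invariant in the
volume offsets.

Eliminating the algebraic relations leaves 8 ODEs in compartment volume.
Total blood volume (919.996 mL at baseline) is conserved exactly by
construction, which the integrator must preserve to ≤ 1e−3 mL over 30
cycles — the primary regression guard on the solver.

### Parameters

38 parameters: 7 per chamber (E_max, E_min, V0, τ_es, τ_ep, E_shift,
R_valve) plus 6 resistances and 4 compliances of the circulations.  The
cardiac period is fixed at τ = 0.81 s and the ventricular activation
shifts are identically 0, leaving **36 varied parameters** for the global
analysis.  Timing parameters are stored in seconds (fraction of the cycle
× τ); activation shifts are dimensionless fractions of the cycle, so the
atrial value 0.85 delays the atrial peak by 85 % of a cycle.  Units:
elastances mmHg/mL, volumes mL, resistances mmHg·s/mL, compliances
mL/mmHg.

### Numerics

The right-hand side and a Dormand–Prince 5(4) adaptive stepper are
compiled with numba; default tolerances are rtol = atol = 1e−6 and the
stepper lands exactly on every output-grid time (150 samples per cycle by
default), so stored waveforms are solution values, not interpolants.  The
diode right-hand side is only piecewise smooth; it is evaluated pointwise
with no event detection, which the error controller absorbs at these
tolerances — verified by the refinement-stability test (halving the
tolerances moves last-cycle waveforms by < 1e−3 relative L2) and by a
cross-check against scipy's DOP853 at rtol = 1e−9.  Runs span 30 cycles
and measurements are read from the final cycle; the periodicity residual
(max relative L2 gap between the last two cycles, ~1e−11 at baseline)
certifies the periodic steady state.

Under ±50 % sampling a draw can invert the activation ordering
(τ_ep ≤ τ_es).  The ordered piecewise branches remain well defined (the
relaxation branch is empty; activation drops to 0 at τ_es), and such
draws are simulated by default, matching how conditional elastance
implementations behave.  A strict policy (`strict_timing=True`) instead
flags them as structured failures, which the ensemble layer removes by
paired complete-case deletion, aborting if fewer than 90 % of rows
survive.  With strict masking roughly half of all draws would be lost
(≈13 % of ventricular and ≈14 % of atrial timing pairs invert,
independently per chamber and per design point), which is why the
permissive policy is the default.

## Measurement sets

Clinical metrics: BP = max(P_sa)/min(P_sa) (a single scalar ratio);
EF = (max V − min V)/min V of a chamber volume trace — kept exactly in
this printed form, with a `denominator="max"` switch for the conventional
clinical definition; Max(Q) peak flows; full waveforms on a half-open
uniform grid over the extraction cycle; and BPN = BP·(1 + ε),
ε ~ N(0, 0.1), modelling a noisy at-home cuff reading.  Designs grow
additively in three modes — discrete (11 sets, ending at m = 11),
continuous (16 waveform sets, m = 16 × 150), mixed (26 sets; the
noise-free in-hospital BP of set 2 replaces the noisy set 1).  In the
mixed sequence, set 5H is the left-atrial volume waveform (completing
the four chamber volumes; V_ra is 5G) and set 6A is the left-ventricular
pressure (the first catheter measurement, preceding the systemic
arterial pressure of 6B).  The mixed library at 100 waveform points
yields m = 1609 for set 7D (9 scalars + 16 × 100).

## Global sensitivity analysis

Inputs are uniform on the box base·(1 ± 0.5) over the 36 varied
parameters.  Sampling uses the Saltelli pick-and-freeze construction: one
scrambled Sobol' sequence in 2n dimensions supplies the paired blocks A
and B (splitting columns — consecutive blocks of a single n-dimensional
sequence are deterministically coupled and break the estimators), and
AB_i replaces column i of A with column i of B, for N(n + 2) model
evaluations in total.  First and total-order indices use the Jansen
estimators with the pooled f(A), f(B) sample variance as V̂; 95 %
percentile-bootstrap intervals over rows are available (B = 1000 by
default).

Estimates are truncated to [0, 1], the definitional range of a variance
fraction.  This matters for heavy-tailed outputs — valve-flow samples
near the opening instant are zero for almost all draws — where the raw
ratio estimator can exceed 1 by orders of magnitude long before
convergence; a handful of such rows would otherwise contribute ~70× more
weight to F = SᵀS than all healthy rows combined.  Truncation bounds
their leverage without touching well-behaved entries.

Waveform outputs enter the sensitivity matrix as one row per time point
(continuous set 4D at 150 points gives S of size 2400 × 36); outputs
with exactly zero ensemble variance are flagged undefined and dropped
from F with a record, never silently zeroed.  The variance-weighted time
average (TAS) is provided as a reporting view of waveform sensitivities
and is not part of the Fisher-information path.

## Influence and sloppiness

F = SᵀS is built from the total-order matrix, symmetrised, and
eigen-decomposed (eigenvalues descending; eigenvector signs
canonicalised).  The influence of parameter i is

    E_i = Σ_j |μ_j Q_ij| / Σ_j |μ_j|,

summing over eigenvalues above the numerical-zero threshold
λ_max · n · ε_machine; 0 ≤ E_i ≤ 1, and parameters with unrounded
E > 0.01 are reported as influential (tables render 2 decimals).

The sloppiness verdict formalises "eigenvalues evenly spaced on a log
scale over many orders of magnitude": a spectrum is sloppy iff its
retained eigenvalues span ≥ 6 decades AND no single adjacent log10 gap
covers more than half of that span (the void fraction).  A
void-dominated spectrum is a cliff-and-cluster pattern — a few stiff
directions far above the rest — which is the stiff, identifiable
regime.  The guard is deliberately weak: individual gap sizes near the
bottom of the spectrum carry estimator noise (candidate statistics such
as max-gap/mean-gap or gaps inside a fixed top window moved by a factor
of two across scramble seeds at desk-scale N), whereas the span itself
separates the discrete (≤ 1.4 decades) and continuous (≥ 8 decades)
regimes with a wide margin.  Both knobs (6 decades, 1/2) are
conventions, exposed as arguments and reported in the diagnostics.

## Sweep and problem sizes

The design loop (define set → total-order S → F → influence + sloppiness
→ next set) shares one model-evaluation ensemble across every set of a
sweep: parameter draws depend only on the space, so per-set work is
column extraction, estimation and an n × n eigen-decomposition.  A
strict per-set resampling mode exists for independence checks and is
verified to give identical results.  All randomness (sequence scrambling,
BPN noise, bootstrap) derives from a single seed; a sweep is a pure
function of its configuration, and artefact CSVs are byte-identical
across reruns.

Desk-scale analyses and the acceptance script use N = 1024 (38,912
solves, roughly 9 minutes on one CPU); a full-scale study of this kind
would use N = 75,000 with 1000 bootstrap replicates, which is retained
as configuration.  At N = 1024 the estimator-oracle errors are below
0.02 and the headline influence values of the small designs are stable
to two decimals; influential-parameter *counts* near the 0.01 threshold
are the most delicate quantity — they are converged in this
implementation (identical at N = 256 and N = 1024) but sensitive to
modelling conventions (volume baselines, activation handling) that
differ between implementations of this model family.  See the test
suite for exactly which reproductions are asserted.

## What the generator does and does not emulate

All data are forward-generated by the model itself: noise-free metrics
and waveforms plus the single noisy metric BPN.  This isolates the
experimental-design question from data quality, but means the analysis
says nothing about measurement noise beyond BPN, operator variability,
model discrepancy, or pathological parameter regimes — conclusions about
real patient data require the noise-aware extension discussed in the
literature.  Within the ±50 % box some draws are unphysiological
(inverted activation timings, elastance crossings E_max < E_min);
they are simulated as-is by default and their handling is configurable.

## Known limitations

* No baroreflex, inertances, pericardium, septal coupling or pathology
  presets; fixed heart rate.
* The diode valves switch instantaneously; no valve dynamics or
  regurgitation.
* Influence counts near the 0.01 threshold are sensitive to the
  sensitivity-matrix noise floor at desk-scale N (see above).
* The bootstrap treats scrambled-QMC rows as exchangeable; intervals are
  mildly conservative.
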