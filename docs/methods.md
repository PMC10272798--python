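# Methods

## The model

`cuffsim` simulates what happens in the arm distal to an inflating
blood-pressure cuff, and what a PAT/PTT measurement chain (ECG R-peak to
finger PPG foot, radial ABP foot to PPG foot) would observe during the
inflation.

### Vessel mechanics

The brachial artery under the cuff is a collapsible tube whose luminal
cross-section follows

    A(Ptm) = d · [ln(a·Ptm + 3.3)]^(1 + e^(−c·Ptm))        [cm²]

with transmural pressure `Ptm` in mmHg, collapse slope `a` (mmHg⁻¹),
collapse steepness `c` (mmHg⁻¹) and area scale `d` (treating `A` as cm²).
Reference values: a = 0.03, c = 0.1, d = 0.08. Once the logarithm's argument
drops to 1 (deep collapse) the law is undefined; the area is clamped at
`A_min = 10⁻⁶ cm²` and the flow resistance capped at `R_max = 10⁹ mmHg·s/mL`
so the ODE right-hand side stays finite.

Two caveats of this law matter numerically and are handled explicitly:

* it is **locally non-monotone**: its full derivative dA/dPtm is negative in
  a narrow band around Ptm ≈ 0…12 mmHg at reference parameters (and the law
  even re-inflates transiently at low `a`). The finite-difference compliance
  (`area_compliance`, step 0.01 mmHg) reports this faithfully, clamped at 0.
* a Bramwell–Hill wave speed built on that full derivative would therefore
  be undefined or non-monotone exactly in the working range. The wave speed
  instead uses the **elastic compliance at fixed collapse state**,
  `dA/dP|_E = d·E·a·ln(u)^(E−1)/u` with `E = 1 + e^(−c·Ptm)` held constant
  during differentiation: the exponent's own pressure dependence describes
  the slow, quasi-static change of collapse state, while the pressure pulse
  rides on the elastic wall response at the current state. This derivative
  is strictly positive wherever the tube is open and gives a monotone
  `PWV(Ptm) = sqrt(A · dP/dA · 133.322 / ρ)` that falls smoothly to zero at
  collapse (ρ = 1060 kg/m³). At distended pressures (Ptm ≳ 50 mmHg) the two
  derivatives agree to ~0.1%, so the distinction only matters near and below
  zero transmural pressure.

Flow resistance of the cuffed segment is Poiseuille,
`R_art = 8ηL_cuff/(π r⁴)` with `r = sqrt(A/π)`, blood viscosity
η = 2.63×10⁻⁵ mmHg·s (≈3.5 mPa·s; the standard physiological value — the
governing publications do not fix it) and cuff length L_cuff.

### Circulation

The distal arm is two lumped compartments — arterial (C_art = 0.03 mL/mmHg)
and venous (C_ven = 30·C_art = 0.9 mL/mmHg) — fed through `R_art(Ptm)` from
a sinusoidal systemic pressure `P_sys(t) = MAP + (PP/2)·sin(2πf t)` and
drained through the microvascular resistance R_systemic = 100 mmHg·s/mL into
the brachial vein. The vein collapses once cuff pressure passes
~30 mmHg; this is a log-space sigmoid in cuff pressure from
R_ven = 10 mmHg·s/mL to R_max (center 30 mmHg, width 2 mmHg — smoothness
keeps the system non-stiff). Systemic venous pressure is fixed at 10 mmHg.

`R_art` is evaluated every step at the **proximal** transmural pressure
`Ptm = P_sys(t) − P_cuff(t)`. This choice (over, e.g., a proximal/distal
midpoint) is deliberate: with the proximal drive, the cuffed segment acts as
a pressure-gated valve once cuff pressure exceeds diastolic pressure —
systolic peaks keep refilling the distal node while diastolic backflow is
blocked — which produces the observed flattening of the distal waveform
toward systolic pressure before full occlusion, and the four canonical
stages of an inflation: (1) nothing below venous pressure; (2) venous
collapse, distal filling; (3) distal systolic attenuation as cuff pressure
approaches systolic pressure; (4) exponential relaxation of the isolated
compartments onto the equilibrium pressure
`P_eq = (C_art·P_a + C_ven·P_v)/(C_art + C_ven)` (charge conservation).

Integration is fixed-step explicit Euler at dt = 0.5 ms (dt ≤ 1 ms
enforced). The fastest time constant of the smoothed system is
C_art·(R_art‖R_sys) ≈ 10 ms, so Euler is comfortably stable; halving dt
changes no pressure sample by more than 0.1 mmHg on the reference run
(tested). A 10 s pre-roll from the near-steady initial condition
(P_art = MAP, P_ven = P_ven_sys) is discarded. The default protocol holds
6 s of baseline, ramps at 6 mmHg/s to SBP + 50 mmHg (guaranteeing full
occlusion) and holds 60 s (≈20 relaxation time constants, so P_eq is read at
the hold end under a |dP/dt| < 0.01 mmHg/s guard rather than extrapolated).

The batch engine integrates thousands of parameter sets simultaneously on a
common grid (rows with faster ramps simply hold longer at their maximum,
which leaves their metrics unchanged) and reduces each heartbeat to
SBP/DBP/mean on the fly, so a 8 000-run campaign needs ~130 MB and about
two to three minutes on one CPU.

### Per-beat metrics

Beats are consecutive one-period windows aligned to the systemic-sinusoid
troughs. All transit-time changes are referenced to the mean of the last
five pre-inflation beats.

The transit-time ("measurement") model evaluates the **nominal reference
tube law** for both segments; the sampled collapse parameters act on the
simulated artery only through `R_art` inside the ODE. Rationale: `a` and `c`
in the sensitivity analysis vary the *simulated vasculature*, while the
PAT/PTT extraction emulates a measurement chain operating with nominal
calibration constants; evaluating transit with per-row tube laws would make
every PAT/PTT metric scale as √a, a dependence the underlying study's
reported sensitivities exclude.

* `dPTT_distal` — the distal arm (arm length − cuff length, both under the
  foot-of-wave convention) evaluated at the per-beat distal diastolic
  pressure. This series derives from the simulated distal pressure and is
  defined for every beat, through occlusion and decay.
* `dPTT_cuff` — the cuffed segment's effective slowness is the average of
  its two bounding states, a two-point (trapezoidal) quadrature over the
  pressure swing the transmitted pulse samples: the reopening-foot state at
  `(DBP_sys + DBP_dist)/2 − P_cuff` and the crest state at
  `(SBP_sys + SBP_dist)/2 − P_cuff`, each floored at zero transmural
  pressure because a pinched segment reopens when upstream pressure crosses
  cuff pressure, so the wave effectively crosses at ≈0 transmural pressure.
  The single-state alternatives bracket the observed behaviour (pure-foot
  makes the maximum PAT change an almost deterministic function of cuff
  length; pure-crest makes it too noisy); the average is the standard
  first-order quadrature, not a fitted weight.
* `dPAT_total = dPTT_cuff + dPTT_distal`, exactly, wherever the pulse
  transmits; the pre-ejection period is constant during an inflation and
  cancels from all changes. PAT metrics use only transmitting beats; pulse
  transmission ends at `P_cuff ≥ SBP` (the oscillometric endpoint).

The six scalar responses of a run: max drop of distal PTT, max |total PAT
change|, max rises of distal MAP and DBP above baseline, P_eq, and the
onset margin `dPTT_onset = systemic MAP − P_cuff` at the first beat where
`dPTT_distal < −0.05 ms` sustained for 3 consecutive beats (fixed declared
thresholds; a distal-MAP criterion at +0.5 mmHg marks the same event within
two beats — the onsets are simultaneous by construction of the physics).
MAP here is the true beat average, which equals (SBP+DBP)/2 for the
sinusoidal drive (not the clinical DBP + PP/3 estimate).

### Sensitivity analysis

Six inputs are varied: a ~ U(0.017, 0.035), c ~ U(0.08, 0.14),
SBP ~ N(125, 15), PP ~ N(40, 5), inflation rate ~ U(4, 8) mmHg/s, cuff
length ~ U(0.1, 0.18) m; everything else stays at reference. A Saltelli
radial design on a scrambled Sobol sequence (A, B, and the k hybrid
matrices; N(k+2) rows, N a power of two; normal margins by exact inverse
CDF) feeds the batch simulator. First-order indices use the Saltelli-2010
estimator, total-order the Jansen estimator, with bootstrap (100 resamples
of the base rows) confidence half-widths. Both estimators reproduce the
analytic Ishigami and Sobol-g benchmarks within ±0.02 at N = 2¹⁴ (tested).
Draws with DBP within 5 mmHg of venous pressure are excluded as
non-physiological (≪1% of rows); exclusion is listwise per metric. Default
N = 1024; second-order indices are not reported (interactions are small:
ST − S1 < 0.04 for five of the six metrics).

## Synthetic-data generator (waveform toolkit)

`waveforms.synthesize_recording` emulates the clinical acquisition: ECG at
500 Hz (narrow unit R waves at beat starts), ABP and PPG at 125 Hz. ABP is
the simulated distal pressure; PPG places one template pulse per
transmitting beat with its foot at R + PEP + (cuff + distal transit), with
amplitude following the distal pulse pressure and a gap once transmission
stops. Optional additive white noise is expressed as a fraction of pulse
amplitude. Detection uses thresholded peak search (R) and intersecting
tangents (feet); the tangent foot carries a constant bias on a curved
upstroke which cancels in all baseline-referenced intervals. What this does
*not* emulate: real PPG/ECG morphology, motion and breathing artifacts,
beat-to-beat physiological variability — so passing round-trip tests show
the interval pipeline is correct, not that it is robust to clinical-grade
noise.

## Known limitations

* The onset metric is structurally fragile: in this model the distal PTT
  drop begins at the arterial attenuation knee, whose position
  `(3.3 − e)/a` moves by ~12 mmHg across the studied range of `a`. The
  collapse slope therefore retains a noticeable variance share of
  `dPTT_onset` (and inflates its ST − S1 gap) under every detection rule we
  examined; reported onset sensitivities should be read with that in mind.
* The distal node is bounded above by systolic pressure (every source
  feeding it is ≤ SBP), so the maximum distal MAP rise is capped at
  SBP − MAP ≈ PP/2 plus the venous contribution.
* Single-segment cuff artery, no wave reflection, no viscoelasticity, no
  deflation protocols, no venous return beyond the single collapsing vein.

## Problem sizes

Default campaign N = 1024 (8 192 simulations, ~2.5 min single-core); the
test suite runs the same pipeline at N = 512. The reference run integrates
~210 000 steps (0.5 ms over ~105 s of simulated time).
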