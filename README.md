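# cuffsim

Simulator of the vasculature response in the arm **distal to an inflating
blood-pressure cuff**, and of the pulse-arrival-time (PAT) / pulse-transit-
time (PTT) signals that response induces.

Cuff-based modulation of PAT/PTT is a candidate route to calibrating
cuffless, continuous blood-pressure surrogates: as the cuff inflates it
lowers the transmural pressure of the brachial artery (slowing the pulse
under the cuff) while venous collapse traps blood in the limb and raises
distal pressures (speeding the pulse beyond the cuff). Interpreting the
measured PAT response requires a model of both effects. `cuffsim`
implements that model and the analyses built on it:

* **Vessel mechanics** — a collapsible-tube law
  `A(Ptm) = d·[ln(a·Ptm + 3.3)]^(1+e^(−c·Ptm))`, Poiseuille resistance
  `R_art = 8ηL/(πr⁴)`, and a Bramwell–Hill wave speed
  `PWV = √(A·(dP/dA)/ρ)` on the elastic (fixed-collapse-state) compliance.
* **Circulation** — a two-compartment RC circuit of the distal arm
  (arterial and venous compliances, microvascular resistance, collapsing
  brachial vein) driven by a sinusoidal systemic pressure and a ramped
  cuff, integrated by a vectorized fixed-step engine:

      dP_art/dt = [P_sys/R_art − P_art(1/R_art + 1/R_sys) + P_ven/R_sys]/C_art
      dP_ven/dt = [P_art/R_sys − P_ven(1/R_sys + 1/R_ven) + P_ven,sys/R_ven]/C_ven

* **Response metrics** — per-beat ΔPTT_cuff, ΔPTT_distal and
  ΔPAT_total = ΔPTT_cuff + ΔPTT_distal, and six scalar summaries per
  inflation: max|ΔPTT_distal|, max|ΔPAT_total|, max|ΔMAP|, max|ΔDBP|, the
  post-occlusion equilibrium pressure P_eq, and the onset margin
  ΔPTT_onset = MAP − P_cuff at the first sustained distal-PTT drop.
* **Sensitivity analysis** — variance-based Sobol indices (Saltelli radial
  design on a scrambled low-discrepancy sequence; Saltelli-2010 / Jansen
  estimators with bootstrap confidence intervals) of all six metrics over
  the physiological parameter space (tube-law a and c, SBP, PP, inflation
  rate, cuff length).
* **Virtual experiments** — OLS regressions of the metrics on the sampled
  inputs and a controlled inflation-rate sweep.
* **Waveform toolkit** — synthetic ECG/ABP/PPG channels (500 / 125 Hz) with
  ground-truth fiducials, plus R-peak and intersecting-tangent foot
  detection to validate the interval-measurement pipeline end to end.

## Worked example

```python
from cuffsim import (SystemicInput, CuffProtocol, simulate, segment_beats,
                     compute_ptt_series, extract_metrics, detect_onset)

inp = SystemicInput()            # 120/80 mmHg, HR 60, venous 10 mmHg
res = simulate(inp, CuffProtocol())   # 6 mmHg/s ramp to SBP+50, hold 60 s
beats = segment_beats(res, inp)
ptt = compute_ptt_series(beats)
print(extract_metrics(res, beats, ptt, inp).as_dict())
print(detect_onset(beats, ptt))
```

prints

```
{'max_dptt_distal_ms': 8.785, 'max_dpat_total_ms': 22.573,
 'max_dmap_mmhg': 7.413, 'p_eq_mmhg': 36.579,
 'max_ddbp_mmhg': 17.257, 'dptt_onset_mmhg': -6.5}
(23, 106.5)
```

Reading: during this inflation the distal transit time drops by at most
8.8 ms (distal filling stiffens the downstream arteries), the total PAT
rises by up to 22.6 ms (dominated by the slowing under the cuff), distal
mean and diastolic pressures rise by 7.4 and 17.3 mmHg, and after full
occlusion both distal compartments relax onto 36.6 mmHg — the
compliance-weighted average of their pressures at occlusion. The distal
PTT drop becomes detectable at beat 23, when cuff pressure is 106.5 mmHg —
6.5 mmHg above the systemic MAP of 100 mmHg (hence the negative onset
margin).

The same pipeline is scriptable from the shell:

```bash
cuffsim simulate --out run.csv
cuffsim metrics --in run.csv --out metrics.json
cuffsim sobol --n 1024 --seed 7 --out sobol.json
cuffsim experiment inflation-rate --out sweep.json
```

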