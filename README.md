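# boilstart

Acoustic-emission (AE) monitoring of boiling onset in herbal-medicine
extraction.

Water decoction time is counted from the onset of boiling, but the industrial
criterion — the tank thermocouple reaching 100 °C — lags the physical onset of
saturated boiling by several minutes, wasting heating energy. Bubble
nucleation, detachment, and collapse emit elastic waves in the 75–100 kHz
band, and the band's power spectral density rises sharply the moment bubbles
begin detaching from the heated wall (discrete saturated boiling). `boilstart`
turns that acoustic signature into an online, self-adaptive boiling detector
that needs no prior model library, plus everything required to exercise it
end-to-end without laboratory hardware.

## Method

1. **Spectral preprocessing.** Each acquisition (10 s at 1 MHz, every 30 s) is
   split into 80 segments; each segment is mean-centered and its PSD estimated
   by a Hann-windowed periodogram
   `P(f) = (1/(fs·N)) |Σₙ h(n)x(n)e^(−j2πfn/fs)|²`, one-sided. The 80
   periodograms are averaged and compressed into 500 × 1 kHz sub-bands; the
   75–100 kHz slice is the monitored feature vector **x** (K = 25).
2. **Multivariate monitoring.** On an in-control window X (N × K), columns are
   autoscaled and PCA retains components with explained-variance ratio > 0.05.
   For scores t = x·P: `T² = (t − t̄) Λ⁻¹ (t − t̄)ᵀ` with limit
   `A(N−1)/(N−A)·F₁₋α(A, N−A)`, and `SPE = ‖x − x̂‖²` with the
   Jackson–Mudholkar weighted-χ² limit from the residual eigenvalues
   (α = 0.01 for both).
3. **Adaptive trigger.** Starting at N = 10 acquisitions, the PCA model and
   its T² limit are re-fitted on the whole history at every step and the
   newest point is scored against its own growing-window model. Two
   consecutive T² exceedances declare boiling; the trigger time t_AE is the
   second exceeding acquisition. SPE is reported in the trail but never used
   for the decision.
4. **Evaluation.** `AET = |t_ref − t_AE|`,
   `δtime = (t_temp − t_AE)/t_temp × 100 %` against the 100 °C criterion
   time, and `CE = EF × EC` (EF = 0.5153 kg CO₂/kWh).
5. **Simulation.** A seeded generator produces the three-stage AE
   phenomenology (quiet baseline → 10× band-power rise → attenuated,
   fluctuating stage) plus a Newtonian heating trace with a 100 °C plateau,
   with ground-truth onset for every run.

## Worked example

```python
from boilstart import (SimulationConfig, simulate_run, BoilStartDetector,
                       DetectorConfig, RunResult, time_to_temperature)

cfg = SimulationConfig(seed=1)            # true onset at acquisition 40 (20 min)
run = simulate_run(cfg)
det = BoilStartDetector(DetectorConfig(band_lo_khz=cfg.band_lo_khz,
                                       band_hi_khz=cfg.band_hi_khz))
event = det.run(run.segments)
print(event.summary())

t_temp = time_to_temperature(run.temperature, 100.0)
result = RunResult(t_ref_min=run.onset_time_min, t_ae_min=event.t_ae_min,
                   t_temp_min=t_temp)
print(f"AET = {result.aet_min:.1f} min, dtime = {result.delta_time_pct:.1f} %")
```

prints

```
BoilStart detection
===================
triggered:        yes
trigger index:    41
t_AE:             20.50 min
evaluated points: 32
model at trigger: A=1, N=41, T2 limit=7.314
AET = 0.5 min, dtime = 31.7 %
```

The detector fires one acquisition (0.5 min) after the true onset — an
absolute timing error well inside the 1.5–2.0 min range achievable on real
extractions — and 9.5 min before the 100 °C criterion, a ~32 % reduction of
the increasing-temperature phase.

The same pipeline is available from the shell:

```sh
boilstart simulate --seed 1 --outdir run/
boilstart monitor --input run/ --config det.json \
    --output-trail trail.csv --output-event event.json
boilstart evaluate --event event.json --truth run/truth.json \
    --temperature run/temperature.csv --output table.csv
```

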