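# hydropulse

Modeling toolkit for a laboratory water-hammer platform that delivers a
single, controllable dynamic compression pulse to living cells (for example
primary microglia in in-vitro blast/TBI studies). A gas-gun-driven projectile
strikes a confined liquid column inside a thin-walled steel tube; the impact
launches one compression wave through the cell suspension, across an
impedance-matched rubber membrane, and into an extension column that carries
it away. `hydropulse` predicts the waveform the cells experience, simulates
virtual gauge records, calibrates strain-to-pressure conversion, solves
inverse design problems (what striker/velocity gives a requested dose), and
normalizes the downstream plate-reader assays.

## The model

For a striker of impedance (ρc)ₚ hitting a fluid of impedance (ρc)_f at
velocity V₀, the peak pressure is the Joukowsky water-hammer surge

    P(0) = (ρc)_f (ρc)ₚ / [(ρc)_f + (ρc)ₚ] · V₀  ≈  (ρc)_f V₀,

after which the pulse decays exponentially, P(t) = P(0) exp(−t/θ) with
θ = ρₚLₚ / (ρc)_f set by the striker's areal mass. The wave travels slower
than the free-fluid sound speed c₀ = √(K_f/ρ_f) because the elastic tube
wall breathes: with the coupling parameter

    β = (c₀²/c_s²)(ρ_f/ρ_s)(2R/h),

the Moens–Korteweg celerity is c_f = c₀/√(1+β). The tube wall also carries a
weak axial precursor at the bar speed c_s = √(E_s/ρ_s), scaled by −ν from the
hoop strain ε_θ = PR/(E_s h). Pulse propagation through the
medium/membrane/extension stack is computed by exact linear superposition of
scaled, time-shifted source copies spawned at each impedance interface
(R_p = (Z₂−Z₁)/(Z₁+Z₂), T_p = 1+R_p).

## Worked example

```python
from hydropulse import WATER, STEEL_TUBE, STEEL_PROJECTILE, NBR_MEMBRANE
from hydropulse.design import design_report

rep = design_report(WATER, STEEL_TUBE, STEEL_PROJECTILE, NBR_MEMBRANE,
                    target_peak=13.5e6, gauge_separation=58.86e-3)
print(rep.summary())
```

prints

```
Experiment design report
  required velocity     : 11.22 m/s
  predicted peak        : 13.5 MPa
  decay constant theta  : 163.2 us
  pulse extent (3 theta): 0.5887 m (exceeds the cell column)
  projectile round trip : 10.01 us
  membrane reflection   : 3.34 % (ok)
  celerities            : c0=1496.7, cf=1202.7, cs=4996.8 m/s
  gauge pair (58.86 mm): flexural lag 48.94 us, precursor lag 11.78 us
```

Reading: an 11.2 m/s, 25-mm steel striker produces a 13.5 MPa pulse decaying
with θ ≈ 163 μs; the pressure wave crosses the 58.86 mm gauge pair in ~49 μs
at 1202.7 m/s (the Moens–Korteweg speed for the 12 mm bore, 0.25 mm wall)
while the wall precursor needs only ~12 μs at 4996.8 m/s; the NBR membrane
reflects only 3.3% of the incident pressure, so the cells see a clean single
pulse. The superposition flag is advisory: the pulse's 3θ decay length
exceeds the 120 mm cell column, but the striker-internal round trip (~10 μs)
is the scale on which the waveform is actually shaped.

The same numbers are available from the shell:

```
hydropulse design --config bench.yaml --target-peak-mpa 13.5
hydropulse simulate --config bench.yaml --out traces.csv
hydropulse calibrate --traces traces.csv --separation-mm 58.86
```

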