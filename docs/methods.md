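# Methods

## Physical model

The platform is a one-dimensional, linear-acoustic idealization of a
projectile-driven water-hammer bench. Its assumptions: the impact is a
"weak" shock (thermal effects negligible, fluid stays in the acoustic
regime), no cavitation or column separation, the tube wall deforms purely
elastically in its hoop mode, and the suspended cells are passive tracers
(10 μm cells in a 10 mm bore do not perturb the wave).

**Source pulse.** The impact produces an instantaneous-rise,
exponential-decay pressure pulse. The peak follows the Joukowsky relation;
`physics.source_pulse_for` uses the rigid-striker limit P(0) = ρ_f c_f V₀
with the FSI-corrected celerity c_f, appropriate for steel on water
(impedance ratio ~26, making the finite-striker correction under 4%; the
exact two-impedance form is available separately). The decay constant is
θ = ρₚLₚ/(ρ_f c_f): the striker's areal mass divided by the acoustic
resistance it works against. That reading is the only dimensionally
consistent one for an exponential water-hammer decay and reproduces
θ ≈ 163 μs for the bench's 25-mm steel striker. The measured ~20 μs rise
time of real records is a transducer/contact effect and is deliberately not
modeled (Heaviside onset).

**Celerity.** Wall compliance slows the pressure wave from
c₀ = √(K_f/ρ_f) to the Moens–Korteweg speed c_f = c₀/√(1+β),
β = (c₀²/c_s²)(ρ_f/ρ_s)(2R/h). Three algebraically equivalent forms (the
general compliance solution, the Korteweg reciprocal form, and the β form)
are implemented as separate code paths and tested to 1e-12 relative
agreement.

**Waveguide engine.** Linearity makes the field an exact superposition of
scaled, time-shifted source copies. The engine tracks wavefronts as events:
at each interface a reflected (×R_p) and transmitted (×T_p = 1+R_p)
descendant spawns; a rigid termination reflects with +1 (pressure doubling
at the wall — the reason the end-mounted transducer records twice the
free-field peak), an anechoic one absorbs. Wavefronts retire below an
amplitude cutoff (default 1e-3 of the source peak) or beyond the record
window. There is no numerical dispersion or grid error; traces are exact to
the retirement cutoff and the sampling grid.

**Precursor.** The axial precursor is modeled one-way: a −ν-scaled copy of
the hoop waveform whose arrival time uses the wall bar speed c_s instead of
c_f. The fully coupled wall–fluid problem (Skalak) is out of scope; the
one-way model reproduces the two observed arrivals and their ~0.3 amplitude
ratio, which is all the calibration workflow needs.

## Parameter conventions and defaults

| Parameter | Default | Why |
|---|---|---|
| Water ρ_f, K_f | 1000 kg/m³, 2.24 GPa | handbook values; c₀ = 1496.7 m/s |
| Steel E_s, ρ_s, ν | 196 GPa, 7850 kg/m³, 0.3 | reproduce the bench's theoretical c_s = 4996.8 m/s |
| Tube R, h, L | 6 mm, 0.25 mm, 140 mm | bench geometry; the quoted 12 mm diameter is read as the bore, R = 6 mm (≤2% ambiguity vs mid-wall radius) |
| NBR membrane ρ_m, c_m | 1000 kg/m³, 1600 m/s | nitrile rubber handbook values; Z_m within 3.4% of water |
| Striker | steel, 25 mm, 11.24 m/s | the bench's high loading level (13.5 MPa) |
| dt, t_end, cutoff | 0.1 μs, 2 ms, 1e-3 | resolves the ~20 μs peak region; spans a full record |

Units are SI internally; reports display MPa, mε, μs, m/s.

Two impedance conventions coexist deliberately. Wave *timing* inside the
instrumented tube uses the FSI-corrected c_f. Interface *reflection* between
fluid and membrane uses the free-fluid ρ_f c₀ ≈ 1.497 MPa·s/m — the
material-property impedance by which the bench selects its membrane
("similar impedance to the medium"). Treating the fluid's in-tube effective
impedance as ρ_f c_f instead would raise the predicted membrane echo from
~3.3% to ~14%; measured records support the small value, consistent with the
membrane match being a material-impedance effect.

The membrane is a thin third segment (its stated thickness), not a
zero-thickness interface, so double-transit effects appear. The source end
is anechoic by default: the source pulse already carries the full striker
momentum exchange, and a rigid source end would double-count striker echoes
(with a rigid source the closed-end recorded peak exceeds 2×P(0) once the
column round trip ~200 μs is comparable to θ ~163 μs). A rigid source
option remains for sensitivity studies.

## Calibration

Arrival picking is a first-crossing detector at 10% of peak; two-gauge
celerity uses that or the cross-correlation argmax (default for noisy
records; the two agree within one sample on clean traces). Peak extraction
for calibration uses an optional short moving average: the raw maximum of a
noisy record is biased upward (a maximum over many noise draws), and a
window of a few μs — far below θ — removes most of that bias while clipping
the true exponential peak only ~1%. The pressure-vs-strain calibration is
ordinary least squares with an intercept; because the physical line
P = (E_s h/R)ε passes through the origin, the zero-intercept slope is
reported alongside rather than silently forced. The device-scale constants
published for a particular gauge signal chain (e.g. a slope of 0.0425 in
instrument units) depend on that chain's gain and are not predictable from
geometry alone; the physical constant E_s h/R = 8.167 MPa/mε is.

## Inverse design

All design operations invert closed forms exactly: V₀ = P/(ρ_f c_f),
Lₚ = θ(ρ_f c_f)/ρₚ. The superposition check defines the pulse's spatial
extent as 3θc_f (95% decay) and flags — advisorily, never blockingly —
whether it fits the cell column; for the bench geometry it does not
(0.59 m vs 0.12 m), so the report also gives the striker-internal round
trip 2Lₚ/cₚ (~10 μs), the scale that actually bounds waveform shaping. The
membrane match reports 100·|Z_m−Z_f|/(Z_m+Z_f) against a 10% bound.

## Assay normalization

Survival is 100·(OD_e−OD_bg)/(OD_c−OD_bg). LDH/ROS/NO normalizations divide
each group's blank-corrected signal by that group's cell count before
taking the fold-over-control; the per-group count in the denominator is
used for control as well (dividing both sides by the experiment count would
make the normalization a no-op for unequal densities). Cell counts come
from a linear CCK-8 standard curve, floored at zero, warning outside its
fit range. Group-comparison statistics are out of scope; `summarize_plate`
emits tidy per-group mean/SEM/n tables ready for any ANOVA routine.

## Synthetic data

`make_noisy_traces` adds i.i.d. Gaussian noise scaled to each channel's
peak — it emulates wideband gauge/bridge noise but not drift, gauge-factor
nonlinearity, trigger jitter, or the finite rise time of real records, so
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to every bench artifact. `synth_plate` draws
multiplicative lognormal replicate noise (unit mean, chosen CV) around
programmed group effects — pipette/reader scatter — without plate-edge or
batch effects. Both are deterministic under a fixed seed.

## Numerical choices and limitations

Event ties at interfaces are processed in creation order (FIFO);
superposition makes the result order-independent, the rule exists only for
reproducibility. Trace CSVs use 9 significant digits; JSON keeps full
doubles. Known limitations: no dispersion, viscous attenuation, nonlinear
steepening, hoop breathing-mode dynamics, cavitation, or wall plasticity;
the precursor is one-way; gas-gun interior ballistics are not modeled
(striker velocity is an input).
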