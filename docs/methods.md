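# Methods

## The measurement principle

Rod photoresponses originate in photoreceptor outer segments that lie against
the RPE, so their temperature tracks RPE temperature during heating. Three
temperature-dependent properties of the ex vivo ERG are exploited:

* **Kinetics** — activation and deactivation of the phototransduction cascade
  and of the bipolar-cell response accelerate with temperature; times-to-X%
  of the a- and b-wave shrink by roughly 2–4% per °C.
* **Absolute sensitivity** — response amplitude per unit flash strength falls
  as temperature rises.
* **Long-wavelength relative sensitivity (LRS)** — at 780 nm the photon energy
  alone barely excites rhodopsin and thermal energy supplements it, so
  warming boosts the 780 nm response relative to the 532 nm response; the
  amplitude ratio V(t_b-peak, 532)/V(t_b-peak, 780) declines ~3.2% per °C.

Because absolute kinetics and sensitivity differ between retinas and drift
over hours, every feature is used as a *relative* value x/x37, normalized to
the same retina's 37.0 °C reference recordings, and temperature is modelled
as a linear function of the relative features.

## Feature extraction

Bright-flash traces are low-pass filtered (FIR order 50, f_c = 100 Hz). The
a-wave peak is the first post-flash sign change (negative → positive) of the
central difference V(t+1 ms) − V(t−1 ms); times-to-X% are the first samples
where V(t) < X%·V(t_a-peak); the inflection point is the argmin of the
derivative of a cubic fitted to the leading edge [0, t_a-peak].

Dim-flash traces (four per wavelength, averaged at the trace level) provide
the b-wave. The peak is the vertex of a quadratic fitted over ±15 ms around
the maximum of the 30 Hz-filtered trace. Leading-edge crossings use an
order-600, 20 Hz filter; trailing-edge crossings and the integration time
(trapezoidal ∫|V|dt from the flash to the first post-peak zero crossing,
divided by the amplitude) use an order-400, 30 Hz filter. Dim kinetics
features are averaged across the 532- and 780-derived values; the b-wave
amplitude uses the 532 nm response only (steeper temperature dependence) and
LRS is the 532/780 amplitude ratio.

Threshold crossings take the first discrete sample satisfying the comparison,
without sub-sample interpolation: at 10 kHz the 0.1 ms quantization is
negligible against 2–4%/°C effects on features tens to hundreds of ms long.
A failed detection leaves only the affected features missing; rows with
missing model features are excluded from fitting and prediction with a logged
count, rather than silently imputed.

### Filtering

Only the FIR order and cutoff of each filter are fixed by the recording
convention; this implementation uses a symmetric Hamming-window kernel
("order n" = n+1 taps) applied with reflection padding and the n/2-sample
group delay compensated, so filtering shifts no event times. A causal
application would shift all timing features by a constant, which the
per-retina normalization would largely cancel; the zero-delay choice keeps
raw and filtered event times directly comparable. `FeatureConfig`
(`apply_filters`, windows, filter settings) exposes every such choice; the
analytic self-tests run with filtering disabled.

### Open choices made here

* The b-peak search and quadratic fit run on the trailing-edge (30 Hz)
  filtered trace; the fitted amplitude is the reference for both edges'
  crossings, each evaluated on its own edge's filtered trace.
* The cubic-fit window for the inflection point is [0, t_a-peak].
* The a-peak search window defaults to 0–200 ms post-flash so b-wave-related
  sign changes are never picked up.

## Normalization

References are recorded at 37.0 °C roughly every 20 min. In `interpolate`
mode x37(t) is linearly interpolated between the two flanking references (the
retrospective analysis); in `recent` mode only the most recent reference is
used (the causal variant available during a heating session). Observations
before the first reference are clamped to it in interpolate mode, with a
warning. Reference observations themselves are kept in training tables — they
carry temperature 37.0 and anchor the intercept.

## Temperature model

c = Xβ + ε with an intercept, fitted by least squares. Forward selection adds
at each step the feature whose augmented set gives the lowest leave-one-out
cross-validated RMS temperature error; the path length is capped at 12 steps
(the BIC optimum in practice lies well inside that). Model size is chosen by
BIC = n·ln(SSE/n) + k·ln(n), computed from the full-training-data fit SSE
with k = number of coefficients including the intercept (counting the noise
variance as well would add ln(n) to every step equally and cannot move the
argmin). Ties in CV error or BIC break toward the lexicographically first
feature / the smaller model, for determinism.

The cross-validation unit defaults to whole retinas (leave-one-retina-out),
which prevents within-retina leakage; observation-level LOO is available and
is verified in tests against the closed-form hat-matrix identity
e_i/(1 − h_ii).

Three reference models with published coefficients are shipped: the full
model (b70T, LRS, a10, ba, b20T), the outer-segment model (a20, LRS, aip,
a30) and the dim-flash model (b70T, LRS, b20T, ba, b20L). At the all-ones
relative feature vector — the 37.0 °C reference state — each evaluates to
37.0 ± 0.1 °C, a consistency check between the coefficients and the
normalization convention.

## Synthetic data

No raw recordings are distributed, so a two-level seeded simulator defines
the study conditions.

**Feature level.** Each relative feature is drawn as
x = 1 + slope·(T − 37) + ε, ε ~ N(0, rmsd), with the 34 (slope, rmsd) pairs
taken from the published training-data calibration (`TABLE1`). Defaults
reproduce the study layout: 8 training and 5 test retinas, 15 stimulus
temperatures per retina drawn uniformly from 35.0–44.0 °C (the narrow
±0.05 °C band around 37.0 is excluded so reference rows stay unambiguous),
observations 180 s apart, 37.0 °C references every 1200 s, and a closing
reference so interpolation always has flanking values. Residuals are
independent across features by default; the real features are certainly
correlated, but no correlation structure is published, so a within-family
equicorrelation ρ is exposed for sensitivity analysis and defaults to 0.
Accuracy figures quoted from this generator are therefore somewhat optimistic
about how much error averaging across redundant features can remove —
passing the end-to-end bound shows the pipeline is correct and well
calibrated under the stated marginal statistics, not that the original
recordings would give the identical error.

**Waveform level.** The dim-flash b-wave is a gamma bump
V(t) ∝ (t/τ)^s·e^{s(1−t/τ)} (τ = 120 ms, s = 4, 30 µV at 37 °C) minus a 5%
amplitude, 3×-slower copy so the response crosses zero after the peak (a pure
gamma bump never would, leaving the integration time undefined). The bright
response blends a fast saturating negative a-wave, 1 − exp(−(t/τ_a)²) with
τ_a = 30 ms and 150 µV, into a larger (250 µV), slower positive b-wave.
Temperature enters as uniform time-axis compression — all event times scale
by 1 + s_t·(T − 37) with s_t = −0.03/°C, matching the 2–4%/°C range with
analytic ground truth — and as linear amplitude scaling per wavelength:
−0.019/°C at 532 nm, with the 780 nm coefficient derived so the 532/780 ratio
declines at −0.032/°C (hence the 780 nm response grows with temperature, as
observed). Gaussian sample noise (default 0.5 µV) is added last. What this
level does not emulate: the slow PIII (Müller-cell) component, stimulus-
strength response families, drift of sensitivity over the session, and any
non-uniformity of the kinetics acceleration across response phases.

A full simulated session mirrors the protocol: per temperature, four dim
532 nm, four dim 780 nm and one bright trace at 6.5 s spacing, 120 s
stabilization between blocks, reference blocks at 37.0 °C every ~20 min and
at both ends of the session.

## Numerical choices and degenerate inputs

* OLS is solved by `numpy.linalg.lstsq` after a QR-with-pivoting rank check
  that names the collinear columns; tests cross-check the estimates against
  the normal equations and statsmodels.
* BIC is undefined at SSE = 0 (perfect fit); it is reported as −∞ sentinel in
  results objects and a parameter error in the low-level function.
* The b-peak quadratic falls back to the discrete maximum (with a warning)
  when the vertex escapes the ±15 ms window; a cubic with no interior
  derivative minimum falls back to the window endpoint with the smaller
  slope.
* Trace files must be strictly increasing in time with a sampling interval
  uniform to 1 ppm; voltages are written with 17 significant digits so
  session round trips are bit-exact.

## Problem sizes

The shipped configuration — 13 retinas × (15 temperatures + references) at
the feature level, and sessions of a handful of temperatures at the waveform
level for the signal-processing tests — was chosen as the smallest layout
that reproduces the study's statistical structure; the full test suite and
the acceptance script each complete in seconds.

## Known limitations

* The pipeline is calibrated for scotopic rod-dominated mouse responses;
  cone-driven features, oscillatory potentials and slow PIII decomposition
  are out of scope.
* Reported accuracies are synthetic-data accuracies under independent
  feature noise (see above).
* The LRS physics (minimum photoactivation energy, theoretical −3.8%/°C) is
  not modelled; the simulator uses the empirical −3.2%/°C calibration slope.
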