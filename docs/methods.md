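# Methods

## Interface circuit model

The electrode–tissue interface is modeled as a linear, bias-independent
network

```
Z(f) = R_bulk + R_spread + [ Z_CDL ∥ (R_CT + Z_CF) ]
```

with two constant-phase elements (CPEs): the double-layer element
`Z_CDL` and a faradaic element `Z_CF` in series with the
charge-transfer resistance `R_CT`. A CPE has impedance
`Z = 1/(Q·(jω)^n)` with `Q` in S·s^n (the admittance at ω = 1 rad/s) and
`n ∈ (0, 1]`; its phase is −n·90° at every frequency, and `n = 1`
recovers an ideal capacitor of capacitance `Q`. The faradaic CPE is
placed in series with `R_CT` inside the parallel branch — the standard
Randles-like extension. A purely capacitive interface is expressed by an
explicit infinite-`R_CT` flag rather than a large float, to avoid
conditioning artifacts in fitting and simulation. Either CPE may also be
omitted entirely, which yields the degenerate resistor-only circuits
used as analytic checks.

The spreading (access) resistance of a disc contact of diameter `D` in a
medium of resistivity `ρ` uses the disc access formula `R = ρ/(2D)`.
This 1/D scaling reflects current crowding at the contact perimeter and
is the reason microcontact impedance is edge- rather than
area-dominated. Bias dependence of the interface elements is real in
strongly driven interfaces but is out of scope here; a no-op hook (scale
elements as a function of bias) would slot in at circuit construction,
and the model otherwise assumes small-signal linearity.

Limitations: no Warburg (diffusion) element, no Butler–Volmer reaction
kinetics, no temperature dependence, and no model of the nanoscale
impedance saturation observed when edge effects dominate at extreme
scaling.

## Fractional-order transient simulation

CPE branches obey `I = Q·d^n v/dt^n`, so the pulse response is a
fractional-order initial-value problem. The simulator discretizes the
fractional derivative with the Grünwald–Letnikov (GL) binomial
convolution on a uniform grid (`w_0 = 1`,
`w_j = w_{j−1}·(1 − (n+1)/j)`) and solves the linear nodal equations of
the parallel network exactly at each step. The drive current is treated
as piecewise constant per step (sampled at interval midpoints) and the
voltage is reported at interval right endpoints, where the GL sum is
consistent: for an ideal capacitor the simulated ramp is then exact, and
for a single CPE under constant current the result converges to the
closed form `V(t) = I·t^n/(Q·Γ(1+n))` with relative error ≈ n(1−n)/(2k)
at step k — under 10⁻⁴ at the end of a 1000-step phase. The startup
samples (first few % of a phase) carry the 1/k GL error; excursion
extrema, which occur at phase ends, are unaffected.

Numerical conventions: the waveform timestep must satisfy
`dt ≤ t_pw/50` so each phase is resolved by at least 50 samples; the GL
convolution has full memory and costs O(N²), so simulations are capped
at a configurable sample-count ceiling (default 100 000) and fail with
advice to increase `dt` rather than silently truncating. A
Richardson-style dt-halving check on the cathodal extremum (tolerance
0.5%) and a steady-state sinusoid comparison against the spectral
impedance (2% amplitude, ~2° phase, with a linear-drift-tolerant
quadrature fit because fractional systems approach steady state only
algebraically) are part of the test suite.

## EIS fitting

`fit_interface` performs complex nonlinear least squares on stacked
(Re, Im) residuals using `lmfit`'s Levenberg–Marquardt backend.
Defaults and rationale:

* **Weighting**: `modulus` (each residual divided by |Z| at its
  frequency). Spectra span several decades of magnitude; unweighted
  fits would be dominated by the low-frequency points. `unit` and
  `proportional` weightings are available.
* **Parameterization**: Q and R values are fitted as log10 to enforce
  positivity and equalize scales; CPE exponents are bounded to
  [0.3, 1.0] by default (overridable) to keep the fit away from
  Warburg-like `n ≈ 0.5` degeneracy when the data do not support it.
* **Identifiability**: spreading and bulk resistance enter the model
  only through their sum, so `r_bulk` is held at its initial value and
  `r_spread` absorbs the fitted series resistance.
* **Multistart**: the initial guess plus 5 seeded log-uniform
  perturbations (×1/3…×3); best residual wins, ties broken by iteration
  count then lexicographic parameter order, making results
  deterministic given (data, seed).
* **Preconditions**: ≥ 8 points spanning ≥ 2 frequency decades;
  narrower designs cannot separate the branches and are rejected.

`fit_diameter_scaling` is an ordinary least-squares line in
(log D, log |Z_imag|), requiring ≥ 3 distinct diameters; the reference
frequency defaults to 1 kHz, the conventional reporting frequency for
electrode impedance. The fitted `α` carries units Ω·m^d1 (diameters in
meters).

## Excursion-potential law and current limits

The five-parameter empirical law
`V_elec = a·ln(b·|I|^k2·t_pw^k4·|Z_imag|^k6 + 1)` is logarithmic in the
drive, strictly increasing in each input, and exactly zero at zero
current. The coefficient `b` absorbs the units of I, t_pw and |Z_imag|,
so every model instance carries a mandatory unit declaration (default
μA, μs, kΩ — the natural scales of microstimulation) and supplying
inputs under a different declared convention raises instead of
converting silently.

The current limit is the closed-form inversion at
`V_elec = |E_mc|` (the cathodal electrolysis limit from cyclic
voltammetry, stored signed, negative by convention; `E_mc` is a user
input — no CV simulation is performed):

```
I_limit = [ (e^{|E_mc|/a} − 1) / (b·t_pw^k4·|Z_imag|^k6) ]^{1/k2}
```

which round-trips through the forward law to ~1e−15 relative.
`current_limit_vs_diameter` evaluates the same expression at
`|Z_imag| = α·D^(−d1)` (converted into the model's impedance unit), so
the two routes are algebraically identical by construction; the test
suite verifies the identity to 1e−10 over randomized parameter draws.
Monotonicity follows from positive exponents: the limit falls with
longer pulses and with higher interface impedance — the latter is why
limits measured in tissue (higher-impedance medium) sit below benchtop
saline values. Inter-contact separation influences the limit in
practice, but no quantitative separation model is provided — limit
tables carry separation only as annotation.

`fit_excursion_model` fits (ln a, ln b, ln k2, ln k4, ln k6) by
nonlinear least squares on excursion residuals (volts), with the same
seeded 5-start strategy as the EIS fitter; standard errors are mapped
back through the delta method. It requires ≥ 20 rows spanning at least a
decade in both current and pulse width — narrower designs leave the
exponent pairs nearly collinear.

Shannon's criterion `log10(Q/A) = k − log10(Q)` (Q in μC, A in cm²)
implies `Q²/A = 10^k`; on a disc of diameter D (cm) this gives a
per-phase charge bound `Q = (D/2)·√(π·10^k)` μC and current
`I = Q/t_pw`. The implementation and its tests both derive from this
charge-density identity independently, and `compare_to_shannon` tabulates
the ratio of the electrochemical-model limit to the Shannon limit over
(D, t_pw) grids. Pulse screening in `check_pulse` uses the empirical
charge thresholds — 30 μC/cm² geometric charge density for macro
contacts and 4 nC per phase for micro contacts — with a three-way
pass / at_limit / fail status (at_limit within 1e−9 relative of the
threshold), plus an excursion-vs-`E_mc` check when a fitted model and an
impedance are supplied.

## Recording-side models

The coupling coefficient lumps the amplifier input resistance (default
16 MΩ) and all shunt capacitance (amplifier input + lead parasitics,
default 1 pF each) into a single divider:
`CC = |Z_shunt|/|Z_shunt + Z_elec|`. It is 1 only for a zero-impedance
electrode and decreases monotonically with electrode impedance for
capacitive-to-resistive electrode phases. Thermal noise is the
Johnson–Nyquist integral `v_rms = √(4·k_B·T·∫Re{Z(f)}df)` (trapezoid
over an arbitrary Re{Z} profile; exact for flat resistance). Flicker
(1/f) noise is available only as an explicit user-parameterized
`A/f^β` PSD helper — no default magnitude is shipped. Conduction delay
is `separation/speed` for user-chosen propagation speed (physiological
range ~0.2–1 m/s). Data rate is exact integer
`channels × sample rate × bit depth`, with decimal (10⁹) Gbps
conversion. The crosstalk bound is the divider fraction
`|Z_elec|/(|Z_elec| + 1/(ωC_interlead))` — an upper bound, not a field
simulation.

## Synthetic data and presets

Generators exist so every fitter can be validated against known ground
truth; at zero noise each generator is exactly its fitter's forward
model. Noise models: multiplicative complex Gaussian (relative sigma per
quadrature component — the standard EIS error model), additive Gaussian
(absolute sigma, used for excursion voltages), and lognormal magnitude
scaling (used for diameter series). All generators are bit-reproducible
under their seed; `child_seeds` fans a single global seed into
independent 31-bit child seeds via `numpy.random.SeedSequence` spawning.

Study conditions used by the recovery tests, chosen for physiological
plausibility: EIS truth circuit `R_bulk = 100 Ω`, `R_spread = 1 kΩ`,
`C_DL: Q = 1e−7 S·s^n, n = 0.9`, `R_CT = 1 MΩ`,
`C_F: Q = 1e−6, n = 0.8`, sampled at 40 log-spaced points over
0.1 Hz–100 kHz with 2% multiplicative noise (each branch dominates part
of that band, making all six parameters identifiable); excursion truth
`a = 0.3 V, b = 0.002, k2 = 0.9, k4 = 0.4, k6 = 0.7` in (μA, μs, kΩ)
on a 5×4×3 factorial grid (10–1000 μA, 50–1000 μs, 10–100 kΩ) with 5 mV
additive noise, giving excursions of ~0.1–1.8 V.

Material presets (Ti, planar Pt, PEDOT:PSS, PtNR) are purely capacitive
circuits calibrated so the modeled |Z(1 kHz)| hits the benchtop targets
1.5 MΩ / 400 kΩ / 30 kΩ; the PtNR value (25 kΩ) is a plausible synthetic
stand-in, not a published figure. Calibration fixes the CPE exponent
(0.9 for the metals, 0.95 for the high-surface-area coatings — plausible
values, not measurements) and a series resistance of 10% of the target,
then solves the magnitude quadratic for `Q` in closed form. Only the
1 kHz magnitude is anchored; the spectral shape away from 1 kHz is a
modeling choice.

What passing the synthetic-recovery tests shows — and does not. They
demonstrate that the estimators are consistent and well-conditioned
under the stated noise models and design ranges. Real electrode data add
effects the generators deliberately omit: drift and nonstationarity,
bias-dependent elements, electrode-to-electrode variability, diffusion
tails at low frequency, and correlated (not i.i.d.) measurement error.
Recovery percentages on synthetic data therefore bound estimator
quality, not field accuracy.

## Degenerate inputs and tie-breaks

Validation errors always name the offending field. Degenerate designs
(single-decade spectra, single-current excursion grids, repeated
diameters) are rejected rather than fitted. Fit ties across multistart
are broken deterministically (residual, then iteration count, then
lexicographic parameter order). File writes are atomic (temp + rename)
so interrupted runs never leave half-written outputs; unsorted spectrum
files are sorted with a warning, while NaN cells are hard errors that
report the line number.
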