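# Methods

## The mechanism and its assumptions

`halokin` models the single-turnover chemistry of a flavin-dependent
halogenase (FDH) as a closed mass-action network over sixteen species
(`halokin.scheme.SPECIES`). The flavin-containing species form a conserved
pool — every simulation is checked against this invariant to 1e-6
relative. The network encodes:

1. **Binary-complex formation and inactivation.** Free enzyme binds FADH⁻
   (`k_bind_flavin`, 1 µM⁻¹ s⁻¹ by default; in the standard presets all
   flavin starts bound, so this step is inert). The active complex
   isomerizes irreversibly to a dead-end conformer at `k_inact`
   (0.41 s⁻¹), which cannot react with oxygen. Fresh-mix presets set
   `k_inact = 0`: with oxygen capture at ~16.5 s⁻¹, isomerization diverts
   ≲2.5 % of the population in a fresh mix, and the observed formation rate
   constant already absorbs that loss. The inactivation experiment itself
   is modeled directly in amplitude space (see below), so the two
   descriptions never conflict.
2. **Oxygenation.** O₂ is a non-depleting bath (pseudo-first-order,
   `k_ox·[O₂]`): 128 µM O₂ against 15 µM FADH⁻ in the standard conditions.
   Free-FADH⁻ autoxidation is omitted — enzyme (30 µM) exceeds flavin
   (15 µM), so all flavin is treated as bound at mixing.
3. **The branch point.** C4a-hydroperoxyflavin either uncouples
   (`k_unc` → FAD + H₂O₂) or reacts with halide. Halide binding is lumped
   by rapid equilibrium: `k_hox_obs = k_hox·[X]/(K_d + [X])`, the same
   two-step law the saturation fitter assumes. An explicit binding mode
   (`halide_on_rate`, with `k_off = k_on·K_d`) exists for sensitivity
   checks; with on/off rates fast against the chemistry it converges to
   the lumped mode. Fluoride is a valid input whose HOX-formation rate is
   forced to zero (constructing parameters with `k_hox[F] > 0` is a
   validation error).
4. **HOX fate.** Nascent HOX partitions memorylessly between capture
   (halogenation of the bound tryptophan, `k_capture`) and leakage to bulk
   (`k_leak`). Only the ratio matters for end-point yields; the defaults
   (3.75 / 6.25 s⁻¹) fix the captured fraction at 0.375 so that an 80 %
   HOX-forming flux yields the measured 0.30 coupling ratio. Transfer
   kinetics, tunnel geometry and the chemistry of leaked HOX with external
   traps are not modeled; leaked equivalents are only counted.

Units are µM and seconds internally; halide concentrations are mM at every
interface and converted once at the boundary. The integrator is LSODA at
rtol 1e-8 / atol 1e-10 µM; round-off negatives are clipped to zero on
output only.

### Population-partition mode

Flux competition with the measured constants predicts uncoupled fractions
of roughly 14–19 % at saturating bromide/chloride, yet the observed
phase-2 450-nm amplitude splits are ~20 % and ~55 %. The mechanistic
origin of that discrepancy is an open question, and the package does not
guess at it: alongside the default flux-competition mode, `f_unc_pop`
routes a *fixed fraction* of the oxygen flux into a subpopulation that can
only uncouple (at the halide-present uncoupling rate), with the remainder
performing halide chemistry only. The generator uses this mode for
amplitude-recovery analyses; both modes share every other reaction.

A related observation: the H₂O₂-elimination rate and the isomerization
rate share the numerical value 0.41 s⁻¹. They are independent parameters
here (`k_unc`, `k_inact`); the coincidence is not exploited anywhere.

## Optical readout

Absorbance channels (380, 450 nm) are Beer–Lambert sums over chromophore
classes (FAD, FADH⁻, C4aOOH-FAD, C4aOH-FAD); fluorescence channels are
linear brightness sums in arbitrary units with C4a-hydroxyflavin
constrained to be the brightest species (a validation invariant).
Enzyme-bound C4a-adduct extinction coefficients are unpublished; the
defaults are literature-typical placeholders (FAD ε450 = 11.3,
ε380 = 6.0 mM⁻¹ cm⁻¹; C4aOOH ε380 = 8.0; C4aOH ε380 = 7.5; FADH⁻
ε380 = 3.0) and are config-overridable. Every downstream quantity depends
on rate constants and *relative* amplitudes, not on the absolute scale.

One deliberate choice: both C4a adducts carry the same 450-nm coefficient
(0.7 mM⁻¹ cm⁻¹, matching FADH⁻). All three species have a bleached 450-nm
band, and assigning them a common value makes the 450-nm signal a pure
reporter of oxidized-FAD formation. That is exactly the premise of
phase-amplitude decomposition of that channel: with distinct adduct
coefficients the C4aOOH→C4aOH conversion would contribute a spurious
sub-percent phase-2 amplitude that belongs to neither branch. Fluorescence
from different PMT settings is never compared in absolute terms.

## Fitting

**Multi-exponential fits** use variable projection: the optimizer works in
log-rate space only, with amplitudes and offset solved linearly at each
step. Initialization is multi-start (20 starts; the first log-spaced
across `[1/t_end, 1/t_min]`, the rest randomized deterministically), since
exponential sums are multi-modal. Phases are reported sorted by decreasing
k_obs; a pair of rates within 5 % sets an `ill_conditioned` flag rather
than failing. Standard errors come from the analytic Jacobian of the full
parameter vector, scaled by the residual variance.

**Phase-count selection** minimizes small-sample AIC (AICc) over 1..4
phases, ties broken toward fewer phases. The residual variance is floored
at (1 ppm of the dynamic range)²: on noise-free simulated traces the
residual at the true phase count is integrator round-off, which is not
exponential in shape, and without the floor extra phases would "win" by
fitting numerical error. One part per million is far below any real
instrument's noise floor and two orders above the integrator tolerance.

**Saturation fits** are unweighted unless per-point errors are supplied
(then weighted, with absolute covariance), with the intercept fixed at
zero — the hyperbola passes through the origin; a free-intercept variant
exists but is off by default, and whether the original titration fits
were weighted is unknown. A fit whose K_d lands above 100× the largest
concentration, or whose K_d standard error reaches 100 % of the estimate,
raises `UnidentifiableKdError` (data consistent with a straight line
through the origin, or a titration run entirely above saturation).

**Amplitude partition** of a 450-nm trace decomposes it into at most three
exponential phases (AICc-selected) and classifies each fitted phase by its
time constant against the user-supplied phase boundaries; the reported
fraction is |A₂|/(|A₂|+|A₃|). Decomposition, rather than differencing the
trace at the boundary times, is what makes the estimate exact for
well-separated rates: the slow phase is only ~17 % complete at the 2.5 s
boundary, so a raw ΔA ratio would misattribute that growth to phase 2.

## Synthetic data

The generator emulates four instruments: stopped-flow absorbance and
fluorescence traces (log-spaced 0.002–100 s, 500 points, mirroring
stopped-flow sampling), k_obs-vs-halide titrations (8 log-spaced
concentrations spanning below and above each K_d), first-phase-amplitude
series at the seven age times of the double-mixing protocol
(0.01–30 s), and rapid-quench product fractions. Noise is additive
Gaussian at a fraction (default 2 %) of the dynamic range — PMT noise at
these signal levels is approximately Gaussian — and every output carries a
sidecar recording the full ground truth and seed; (truth, seed) →
byte-identical data. Dead time, mixing artifacts, PMT-voltage effects,
photobleaching, inner-filter effects and heteroscedastic noise are *not*
emulated, so passing round-trip tests demonstrate estimator correctness
under the stated noise model, not robustness to real instrument
pathologies.

The inactivation series is generated in amplitude space
(`floor + A₀·e^(−k_inact·age)`) rather than by simulating the double-mix
ODE per age time: the observable actually analyzed is the first-phase
amplitude, and its age dependence is exactly this decay under the scheme's
assumptions.

## Energetics

Computed potential-energy barriers for HOX formation (1.3, 5.7,
12.6 kcal/mol for I⁻, Br⁻, Cl⁻) are converted to Eyring rates,
`k = (k_B T/h)·exp(−ΔE‡/RT)` at 298.15 K, *only* to check ordering against
the measured limiting rates (Spearman rank correlation −1 expected).
Potential energies are free-energy proxies: the chloride barrier implies
~3.6e3 s⁻¹ against a measured 1.83 s⁻¹, a gap that is documented, not
reconciled — entropic, tunneling and dynamical contributions are outside
the model, as is any quantum-chemistry computation.

## Problem sizes and numerical checks

The standard analyses use 500-point traces, 8-point titrations, 7-point
age series, and 200 replicates for coverage checks; the stochastic oracle
uses 10,000 molecules, where branch-fraction agreement is asserted within
3 binomial standard deviations. The ODE path is verified against the
closed-form two-step chain to 1e-6 of the flavin pool at every grid point,
and the saturation optimizer against a 200×200 brute-force log-grid search
to within one grid cell. Degenerate inputs are rejected rather than
silently handled: equal rates in the closed-form chain, constant traces,
non-decaying inactivation series, budgets where the coupling ratio exceeds
the HOX-forming fraction.

## Known limitations

* No pH or temperature dependence (beyond the fixed-T Eyring conversion);
  no global multi-trace fitting; no SVD spectral analysis; no diode-array
  spectra.
* The capture/leak partition is a two-way split with no chemistry for the
  leaked species; distinguishing steady leakage from progressive enzyme
  inactivation within a single turnover is not possible from end-point
  budgets, and the model attributes the measured coupling loss wholly to
  the partition.
* Optical coefficients are placeholders; analyses that depend on absolute
  absorbance scales should supply measured values via the config layer.
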