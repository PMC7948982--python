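# halokin

Pre-steady-state kinetics of flavin-dependent halogenases (FDHs).

FDHs such as tryptophan 6-halogenase (Thal) are attractive biocatalysts —
they halogenate aromatic substrates regioselectively under mild conditions —
but they are slow, and much of their oxidative flux is wasted. `halokin` is
a toolbox for dissecting *where* the flux goes. It simulates the branched
catalytic cycle as a mass-action ODE system, renders the resulting flavin
populations as stopped-flow observables, and provides the fitting machinery
that turns such observables back into rate constants. A seeded
synthetic-data generator stands in for the stopped-flow and rapid-quench
instruments, so every analysis can be exercised end-to-end on data whose
ground truth is known exactly.

## The model

The catalytic cycle, written per flavin equivalent:

```
E + FADH⁻  →  E:FADH⁻  →  (Thal:FADH⁻*, inactive)          k_inact
E:FADH⁻ + O₂  →  C4aOOH-FAD                                 k_ox·[O₂]
C4aOOH-FAD  →  FAD + H₂O₂            (uncoupling)           k_unc
C4aOOH-FAD + X⁻ ⇌ C4aOOH-FAD:X⁻ → C4aOH-FAD + HOX           K_d, k_hox
C4aOH-FAD  →  FAD + H₂O              (dehydration)          k_dehyd
HOX →  Trp-X   (capture)   |   HOX → bulk  (leakage)        k_capture, k_leak
```

O₂ and halide are non-depleting baths (pseudo-first-order); halide binding
is lumped by rapid equilibrium, so the observed HOX-formation rate follows
the two-step saturation law

    k_obs = k · [X⁻] / (K_d + [X⁻]).

Iodide, bromide and chloride react (K_d = 0.064, 0.40, 0.78 mM; k = 4.51,
2.54, 1.83 s⁻¹ for Thal); fluoride does not. Competition at the two branch
points factorizes the yields: the coupling ratio (halogenated product per
flavin) is `f_hox · f_capture`, and an Eyring transition-state module checks
that computed HOX-formation barriers anti-correlate with the measured
halide reactivities (HOI > HOBr > HOCl).

Fitting covers multi-exponential phase analysis (variable projection,
multi-start, AICc phase-count selection), the saturation hyperbola above,
and the single-exponential decay of first-phase amplitude with anaerobic
age time, whose rate is the isomerization rate to the dead-end
Thal:FADH⁻* complex.

## Worked example

Simulate the halide-free oxygen reaction at 2 % instrument noise, let AICc
pick the phase count, and refit the observed rate constants; then refit an
iodide titration:

```python
import halokin as hk
from halokin import presets
from halokin.synthetic import (GeneratorTruth, NoiseModel,
                               generate_trace, generate_saturation_dataset)

params, init = presets.halide_free_oxidation()
truth = GeneratorTruth(params, init, hk.OpticalModel())
trace, sidecar = generate_trace(truth, None, "A380", presets.default_grid(),
                                NoiseModel(sigma_frac=0.02, seed=1))
n = hk.select_phase_count(trace, max_n=3)
fit = hk.fit_exponentials(trace, n)
for phase in fit.phases:
    print(f"kobs = {phase.kobs:8.4f} +/- {phase.kobs_se:.4f} s^-1   "
          f"amplitude = {phase.amplitude:+.4f}")

ds, _ = generate_saturation_dataset(0.064, 4.51, "I",
                                    presets.saturation_concentrations("I"),
                                    NoiseModel(sigma_frac=0.02, seed=2))
sat = hk.fit_saturation(ds)
print(f"Kd = {sat.kd_mM:.4f} +/- {sat.kd_se:.4f} mM,  "
      f"k = {sat.k:.3f} +/- {sat.k_se:.3f} s^-1")
```

Output:

```
kobs =  16.6114 +/- 0.1481 s^-1   amplitude = -0.0756
kobs =   0.4140 +/- 0.0085 s^-1   amplitude = +0.0302
Kd = 0.0698 +/- 0.0042 mM,  k = 4.603 +/- 0.066 s^-1
```

The two phases are C4a-hydroperoxyflavin formation (truth 16.52 s⁻¹, the
negative amplitude is the 380-nm rise) and its H₂O₂-eliminating decay
(truth 0.41 s⁻¹); both truths sit within two standard errors of the fits,
as do the iodide K_d (truth 0.064 mM) and limiting rate (truth 4.51 s⁻¹).

The same analyses are available from the shell:

```sh
halokin generate --kind trace --halide none --channel A380 --sigma 0.02 \
        --seed 1 --out trace.csv
halokin fit-trace --trace trace.csv --out fit.yaml
halokin reproduce --seed 0 --out-dir report/
```

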