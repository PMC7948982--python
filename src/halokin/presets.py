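"""Reference experimental conditions and measured constants for Thal.

These presets encode the published stopped-flow / rapid-quench operating
conditions and rate constants for tryptophan 6-halogenase (Thal) that the
synthetic-data generator uses as ground truth.  They are the package's
fixed study conditions, not tuning knobs.

Measured constants
------------------
* C4aOOH-FAD formation kobs 16.52 s^-1 at air-level oxygen (128 uM), and
  halide-free decay (H2O2 elimination) kobs 0.41 s^-1;
* halide saturation of C4aOH-FAD formation: Kd / limiting k of
  0.064 mM / 4.51 s^-1 (iodide), 0.40 mM / 2.54 s^-1 (bromide),
  0.78 mM / 1.83 s^-1 (chloride);
* chloride-present fluorescence rise 1.5 s^-1 and C4aOH-FAD dehydration
  0.073 s^-1; halide-present uncoupling phase 1.6 s^-1;
* enzyme:FADH- isomerization to the inactive complex 0.41 s^-1;
* phase-2 450-nm amplitude fractions ~20% (bromide) and ~55% (chloride);
* single-turnover bromination coupling ratio ~0.30 with ~80% of
  C4aOOH-FAD flux forming HOBr;
* computed HOX-formation barriers 1.3 / 5.7 / 12.6 kcal/mol
  (I, Br, Cl) with product energies -51.8 / -39.8 / -28.5 kcal/mol.
"""

from __future__ import annotations

import numpy as np

from .energetics import EnergeticsProfile
from .scheme import Halide, InitialConditions, RateParameters, TimeGrid

__all__ = [
    "SATURATION_TRUTH",
    "SATURATION_CONC_RANGES_MM",
    "HOX_BARRIERS_KCAL",
    "HOX_PRODUCT_ENERGIES_KCAL",
    "KOBS_FORMATION",
    "KOBS_UNCOUPLING",
    "KOBS_UNCOUPLING_HALIDE_PRESENT",
    "KOBS_C4AOH_RISE",
    "KOBS_C4AOH_DECAY",
    "K_INACTIVATION",
    "PHASE2_AMPLITUDE_FRACTION",
    "COUPLING_RATIO_BR",
    "F_HOX_BR",
    "INACTIVATION_AGES_S",
    "O2_AIR_UM",
    "energetics_profiles",
    "default_grid",
    "halide_free_oxidation",
    "chloride_fluorescence",
    "halide_present_absorbance",
    "chloride_population_partition",
    "bromide_single_turnover",
]

# --- measured constants used as generator ground truth -----------------------

#: Halide saturation constants: (Kd in mM, limiting k in s^-1, and reported SEs).
SATURATION_TRUTH: dict[Halide, tuple[float, float, float, float]] = {
    Halide.I: (0.064, 4.51, 0.021, 0.24),
    Halide.BR: (0.40, 2.54, 0.073, 0.12),
    Halide.CL: (0.78, 1.83, 0.39, 0.26),
}

#: Concentration windows (mM) spanning below and above each Kd, as in the
#: halide-titration stopped-flow experiments.
SATURATION_CONC_RANGES_MM: dict[Halide, tuple[float, float]] = {
    Halide.I: (0.01, 2.0),
    Halide.BR: (0.05, 10.0),
    Halide.CL: (0.1, 20.0),
}

#: Computed potential-energy barriers to HOX formation (kcal/mol).
HOX_BARRIERS_KCAL: dict[Halide, float] = {Halide.I: 1.3, Halide.BR: 5.7, Halide.CL: 12.6}
HOX_PRODUCT_ENERGIES_KCAL: dict[Halide, float] = {
    Halide.I: -51.8,
    Halide.BR: -39.8,
    Halide.CL: -28.5,
}

KOBS_FORMATION = 16.52      # s^-1, C4aOOH-FAD formation at 128 uM O2
KOBS_UNCOUPLING = 0.41      # s^-1, halide-free H2O2-eliminating decay
KOBS_UNCOUPLING_HALIDE_PRESENT = 1.6  # s^-1, uncoupling phase with halide present
KOBS_C4AOH_RISE = 1.5       # s^-1, chloride-present fluorescence rise
KOBS_C4AOH_DECAY = 0.073    # s^-1, C4aOH-FAD dehydration
K_INACTIVATION = 0.41       # s^-1, enzyme:FADH- isomerization to inactive complex

PHASE2_AMPLITUDE_FRACTION: dict[Halide, float] = {Halide.BR: 0.20, Halide.CL: 0.55}
COUPLING_RATIO_BR = 0.30    # halogenated Trp per flavin, bromide single turnover
F_HOX_BR = 0.80             # fraction of C4aOOH-FAD flux forming HOBr

#: Anaerobic age times (s) of the double-mixing inactivation experiment.
INACTIVATION_AGES_S = (0.01, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0)

O2_AIR_UM = 128.0           # uM dissolved O2 after mixing, air-saturated buffer
ENZYME_UM = 30.0
FADH_UM = 15.0
SATURATING_X_MM = 10.0      # mM halide, well above every Kd


def energetics_profiles() -> list[EnergeticsProfile]:
    """Energy profiles for HOX formation by I-, Br-, and Cl-."""
    return [
        EnergeticsProfile(h, e_ts=HOX_BARRIERS_KCAL[h], e_product=HOX_PRODUCT_ENERGIES_KCAL[h])
        for h in (Halide.I, Halide.BR, Halide.CL)
    ]


def default_grid() -> TimeGrid:
    """Log-spaced stopped-flow observation grid, 2 ms to 100 s, 500 points."""
    return TimeGrid.log_spaced(0.002, 100.0, 500)


def _base_init(x_conc_mM: float = 0.0) -> InitialConditions:
    return InitialConditions(
        e_free=ENZYME_UM - FADH_UM,
        e_fadh=FADH_UM,
        trp=FADH_UM,
        o2_uM=O2_AIR_UM,
        x_conc_mM=x_conc_mM,
    )


def halide_free_oxidation() -> tuple[RateParameters, InitialConditions]:
    """Fresh-mix oxygen reaction without halide: biphasic 380-nm kinetics.

    Formation at 16.52 s^-1 followed by H2O2-eliminating decay at
    0.41 s^-1.  Isomerization is off: fresh mixing leaves no time for the
    inactive complex to form before oxygen capture.
    """
    params = RateParameters(
        k_inact=0.0,
        k_ox=KOBS_FORMATION / O2_AIR_UM,
        k_unc=KOBS_UNCOUPLING,
    )
    return params, _base_init(x_conc_mM=0.0)


def chloride_fluorescence() -> tuple[RateParameters, InitialConditions, Halide]:
    """Chloride-present cascade tuned to the fluorescence observables.

    C4aOH-FAD rises at 1.5 s^-1 (10 mM Cl-, so k_hox is back-computed from
    the hyperbolic rate law) and decays at 0.073 s^-1.  Uncoupling is off
    so the fluorescent intermediate carries the whole flux, matching the
    rise/decay analysis of the fluorescence channel.
    """
    kd = SATURATION_TRUTH[Halide.CL][0]
    x = SATURATING_X_MM
    params = RateParameters(
        k_inact=0.0,
        k_ox=KOBS_FORMATION / O2_AIR_UM,
        k_unc=0.0,
        k_hox={Halide.CL: KOBS_C4AOH_RISE * (kd + x) / x, Halide.BR: 0.0, Halide.I: 0.0, Halide.F: 0.0},
        k_dehyd=KOBS_C4AOH_DECAY,
    )
    return params, _base_init(x_conc_mM=x), Halide.CL


def halide_present_absorbance(halide: Halide | str = Halide.CL) -> tuple[RateParameters, InitialConditions, Halide]:
    """Halide-present absorbance kinetics with flux competition at the branch.

    Three 450-nm phases: formation (16.52 s^-1), combined C4aOOH-FAD decay
    (uncoupling + HOX formation), and C4aOH-FAD dehydration (0.073 s^-1).
    """
    halide = Halide.coerce(halide)
    params = RateParameters(
        k_inact=0.0,
        k_ox=KOBS_FORMATION / O2_AIR_UM,
        k_unc=KOBS_UNCOUPLING,
        k_dehyd=KOBS_C4AOH_DECAY,
    )
    return params, _base_init(x_conc_mM=SATURATING_X_MM), halide


def chloride_population_partition(
    f_unc_pop: float | None = None,
) -> tuple[RateParameters, InitialConditions, Halide]:
    """Chloride reaction in population-partition mode.

    A fixed fraction of the flavin population (default: the chloride
    phase-2 amplitude fraction, 0.55) is routed to uncoupling at the
    halide-present uncoupling rate (1.6 s^-1); the rest forms C4aOH-FAD at
    the fluorescence-rise rate (1.5 s^-1) and dehydrates at 0.073 s^-1.
    """
    if f_unc_pop is None:
        f_unc_pop = PHASE2_AMPLITUDE_FRACTION[Halide.CL]
    kd = SATURATION_TRUTH[Halide.CL][0]
    x = SATURATING_X_MM
    params = RateParameters(
        k_inact=0.0,
        k_ox=KOBS_FORMATION / O2_AIR_UM,
        k_unc=KOBS_UNCOUPLING_HALIDE_PRESENT,
        k_hox={Halide.CL: KOBS_C4AOH_RISE * (kd + x) / x, Halide.BR: 0.0, Halide.I: 0.0, Halide.F: 0.0},
        k_dehyd=KOBS_C4AOH_DECAY,
        f_unc_pop=f_unc_pop,
    )
    return params, _base_init(x_conc_mM=x), Halide.CL


def bromide_single_turnover() -> tuple[RateParameters, InitialConditions, Halide]:
    """Rapid-quench bromination conditions: limiting FADH-, 5 mM Br-.

    The branch rates give an 80% HOBr-forming flux fraction and the
    capture/leak split is 0.375 / 0.625, so the single-turnover plateau is
    the 0.30 coupling ratio.
    """
    kd = SATURATION_TRUTH[Halide.BR][0]
    x = 5.0  # mM NaBr after quench
    k_unc = KOBS_UNCOUPLING
    # k_hox_obs such that f_hox = k_hox_obs / (k_unc + k_hox_obs) = F_HOX_BR
    k_hox_obs = k_unc * F_HOX_BR / (1.0 - F_HOX_BR)
    f_capture = COUPLING_RATIO_BR / F_HOX_BR
    params = RateParameters(
        k_inact=0.0,
        k_ox=KOBS_FORMATION / O2_AIR_UM,
        k_unc=k_unc,
        k_hox={Halide.BR: k_hox_obs * (kd + x) / x, Halide.CL: 0.0, Halide.I: 0.0, Halide.F: 0.0},
        k_dehyd=KOBS_C4AOH_DECAY,
        k_capture=10.0 * f_capture,
        k_leak=10.0 * (1.0 - f_capture),
    )
    init = InitialConditions(
        e_free=15.0 - 7.5,
        e_fadh=7.5,
        trp=15.0,
        o2_uM=O2_AIR_UM,
        x_conc_mM=x,
    )
    return params, init, Halide.BR


def saturation_concentrations(halide: Halide | str, n: int = 8) -> np.ndarray:
    """Log-spaced halide concentrations (mM) spanning the titration window."""
    lo, hi = SATURATION_CONC_RANGES_MM[Halide.coerce(halide)]
    return np.geomspace(lo, hi, n)
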