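"""Branched kinetic mechanism of flavin-dependent halogenase (FDH) catalysis.

The module encodes the catalytic cycle of a tryptophan halogenase such as
Thal as a mass-action reaction network and integrates it as a stiff ODE
system:

* free enzyme binds reduced flavin (FADH-) to form the active binary
  complex;
* the binary complex either isomerizes to a dead-end inactive conformer
  (``Thal:FADH-*``) or reacts with dissolved oxygen to form the
  C4a-hydroperoxyflavin intermediate (C4aOOH-FAD);
* C4aOOH-FAD partitions between uncoupling (H2O2 elimination, regenerating
  oxidized FAD) and reaction with a halide ion to form hypohalous acid
  (HOX) plus the strongly fluorescent C4a-hydroxyflavin (C4aOH-FAD);
* C4aOH-FAD dehydrates to oxidized FAD;
* nascent HOX either halogenates the bound tryptophan (capture) or leaks
  to bulk solvent.

Oxygen and halide are treated as non-depleting baths (pseudo-first-order),
matching the large excesses used in stopped-flow work (e.g. 128 uM O2
against 15 uM FADH-).  Halide binding to C4aOOH-FAD is lumped by rapid
equilibrium by default, giving the observed hyperbolic rate law
``k_hox_obs = k_hox * [X] / (Kd + [X])``; an explicit two-step binding mode
with finite on/off rates consistent with the same Kd is available for
sensitivity checks.

Two oracles accompany the integrator: :func:`closed_form_chain` (the exact
solution of two sequential irreversible steps) and
:func:`gillespie_scheme` (an exact stochastic simulation over the same
reaction network).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DegenerateRatesError, IntegrationError, ValidationError

__all__ = [
    "Halide",
    "RateParameters",
    "InitialConditions",
    "TimeGrid",
    "SpeciesTimeCourse",
    "Reaction",
    "SPECIES",
    "FLAVIN_SPECIES",
    "build_reactions",
    "simulate_scheme",
    "closed_form_chain",
    "gillespie_scheme",
    "GillespieResult",
]


class Halide(str, Enum):
    """Halide ion identity.

    Fluoride is accepted as an input everywhere but carries a zero
    HOX-formation rate: C4a-hydroperoxyflavin does not react with F-.
    """

    CL = "Cl"
    BR = "Br"
    I = "I"
    F = "F"

    @classmethod
    def coerce(cls, value: "Halide | str | None") -> "Halide | None":
        if value is None or isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError as exc:
            raise ValidationError(f"unknown halide {value!r}; expected one of Cl, Br, I, F") from exc


# Canonical species ordering used by the integrator and the CSV writer.
SPECIES: tuple[str, ...] = (
    "e_free",        # free enzyme (uM)
    "fadh_free",     # free reduced flavin (uM)
    "e_fadh",        # active enzyme:FADH- binary complex (uM)
    "e_fadh_star",   # isomerized inactive complex, cannot form C4aOOH-FAD (uM)
    "c4aooh",        # C4a-hydroperoxyflavin (productive pool) (uM)
    "c4aooh_unc",    # C4a-hydroperoxyflavin routed to uncoupling (population-partition mode only)
    "c4aooh_x",      # C4aOOH-FAD:X- complex (explicit halide-binding mode only)
    "c4aoh",         # C4a-hydroxyflavin (uM)
    "e_fad",         # oxidized FAD still enzyme-bound (uM)
    "fad_free",      # released oxidized FAD (uM)
    "hox_site",      # nascent HOX at the active site, prior to capture/leak partition (uM)
    "hox_free",      # HOX escaped to bulk (uM)
    "h2o2",          # hydrogen peroxide from uncoupling (uM)
    "trp",           # tryptophan substrate (uM)
    "trp_x",         # halogenated tryptophan product (uM)
    "leaked_trap",   # running counter of leaked HOX equivalents (uM)
)

#: Species that contain the flavin; their sum is conserved by every reaction.
FLAVIN_SPECIES: tuple[str, ...] = (
    "fadh_free",
    "e_fadh",
    "e_fadh_star",
    "c4aooh",
    "c4aooh_unc",
    "c4aooh_x",
    "c4aoh",
    "e_fad",
    "fad_free",
)

_SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

_DEFAULT_KD = {Halide.CL: 0.78, Halide.BR: 0.40, Halide.I: 0.064}
_DEFAULT_KHOX = {Halide.CL: 1.83, Halide.BR: 2.54, Halide.I: 4.51, Halide.F: 0.0}


def _as_halide_map(raw: Mapping, what: str) -> dict[Halide, float]:
    out = {}
    for key, value in raw.items():
        out[Halide.coerce(key)] = float(value)
    return out


@dataclass(frozen=True)
class RateParameters:
    """Microscopic rate constants of the FDH catalytic cycle.

    Units: bimolecular constants are per uM per s; unimolecular constants
    per s; halide dissociation constants (``kd_mM``) in mM, matching the
    millimolar halide concentrations used at the interface.

    ``f_unc_pop`` switches on population-partition mode: a fixed fraction of
    the oxygen flux is routed into a C4aOOH-FAD subpopulation that can only
    uncouple, while the remainder performs halide chemistry only.  This mode
    reproduces the experimentally observed phase-amplitude splits that
    simple flux competition between ``k_unc`` and ``k_hox_obs`` does not
    (see docs/methods.md); it is off (``None``) by default.
    """

    k_bind_flavin: float = 1.0          # uM^-1 s^-1, E + FADH- association
    k_inact: float = 0.41               # s^-1, E:FADH- -> E:FADH-* isomerization
    k_ox: float = 16.52 / 128.0         # uM^-1 s^-1, O2 + bound FADH- -> C4aOOH-FAD
    k_unc: float = 0.41                 # s^-1, C4aOOH-FAD -> FAD + H2O2
    kd_mM: Mapping[Halide, float] = field(default_factory=lambda: dict(_DEFAULT_KD))
    k_hox: Mapping[Halide, float] = field(default_factory=lambda: dict(_DEFAULT_KHOX))
    k_dehyd: float = 0.073              # s^-1, C4aOH-FAD -> FAD + H2O
    k_capture: float = 3.75             # s^-1, site HOX -> halogenated Trp
    k_leak: float = 6.25                # s^-1, site HOX -> bulk
    f_unc_pop: float | None = None      # population-partition fraction, in [0, 1]
    halide_on_rate: float | None = None  # mM^-1 s^-1; enables explicit binding mode

    def __post_init__(self):
        object.__setattr__(self, "kd_mM", _as_halide_map(self.kd_mM, "kd_mM"))
        object.__setattr__(self, "k_hox", _as_halide_map(self.k_hox, "k_hox"))
        for name in ("k_bind_flavin", "k_inact", "k_ox", "k_unc", "k_dehyd", "k_capture", "k_leak"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"rate constant {name} must be finite and >= 0, got {value}")
        for halide, value in self.k_hox.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"k_hox[{halide.value}] must be finite and >= 0, got {value}")
        if self.k_hox.get(Halide.F, 0.0) != 0.0:
            raise ValidationError("fluoride does not react with C4a-hydroperoxyflavin: k_hox[F] must be 0")
        for halide, value in self.kd_mM.items():
            if halide is not Halide.F and (not math.isfinite(value) or value <= 0):
                raise ValidationError(f"kd_mM[{halide.value}] must be finite and > 0, got {value}")
        if self.f_unc_pop is not None and not (0.0 <= self.f_unc_pop <= 1.0):
            raise ValidationError(f"f_unc_pop must lie in [0, 1], got {self.f_unc_pop}")
        if self.halide_on_rate is not None and self.halide_on_rate <= 0:
            raise ValidationError("halide_on_rate must be > 0 when given")

    def k_hox_observed(self, halide: Halide | str | None, x_conc_mM: float) -> float:
        """Rapid-equilibrium lumped HOX-formation rate at halide concentration ``x_conc_mM``.

        ``k_hox * [X] / (Kd + [X])``; zero for no halide, zero concentration,
        or fluoride.
        """
        halide = Halide.coerce(halide)
        if halide is None or x_conc_mM <= 0:
            return 0.0
        k = self.k_hox.get(halide, 0.0)
        if k == 0.0:
            return 0.0
        kd = self.kd_mM.get(halide)
        if kd is None:
            raise ValidationError(f"no dissociation constant configured for halide {halide.value}")
        return k * x_conc_mM / (kd + x_conc_mM)

    def with_updates(self, **kwargs) -> "RateParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitialConditions:
    """Initial concentrations (uM) plus the two fixed baths.

    ``o2_uM`` (uM) and ``x_conc_mM`` (mM) are held constant during a
    simulation: both are present in large excess over the flavin in all
    emulated experiments, so their depletion is negligible.

    Defaults mirror the standard single-mixing oxygen reaction: 30 uM
    enzyme, 15 uM FADH- bound at mixing, air-level oxygen.
    """

    e_free: float = 15.0
    fadh_free: float = 0.0
    e_fadh: float = 15.0
    e_fadh_star: float = 0.0
    c4aooh: float = 0.0
    c4aooh_unc: float = 0.0
    c4aooh_x: float = 0.0
    c4aoh: float = 0.0
    e_fad: float = 0.0
    fad_free: float = 0.0
    hox_site: float = 0.0
    hox_free: float = 0.0
    h2o2: float = 0.0
    trp: float = 15.0
    trp_x: float = 0.0
    leaked_trap: float = 0.0
    o2_uM: float = 128.0
    x_conc_mM: float = 0.0

    def __post_init__(self):
        for name in SPECIES + ("o2_uM", "x_conc_mM"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"initial concentration {name} must be finite and >= 0, got {value}")

    def state_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    def total_flavin(self) -> float:
        return float(sum(getattr(self, name) for name in FLAVIN_SPECIES))

    def with_updates(self, **kwargs) -> "InitialConditions":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times in seconds, first >= 0."""

    times: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("time grid must be a 1-D array with at least two points")
        if times[0] < 0 or not np.all(np.diff(times) > 0):
            raise ValidationError("time grid must be strictly increasing with first point >= 0")
        object.__setattr__(self, "times", times)

    @classmethod
    def log_spaced(cls, t_min: float = 0.002, t_max: float = 100.0, n: int = 500) -> "TimeGrid":
        """Logarithmic grid mirroring stopped-flow sampling (default 2 ms - 100 s)."""
        if t_min <= 0 or t_max <= t_min:
            raise ValidationError("log grid requires 0 < t_min < t_max")
        return cls(np.geomspace(t_min, t_max, n))

    @classmethod
    def linear(cls, t_min: float, t_max: float, n: int) -> "TimeGrid":
        return cls(np.linspace(t_min, t_max, n))

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SpeciesTimeCourse:
    """Concentration of every species on a time grid (uM)."""

    grid: TimeGrid
    conc: Mapping[str, np.ndarray]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.conc[species]

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def total_flavin(self) -> np.ndarray:
        return sum(self.conc[name] for name in FLAVIN_SPECIES)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.grid.times}
        data.update({name: self.conc[name] for name in SPECIES})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: first order in each listed reactant.

    Bath concentrations (O2, halide) are folded into ``rate_constant``, so
    every reaction is effectively uni- or bimolecular in tracked species.
    """

    name: str
    rate_constant: float
    reactants: tuple[str, ...]
    stoich: Mapping[str, int]


def build_reactions(
    params: RateParameters,
    init: InitialConditions,
    halide: Halide | str | None,
    mode: str = "rapid_eq",
) -> list[Reaction]:
    """Assemble the reaction network for the given conditions.

    ``mode`` is ``"rapid_eq"`` (default; halide binding lumped into an
    observed rate) or ``"explicit"`` (finite on/off rates consistent with
    Kd, requires ``params.halide_on_rate``).
    """
    halide = Halide.coerce(halide)
    if mode not in ("rapid_eq", "explicit"):
        raise ValidationError(f"unknown halide-binding mode {mode!r}")
    rxns: list[Reaction] = []

    def add(name, k, reactants, stoich):
        if k > 0:
            rxns.append(Reaction(name, float(k), tuple(reactants), dict(stoich)))

    add("flavin_binding", params.k_bind_flavin, ("e_free", "fadh_free"),
        {"e_free": -1, "fadh_free": -1, "e_fadh": +1})
    add("isomerization", params.k_inact, ("e_fadh",), {"e_fadh": -1, "e_fadh_star": +1})

    k_oxygen = params.k_ox * init.o2_uM
    if params.f_unc_pop is None:
        add("oxygenation", k_oxygen, ("e_fadh",), {"e_fadh": -1, "c4aooh": +1})
        add("uncoupling", params.k_unc, ("c4aooh",), {"c4aooh": -1, "e_fad": +1, "h2o2": +1})
    else:
        # Population-partition mode: the oxygen flux is split once, at
        # C4aOOH-FAD formation, into an uncoupling-only pool and a
        # halide-chemistry-only pool.
        add("oxygenation_unc_pool", k_oxygen * params.f_unc_pop, ("e_fadh",),
            {"e_fadh": -1, "c4aooh_unc": +1})
        add("oxygenation", k_oxygen * (1.0 - params.f_unc_pop), ("e_fadh",),
            {"e_fadh": -1, "c4aooh": +1})
        add("uncoupling", params.k_unc, ("c4aooh_unc",), {"c4aooh_unc": -1, "e_fad": +1, "h2o2": +1})

    hox_stoich_from = lambda src: {src: -1, "c4aoh": +1, "hox_site": +1}
    if mode == "rapid_eq":
        add("hox_formation", params.k_hox_observed(halide, init.x_conc_mM), ("c4aooh",),
            hox_stoich_from("c4aooh"))
    else:
        if params.halide_on_rate is None:
            raise ValidationError("explicit halide-binding mode requires params.halide_on_rate")
        if halide is not None and init.x_conc_mM > 0 and params.k_hox.get(halide, 0.0) > 0:
            kd = params.kd_mM[halide]
            add("halide_on", params.halide_on_rate * init.x_conc_mM, ("c4aooh",),
                {"c4aooh": -1, "c4aooh_x": +1})
            add("halide_off", params.halide_on_rate * kd, ("c4aooh_x",),
                {"c4aooh_x": -1, "c4aooh": +1})
            add("hox_formation", params.k_hox[halide], ("c4aooh_x",), hox_stoich_from("c4aooh_x"))

    add("dehydration", params.k_dehyd, ("c4aoh",), {"c4aoh": -1, "e_fad": +1})
    add("hox_capture", params.k_capture, ("hox_site",),
        {"hox_site": -1, "trp": -1, "trp_x": +1})
    add("hox_leak", params.k_leak, ("hox_site",),
        {"hox_site": -1, "hox_free": +1, "leaked_trap": +1})
    return rxns


def _compile_network(rxns: Sequence[Reaction]):
    """Flatten the reaction list into index arrays for a fast RHS."""
    ks = np.array([r.rate_constant for r in rxns])
    reactant_idx = [tuple(_SPECIES_INDEX[s] for s in r.reactants) for r in rxns]
    stoich = np.zeros((len(SPECIES), len(rxns)))
    for j, r in enumerate(rxns):
        for s, nu in r.stoich.items():
            stoich[_SPECIES_INDEX[s], j] = nu
    return ks, reactant_idx, stoich


def simulate_scheme(
    params: RateParameters,
    init: InitialConditions,
    halide: Halide | str | None,
    grid: TimeGrid,
    mode: str = "rapid_eq",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SpeciesTimeCourse:
    """Integrate the mechanism from the mixing event (t = 0) onto ``grid``.

    The initial state is the composition at t = 0 (the mixing dead point);
    the grid may start later, as in a real stopped-flow observation window.
    Small negative concentrations from integrator round-off are clipped to
    zero on output only.

    Raises :class:`IntegrationError` naming the failing interval if the
    stiff solver gives up, and propagates :class:`ValidationError` from
    invalid inputs.
    """
    rxns = build_reactions(params, init, halide, mode=mode)
    y0 = init.state_vector()
    if not rxns:
        values = np.tile(y0[:, None], (1, len(grid)))
        return SpeciesTimeCourse(grid, {name: values[i].copy() for i, name in enumerate(SPECIES)})

    ks, reactant_idx, stoich = _compile_network(rxns)

    def rhs(_t, y):
        rates = ks.copy()
        for j, idx in enumerate(reactant_idx):
            for i in idx:
                rates[j] *= y[i]
        return stoich @ rates

    sol = solve_ivp(
        rhs,
        (0.0, grid.t_end),
        y0,
        method="LSODA",
        t_eval=grid.times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"stiff integration failed on interval [{reached:.6g}, {grid.t_end:.6g}] s: {sol.message}"
        )
    values = np.clip(sol.y, 0.0, None)
    return SpeciesTimeCourse(grid, {name: values[i] for i, name in enumerate(SPECIES)})


def closed_form_chain(k1: float, k2: float, a0: float, t: np.ndarray):
    """Exact solution of the irreversible chain A -k1-> B -k2-> C.

    Returns ``(A, B, C)`` concentrations at times ``t``:

    ``A = a0 exp(-k1 t)``;
    ``B = a0 k1/(k2-k1) (exp(-k1 t) - exp(-k2 t))``;
    ``C = a0 - A - B``.

    This is the analytic oracle for the linear sub-chain
    bound FADH- -> C4aOOH-FAD -> FAD of the halide-free oxygen reaction.
    Rejects ``k1 == k2`` (within 1e-12 relative), where the two-exponential
    form is singular; use a perturbed rate instead.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValidationError("closed_form_chain requires k1 > 0 and k2 > 0")
    if abs(k1 - k2) <= 1e-12 * max(k1, k2):
        raise DegenerateRatesError(
            "k1 == k2 is a degenerate case of the sequential chain; perturb one rate"
        )
    t = np.asarray(t, dtype=float)
    a = a0 * np.exp(-k1 * t)
    b = a0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    c = a0 - a - b
    return a, b, c


@dataclass(frozen=True)
class GillespieResult:
    """Outcome of one exact stochastic realization of the scheme."""

    events: list[tuple[float, str]]
    final_counts: dict[str, int]
    event_counts: dict[str, int]
    t_end: float
    exhausted: bool  # True if total propensity hit zero before t_end

    def branch_fraction(self, numerator: str, *competing: str) -> float:
        """Fraction of events ``numerator`` among ``numerator`` plus ``competing``."""
        num = self.event_counts.get(numerator, 0)
        total = num + sum(self.event_counts.get(name, 0) for name in competing)
        if total == 0:
            raise ValidationError("no events recorded for the requested branches")
        return num / total


def gillespie_scheme(
    params: RateParameters,
    init: InitialConditions,
    halide: Halide | str | None,
    t_end: float,
    seed: int,
    molecules_per_uM: float = 1.0,
    mode: str = "rapid_eq",
) -> GillespieResult:
    """Exact stochastic simulation (direct method) of the reaction network.

    Initial concentrations are converted to integer molecule counts through
    ``molecules_per_uM``; bimolecular rate constants are rescaled by the
    same factor.  Runs are reproducible given ``seed`` and terminate
    normally (with a complete event log) if all propensities vanish before
    ``t_end``.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    rxns = build_reactions(params, init, halide, mode=mode)
    rng = np.random.default_rng(seed)
    counts = {name: int(round(getattr(init, name) * molecules_per_uM)) for name in SPECIES}
    # Bimolecular propensities scale as k/V; V enters through the count conversion.
    eff_k = [r.rate_constant / (molecules_per_uM ** (len(r.reactants) - 1)) for r in rxns]

    t = 0.0
    events: list[tuple[float, str]] = []
    event_counts: dict[str, int] = {}
    exhausted = False
    while True:
        props = np.array([
            k * math.prod(counts[s] for s in r.reactants) for k, r in zip(eff_k, rxns)
        ])
        total = props.sum()
        if total <= 0:
            exhausted = True
            break
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        j = rng.choice(len(rxns), p=props / total)
        r = rxns[j]
        for s, nu in r.stoich.items():
            counts[s] += nu
        events.append((t, r.name))
        event_counts[r.name] = event_counts.get(r.name, 0) + 1
    return GillespieResult(events, counts, event_counts, t_end, exhausted)
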