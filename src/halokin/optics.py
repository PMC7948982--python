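"""Beer-Lambert readout of flavin species onto stopped-flow detector channels.

Channels mirror the instrument configurations used to watch FDH flavin
chemistry: absorbance at 380 nm (where the C4a adducts dominate) and
450 nm (where oxidized FAD dominates), and long-pass (>495 nm emission)
fluorescence with excitation at 380 or 450 nm, where C4a-hydroxyflavin is
by far the brightest species.

Absorbance is ``sum_s eps(s) * conc_s(t) * path / 1000`` with molar
absorptivities in mM^-1 cm^-1 and concentrations in uM; fluorescence uses
relative brightness coefficients in arbitrary units per uM.  Exact
extinction coefficients of the enzyme-bound C4a adducts are not published;
the defaults below are literature-typical flavin/C4a-adduct values and are
config-overridable.  Downstream rate-constant and amplitude-fraction
analyses depend only on rate constants and relative amplitudes, so the
absolute scale of these coefficients is immaterial.  The two C4a adducts
are assigned identical (low) 450-nm absorptivity: both have a bleached
450-nm band, and giving them a common value keeps the 450-nm signal a pure
reporter of oxidized-FAD formation, which is what phase-amplitude
decomposition of that channel assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .scheme import SPECIES, SpeciesTimeCourse, TimeGrid

__all__ = ["CHANNELS", "OpticalModel", "Trace", "species_to_trace"]

CHANNELS = ("A380", "A450", "F_ex380", "F_ex450")

# Chromophore class of each mechanistic species; everything else is optically silent.
_CHROMOPHORE_CLASS = {
    "fadh_free": "FADH",
    "e_fadh": "FADH",
    "e_fadh_star": "FADH",
    "c4aooh": "C4aOOH",
    "c4aooh_unc": "C4aOOH",
    "c4aooh_x": "C4aOOH",
    "c4aoh": "C4aOH",
    "e_fad": "FAD",
    "fad_free": "FAD",
}

_SILENT_SPECIES = frozenset(
    ("e_free", "hox_site", "hox_free", "h2o2", "trp", "trp_x", "leaked_trap")
)

_DEFAULT_EPS = {  # mM^-1 cm^-1
    "A380": {"FAD": 6.0, "C4aOOH": 8.0, "C4aOH": 7.5, "FADH": 3.0},
    "A450": {"FAD": 11.3, "C4aOOH": 0.7, "C4aOH": 0.7, "FADH": 0.7},
}

_DEFAULT_PHI = {  # arbitrary units per uM; C4aOH-FAD is the strongly fluorescent species
    "F_ex380": {"C4aOH": 1.0, "C4aOOH": 0.03, "FAD": 0.02, "FADH": 0.0},
    "F_ex450": {"C4aOH": 0.5, "C4aOOH": 0.01, "FAD": 0.05, "FADH": 0.0},
}


@dataclass(frozen=True)
class OpticalModel:
    """Per-chromophore optical coefficients for each detector channel."""

    path_length_cm: float = 1.0
    eps: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        ch: dict(table) for ch, table in _DEFAULT_EPS.items()
    })
    phi: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        ch: dict(table) for ch, table in _DEFAULT_PHI.items()
    })

    def __post_init__(self):
        if self.path_length_cm <= 0:
            raise ValidationError("path length must be > 0 cm")
        for table in (*self.eps.values(), *self.phi.values()):
            for chrom, value in table.items():
                if value < 0:
                    raise ValidationError(f"optical coefficient for {chrom} must be >= 0")
        for channel, table in self.phi.items():
            c4aoh = table.get("C4aOH", 0.0)
            others = [v for chrom, v in table.items() if chrom != "C4aOH"]
            if others and c4aoh <= max(others):
                raise ValidationError(
                    f"C4aOH-FAD must be the brightest fluorophore in channel {channel}"
                )

    def coefficient(self, species: str, channel: str) -> float:
        """Signal per uM of ``species`` in ``channel`` (path length included)."""
        if channel in self.eps:
            table, scale = self.eps[channel], self.path_length_cm / 1000.0
        elif channel in self.phi:
            table, scale = self.phi[channel], 1.0
        else:
            raise ConfigError(f"unknown detector channel {channel!r}")
        if species in _SILENT_SPECIES:
            return 0.0
        chrom = _CHROMOPHORE_CLASS.get(species)
        if chrom is None:
            raise ConfigError(f"no optical coefficient configured for species {species!r}")
        return table.get(chrom, 0.0) * scale


@dataclass(frozen=True)
class Trace:
    """One detector channel's signal versus time."""

    channel: str
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.times.shape:
            raise ValidationError("trace length must match its time grid")
        if not np.all(np.isfinite(values)):
            raise ValidationError("trace values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def windowed(self, t_min: float | None = None, t_max: float | None = None) -> "Trace":
        mask = np.ones_like(self.times, dtype=bool)
        if t_min is not None:
            mask &= self.times >= t_min
        if t_max is not None:
            mask &= self.times <= t_max
        if mask.sum() < 2:
            raise ValidationError("window leaves fewer than two trace points")
        return Trace(self.channel, TimeGrid(self.times[mask]), self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "value": self.values, "channel": self.channel}
        )


def species_to_trace(tc: SpeciesTimeCourse, optics: OpticalModel, channel: str) -> Trace:
    """Project a species time course onto one detector channel.

    The signal is linear in concentrations (superposition holds), which the
    multi-exponential fitting layer relies on.
    """
    signal = np.zeros_like(tc.times)
    for species in SPECIES:
        coeff = optics.coefficient(species, channel)
        if coeff != 0.0:
            signal = signal + coeff * tc[species]
    return Trace(channel, tc.grid, signal)
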