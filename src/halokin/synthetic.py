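"""Seeded synthetic-data generator emulating the stopped-flow / quench-flow instruments.

Every generator runs the forward model (mechanism simulation plus optical
readout, or a closed-form observable), adds additive Gaussian noise scaled
to the trace's dynamic range, and returns the observable together with a
sidecar dictionary recording the exact ground truth and seed.  The same
(truth, seed) pair always reproduces byte-identical output, and the
sidecar round-trips losslessly through the YAML config layer, so every
generated file can be traced back to the parameters that produced it.

Noise is additive Gaussian on the signal: photomultiplier noise at
stopped-flow signal levels is approximately Gaussian, and no shot-noise or
heteroscedastic model is attempted.  Instrument dead time, mixing
artifacts and PMT-voltage effects are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fitting import InactivationSeries, SaturationDataset, predict_kobs
from .optics import OpticalModel, Trace, species_to_trace
from .partition import simulate_single_turnover
from .scheme import Halide, InitialConditions, RateParameters, TimeGrid, simulate_scheme

__all__ = [
    "NoiseModel",
    "GeneratorTruth",
    "generate_trace",
    "generate_saturation_dataset",
    "generate_inactivation_series",
    "generate_quench_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: sigma = ``sigma_frac`` x trace dynamic range."""

    sigma_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sigma_frac < 0:
            raise ValidationError("sigma_frac must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GeneratorTruth:
    """The full forward model behind a generated dataset."""

    params: RateParameters
    init: InitialConditions
    optics: OpticalModel

    def to_dict(self) -> dict:
        from .io import optics_to_dict, params_to_dict, init_to_dict

        return {
            "rates": params_to_dict(self.params),
            "initial": init_to_dict(self.init),
            "optics": optics_to_dict(self.optics),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorTruth":
        from .io import optics_from_dict, params_from_dict, init_from_dict

        return cls(
            params=params_from_dict(raw["rates"]),
            init=init_from_dict(raw["initial"]),
            optics=optics_from_dict(raw.get("optics", {})),
        )


def _sidecar(kind: str, noise: NoiseModel, **extra) -> dict:
    meta = {"kind": kind, "noise": {"sigma_frac": noise.sigma_frac, "seed": noise.seed}}
    meta.update(extra)
    return meta


def generate_trace(
    truth: GeneratorTruth,
    halide: Halide | str | None,
    channel: str,
    grid: TimeGrid,
    noise: NoiseModel,
    mode: str = "rapid_eq",
) -> tuple[Trace, dict]:
    """Simulate one detector channel and add seeded noise.

    Pipeline: mechanism ODE -> optical projection -> additive Gaussian
    noise with sigma = ``sigma_frac`` x (max - min) of the clean trace.
    ``sigma_frac = 0`` reproduces the deterministic trace exactly.
    """
    tc = simulate_scheme(truth.params, truth.init, halide, grid, mode=mode)
    clean = species_to_trace(tc, truth.optics, channel)
    sigma = noise.sigma_frac * float(np.ptp(clean.values))
    values = clean.values
    if sigma > 0:
        values = values + noise.rng().normal(0.0, sigma, size=values.shape)
    trace = Trace(channel, grid, values)
    sidecar = _sidecar(
        "trace",
        noise,
        truth=truth.to_dict(),
        halide=None if halide is None else Halide.coerce(halide).value,
        channel=channel,
        binding_mode=mode,
        sigma_signal=sigma,
    )
    return trace, sidecar


def generate_saturation_dataset(
    kd_mM: float,
    k: float,
    halide: Halide | str,
    conc_mM: Sequence[float],
    noise: NoiseModel,
) -> tuple[SaturationDataset, dict]:
    """Noisy kobs-vs-concentration points on the two-step hyperbola.

    Each kobs is ``k [X]/(Kd + [X])`` plus Gaussian noise with
    sigma = ``sigma_frac`` x k (the dynamic range of the saturation curve).
    The known noise sigma is recorded as the per-point standard error so
    downstream fits can weight properly; with ``sigma_frac = 0`` no SE
    column is attached and the points lie exactly on the hyperbola.
    """
    conc = np.asarray(conc_mM, dtype=float)
    if conc.size < 4 or np.unique(conc).size != conc.size:
        raise ValidationError("need at least 4 distinct concentrations")
    clean = np.array([predict_kobs(kd_mM, k, c) for c in conc])
    sigma = noise.sigma_frac * k
    if sigma > 0:
        kobs = clean + noise.rng().normal(0.0, sigma, size=clean.shape)
        se = np.full_like(clean, sigma)
    else:
        kobs, se = clean, None
    ds = SaturationDataset(Halide.coerce(halide), conc, kobs, se)
    sidecar = _sidecar(
        "saturation",
        noise,
        truth={"kd_mM": kd_mM, "k": k},
        halide=Halide.coerce(halide).value,
        sigma_kobs=sigma,
    )
    return ds, sidecar


def generate_inactivation_series(
    k_inact: float,
    ages_s: Sequence[float],
    noise: NoiseModel,
    a0: float = 0.12,
    floor: float = 0.0,
) -> tuple[InactivationSeries, dict]:
    """First-phase amplitude versus anaerobic age time.

    ``amplitude(age) = floor + a0 exp(-k_inact age)`` plus noise; the
    default ``a0`` is a typical 380-nm first-phase absorbance amplitude.
    """
    ages = np.asarray(ages_s, dtype=float)
    if np.any(ages < 0) or not np.all(np.diff(ages) > 0):
        raise ValidationError("ages must be >= 0 and strictly increasing")
    clean = floor + a0 * np.exp(-k_inact * ages)
    sigma = noise.sigma_frac * float(np.ptp(clean)) if clean.size else 0.0
    amps = clean + noise.rng().normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean
    series = InactivationSeries(ages, amps)
    sidecar = _sidecar(
        "inactivation",
        noise,
        truth={"k_inact": k_inact, "a0": a0, "floor": floor},
    )
    return series, sidecar


def generate_quench_series(
    truth: GeneratorTruth,
    halide: Halide | str,
    quench_times_s: Sequence[float],
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Halogenated-product fraction at each quench time, clipped to [0, 1].

    Returns ``(times, fractions, sidecar)``; with zero noise the series is
    monotone non-decreasing and plateaus at the coupling ratio.
    """
    times = np.asarray(quench_times_s, dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValidationError("quench times must be strictly increasing")
    clean = simulate_single_turnover(truth.params, truth.init, halide, times)
    sigma = noise.sigma_frac * float(np.ptp(clean)) if clean.size else 0.0
    fractions = clean + noise.rng().normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean
    fractions = np.clip(fractions, 0.0, 1.0)
    sidecar = _sidecar(
        "quench",
        noise,
        truth=truth.to_dict(),
        halide=Halide.coerce(halide).value,
    )
    return times, fractions, sidecar
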