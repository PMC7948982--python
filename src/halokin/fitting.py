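"""Rate-constant extraction from kinetic traces and saturation datasets.

Three fitters cover the analyses used throughout pre-steady-state FDH work:

* :func:`fit_exponentials` — sum-of-exponentials fits of stopped-flow
  traces, ``y(t) = offset + sum_i A_i exp(-kobs_i t)``, via variable
  projection with multi-start initialization (exponential sums are
  notoriously multi-modal);
* :func:`fit_saturation` — the rapid-equilibrium two-step rate law
  ``kobs = k [X] / (Kd + [X])`` for halide-dependence data;
* :func:`fit_inactivation` — single-exponential decay of the
  first-phase amplitude against anaerobic age time, whose rate is the
  enzyme:FADH- isomerization rate to the inactive complex.

Standard errors come from the Jacobian-based covariance at the optimum
(scaled by the residual variance when no measurement errors are supplied,
absolute when they are).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import (
    DegenerateTraceError,
    FitError,
    UnidentifiableKdError,
    ValidationError,
)
from .scheme import Halide
from .optics import Trace

__all__ = [
    "Phase",
    "ExpFitResult",
    "SaturationDataset",
    "SaturationFit",
    "InactivationSeries",
    "InactivationFit",
    "fit_exponentials",
    "select_phase_count",
    "predict_kobs",
    "fit_saturation",
    "fit_inactivation",
]


@dataclass(frozen=True)
class Phase:
    """One kinetic phase: observed rate constant and signed amplitude."""

    kobs: float          # s^-1
    amplitude: float     # signal units; negative amplitude = rising phase
    kobs_se: float = float("nan")
    amplitude_se: float = float("nan")


@dataclass(frozen=True)
class ExpFitResult:
    """Multi-exponential fit, phases ordered by decreasing kobs."""

    phases: tuple[Phase, ...]
    offset: float
    offset_se: float
    rmse: float
    n_points: int
    aicc: float
    ill_conditioned: bool = False  # two kobs within 5% of each other

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def kobs(self) -> tuple[float, ...]:
        return tuple(p.kobs for p in self.phases)

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for p in self.phases:
            y = y + p.amplitude * np.exp(-p.kobs * t)
        return y


def _trace_xy(trace: Trace, window) -> tuple[np.ndarray, np.ndarray]:
    if window is not None:
        trace = trace.windowed(*window)
    return trace.times, trace.values


def _varpro_residual(t, y, log_k):
    """Residual of the best linear-amplitude fit at fixed rates (variable projection)."""
    k = np.exp(np.clip(log_k, -60.0, 60.0))
    design = np.column_stack([np.exp(-np.outer(t, k)), np.ones_like(t)])
    amps, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ amps - y, amps, design


def _fit_exponentials_xy(
    t: np.ndarray,
    y: np.ndarray,
    n_phases: int,
    n_starts: int = 20,
) -> ExpFitResult:
    if n_phases < 1:
        raise ValidationError("n_phases must be >= 1")
    n_min = 5 * (2 * n_phases + 1)
    if t.size < n_min:
        raise ValidationError(
            f"need at least {n_min} points to fit {n_phases} phases, got {t.size}"
        )
    span = float(np.ptp(y))
    scale = max(abs(float(np.max(y))), abs(float(np.min(y))), 1.0)
    if span <= 1e-12 * scale:
        raise DegenerateTraceError("trace is constant: no decaying component to fit")

    t_pos = t[t > 0]
    if t_pos.size == 0:
        raise ValidationError("trace must contain positive times")
    k_lo, k_hi = 1.0 / t.max(), 1.0 / t_pos.min()
    if k_hi <= k_lo:
        k_hi = k_lo * 1e4
    rng = np.random.default_rng(1234)  # fixed: starts are deterministic

    best = None
    for start in range(n_starts):
        if start == 0:
            ks0 = np.geomspace(k_lo * 2, k_hi / 2, n_phases)
        else:
            ks0 = np.exp(rng.uniform(math.log(k_lo), math.log(k_hi), n_phases))
        try:
            sol = least_squares(
                lambda lk: _varpro_residual(t, y, lk)[0],
                np.log(np.sort(ks0)),
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=4000,
            )
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitError(f"{n_phases}-exponential fit failed to converge from any start")

    rss, log_k = best
    resid, amps, design = _varpro_residual(t, y, log_k)
    k = np.exp(log_k)
    order = np.argsort(-k)
    k, amp = k[order], amps[:-1][order]
    offset = float(amps[-1])

    # Covariance of the full nonlinear parameter vector (k_i, A_i, offset).
    jac = np.column_stack(
        [-amp[i] * t * np.exp(-k[i] * t) for i in range(n_phases)]
        + [np.exp(-k[i] * t) for i in range(n_phases)]
        + [np.ones_like(t)]
    )
    dof = max(t.size - (2 * n_phases + 1), 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(2 * n_phases + 1, np.nan)

    phases = tuple(
        Phase(float(k[i]), float(amp[i]), float(se[i]), float(se[n_phases + i]))
        for i in range(n_phases)
    )
    ill = any(
        abs(k[i] - k[j]) < 0.05 * max(k[i], k[j])
        for i in range(n_phases)
        for j in range(i + 1, n_phases)
    )
    n_par = 2 * n_phases + 1
    aicc = _aicc(rss, t.size, n_par, span)
    return ExpFitResult(
        phases=phases,
        offset=offset,
        offset_se=float(se[-1]),
        rmse=math.sqrt(rss / t.size),
        n_points=int(t.size),
        aicc=aicc,
        ill_conditioned=ill,
    )


def _aicc(rss: float, n: int, p: int, span: float) -> float:
    # Variance floor keeps noise-free fits comparable: residual structure below
    # ~1 ppm of the dynamic range (integrator round-off, not chemistry) must
    # not reward extra phases.
    floor = (1e-6 * max(span, 1e-300)) ** 2
    var = rss / n + floor
    aic = n * math.log(var) + 2 * p
    if n - p - 1 > 0:
        aic += 2 * p * (p + 1) / (n - p - 1)
    return aic


def fit_exponentials(
    trace: Trace,
    n_phases: int,
    window: tuple[float | None, float | None] | None = None,
    n_starts: int = 20,
) -> ExpFitResult:
    """Least-squares multi-exponential fit of one trace.

    ``window`` optionally restricts the fit to ``(t_min, t_max)`` seconds,
    mirroring the per-phase windows used in manual stopped-flow analysis;
    the default is a global fit.  Initialization is multi-start: rate seeds
    log-spaced (then randomized, deterministically) across the observable
    window, amplitudes obtained by linear solve at fixed rates; the best of
    ``n_starts`` attempts is kept and polished.

    Raises :class:`DegenerateTraceError` for a constant trace and
    :class:`FitError` if no start converges.  Near-degenerate rate pairs
    (within 5%) are flagged via ``ill_conditioned`` rather than rejected.
    """
    t, y = _trace_xy(trace, window)
    return _fit_exponentials_xy(t, y, n_phases, n_starts=n_starts)


def select_phase_count(
    trace: Trace,
    max_n: int = 4,
    window: tuple[float | None, float | None] | None = None,
) -> int:
    """Pick the number of kinetic phases by small-sample AIC.

    Fits 1..``max_n`` exponentials and returns the count minimizing AICc,
    breaking ties toward the smaller model.  A residual-variance floor near
    numerical precision makes noise-free data prefer the true phase count
    instead of rewarding meaningless extra exponentials.
    """
    if max_n < 1 or max_n > 4:
        raise ValidationError("max_n must be between 1 and 4")
    t, y = _trace_xy(trace, window)
    best_n, best_aicc = None, np.inf
    last_error: FitError | None = None
    for n in range(1, max_n + 1):
        try:
            fit = _fit_exponentials_xy(t, y, n)
        except (FitError, ValidationError) as exc:
            if isinstance(exc, DegenerateTraceError):
                raise
            last_error = exc if isinstance(exc, FitError) else last_error
            continue
        if fit.aicc < best_aicc - 1e-9:
            best_n, best_aicc = n, fit.aicc
    if best_n is None:
        raise FitError("no exponential model could be fitted", best_attempt=last_error)
    return best_n


def predict_kobs(kd_mM: float, k: float, conc_mM: float) -> float:
    """Observed rate of the rapid-equilibrium two-step reaction.

    ``kobs = k * [X] / (Kd + [X])``: zero at zero halide, approaching the
    chemistry-limited ``k`` at saturation, half-maximal at ``[X] = Kd``.
    """
    if kd_mM <= 0:
        raise ValidationError("Kd must be > 0")
    if conc_mM < 0:
        raise ValidationError("halide concentration must be >= 0")
    return k * conc_mM / (kd_mM + conc_mM)


@dataclass(frozen=True)
class SaturationDataset:
    """kobs of C4aOH-FAD formation at a series of halide concentrations."""

    halide: Halide | None
    conc_mM: np.ndarray
    kobs: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.conc_mM, dtype=float)
        kobs = np.asarray(self.kobs, dtype=float)
        if conc.shape != kobs.shape or conc.ndim != 1:
            raise ValidationError("conc and kobs must be 1-D arrays of equal length")
        if np.any(conc < 0):
            raise ValidationError("halide concentrations must be >= 0")
        if np.unique(conc).size != conc.size:
            raise ValidationError("halide concentrations must be distinct")
        object.__setattr__(self, "conc_mM", conc)
        object.__setattr__(self, "kobs", kobs)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != conc.shape or np.any(se < 0):
                raise ValidationError("se must match conc in length and be >= 0")
            object.__setattr__(self, "se", se)
        object.__setattr__(self, "halide", Halide.coerce(self.halide))

    def __len__(self) -> int:
        return int(self.conc_mM.size)


@dataclass(frozen=True)
class SaturationFit:
    """Hyperbolic two-step fit: dissociation constant and limiting rate."""

    kd_mM: float
    kd_se: float
    k: float
    k_se: float
    rmse: float
    n_points: int
    halide: Halide | None = None
    intercept: float = 0.0
    intercept_se: float = 0.0


def fit_saturation(ds: SaturationDataset, allow_intercept: bool = False) -> SaturationFit:
    """Fit ``kobs = k [X]/(Kd + [X])`` to a halide-saturation dataset.

    Weighted least squares when per-point standard errors are present
    (absolute covariance), unweighted otherwise (covariance scaled by the
    residual variance).  The intercept is fixed at zero by default — the
    hyperbola passes through the origin — with an optional free intercept
    for a reversible halide-reaction variant.

    Raises :class:`UnidentifiableKdError` when the data carry no curvature
    (straight line through the origin, or Kd unresolvable relative to its
    own uncertainty).
    """
    if len(ds) < 4:
        raise ValidationError("saturation fitting requires at least 4 distinct concentrations")
    conc, kobs = ds.conc_mM, ds.kobs
    k0 = max(float(np.max(kobs)) * 1.05, 1e-6)
    half = k0 / 2.0
    idx = int(np.argmin(np.abs(kobs - half)))
    kd0 = float(conc[idx]) if conc[idx] > 0 else float(np.median(conc[conc > 0]))

    if allow_intercept:
        def model(c, kd, k, b):
            return b + k * c / (kd + c)
        p0 = (kd0, k0, 0.0)
        lower, upper = (1e-12, 1e-12, -np.inf), (np.inf, np.inf, np.inf)
    else:
        def model(c, kd, k):
            return k * c / (kd + c)
        p0 = (kd0, k0)
        lower, upper = (1e-12, 1e-12), (np.inf, np.inf)

    sigma = ds.se if (ds.se is not None and np.all(ds.se > 0)) else None
    try:
        popt, pcov = curve_fit(
            model,
            conc,
            kobs,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=(lower, upper),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"saturation fit did not converge: {exc}") from exc

    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = kobs - model(conc, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    kd, k = float(popt[0]), float(popt[1])
    fit = SaturationFit(
        kd_mM=kd,
        kd_se=float(se[0]),
        k=k,
        k_se=float(se[1]),
        rmse=rmse,
        n_points=len(ds),
        halide=ds.halide,
        intercept=float(popt[2]) if allow_intercept else 0.0,
        intercept_se=float(se[2]) if allow_intercept else 0.0,
    )
    c_max = float(np.max(conc))
    rel_se = fit.kd_se / kd if kd > 0 else np.inf
    if kd > 100.0 * c_max or not math.isfinite(rel_se) or rel_se >= 1.0:
        raise UnidentifiableKdError(
            "saturation data carry no usable curvature: Kd is unidentifiable "
            f"(Kd = {kd:.3g} mM, SE = {fit.kd_se:.3g}, max conc = {c_max:.3g} mM)",
            best_attempt=fit,
        )
    return fit


@dataclass(frozen=True)
class InactivationSeries:
    """First-phase 380-nm amplitude versus anaerobic age (incubation) time."""

    age_s: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self):
        age = np.asarray(self.age_s, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if age.shape != amp.shape or age.ndim != 1:
            raise ValidationError("age and amplitude must be 1-D arrays of equal length")
        if np.any(age < 0) or not np.all(np.diff(age) > 0):
            raise ValidationError("age times must be >= 0 and strictly increasing")
        object.__setattr__(self, "age_s", age)
        object.__setattr__(self, "amplitude", amp)

    def __len__(self) -> int:
        return int(self.age_s.size)


@dataclass(frozen=True)
class InactivationFit:
    """Single-exponential decay of first-phase yield with age time."""

    k_inact: float   # s^-1, isomerization rate to the inactive complex
    k_se: float
    a0: float        # decaying amplitude at age 0
    floor: float     # residual amplitude at long age
    rmse: float
    n_points: int


def fit_inactivation(series: InactivationSeries) -> InactivationFit:
    """Fit ``amplitude(age) = floor + A0 exp(-k_inact age)``.

    The shortest preincubation gives the maximal C4aOOH-FAD yield; a series
    that does not decay (flat, or rising) is rejected with
    :class:`FitError`.
    """
    if len(series) < 4:
        raise ValidationError("inactivation fitting requires at least 4 points")
    t, y = series.age_s, series.amplitude
    span = float(np.ptp(y))
    scale = max(abs(float(np.max(y))), 1.0)
    if span <= 1e-12 * scale:
        raise FitError("amplitude series does not decay (constant)")
    if y[0] <= y[-1]:
        raise FitError("amplitude series does not decay (no loss of first-phase yield)")

    floor0 = float(np.min(y))
    a00 = span
    half_level = floor0 + span / 2.0
    below = np.nonzero(y <= half_level)[0]
    t_half = float(t[below[0]]) if below.size and t[below[0]] > 0 else float(np.median(t[t > 0]))
    k0 = math.log(2.0) / t_half

    def model(tt, k, a0, floor):
        return floor + a0 * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=(k0, a00, floor0),
            bounds=((1e-12, 1e-12, -np.inf), (np.inf, np.inf, np.inf)),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"inactivation fit did not converge: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = y - model(t, *popt)
    return InactivationFit(
        k_inact=float(popt[0]),
        k_se=float(se[0]),
        a0=float(popt[1]),
        floor=float(popt[2]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(series),
    )
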