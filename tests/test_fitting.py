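"""Fitters: exact recovery on clean data, honest uncertainties on noisy data."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import halokin as hk
from halokin import presets
from halokin.fitting import InactivationSeries, SaturationDataset
from halokin.optics import Trace
from halokin.scheme import TimeGrid
from halokin.synthetic import NoiseModel, generate_inactivation_series, generate_saturation_dataset


def _trace(times, values, channel="A380"):
    return Trace(channel, TimeGrid(times), np.asarray(values, dtype=float))


class TestFitExponentials:
    def test_single_exponential_exact_recovery(self):
        """A clean first-order rise comes back with its kobs to 0.1%."""
        t = np.geomspace(0.002, 1.0, 200)
        trace = _trace(t, 1.0 - np.exp(-16.52 * t))
        fit = hk.fit_exponentials(trace, 1)
        assert fit.phases[0].kobs == pytest.approx(16.52, rel=1e-3)
        assert fit.phases[0].amplitude == pytest.approx(-1.0, rel=1e-3)
        assert fit.offset == pytest.approx(1.0, rel=1e-3)

    def test_biexponential_recovery_of_fluorescence_rates(self):
        """Rise 1.5 s^-1 and decay 0.073 s^-1 recovered within 0.5% each."""
        t = np.geomspace(0.01, 100.0, 400)
        y = 0.3 - 0.9 * np.exp(-1.5 * t) + 0.6 * np.exp(-0.073 * t)
        fit = hk.fit_exponentials(_trace(t, y), 2)
        assert fit.phases[0].kobs == pytest.approx(1.5, rel=5e-3)
        assert fit.phases[1].kobs == pytest.approx(0.073, rel=5e-3)

    def test_phases_sorted_by_decreasing_kobs(self, halide_free_trace):
        fit = hk.fit_exponentials(halide_free_trace, 2)
        kobs = fit.kobs()
        assert all(kobs[i] > kobs[i + 1] for i in range(len(kobs) - 1))

    def test_constant_trace_is_rejected(self):
        t = np.linspace(0.01, 10, 100)
        with pytest.raises(hk.DegenerateTraceError):
            hk.fit_exponentials(_trace(t, np.full_like(t, 0.7)), 1)

    def test_too_few_points_rejected(self):
        t = np.linspace(0.01, 1, 10)
        with pytest.raises(hk.ValidationError):
            hk.fit_exponentials(_trace(t, np.exp(-t)), 1)

    def test_near_degenerate_rates_flagged(self):
        t = np.geomspace(0.01, 10, 300)
        y = np.exp(-1.0 * t) + np.exp(-1.03 * t)
        fit = hk.fit_exponentials(_trace(t, y), 2)
        assert fit.ill_conditioned

    def test_window_restricts_the_fit(self):
        t = np.geomspace(0.002, 100, 500)
        y = 1.0 - np.exp(-16.52 * t) + 0.5 * np.exp(-0.073 * t)
        fit = hk.fit_exponentials(_trace(t, y), 1, window=(2.5, 100.0))
        assert fit.phases[0].kobs == pytest.approx(0.073, rel=1e-2)

    def test_noisy_recovery_within_two_se(self):
        """2% noise, 500 points: truth falls inside +/-2 SE in >=95% of replicates."""
        t = np.geomspace(0.002, 1.0, 500)
        clean = 1.0 - np.exp(-16.52 * t)
        sigma = 0.02 * np.ptp(clean)
        hits = total = 0
        for rep in range(200):
            rng = np.random.default_rng(5000 + rep)
            trace = _trace(t, clean + rng.normal(0, sigma, t.size))
            fit = hk.fit_exponentials(trace, 1, n_starts=5)
            hits += abs(fit.phases[0].kobs - 16.52) <= 2 * fit.phases[0].kobs_se
            total += 1
        assert hits / total >= 0.95


class TestSelectPhaseCount:
    def test_clean_single_exponential_selects_one(self):
        t = np.geomspace(0.002, 1.0, 200)
        assert hk.select_phase_count(_trace(t, np.exp(-3.0 * t)), 4) == 1

    def test_halide_free_absorbance_has_two_phases(self, halide_free_trace):
        assert hk.select_phase_count(halide_free_trace, 4) == 2

    def test_halide_present_450nm_has_three_phases(self, chloride_a450_trace):
        assert hk.select_phase_count(chloride_a450_trace, 4) == 3

    def test_constant_trace_propagates_error(self):
        t = np.linspace(0.01, 10, 100)
        with pytest.raises(hk.DegenerateTraceError):
            hk.select_phase_count(_trace(t, np.ones_like(t)), 3)


class TestPredictKobs:
    def test_half_saturation_identity(self):
        assert hk.predict_kobs(0.064, 4.51, 0.064) == pytest.approx(4.51 / 2)

    def test_zero_concentration(self):
        assert hk.predict_kobs(0.78, 1.83, 0.0) == 0.0

    def test_chloride_at_ten_millimolar(self):
        assert hk.predict_kobs(0.78, 1.83, 10.0) == pytest.approx(1.6976, rel=1e-3)

    @given(conc=st.floats(min_value=0, max_value=1e4))
    def test_bounded_by_limiting_rate(self, conc):
        k = hk.predict_kobs(0.4, 2.54, conc)
        assert 0.0 <= k <= 2.54

    def test_invalid_inputs(self):
        with pytest.raises(hk.ValidationError):
            hk.predict_kobs(-1.0, 2.0, 1.0)
        with pytest.raises(hk.ValidationError):
            hk.predict_kobs(1.0, 2.0, -1.0)


class TestFitSaturation:
    @pytest.mark.parametrize("halide", [hk.Halide.I, hk.Halide.BR, hk.Halide.CL])
    def test_exact_recovery_per_halide(self, halide):
        kd, k, *_ = presets.SATURATION_TRUTH[halide]
        ds, _ = generate_saturation_dataset(
            kd, k, halide, presets.saturation_concentrations(halide), NoiseModel(0.0, 0)
        )
        fit = hk.fit_saturation(ds)
        assert fit.kd_mM == pytest.approx(kd, rel=1e-3)
        assert fit.k == pytest.approx(k, rel=1e-3)

    def test_scale_equivariance(self):
        """Rescaling concentrations rescales Kd and leaves k untouched."""
        conc = np.geomspace(0.01, 2.0, 8)
        ds, _ = generate_saturation_dataset(0.064, 4.51, "I", conc, NoiseModel(0.0, 0))
        scaled = SaturationDataset(ds.halide, ds.conc_mM * 3.0, ds.kobs)
        base = hk.fit_saturation(ds)
        fit = hk.fit_saturation(scaled)
        assert fit.kd_mM == pytest.approx(3.0 * base.kd_mM, rel=1e-6)
        assert fit.k == pytest.approx(base.k, rel=1e-6)

    def test_fitted_constants_reproduce_halide_ordering(self):
        """Refit constants keep k(I) > k(Br) > k(Cl) and Kd(I) < Kd(Br) < Kd(Cl)."""
        fits = {}
        for halide, (kd, k, *_) in presets.SATURATION_TRUTH.items():
            ds, _ = generate_saturation_dataset(
                kd, k, halide, presets.saturation_concentrations(halide), NoiseModel(0.0, 0)
            )
            fits[halide] = hk.fit_saturation(ds)
        assert fits[hk.Halide.I].k > fits[hk.Halide.BR].k > fits[hk.Halide.CL].k
        assert fits[hk.Halide.I].kd_mM < fits[hk.Halide.BR].kd_mM < fits[hk.Halide.CL].kd_mM

    def test_linear_data_unidentifiable(self):
        """kobs proportional to concentration carries no Kd information."""
        conc = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        ds = SaturationDataset(None, conc, 0.5 * conc)
        with pytest.raises(hk.UnidentifiableKdError):
            hk.fit_saturation(ds)

    def test_fully_saturated_data_unidentifiable(self):
        """Every point far above Kd: the fitted Kd is flagged, not silently reported."""
        conc = np.geomspace(50, 500, 6)  # Kd truth 0.064: all >> Kd
        rng = np.random.default_rng(2)
        kobs = 4.51 * conc / (0.064 + conc) + rng.normal(0, 0.09, conc.size)
        ds = SaturationDataset(hk.Halide.I, conc, kobs)
        with pytest.raises(hk.UnidentifiableKdError):
            hk.fit_saturation(ds)

    def test_too_few_points(self):
        ds = SaturationDataset(None, np.array([0.1, 1.0, 5.0]), np.array([0.5, 1.5, 2.0]))
        with pytest.raises(hk.ValidationError):
            hk.fit_saturation(ds)


class TestFitInactivation:
    def test_exact_recovery_of_isomerization_rate(self):
        series, _ = generate_inactivation_series(
            0.41, presets.INACTIVATION_AGES_S, NoiseModel(0.0, 0)
        )
        fit = hk.fit_inactivation(series)
        assert fit.k_inact == pytest.approx(0.41, rel=1e-3)

    def test_shortest_age_gives_nearly_full_amplitude(self):
        """At 0.01 s of anaerobic aging essentially no complex has isomerized."""
        series, _ = generate_inactivation_series(
            0.41, presets.INACTIVATION_AGES_S, NoiseModel(0.0, 0), a0=0.12, floor=0.0
        )
        assert series.amplitude[0] == pytest.approx(0.12, rel=0.01)

    def test_flat_series_rejected(self):
        series = InactivationSeries(np.array([0.01, 1.0, 5.0, 30.0]), np.full(4, 0.12))
        with pytest.raises(hk.FitError):
            hk.fit_inactivation(series)

    def test_rising_series_rejected(self):
        series = InactivationSeries(np.array([0.01, 1.0, 5.0, 30.0]), np.array([0.1, 0.2, 0.3, 0.4]))
        with pytest.raises(hk.FitError):
            hk.fit_inactivation(series)
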