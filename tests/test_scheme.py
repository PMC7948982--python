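"""Mechanism simulation: conservation laws, analytic oracle, stochastic oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import halokin as hk
from halokin import presets
from halokin.scheme import FLAVIN_SPECIES

RATES = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def test_flavin_is_conserved_in_every_preset(grid):
    """The flavin never leaves the system: its total is constant to 1e-6 relative."""
    configs = [
        (*presets.halide_free_oxidation(), None),
        presets.chloride_fluorescence(),
        presets.halide_present_absorbance("Br"),
        presets.chloride_population_partition(),
        presets.bromide_single_turnover(),
    ]
    for params, init, halide in configs:
        tc = hk.simulate_scheme(params, init, halide, grid)
        total = tc.total_flavin()
        assert np.allclose(total, init.total_flavin(), rtol=1e-6)


def test_simulation_matches_closed_form_chain(halide_free_timecourse):
    """The linear sub-chain FADH- -> C4aOOH -> FAD agrees with the exact solution.

    Agreement is measured relative to the total flavin pool (the natural
    concentration scale of the experiment).
    """
    tc = halide_free_timecourse
    a0 = 15.0
    a, b, c = hk.closed_form_chain(presets.KOBS_FORMATION, presets.KOBS_UNCOUPLING, a0, tc.times)
    assert np.max(np.abs(tc["e_fadh"] - a)) / a0 < 1e-6
    assert np.max(np.abs(tc["c4aooh"] - b)) / a0 < 1e-6
    assert np.max(np.abs(tc["e_fad"] - c)) / a0 < 1e-6


def test_closed_form_chain_limits_and_peak():
    """t=0 gives (A0,0,0); completion gives (0,0,A0); B peaks at ln(k1/k2)/(k1-k2)."""
    k1, k2, a0 = 16.52, 0.41, 15.0
    a, b, c = hk.closed_form_chain(k1, k2, a0, np.array([0.0]))
    assert (a[0], b[0], c[0]) == (a0, 0.0, 0.0)
    a, b, c = hk.closed_form_chain(k1, k2, a0, np.array([2000.0]))
    assert a[0] < 1e-9 and b[0] < 1e-9 and abs(c[0] - a0) < 1e-9
    t_peak = math.log(k1 / k2) / (k1 - k2)
    assert t_peak == pytest.approx(0.229, abs=5e-4)
    _, b_peak, _ = hk.closed_form_chain(k1, k2, a0, np.array([t_peak]))
    assert b_peak[0] == pytest.approx(0.910 * a0, rel=1e-3)
    # peak really is the maximum
    _, b_near, _ = hk.closed_form_chain(k1, k2, a0, np.array([t_peak * 0.9, t_peak * 1.1]))
    assert b_peak[0] >= b_near.max()


def test_closed_form_chain_rejects_equal_rates():
    with pytest.raises(hk.DegenerateRatesError):
        hk.closed_form_chain(1.0, 1.0, 10.0, np.array([0.1]))


@given(k1=RATES, k2=RATES, t=st.floats(min_value=0.0, max_value=1e3))
def test_closed_form_chain_is_a_probability_split(k1, k2, t):
    """A, B, C are non-negative and sum to A0 for any rate pair and time."""
    if abs(k1 - k2) <= 1e-9 * max(k1, k2):
        return
    a, b, c = hk.closed_form_chain(k1, k2, 1.0, np.array([t]))
    assert a[0] + b[0] + c[0] == pytest.approx(1.0, abs=1e-9)
    assert min(a[0], b[0], c[0]) >= -1e-12


def test_zero_rates_freeze_all_concentrations(grid):
    params = hk.RateParameters(
        k_bind_flavin=0, k_inact=0, k_ox=0, k_unc=0, k_dehyd=0, k_capture=0, k_leak=0,
        k_hox={"Cl": 0, "Br": 0, "I": 0, "F": 0},
    )
    init = hk.InitialConditions(x_conc_mM=10.0)
    tc = hk.simulate_scheme(params, init, "Cl", grid)
    for name in hk.SPECIES:
        assert np.allclose(tc[name], getattr(init, name), atol=1e-12)


def test_fluoride_never_forms_c4a_hydroxyflavin(grid):
    """F- binds nowhere in the chemistry: the fluorescent intermediate stays at zero."""
    params, init, _ = presets.halide_present_absorbance("Cl")
    init = init.with_updates(x_conc_mM=50.0)
    tc = hk.simulate_scheme(params, init, hk.Halide.F, grid)
    assert np.all(tc["c4aoh"] == 0.0)
    assert np.all(tc["hox_free"] == 0.0)


def test_fluoride_hox_rate_must_be_zero():
    with pytest.raises(hk.ValidationError):
        hk.RateParameters(k_hox={"Cl": 1.83, "Br": 2.54, "I": 4.51, "F": 0.5})


def test_negative_rate_is_rejected():
    with pytest.raises(hk.ValidationError):
        hk.RateParameters(k_unc=-0.1)
    with pytest.raises(hk.ValidationError):
        hk.InitialConditions(e_fadh=-1.0)


def test_halide_flux_increases_with_concentration(grid):
    """Cumulative HOX output never decreases as the halide bath is raised."""
    params, init, halide = presets.halide_present_absorbance("Cl")
    produced = []
    for x in (0.0, 0.2, 1.0, 5.0, 20.0):
        tc = hk.simulate_scheme(params, init.with_updates(x_conc_mM=x), halide, grid)
        produced.append(tc["trp_x"][-1] + tc["hox_free"][-1] + tc["hox_site"][-1])
    assert np.all(np.diff(produced) >= -1e-9)
    assert produced[0] == pytest.approx(0.0, abs=1e-9)


def test_observed_hox_rate_saturates():
    """At 100x Kd the lumped rate is within 1% of the chemistry-limited k."""
    params = hk.RateParameters()
    for halide in (hk.Halide.CL, hk.Halide.BR, hk.Halide.I):
        kd = params.kd_mM[halide]
        k = params.k_hox[halide]
        assert params.k_hox_observed(halide, 100 * kd) == pytest.approx(k, rel=0.01)
        assert params.k_hox_observed(halide, 0.0) == 0.0


def test_explicit_binding_mode_matches_rapid_equilibrium(grid):
    """With fast on/off rates at the same Kd the two binding modes coincide."""
    params, init, halide = presets.chloride_fluorescence()
    fast = params.with_updates(halide_on_rate=500.0)  # mM^-1 s^-1 >> chemistry
    tc_lumped = hk.simulate_scheme(params, init, halide, grid)
    tc_explicit = hk.simulate_scheme(fast, init, halide, grid, mode="explicit")
    c4aoh_total = tc_explicit["c4aoh"]
    assert np.max(np.abs(c4aoh_total - tc_lumped["c4aoh"])) / 15.0 < 5e-3


def test_explicit_mode_requires_on_rate(grid):
    params, init, halide = presets.chloride_fluorescence()
    with pytest.raises(hk.ValidationError):
        hk.simulate_scheme(params, init, halide, grid, mode="explicit")


def test_time_grid_validation():
    with pytest.raises(hk.ValidationError):
        hk.TimeGrid(np.array([0.0, 0.0, 1.0]))
    with pytest.raises(hk.ValidationError):
        hk.TimeGrid(np.array([-1.0, 1.0]))
    assert len(hk.TimeGrid.log_spaced(0.002, 100, 50)) == 50


class TestGillespie:
    def test_same_seed_gives_identical_event_logs(self):
        params, init, halide = presets.halide_present_absorbance("Cl")
        a = hk.gillespie_scheme(params, init, halide, 50.0, seed=3)
        b = hk.gillespie_scheme(params, init, halide, 50.0, seed=3)
        assert a.events == b.events
        assert a.final_counts == b.final_counts

    def test_single_molecule_with_only_uncoupling(self):
        """One C4aOOH-FAD molecule and one open channel: exactly one uncoupling event."""
        params = hk.RateParameters(
            k_bind_flavin=0, k_inact=0, k_ox=0, k_unc=0.41, k_dehyd=0,
            k_capture=0, k_leak=0,
        )
        init = hk.InitialConditions(e_free=0, e_fadh=0, c4aooh=1, trp=0, o2_uM=0)
        res = hk.gillespie_scheme(params, init, "Cl", 1e4, seed=0)
        assert res.event_counts == {"uncoupling": 1}
        assert res.exhausted

    def test_branch_fractions_match_deterministic_split(self):
        """10,000 molecules: stochastic branch fractions sit within 3 binomial SD."""
        params = hk.RateParameters(k_bind_flavin=0, k_inact=0, k_ox=0, k_unc=0.41)
        init = hk.InitialConditions(
            e_free=0, e_fadh=0, c4aooh=10_000, trp=20_000, o2_uM=0, x_conc_mM=10.0
        )
        n = 10_000
        res = hk.gillespie_scheme(params, init, "Cl", 1e5, seed=11)
        k_hox_obs = params.k_hox_observed("Cl", 10.0)
        expected = params.k_unc / (params.k_unc + k_hox_obs)
        sd3 = 3 * math.sqrt(expected * (1 - expected) / n)
        assert abs(res.branch_fraction("uncoupling", "hox_formation") - expected) < sd3
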