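"""Shared fixtures: reference-condition simulations reused across test modules.

Simulation-backed traces are session-scoped — they are deterministic and
moderately expensive, and many tests only read them.
"""

import numpy as np
import pytest
from hypothesis import settings

import halokin as hk
from halokin import presets
from halokin.synthetic import GeneratorTruth, NoiseModel, generate_trace

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return presets.default_grid()


@pytest.fixture(scope="session")
def optics():
    return hk.OpticalModel()


@pytest.fixture(scope="session")
def halide_free_trace(grid, optics):
    """Noise-free 380-nm absorbance trace of the halide-free oxygen reaction."""
    params, init = presets.halide_free_oxidation()
    trace, _ = generate_trace(GeneratorTruth(params, init, optics), None, "A380", grid, NoiseModel(0.0, 0))
    return trace


@pytest.fixture(scope="session")
def chloride_fluorescence_trace(grid, optics):
    """Noise-free Ex-380 fluorescence trace of the chloride-present cascade."""
    params, init, halide = presets.chloride_fluorescence()
    trace, _ = generate_trace(GeneratorTruth(params, init, optics), halide, "F_ex380", grid, NoiseModel(0.0, 0))
    return trace


@pytest.fixture(scope="session")
def chloride_a450_trace(grid, optics):
    """Noise-free 450-nm trace with chloride present (flux-competition mode)."""
    params, init, halide = presets.halide_present_absorbance("Cl")
    trace, _ = generate_trace(GeneratorTruth(params, init, optics), halide, "A450", grid, NoiseModel(0.0, 0))
    return trace


@pytest.fixture(scope="session")
def population_a450_trace(grid, optics):
    """Noise-free 450-nm chloride trace in population-partition mode (f = 0.55)."""
    params, init, halide = presets.chloride_population_partition()
    trace, _ = generate_trace(GeneratorTruth(params, init, optics), halide, "A450", grid, NoiseModel(0.0, 0))
    return trace


@pytest.fixture(scope="session")
def halide_free_timecourse(grid):
    params, init = presets.halide_free_oxidation()
    return hk.simulate_scheme(params, init, None, grid)
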