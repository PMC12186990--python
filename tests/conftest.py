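"""Shared fixtures.

The heavy session fixture ``model_analysis`` evaluates one shared
scrambled-Sobol ensemble (N = 1024, 38 design points per row, 30 cycles
per solve) over the union of every discrete and continuous measurement,
and exposes per-set analyses; it is only built when a test requests it.
"""

import numpy as np
import pytest

import cvsloppy as cv
from cvsloppy.design_sweep import (analyse_design, build_shared_ensemble)

ANALYSIS_SEED = 0
ANALYSIS_N = 1024


@pytest.fixture(scope="session")
def base_params():
    return cv.table1()


@pytest.fixture(scope="session")
def steady_trajectory(base_params):
    """One default 30-cycle solve of the baseline parameterisation."""
    traj = cv.simulate(base_params, cv.SimulationConfig())
    assert traj.ok
    return traj


class ModelAnalysis:
    """Lazy per-set analysis on top of the shared ensemble."""

    def __init__(self, ensemble, superset):
        self.ensemble = ensemble
        self.superset = superset
        self._cache = {}

    def result(self, mode, set_id):
        key = (mode, set_id)
        if key not in self._cache:
            design = cv.get_design(mode, set_id)
            self._cache[key] = analyse_design(self.ensemble, design,
                                              self.superset)
        return self._cache[key]


@pytest.fixture(scope="session")
def model_analysis():
    designs = (cv.design_library("discrete") + cv.design_library("continuous")
               + [cv.get_design("mixed", "3D")])
    space = cv.build_parameter_space(cv.table1(), 0.5)
    seeds = np.random.SeedSequence(ANALYSIS_SEED).generate_state(2)
    sobol = cv.sobol_matrices(space, ANALYSIS_N, int(seeds[0]) % 2 ** 31)
    rng = np.random.default_rng(int(seeds[1]) % 2 ** 31)
    ensemble, superset = build_shared_ensemble(
        designs, sobol, cv.SimulationConfig(), rng)
    return ModelAnalysis(ensemble, superset)
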