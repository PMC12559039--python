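"""Shared fixtures: the acquisition schedule, a ground-truth arterial input,
and reconstructed (sampled) input curves, built once per session."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from petkinfit.plasma_input import (InputFunction, correct_plasma,
                                    fit_parent_fraction)
from petkinfit.synthetic_data import (SyntheticInputConfig,
                                      acquisition_schedule,
                                      ground_truth_input, simulate_input)


@pytest.fixture(scope="session")
def schedule():
    return acquisition_schedule()


@pytest.fixture(scope="session")
def input_config():
    return SyntheticInputConfig()


@pytest.fixture(scope="session")
def cp_true(input_config):
    """Dense ground-truth metabolite-corrected input (the generator's Cp)."""
    return ground_truth_input(input_config)


@pytest.fixture(scope="session")
def blood_true(input_config, cp_true):
    """Dense ground-truth total-plasma curve (vascular term)."""
    return InputFunction(cp_true.knot_time, input_config.feng(cp_true.knot_time))


@pytest.fixture(scope="session")
def sampled_curves(input_config):
    """(corrected input, total plasma) reconstructed from the 29 serial
    samples the way the analysis side would: parent-fraction fit on the five
    assay points, correction at the sample times."""
    plasma = simulate_input(input_config)
    pf = fit_parent_fraction(plasma.parent_fraction_time, plasma.parent_fraction)
    cp = correct_plasma(plasma, pf.model)
    total = InputFunction(plasma.sample_time, plasma.total_activity)
    return cp, total
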