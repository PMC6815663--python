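import numpy as np
import pytest

import erpdecon as ed
from erpdecon.formula import ModelSpec
from erpdecon.timeexpand import TemporalBasis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_intercept_fit(preset_name, seed, basis=None, tol=1e-10):
    """Simulate a preset and fit the intercept-only deconvolution model."""
    scenario = ed.preset(preset_name)
    data, events, truth = ed.simulate(scenario, seed=seed)
    spec = ModelSpec(
        "y ~ 1", window=(0.0, 0.6), basis=basis or TemporalBasis("stick")
    )
    design = ed.build_design(events, spec)
    window = ed.local_window(0.0, 0.6, scenario.srate)
    onsets = ed.onsets_to_samples(events["onset"], scenario.srate)
    expanded = ed.time_expand(
        design, onsets, window, spec.basis, data.shape[1], "stim", scenario.srate
    )
    fit = ed.fit_lsmr(expanded, data, tol=tol)
    return scenario, data, events, truth, expanded, fit


@pytest.fixture
def boxcar_fit():
    return build_intercept_fit("fig10_boxcar", seed=1)
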