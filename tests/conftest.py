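"""Shared fixtures: small cortical workbenches reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from sefmap.evoked import average_epochs, baseline_correct, estimate_noise_scale
from sefmap.geometry import build_cortex_model
from sefmap.inverse import make_inverse
from sefmap.simulate import build_workbench, simulate_patient


@pytest.fixture(scope="session")
def wb3():
    """Ico-3 workbench: 1,284 sources, full 306-channel array + lead field."""
    return build_workbench(subdivisions=3, seed=0)


@pytest.fixture(scope="session")
def model2():
    """Ico-2 cortical model (no lead field): cheap geometry oracle target."""
    return build_cortex_model(subdivisions=2, seed=0)


@pytest.fixture(scope="session")
def noiseless_patient(wb3):
    """One noiseless simulated patient on ico-3 with its evoked and inverse."""
    epochs, truth = simulate_patient(wb3, "UL", snr=np.inf, n_epochs=10, seed=7)
    evoked = average_epochs(baseline_correct(epochs))
    inv = make_inverse(wb3.leadfield, estimate_noise_scale(evoked))
    return epochs, truth, evoked, inv
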