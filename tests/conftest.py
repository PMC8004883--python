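"""Shared fixtures.

Expensive Bayesian-optimization runs are session-scoped and lazily computed so
unit tests stay fast; everything is generated programmatically from the
synthetic ground-truth world (no data files).
"""

from __future__ import annotations

import numpy as np
import pytest

from psprmap import calibration as cal
from psprmap import synthetic as syn


@pytest.fixture(scope="session")
def default_chip() -> syn.GroundTruthChip:
    return syn.GroundTruthChip()


@pytest.fixture(scope="session")
def noiseless_calibration(default_chip) -> cal.CalibrationSet:
    return syn.make_calibration(default_chip)


@pytest.fixture(scope="session")
def truth_model(default_chip, noiseless_calibration):
    """Meta-model built at the chip's true parameters (no optimization)."""
    return cal._trial_model(
        np.array(
            [
                default_chip.incident_angle,
                default_chip.au_thickness,
                default_chip.probe_thickness,
                default_chip.probe_ri,
            ]
        ),
        noiseless_calibration,
        None,
        301,
        0.1,
    )


@pytest.fixture(scope="session")
def bo_result_seed0(noiseless_calibration) -> cal.OptimizationResult:
    """The 150-iteration seeded calibration run on the default chip."""
    return cal.optimize(noiseless_calibration, n_iter=150, seed=0)


@pytest.fixture(scope="session")
def chip_family_results():
    """Separately calibrated 44/46/48 nm chips (noiseless five-point sets)."""
    out = {}
    for au in (44.0, 46.0, 48.0):
        chip = syn.GroundTruthChip(au_thickness=au)
        out[au] = (chip, cal.optimize(syn.make_calibration(chip), n_iter=150, seed=0))
    return out


@pytest.fixture(scope="session")
def roi_pair_results(default_chip):
    """The 1.2 nm / 0.05 deg ROI pair, each ROI calibrated on its own."""
    out = []
    for chip in syn.make_roi_pair(default_chip):
        out.append((chip, cal.optimize(syn.make_calibration(chip), n_iter=150, seed=0)))
    return out
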