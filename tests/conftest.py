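"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from smadtrace import synth, tracking
from smadtrace.kinetics import PRESETS, PerturbationSchedule
from smadtrace.synth import ImagingParams, PopulationParams


def short_pulse_map(duration: float = 3.0):
    """Responder models whose schedule fits inside very short test movies."""
    p = PRESETS["dynGFP"]
    pulse = PerturbationSchedule.pulse(0.0, duration)
    return {
        "early": (p, pulse),
        "late": (p, pulse),
        "non": (p, PerturbationSchedule.unstimulated()),
    }


@pytest.fixture(scope="session")
def small_noisy_scene():
    """30 cells, 256 px field, 40 noisy frames: enough structure for
    detection/tracking tests at a few seconds' cost."""
    pp = PopulationParams(
        n_cells=30, field_width=256, field_height=256, n_frames=40, seed=5,
        onset_early_mean=30.0, onset_early_sd=10.0,
        onset_late_mean=70.0, onset_late_sd=10.0,
    )
    # boosted reporter gain so 40 frames carry usable GFP signal
    ip = ImagingParams(photons_per_unit=0.1)
    cells = synth.simulate_population(pp, short_pulse_map(60.0))
    stack = synth.render_frames(cells, pp, ip, noise=True)
    return pp, ip, cells, stack


@pytest.fixture(scope="session")
def small_noisy_detections(small_noisy_scene):
    pp, ip, cells, stack = small_noisy_scene
    dets = [
        tracking.detect_nuclei(stack[k, 0].astype(float), 50, 5, frame=k)
        for k in range(pp.n_frames)
    ]
    return pp, ip, cells, stack, dets


@pytest.fixture(scope="session")
def sparse_noiseless_scene():
    """8 static, well-separated cells rendered without noise: the renderer
    acts as an exact oracle for detection and trace extraction."""
    pp = PopulationParams(
        n_cells=8,
        frac_early=1.0,
        frac_late=0.0,
        frac_non=0.0,
        field_width=200,
        field_height=200,
        motion_sd=0.0,
        n_frames=50,
        onset_early_mean=60.0,
        onset_early_sd=10.0,
        seed=3,
    )
    ip = ImagingParams()
    cells = synth.simulate_population(pp, short_pulse_map(45.0))
    # place cells on a grid at integer coordinates, >= 8 sigma apart
    coords = [(40.0, 40.0), (120.0, 40.0), (40.0, 120.0), (120.0, 120.0),
              (80.0, 80.0), (160.0, 80.0), (80.0, 160.0), (160.0, 160.0)]
    for c, (x, y) in zip(cells, coords):
        c.positions[:] = (x, y)
        c.nucleus_sigma = 3.0
    stack = synth.render_frames(cells, pp, ip, noise=False)
    return pp, ip, cells, stack
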