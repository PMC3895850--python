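import dataclasses

import numpy as np
import pytest

import densewall as dw


def circle_points(n, radius, center=(0.0, 0.0)):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


@pytest.fixture
def identity_spec():
    return dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.0))


@pytest.fixture
def uniform_spec():
    """Uniform 6% expansion — the magnitude scale of healthy aortic stretch."""
    return dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.06))


@pytest.fixture
def asymmetric_spec():
    """Anterior-peaked stretch pattern s(theta) = 1.05 + 0.03 cos(theta)."""
    return dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.05, ((0.03, 0.0),)))


def run_stretch_pipeline(spec, n_points=100, pieces=5, exclusion_fraction=0.3):
    """Phantom -> phase processing -> tracking -> quadrant summary."""
    acq, truth, delin = dw.make_phantom(spec, exclusion_fraction=exclusion_fraction)
    field = dw.process_acquisition(acq, delin.mask)
    seeds = dw.seed_points(delin.mid, n_points)
    tracked = dw.track_points(seeds, field)
    profile = dw.stretch_profile(tracked, pieces=pieces, center=delin.center)
    return dw.quadrant_summary(profile), profile, truth, tracked


def replace(spec, **kwargs):
    return dataclasses.replace(spec, **kwargs)
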