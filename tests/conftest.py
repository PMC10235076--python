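import math

import numpy as np
import pytest

from telogel.calibration import BUILTIN_LADDERS, build_scale, refine_peaks
from telogel.synthetic import MigrationModel, NoiseSpec, SmearSpec, simulate_ladder_lane


@pytest.fixture
def model():
    """Exactly log2-linear migration (no curvature)."""
    return MigrationModel(r0=40.0, stretch=130.0, curvature=0.0, lmax_kb=64.0)


@pytest.fixture
def curved_model():
    """Compressed high-MW region: motivates the two-segment scale."""
    return MigrationModel(r0=40.0, stretch=110.0, curvature=8.0, lmax_kb=64.0)


@pytest.fixture
def quickload():
    return BUILTIN_LADDERS["quickload-1kb-extend"]


@pytest.fixture
def smartladder():
    return BUILTIN_LADDERS["smartladder"]


@pytest.fixture
def exact_scale(model, quickload):
    """Piecewise scale built from a noiseless ladder lane under `model`."""
    profile, seeds = simulate_ladder_lane(quickload, model, NoiseSpec(seed=0))
    return build_scale(refine_peaks(profile, seeds), quickload)


def lognormal_smear(median_kb=5.0, sigma=0.3, **kw):
    return SmearSpec(mu=math.log(median_kb), sigma=sigma, **kw)
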