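import numpy as np
import pytest

from displaceq import (
    PRESETS,
    NoiseModel,
    PlateSet,
    QuadraticBindingModel,
    Well,
)


@pytest.fixture
def quench_model():
    """Strongly quenched probe binding model used across fitting tests."""
    return QuadraticBindingModel(f0=1000.0, fb=200.0, kd=2.0, probe_total=100.0)


@pytest.fixture
def mir504_condition():
    return PRESETS["mir504"]


@pytest.fixture
def no_noise():
    return NoiseModel(cv=0.0)


def build_plate(plate_id="p1", baseline=(200.0, 202.0), neomycin=(400.0, 402.0),
                compounds=None, probe_only=()):
    """Assemble a small PlateSet from control and compound signal tuples."""
    wells = []
    positions = iter(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))
    for s in probe_only:
        wells.append(Well(plate_id, next(positions), "probe_only", s))
    for s in baseline:
        wells.append(Well(plate_id, next(positions), "negative", s))
    for s in neomycin:
        wells.append(Well(plate_id, next(positions), "positive", s, "Neomycin"))
    for name, signals in (compounds or {}).items():
        for s in signals:
            wells.append(Well(plate_id, next(positions), "compound", s, name))
    return PlateSet(wells=wells)


@pytest.fixture
def toy_plate():
    return build_plate(compounds={"NeoRS": (350.0, 360.0)})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
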