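import numpy as np
import pytest

import mitopotential as mp
from mitopotential.segmentation import LabelMap


@pytest.fixture(scope="session")
def monolayer_set():
    """20-cell monolayer time-lapse with default kinetics (f_o=1.3, f_f=0.4)."""
    return mp.generate_monolayer_timelapse(n_cells=20, seed=5)


@pytest.fixture(scope="session")
def aggregation_set():
    return mp.generate_aggregation_field(
        {"single": 5, "grouped": 3, "aggregate": 2, "spheroid": 1}, seed=0)


@pytest.fixture(scope="session")
def fiber_set():
    return mp.generate_fiber_stack(n_fibers=3, n_debris=5, seed=3)


@pytest.fixture(scope="session")
def fiber_candidates(fiber_set):
    """Detected candidates + the flattened brightfield they were scored on."""
    from mitopotential.fibers import (basic_flatfield, sliding_parabola,
                                      detect_fiber_candidates)
    pset, gt = fiber_set
    stack = pset.stack("B02", 0, "brightfield", 0)
    candidates = detect_fiber_candidates(stack)
    flat = np.max([sliding_parabola(basic_flatfield(p)) for p in stack], axis=0)
    return candidates, flat


@pytest.fixture
def disc_label():
    """A single filled disc (radius 15) with uniform intensity 500."""
    rr, cc = np.mgrid[0:64, 0:64]
    mask = ((rr - 32) ** 2 + (cc - 32) ** 2) <= 15 ** 2
    img = np.where(mask, 500.0, 0.0)
    return LabelMap(mask.astype(np.int32), 1), img
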