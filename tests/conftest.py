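"""Shared fixtures: small transducers, cached simulated frames.

Frame-level fixtures are session-scoped because RF simulation is the
costly step; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from qusnac.phantom import (
    PhantomSpec,
    Rect,
    Region,
    TransducerSpec,
    make_reference_phantom_spec,
    make_tumour_phantom,
    core_mask_for_phantom,
)
from qusnac.rfsim import simulate_rf_frame


@pytest.fixture(scope="session")
def transducer() -> TransducerSpec:
    """Clinical-geometry probe with a 4 cm axial depth (the emulated scanner images 4-6 cm)."""
    return TransducerSpec(axial_extent=0.04)


@pytest.fixture(scope="session")
def small_transducer() -> TransducerSpec:
    """Reduced-lateral-extent probe for fast unit tests."""
    return TransducerSpec(n_lines=128, lateral_extent=0.015, axial_extent=0.03)


def uniform_phantom(
    t: TransducerSpec,
    alpha: float,
    density: float = 1.0e8,
    radius: float = 40e-6,
    radius_sd: float = 3e-6,
    contrast: float = 1.0,
) -> PhantomSpec:
    return PhantomSpec(
        "uniform",
        (
            Region(
                "body",
                Rect(0.0, t.lateral_extent, 0.0, t.axial_extent),
                density=density,
                radius_mean=radius,
                radius_sd=radius_sd,
                contrast=contrast,
            ),
        ),
        attenuation=alpha,
    )


@pytest.fixture(scope="session")
def reference_frames(transducer):
    ref = make_reference_phantom_spec(transducer)
    return [simulate_rf_frame(ref, transducer, seed=900 + s) for s in range(2)]


@pytest.fixture(scope="session")
def nr_patient(transducer):
    phantom, core = make_tumour_phantom("NR", 1, transducer=transducer)
    frame = simulate_rf_frame(phantom, transducer, seed=11)
    return frame, core_mask_for_phantom(core, transducer), phantom


@pytest.fixture(scope="session")
def r_patient(transducer):
    phantom, core = make_tumour_phantom("R", 1, transducer=transducer)
    frame = simulate_rf_frame(phantom, transducer, seed=12)
    return frame, core_mask_for_phantom(core, transducer), phantom
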