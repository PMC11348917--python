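"""Shared fixtures: small, seeded synthetic sessions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from geniculate.protocol import StimulusProtocol
from geniculate.synth.gratings import GratingSimConfig, TuningSpec, gen_grating_session
from geniculate.synth.retina import PhantomCell, RetinaPhantomConfig, gen_retina_stack


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    """Standard grating protocol at 5 trials with shuffled presentation order."""
    return StimulusProtocol(n_trials=5, order_seed=4)


@pytest.fixture(scope="session")
def six_kind_session(protocol):
    """One low-noise session containing every ground-truth tuning kind."""
    specs = (
        TuningSpec("DS", 90.0, concentration=2),
        TuningSpec("OS", 45.0, concentration=2),
        TuningSpec("DS_neg", 180.0, concentration=2),
        TuningSpec("OS_neg", 0.0, concentration=2),
        TuningSpec("SbC"),
        TuningSpec("broad"),
    )
    cfg = GratingSimConfig(
        tuning_specs=specs, protocol=protocol, frame_rate=4.0, noise_sd=0.03, seed=11
    )
    movie, roi_truth, tuning_truth = gen_grating_session(cfg)
    return cfg, movie, roi_truth, tuning_truth


@pytest.fixture(scope="session")
def curved_retina_phantom():
    """Curved-band phantom with one cell per canonical stratification pattern."""
    cells = (
        PhantomCell((14, 14), (3, 7), cofasciculating=True),      # type 37
        PhantomCell((14, 40), (7,), cofasciculating=True),        # type 7
        PhantomCell((40, 14), (1, 2)),                            # type 12
        PhantomCell((40, 40), (1, 2), asymmetric=True),           # type 12_asym
        PhantomCell((64, 14), (4,)),                              # type 4
        PhantomCell((64, 40), (8, 9)),                            # type 89
        PhantomCell((64, 64), (1, 2, 8, 9)),                      # type 189
    )
    cfg = RetinaPhantomConfig(
        xy_size=80, z_size=48, curvature_amp=3.0, cells=cells, noise_sd=0.02, seed=5
    )
    stack, surfaces, cells_truth = gen_retina_stack(cfg)
    return cfg, stack, surfaces, cells_truth
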