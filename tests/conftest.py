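"""Shared fixtures: small synthetic scenes and frames rendered at test time."""
import numpy as np
import pytest

from ffakit.synthetic_fundus import KineticParams, build_scene, render_frame


@pytest.fixture(scope="session")
def scene():
    """One 256-px eye anatomy shared across tests (read-only)."""
    return build_scene(seed=3, size=256)


@pytest.fixture(scope="session")
def kinetics():
    return KineticParams()


@pytest.fixture(scope="session")
def peak_frame(scene, kinetics):
    """Motion-free frame at the vascular peak (30 s)."""
    frame, _ = render_frame(30.0, scene, kinetics, rng=np.random.default_rng(1))
    return frame
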