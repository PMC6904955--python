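"""Shared fixtures: small phantoms and series used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from prostate_qmri.phantom import PhantomGeometry, build_phantom


@pytest.fixture(scope="session")
def flat_phantom():
    """Piecewise-constant phantom (no within-region variation, no texture)."""
    return build_phantom(within_roi_variation=0.0, s0_texture=0.0)


@pytest.fixture(scope="session")
def textured_phantom():
    """Phantom with smooth within-region variation and S0 texture, seeded."""
    rng = np.random.default_rng(11)
    return build_phantom(within_roi_variation=0.05, rng=rng)


@pytest.fixture(scope="session")
def small_geometry():
    """A reduced phantom grid for fast simulation-heavy tests."""
    return PhantomGeometry(
        shape=(72, 72, 48),
        spacing=(1.5, 1.5, 1.5),
        prostate_semiaxes=(23.0, 20.0, 20.0),
        body_semiaxes=(48.0, 44.0, 34.0),
        bladder_center=(0.0, -25.0, 18.0),
    )
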