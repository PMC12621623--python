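"""Shared fixtures.  Heavy objects (spatula networks, meshes) are built once
per session; tests must treat them as read-only."""

from __future__ import annotations

import numpy as np
import pytest

from setascale.geometry import build_skeleton, generate_mesh, mini_params
from setascale.spatula import build_spatula, build_substrate


@pytest.fixture(scope="session")
def mini_spatula():
    return build_spatula(preset="mini", rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_substrate():
    return build_substrate(extent=(-80.0, 80.0, -80.0, 80.0),
                           rng=np.random.default_rng(12))


@pytest.fixture(scope="session")
def mini_mesh():
    geom = mini_params()
    return generate_mesh(build_skeleton(geom), mesh_density=geom.mesh_density), geom
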