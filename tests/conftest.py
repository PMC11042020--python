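"""Shared fixtures: meshes, FEM contexts, and the canonical protocol.

Session scope keeps the expensive objects (factorizations, meshes) shared
across test modules; everything is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from eit3d.fem import CEMParams, ConductivityField, FEMContext
from eit3d.geometry import CylinderSpec, build_cylinder_mesh
from eit3d.protocol import build_protocol


@pytest.fixture(scope="session")
def protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def cem():
    return CEMParams()


@pytest.fixture(scope="session")
def mesh_default(cem):
    """~1,000-element electrode-conforming mesh with the default 10-degree pads."""
    return build_cylinder_mesh(CylinderSpec(), refinement=1)


@pytest.fixture(scope="session")
def ctx_default(mesh_default, cem):
    return FEMContext(mesh_default, cem)


@pytest.fixture(scope="session")
def mesh_fine():
    """Default ~3,000-element mesh; resolves interior inclusions radially."""
    return build_cylinder_mesh(CylinderSpec(), refinement=2)


@pytest.fixture(scope="session")
def mesh_coarse(cem):
    """240-element mesh (full-sector electrodes) for finite-difference oracles."""
    spec = CylinderSpec(electrode_angular_width=22.5, electrode_height=2.0)
    return build_cylinder_mesh(spec, refinement=1)


@pytest.fixture(scope="session")
def ctx_coarse(mesh_coarse, cem):
    return FEMContext(mesh_coarse, cem)


@pytest.fixture(scope="session")
def homog_default(mesh_default):
    return ConductivityField.from_uS_per_cm(mesh_default, 350.0)


@pytest.fixture(scope="session")
def frame_default(ctx_default, homog_default, protocol):
    from eit3d.protocol import extract_frame

    pattern, scheme = protocol
    return extract_frame(ctx_default.solve(homog_default, pattern), scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
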