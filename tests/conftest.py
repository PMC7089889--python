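"""Shared fixtures: coarse desk-scale meshes and one solved baseline case.

Heavy objects (meshes, factorised solves) are session-scoped; tests must
not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from boneplug import fe
from boneplug.geometry import AssemblySpec, SliceSpec, build_assembly_mesh
from boneplug.loads import lc2, equivalent_face_loads
from boneplug.materials import default_cards


@pytest.fixture(scope="session")
def coarse_spec() -> AssemblySpec:
    """Desk-scale discretisation of the default assembly."""
    return AssemblySpec(element_edge_length=0.004, n_sectors=16)


@pytest.fixture(scope="session")
def sliced_mesh(coarse_spec):
    return build_assembly_mesh(coarse_spec, slices=SliceSpec())


@pytest.fixture(scope="session")
def materials():
    return default_cards()


@pytest.fixture(scope="session")
def solved_lc2(sliced_mesh, materials):
    """Baseline LC2 solve on the coarse sliced mesh: returns
    (mesh, load vector, displacement, tensors, sed field)."""
    system = fe.assemble(sliced_mesh, materials)
    f = equivalent_face_loads(lc2(), sliced_mesh)
    u = fe.solve(system, f)
    tensors = fe.strain_stress(sliced_mesh, materials, u, elem_C=system.elem_C)
    sed_field = fe.sed(tensors)
    return sliced_mesh, f, u, tensors, sed_field


@pytest.fixture(scope="session")
def uniform_composite():
    """Untapered flush four-part composite cylinder for transformed-section
    oracles (thin outer wall so the section matches the three-part oracle
    closely)."""
    spec = AssemblySpec(stem_length=0.12, residual_length=0.12,
                        stem_diameter_distal=0.012, stem_diameter_proximal=0.012,
                        cement_taper_rule="uniform", cement_thickness_distal=0.001,
                        outer_bone_wall_thickness=0.0002,
                        element_edge_length=0.003, n_sectors=16)
    return build_assembly_mesh(spec)
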