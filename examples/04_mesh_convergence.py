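"""Richardson mesh-convergence study on a virtual gauge strain.

Solves the assembly at normalised element edge lengths 2, 1 and 0.5
(self-similar refinements of a 5 mm base mesh), extrapolates the gauge
strain to zero mesh size, and reports the observed order and the relative
discretisation error at the base level.
"""

from boneplug import (AssemblySpec, assemble, build_assembly_mesh,
                      default_cards, equivalent_face_loads, lc2, refine,
                      richardson, solve, strain_stress, virtual_gauge)
from boneplug.fe import GaugeSite

base = build_assembly_mesh(AssemblySpec(element_edge_length=0.005))
materials = default_cards()
site = GaugeSite(0.06, 0.0, 0.001, "conv")

values = []
for factor in (2.0, 1.0, 0.5):
    mesh = refine(base, factor)
    system = assemble(mesh, materials)
    u = solve(system, equivalent_face_loads(lc2(), mesh))
    tensors = strain_stress(mesh, materials, u, elem_C=system.elem_C)
    reading = virtual_gauge(mesh, tensors, site)
    values.append(reading)
    print(f"normalised edge length {factor:>3}: {mesh.n_elements:6d} elements, "
          f"gauge strain {reading:9.2f} microstrain")

result = richardson(tuple(values))
print(f"\nobserved order p = {result.observed_order:.2f}")
print(f"extrapolated strain = {result.extrapolated:.2f} microstrain")
print(f"relative error at the finest level = {result.relative_error:.3%}")
print("A relative error below 1% means the base discretisation is inside "
      "the accepted convergence band.")
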