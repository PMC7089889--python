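"""Linear-elastic finite-element core on the assembly mesh.

Small-strain, fully bonded (shared-node) composite; 8-node hexahedra with
full 2x2x2 Gauss integration; direct sparse factorisation.  Produces
displacement, strain, stress and strain-energy-density fields and emulates
the in vitro instrumentation (uniaxial surface strain gauges, full-field
displacement spans).

Voigt order throughout: (xx, yy, zz, yz, xz, xy) with engineering shear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _hex
from .geometry import AssemblyMesh, PART_ID
from .materials import MaterialCard, stiffness_matrix, cylindrical_basis

__all__ = [
    "FESystem",
    "DisplacementField",
    "TensorField",
    "SEDField",
    "GaugeSite",
    "assemble",
    "solve",
    "strain_stress",
    "sed",
    "virtual_gauge",
    "nodal_axial_strain",
    "displacement_span",
]

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


@dataclass
class FESystem:
    """Assembled (unconstrained) stiffness matrix and per-element data."""

    mesh: AssemblyMesh
    K: sp.csr_matrix            # (3 nn, 3 nn), symmetric
    elem_C: np.ndarray          # (ne, 6, 6) global-frame constitutive matrices

    @property
    def ndof(self) -> int:
        return self.K.shape[0]


@dataclass
class DisplacementField:
    """Solved nodal displacements (m) with reactions on the fixed set."""

    u: np.ndarray               # (nn, 3)
    reactions: np.ndarray       # (nn, 3), nonzero only on fixed nodes
    fixed_nodes: np.ndarray
    residual: float             # ||K u - f|| / ||f|| on free dofs

    @property
    def flat(self) -> np.ndarray:
        return self.u.ravel()


@dataclass
class TensorField:
    """Per-element strain and stress: Gauss-point values plus
    volume-averaged element tensors (Voigt, engineering shear)."""

    strain_gp: np.ndarray       # (ne, 8, 6)
    stress_gp: np.ndarray       # (ne, 8, 6)
    weights_gp: np.ndarray      # (ne, 8) det J * w  (partial volumes)
    strain: np.ndarray          # (ne, 6) volume-averaged
    stress: np.ndarray          # (ne, 6)
    strain_corner: np.ndarray   # (ne, 8, 6) strains evaluated at corner nodes


@dataclass
class SEDField:
    """Per-element strain energy density (J m^-3) and element volume (m^3)."""

    U: np.ndarray
    volume: np.ndarray

    @property
    def total_energy(self) -> float:
        return float(self.U @ self.volume)


@dataclass(frozen=True)
class GaugeSite:
    """Uniaxial surface strain gauge: measures mean axial (YY) strain over a
    square footprint of side ``gauge_length`` centred on the outer bone
    surface at (axial_position, angle_deg)."""

    axial_position: float
    angle_deg: float
    gauge_length: float = 0.001
    label: str = ""


def _rotated_bone_matrices(C_local: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Vectorised cylindrical->global Voigt rotation for many azimuths."""
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = C_local[a, b]
    Q = np.stack([cylindrical_basis(t) for t in np.atleast_1d(thetas)])
    Tg = np.einsum("nip,pqrs->niqrs", Q, T)
    Tg = np.einsum("njq,niqrs->nijrs", Q, Tg)
    Tg = np.einsum("nkr,nijrs->nijks", Q, Tg)
    Tg = np.einsum("nls,nijks->nijkl", Q, Tg)
    out = np.empty((len(Q), 6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            out[:, a, b] = Tg[:, i, j, k, l]
    return 0.5 * (out + out.transpose(0, 2, 1))


def element_constitutive(mesh: AssemblyMesh,
                         materials: dict[str, MaterialCard]) -> np.ndarray:
    """(ne, 6, 6) global-frame constitutive matrix per element."""
    missing = [p for p in PART_ID if p not in materials]
    if missing:
        raise ValueError(f"missing material card(s) for part(s): {missing}")
    ne = mesh.n_elements
    C = np.empty((ne, 6, 6))
    theta = mesh.centroid_cylindrical()[:, 1]
    for name, pid in PART_ID.items():
        card = materials[name]
        sel = mesh.part == pid
        if not np.any(sel):
            continue
        if card.frame == "cylindrical" and card.kind == "orthotropic":
            C[sel] = _rotated_bone_matrices(stiffness_matrix(card), theta[sel])
        else:
            C[sel] = stiffness_matrix(card)
    return C


def _b_matrices(coords: np.ndarray, pt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """B matrices (ne, 6, 24) and det J (ne,) at one natural point."""
    dN = _hex.shape_gradients(pt)                     # (8, 3)
    J = np.einsum("nai,aj->nij", coords, dN)
    det = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    g = np.einsum("aj,nji->nai", dN, Jinv)            # dN/dx (ne, 8, 3)
    ne = coords.shape[0]
    B = np.zeros((ne, 6, 24))
    B[:, 0, 0::3] = g[:, :, 0]
    B[:, 1, 1::3] = g[:, :, 1]
    B[:, 2, 2::3] = g[:, :, 2]
    B[:, 3, 1::3] = g[:, :, 2]
    B[:, 3, 2::3] = g[:, :, 1]
    B[:, 4, 0::3] = g[:, :, 2]
    B[:, 4, 2::3] = g[:, :, 0]
    B[:, 5, 0::3] = g[:, :, 1]
    B[:, 5, 1::3] = g[:, :, 0]
    return B, det


def assemble(mesh: AssemblyMesh, materials: dict[str, MaterialCard]) -> FESystem:
    """Assemble the global stiffness matrix (symmetric, unconstrained)."""
    C = element_constitutive(mesh, materials)
    coords = mesh.element_coords()
    ne = mesh.n_elements
    pts, w = _hex.gauss_points_2x2x2()
    Ke = np.zeros((ne, 24, 24))
    for g, pt in enumerate(pts):
        B, det = _b_matrices(coords, pt)
        Ke += w[g] * np.einsum("n,nia,nij,njb->nab", det, B, C, B, optimize=True)
    dofs = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()
    return FESystem(mesh=mesh, K=K, elem_C=C)


def solve(system: FESystem, loads: np.ndarray,
          fixed_nodes: np.ndarray | None = None) -> DisplacementField:
    """Solve K u = f with homogeneous constraints on ``fixed_nodes``
    (default: the mesh's ``distal_fixed_face`` set).

    Verifies the residual (<= 1e-8 relative) and that reactions balance the
    applied resultant.
    """
    mesh = system.mesh
    if fixed_nodes is None:
        fixed_nodes = mesh.node_sets["distal_fixed_face"]
    fixed_nodes = np.asarray(fixed_nodes)
    f = np.asarray(loads, dtype=float).reshape(-1)
    if f.shape[0] != system.ndof:
        raise ValueError("load vector size does not match system")

    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.ones(system.ndof, dtype=bool)
    free[fixed_dofs] = False
    Kff = system.K[free][:, free].tocsc()
    ff = f[free]

    if np.allclose(ff, 0.0):
        u_free = np.zeros_like(ff)
        residual = 0.0
    else:
        try:
            lu = spla.splu(Kff)
            u_free = lu.solve(ff)
        except RuntimeError as exc:
            raise RuntimeError(
                f"sparse factorisation failed (under-constrained or singular "
                f"model): {exc}") from exc
        if not np.all(np.isfinite(u_free)):
            raise RuntimeError("solver produced non-finite displacements "
                               "(model not positive definite after constraints)")
        residual = float(np.linalg.norm(Kff @ u_free - ff) / np.linalg.norm(ff))
        if residual > 1e-8:
            raise RuntimeError(f"solver residual {residual:.3e} exceeds 1e-8")

    u = np.zeros(system.ndof)
    u[free] = u_free
    r_full = system.K @ u - f
    reactions = np.zeros(system.ndof)
    reactions[fixed_dofs] = r_full[fixed_dofs]

    applied = f.reshape(-1, 3).sum(axis=0)
    reacted = reactions.reshape(-1, 3).sum(axis=0)
    # rigid-body null space of K makes the total internal force vanish, so
    # the fixed-set reactions must balance the applied resultant exactly
    scale = max(np.linalg.norm(applied), 1.0)
    if np.linalg.norm(reacted + applied) > 1e-8 * scale and np.linalg.norm(applied) > 0:
        raise RuntimeError("reactions do not balance applied loads: "
                           f"|R + F| = {np.linalg.norm(reacted + applied):.3e}")
    return DisplacementField(u=u.reshape(-1, 3), reactions=reactions.reshape(-1, 3),
                             fixed_nodes=fixed_nodes, residual=residual)


def strain_stress(mesh: AssemblyMesh, materials: dict[str, MaterialCard],
                  u: DisplacementField | np.ndarray,
                  elem_C: np.ndarray | None = None) -> TensorField:
    """Strains and stresses at Gauss points plus volume-averaged element
    tensors, from a solved displacement field."""
    if isinstance(u, DisplacementField):
        u = u.u
    uvec = np.asarray(u, dtype=float).reshape(-1)
    if elem_C is None:
        elem_C = element_constitutive(mesh, materials)
    coords = mesh.element_coords()
    ne = mesh.n_elements
    dofs = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(ne, 24)
    ue = uvec[dofs]
    pts, w = _hex.gauss_points_2x2x2()
    eps = np.empty((ne, 8, 6))
    wgt = np.empty((ne, 8))
    for g, pt in enumerate(pts):
        B, det = _b_matrices(coords, pt)
        eps[:, g, :] = np.einsum("nia,na->ni", B, ue)
        wgt[:, g] = w[g] * det
    # corner-evaluated strains for unbiased nodal recovery on surfaces
    eps_c = np.empty((ne, 8, 6))
    for c, pt in enumerate(_hex._XI):
        B, _ = _b_matrices(coords, pt)
        eps_c[:, c, :] = np.einsum("nia,na->ni", B, ue)
    sig = np.einsum("nij,ngj->ngi", elem_C, eps)
    vol = wgt.sum(axis=1)
    eps_avg = np.einsum("ng,ngi->ni", wgt, eps) / vol[:, None]
    sig_avg = np.einsum("ng,ngi->ni", wgt, sig) / vol[:, None]
    return TensorField(strain_gp=eps, stress_gp=sig, weights_gp=wgt,
                       strain=eps_avg, stress=sig_avg, strain_corner=eps_c)


def sed(tensors: TensorField) -> SEDField:
    """Strain energy density U = 1/2 sigma : epsilon per Gauss point,
    volume-averaged per element (J m^-3).

    With engineering shear strain the Voigt dot product equals the full
    tensor contraction, so total energy Sum U V matches the external work
    1/2 f.u exactly.
    """
    U_gp = 0.5 * np.einsum("ngi,ngi->ng", tensors.stress_gp, tensors.strain_gp)
    scale = max(float(np.abs(U_gp).max()), 1.0)
    if U_gp.min() < -1e-12 * scale:
        raise ValueError("negative strain energy density: inconsistent "
                         "constitutive data")
    vol = tensors.weights_gp.sum(axis=1)
    U = np.einsum("ng,ng->n", tensors.weights_gp, np.maximum(U_gp, 0.0)) / vol
    return SEDField(U=U, volume=vol)


def nodal_axial_strain(mesh: AssemblyMesh, tensors: TensorField) -> np.ndarray:
    """Axial (YY) strain recovered at nodes: each element's strain is
    evaluated at its corner nodes and averaged over the elements sharing
    the node (standard nodal-averaged recovery; unbiased at surfaces)."""
    acc = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(acc, mesh.elems.ravel(), tensors.strain_corner[:, :, 1].ravel())
    np.add.at(cnt, mesh.elems.ravel(), 1.0)
    cnt[cnt == 0] = 1.0
    return acc / cnt


def virtual_gauge(mesh: AssemblyMesh, tensors: TensorField,
                  site: GaugeSite) -> float:
    """Virtual uniaxial strain gauge reading in microstrain.

    Mean nodal axial strain over outer-surface nodes inside the gauge
    footprint: |y - y0| <= L/2 and arc distance r |dtheta| <= L/2.
    """
    surf = mesh.node_sets["outer_surface"]
    X = mesh.nodes[surf]
    y = X[:, 1]
    theta = np.arctan2(X[:, 2], X[:, 0])
    r = np.hypot(X[:, 0], X[:, 2])
    half = 0.5 * site.gauge_length
    dth = np.angle(np.exp(1j * (theta - np.deg2rad(site.angle_deg))))
    inside = (np.abs(y - site.axial_position) <= half + 1e-12) & \
             (np.abs(r * dth) <= half + 1e-12)
    if not np.any(inside):
        raise ValueError(
            f"empty gauge footprint at y={site.axial_position} m, "
            f"theta={site.angle_deg} deg (gauge length {site.gauge_length} m)")
    eyy = nodal_axial_strain(mesh, tensors)[surf]
    return float(eyy[inside].mean() * 1e6)


def displacement_span(u: DisplacementField | np.ndarray, axis: int,
                      region: np.ndarray, ci: float = 0.95) -> float:
    """Displacement span (m): central ``ci`` inter-percentile range of one
    displacement component over the nodes in ``region`` (outlier-robust
    range, as used for full-field displacement comparison)."""
    if isinstance(u, DisplacementField):
        u = u.u
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region for displacement span")
    if not 0 < ci <= 1:
        raise ValueError("ci must be in (0, 1]")
    vals = np.asarray(u)[region, axis]
    lo = 100.0 * (1.0 - ci) / 2.0
    return float(np.percentile(vals, 100.0 - lo) - np.percentile(vals, lo))
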