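"""Load cases: body-weight scaling, limb-orientation transform, and
statically equivalent nodal load distribution.

Global frame: X lateral (+), Y proximal (+), Z anterior (+).  The axial
body-weight load is decomposed onto the global axes by per-component
direction cosines of the limb orientation (adduction tilts the axis
laterally, flexion anteriorly); anteversion does not enter the axial-force
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AssemblyMesh

__all__ = [
    "Orientation",
    "LoadCase",
    "bodyweight_load",
    "transform_axial_load",
    "lc1",
    "lc2",
    "equivalent_face_loads",
    "DONOR_MASS_KG",
    "STANDARD_GRAVITY",
    "IN_VITRO_ORIENTATION",
]

#: donor body mass (kg) and the gravitational acceleration used to convert
#: it to the 1.0 BW load of 842.8 N
DONOR_MASS_KG = 86.0
STANDARD_GRAVITY = 9.8

#: femoral orientation on the load test bed (degrees)
IN_VITRO_ORIENTATION_ANGLES = (6.9, 2.0, 12.7)


@dataclass(frozen=True)
class Orientation:
    """Limb orientation in degrees: adduction, flexion, anteversion."""

    adduction: float = 0.0
    flexion: float = 0.0
    anteversion: float = 0.0

    def __post_init__(self) -> None:
        for a in (self.adduction, self.flexion, self.anteversion):
            if not abs(a) <= 90.0:
                raise ValueError("orientation angles must satisfy |angle| <= 90 deg")


IN_VITRO_ORIENTATION = Orientation(*IN_VITRO_ORIENTATION_ANGLES)


@dataclass(frozen=True)
class LoadCase:
    """Global force components (N) applied on a named node set, offset by a
    lever arm (m) from the face centroid (the femoral-head offset)."""

    FX: float
    FY: float
    FZ: float
    application: str = "proximal_load_face"
    lever_arm: tuple[float, float, float] = (-0.04, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.FX, self.FY, self.FZ])):
            raise ValueError("force components must be finite")

    @property
    def force(self) -> np.ndarray:
        return np.array([self.FX, self.FY, self.FZ])

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.force))

    def scaled(self, alpha: float) -> "LoadCase":
        return LoadCase(alpha * self.FX, alpha * self.FY, alpha * self.FZ,
                        self.application, self.lever_arm, self.name)


def bodyweight_load(mass: float, g: float = STANDARD_GRAVITY) -> float:
    """Axial load (N) equal to ``mass`` kg under gravity ``g``; 1.0 BW for
    the 86 kg donor is 842.8 N."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass * g


def transform_axial_load(F: float, orient: Orientation) -> tuple[float, float, float]:
    """Decompose an axial (gravity-line) load of magnitude ``F`` onto the
    global axes for a limb tilted by ``orient``.

    FX = F sin(add) cos(flex); FY = -F cos(add) cos(flex);
    FZ = -F cos(add) sin(flex).  The anteversion angle spins the femur about
    its own axis and leaves the axial-force decomposition unchanged.
    """
    if F < 0:
        raise ValueError("load magnitude must be non-negative")
    add = np.deg2rad(orient.adduction)
    flex = np.deg2rad(orient.flexion)
    FX = F * np.sin(add) * np.cos(flex)
    FY = -F * np.cos(add) * np.cos(flex)
    FZ = -F * np.cos(add) * np.sin(flex)
    return float(FX), float(FY), float(FZ)


def lc1(bw_multiple: float = 1.0,
        lever_arm: tuple[float, float, float] = (-0.04, 0.0, 0.0)) -> LoadCase:
    """Validation load case: the 842.8 N (1.0 BW) axial load decomposed for
    the in vitro limb orientation, scalable in BW multiples."""
    F = bw_multiple * bodyweight_load(DONOR_MASS_KG, STANDARD_GRAVITY)
    FX, FY, FZ = transform_axial_load(F, IN_VITRO_ORIENTATION)
    return LoadCase(FX, FY, FZ, lever_arm=lever_arm, name="lc1")


def lc2(lever_arm: tuple[float, float, float] = (-0.04, 0.0, 0.0)) -> LoadCase:
    """Early-stance load case with intact musculoskeletal hip joint contact
    (fixed published components; medially directed FX)."""
    return LoadCase(-804.05, -1957.53, -141.95, lever_arm=lever_arm, name="lc2")


def equivalent_face_loads(lc: LoadCase, mesh: AssemblyMesh) -> np.ndarray:
    """Nodal force vector (nn, 3) statically equivalent to the load case.

    The forces on the application node set are the minimum-norm distribution
    whose resultant force equals (FX, FY, FZ) and whose resultant moment
    about the face centroid equals lever_arm x force.
    """
    try:
        ids = mesh.node_sets[lc.application]
    except KeyError:
        raise ValueError(f"mesh has no node set {lc.application!r}") from None
    if len(ids) == 0:
        raise ValueError(f"application node set {lc.application!r} is empty")
    X = mesh.nodes[ids]
    centroid = X.mean(axis=0)
    r = X - centroid
    n = len(ids)

    F = lc.force
    M = np.cross(np.asarray(lc.lever_arm, dtype=float), F)
    b = np.concatenate([F, M])

    # equilibrium matrix A (6 x 3n): rows = resultant force, resultant moment
    A = np.zeros((6, 3 * n))
    for k in range(3):
        A[k, k::3] = 1.0
    # moment rows: (r x f)_i
    A[3, 1::3] = -r[:, 2]
    A[3, 2::3] = r[:, 1]
    A[4, 0::3] = r[:, 2]
    A[4, 2::3] = -r[:, 0]
    A[5, 0::3] = -r[:, 1]
    A[5, 1::3] = r[:, 0]

    G = A @ A.T
    if np.linalg.cond(G) > 1e12:
        raise ValueError("singular load distribution: application face nodes "
                         "are (nearly) collinear")
    lam = np.linalg.solve(G, b)
    f_face = (A.T @ lam).reshape(n, 3)

    f = np.zeros_like(mesh.nodes)
    f[ids] = f_face
    return f
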