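"""Elastic material cards and constitutive matrices.

The assembly combines three materials: an isotropic titanium-alloy stem,
isotropic PMMA bone cement, and orthotropic cortical bone whose principal
axes follow the cylindrical frame of the diaphysis (local X = radial,
Y = axial, Z = circumferential).  Constitutive matrices use Voigt notation
with engineering shear strain, component order
(xx, yy, zz, yz, xz, xy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialCard",
    "PowerLawCard",
    "stiffness_matrix",
    "rotate_to_global",
    "density_modulus",
    "default_cards",
    "STEM_MODULI_SWEEP",
]

# Voigt index pairs for order (xx, yy, zz, yz, xz, xy)
_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


@dataclass(frozen=True)
class MaterialCard:
    """Elasticity constants for one part of the assembly.

    For ``kind="isotropic"`` only ``E`` and ``nu`` are used.  For
    ``kind="orthotropic"`` the nine engineering constants are given in the
    material frame; ``frame="cylindrical"`` means local X = radial,
    Y = axial, Z = circumferential, and the matrix must be rotated to the
    global frame per element (see :func:`rotate_to_global`).

    Units: moduli in Pa, density in g cm^-3.
    """

    kind: str = "isotropic"
    E: float | None = None
    nu: float | None = None
    EX: float | None = None
    EY: float | None = None
    EZ: float | None = None
    nuXY: float | None = None
    nuYZ: float | None = None
    nuXZ: float | None = None
    GXY: float | None = None
    GYZ: float | None = None
    GXZ: float | None = None
    frame: str = "global"
    density: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "orthotropic"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.frame not in ("global", "cylindrical"):
            raise ValueError(f"unknown material frame {self.frame!r}")
        if self.kind == "isotropic":
            if self.E is None or self.nu is None:
                raise ValueError("isotropic card requires E and nu")
            if self.E <= 0:
                raise ValueError("Young's modulus must be positive")
            if not -1.0 < self.nu < 0.5:
                raise ValueError("isotropic Poisson ratio must lie in (-1, 0.5)")
        else:
            for attr in ("EX", "EY", "EZ", "GXY", "GYZ", "GXZ"):
                v = getattr(self, attr)
                if v is None or v <= 0:
                    raise ValueError(f"orthotropic card requires {attr} > 0")
            for attr in ("nuXY", "nuYZ", "nuXZ"):
                if getattr(self, attr) is None:
                    raise ValueError(f"orthotropic card requires {attr}")

    def with_modulus(self, E: float) -> "MaterialCard":
        """Return a copy of an isotropic card with a different Young's modulus."""
        if self.kind != "isotropic":
            raise ValueError("with_modulus only applies to isotropic cards")
        return MaterialCard(kind="isotropic", E=E, nu=self.nu, frame=self.frame,
                            density=self.density, name=self.name)


@dataclass(frozen=True)
class PowerLawCard:
    """Density-to-modulus power law E = a * rho**b.

    ``a`` carries units Pa (g cm^-3)^-b; ``b`` is dimensionless.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("power-law constants a, b must be positive")


def _isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2.0 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _orthotropic_compliance(card: MaterialCard) -> np.ndarray:
    EX, EY, EZ = card.EX, card.EY, card.EZ
    # conjugate Poisson ratios from compliance symmetry nu_ji = nu_ij * Ej / Ei
    S = np.zeros((6, 6))
    S[0, 0], S[1, 1], S[2, 2] = 1.0 / EX, 1.0 / EY, 1.0 / EZ
    S[0, 1] = S[1, 0] = -card.nuXY / EX
    S[0, 2] = S[2, 0] = -card.nuXZ / EX
    S[1, 2] = S[2, 1] = -card.nuYZ / EY
    S[3, 3] = 1.0 / card.GYZ
    S[4, 4] = 1.0 / card.GXZ
    S[5, 5] = 1.0 / card.GXY
    return S


def stiffness_matrix(card: MaterialCard) -> np.ndarray:
    """6x6 constitutive (stiffness) matrix in Voigt notation, material frame.

    Raises ``ValueError`` naming the offending eigenvalue if the constants
    are not physically admissible (stiffness not positive definite).
    """
    if card.kind == "isotropic":
        C = _isotropic_stiffness(card.E, card.nu)
    else:
        S = _orthotropic_compliance(card)
        C = np.linalg.inv(S)
    C = 0.5 * (C + C.T)
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= 0:
        raise ValueError(
            f"inadmissible elastic constants: stiffness eigenvalue {eig[0]:.4g} <= 0"
        )
    return C


def _voigt_rotation(Q: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness matrix by basis matrix Q (columns = local axes
    in global coordinates) via the full 4th-order tensor transform."""
    # Voigt -> full tensor (engineering shear handled by symmetric storage)
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = C[a, b]
    Tg = np.einsum("ip,jq,kr,ls,pqrs->ijkl", Q, Q, Q, Q, T)
    Cg = np.empty((6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            Cg[a, b] = Tg[i, j, k, l]
    return 0.5 * (Cg + Cg.T)


def cylindrical_basis(theta: float) -> np.ndarray:
    """Columns = (radial, axial, circumferential) unit vectors in the global
    frame (X lateral, Y proximal, Z anterior) at azimuth ``theta`` measured
    from +X towards +Z in the X-Z plane."""
    c, s = np.cos(theta), np.sin(theta)
    r_hat = np.array([c, 0.0, s])
    y_hat = np.array([0.0, 1.0, 0.0])
    t_hat = np.array([-s, 0.0, c])
    return np.column_stack([r_hat, y_hat, t_hat])


def rotate_to_global(card: MaterialCard, centroid_angle: float) -> np.ndarray:
    """Constitutive matrix in the global frame for an element whose centroid
    sits at azimuth ``centroid_angle`` (radians).

    A card already expressed in the global frame is returned unrotated with a
    warning; an isotropic card is rotation invariant so the fast path skips
    the tensor transform.
    """
    C = stiffness_matrix(card)
    if card.frame == "global":
        warnings.warn("rotate_to_global called on a global-frame card; no-op",
                      stacklevel=2)
        return C
    if card.kind == "isotropic":
        return C
    return _voigt_rotation(cylindrical_basis(centroid_angle), C)


def density_modulus(rho: float, law: PowerLawCard) -> float:
    """Young's modulus (Pa) from apparent density (g cm^-3): E = a rho^b."""
    if rho <= 0:
        raise ValueError("density must be positive")
    return law.a * rho ** law.b


# Baseline material cards of the modelled assembly: Ti6Al4V stem, PMMA
# cement, and the idealised orthotropic cortical bone used for both the
# periprosthetic bone layer and the outer bone wall.
def default_cards(stem_modulus: float = 115e9) -> dict[str, MaterialCard]:
    bone = MaterialCard(
        kind="orthotropic",
        EX=12.00e9, EY=20.00e9, EZ=13.40e9,
        nuXY=0.22, nuYZ=0.35, nuXZ=0.38,
        GXY=5.61e9, GYZ=6.23e9, GXZ=4.53e9,
        frame="cylindrical", density=1.8, name="cortical_bone",
    )
    return {
        "stem": MaterialCard(E=stem_modulus, nu=0.30, name="stem"),
        "cement": MaterialCard(E=2.00e9, nu=0.40, name="cement"),
        "bone_layer": bone,
        "outer_bone": bone,
    }


#: stem Young's moduli of the stiffness sweep: flexible porous-tantalum
#: surrogate, Ti6Al4V baseline, CoCr surrogate (Pa)
STEM_MODULI_SWEEP = (20e9, 115e9, 210e9)
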