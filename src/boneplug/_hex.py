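"""Trilinear 8-node hexahedron shape functions and Gauss quadrature.

Shared by the mesh generator (volumes, centroids, Jacobian checks) and the
finite-element core (stiffness integration, strain recovery).  Node order
follows the VTK_HEXAHEDRON convention: nodes 0-3 on the bottom face, 4-7
vertically above them.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the 8 corner nodes
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def gauss_points_2x2x2() -> tuple[np.ndarray, np.ndarray]:
    """Full 2x2x2 Gauss rule: (8, 3) points and (8,) unit weights."""
    g = 1.0 / np.sqrt(3.0)
    pts = _XI * g
    return pts, np.ones(8)


def shape_functions(pt: np.ndarray) -> np.ndarray:
    """Shape-function values N_i at one natural point, shape (8,)."""
    xi, eta, zeta = pt
    return 0.125 * (1 + _XI[:, 0] * xi) * (1 + _XI[:, 1] * eta) * (1 + _XI[:, 2] * zeta)


def shape_gradients(pt: np.ndarray) -> np.ndarray:
    """dN_i/d(xi, eta, zeta) at one natural point, shape (8, 3)."""
    xi, eta, zeta = pt
    d = np.empty((8, 3))
    d[:, 0] = 0.125 * _XI[:, 0] * (1 + _XI[:, 1] * eta) * (1 + _XI[:, 2] * zeta)
    d[:, 1] = 0.125 * _XI[:, 1] * (1 + _XI[:, 0] * xi) * (1 + _XI[:, 2] * zeta)
    d[:, 2] = 0.125 * _XI[:, 2] * (1 + _XI[:, 0] * xi) * (1 + _XI[:, 1] * eta)
    return d


def jacobian_dets(coords: np.ndarray) -> np.ndarray:
    """Jacobian determinant at every Gauss point for a batch of elements.

    ``coords``: (ne, 8, 3) corner coordinates.  Returns (ne, 8).
    """
    pts, _ = gauss_points_2x2x2()
    ne = coords.shape[0]
    dets = np.empty((ne, len(pts)))
    for g, pt in enumerate(pts):
        dN = shape_gradients(pt)                      # (8, 3)
        J = np.einsum("nai,aj->nij", coords, dN)      # dx_i/dxi_j
        dets[:, g] = np.linalg.det(J)
    return dets


def volumes(coords: np.ndarray) -> np.ndarray:
    """Exact volumes of trilinear hexes, shape (ne,)."""
    return jacobian_dets(coords).sum(axis=1)


def centroids(coords: np.ndarray) -> np.ndarray:
    """Volume centroids approximated by the mean of Gauss-point positions
    weighted by det J (exact for the trilinear map)."""
    pts, _ = gauss_points_2x2x2()
    ne = coords.shape[0]
    num = np.zeros((ne, 3))
    den = np.zeros(ne)
    for g, pt in enumerate(pts):
        N = shape_functions(pt)
        dN = shape_gradients(pt)
        J = np.einsum("nai,aj->nij", coords, dN)
        det = np.linalg.det(J)
        x = np.einsum("a,nai->ni", N, coords)
        num += x * det[:, None]
        den += det
    return num / den[:, None]
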