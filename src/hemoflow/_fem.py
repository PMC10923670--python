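"""Reference-element machinery for the mixed P2/P1 (Taylor-Hood-type) triangle.

Velocity and extra-stress components live on all six nodes of a quadratic
triangle; pressure lives on the three corner nodes.  Elements are
straight-sided, so the geometric map is affine and every element shares the
reference-element shape values below.

Node ordering on the reference triangle (vertices v0=(0,0), v1=(1,0),
v2=(0,1)): corners 0,1,2 then midsides 3=(v0+v1)/2, 4=(v1+v2)/2,
5=(v2+v0)/2.
"""

from __future__ import annotations

import numpy as np

# 7-point, degree-5 quadrature on the reference triangle (area 1/2).
_A1 = 0.0597158717897698
_B1 = 0.4701420641051151
_A2 = 0.7974269853530873
_B2 = 0.1012865073234563
QUAD_POINTS = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0],
        [_A1, _B1],
        [_B1, _A1],
        [_B1, _B1],
        [_A2, _B2],
        [_B2, _A2],
        [_B2, _B2],
    ]
)
QUAD_WEIGHTS = 0.5 * np.array(
    [
        0.225,
        0.1323941527885062,
        0.1323941527885062,
        0.1323941527885062,
        0.1259391805448271,
        0.1259391805448271,
        0.1259391805448271,
    ]
)


def p2_basis(xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Quadratic basis values, shape (6, npts)."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    l0 = 1.0 - xi - eta
    return np.array(
        [
            l0 * (2 * l0 - 1),
            xi * (2 * xi - 1),
            eta * (2 * eta - 1),
            4 * l0 * xi,
            4 * xi * eta,
            4 * eta * l0,
        ]
    )


def p2_grad(xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Reference gradients of the quadratic basis, shape (6, 2, npts)."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    l0 = 1.0 - xi - eta
    z = np.zeros_like(xi)
    d = np.empty((6, 2) + xi.shape)
    d[0, 0] = 1 - 4 * l0
    d[0, 1] = 1 - 4 * l0
    d[1, 0] = 4 * xi - 1
    d[1, 1] = z
    d[2, 0] = z
    d[2, 1] = 4 * eta - 1
    d[3, 0] = 4 * (l0 - xi)
    d[3, 1] = -4 * xi
    d[4, 0] = 4 * eta
    d[4, 1] = 4 * xi
    d[5, 0] = -4 * eta
    d[5, 1] = 4 * (l0 - eta)
    return d


def p1_basis(xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Linear (corner) basis values, shape (3, npts)."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return np.array([1.0 - xi - eta, xi, eta])


P1_GRAD = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (3, 2), constant

# Shape tables at the quadrature points (used by every assembly loop).
QP_N2 = p2_basis(QUAD_POINTS[:, 0], QUAD_POINTS[:, 1])          # (6, nq)
QP_DN2 = p2_grad(QUAD_POINTS[:, 0], QUAD_POINTS[:, 1])          # (6, 2, nq)
QP_H = p1_basis(QUAD_POINTS[:, 0], QUAD_POINTS[:, 1])           # (3, nq)
NQ = QUAD_POINTS.shape[0]


def element_geometry(coords: np.ndarray, tris: np.ndarray):
    """Affine geometry factors for straight-sided six-node triangles.

    Parameters
    ----------
    coords : (n_nodes, 2) node coordinates
    tris : (n_el, 6) connectivity

    Returns
    -------
    detJ : (n_el,) Jacobian determinants (twice the element area)
    inv_jt : (n_el, 2, 2) inverse-transpose Jacobians
    """
    p0 = coords[tris[:, 0]]
    p1 = coords[tris[:, 1]]
    p2 = coords[tris[:, 2]]
    j11 = p1[:, 0] - p0[:, 0]
    j12 = p2[:, 0] - p0[:, 0]
    j21 = p1[:, 1] - p0[:, 1]
    j22 = p2[:, 1] - p0[:, 1]
    detj = j11 * j22 - j12 * j21
    inv_jt = np.empty((tris.shape[0], 2, 2))
    inv_jt[:, 0, 0] = j22 / detj
    inv_jt[:, 0, 1] = -j21 / detj
    inv_jt[:, 1, 0] = -j12 / detj
    inv_jt[:, 1, 1] = j11 / detj
    return detj, inv_jt


def physical_gradients(inv_jt: np.ndarray):
    """Physical-space shape gradients at the quadrature points.

    Returns
    -------
    dn2 : (n_el, 6, 2, nq) quadratic-basis gradients
    dh : (n_el, 3, 2) linear-basis gradients (constant per element)
    """
    # dN_phys[e, a, i, q] = inv_jt[e, i, k] * QP_DN2[a, k, q]
    dn2 = np.einsum("eik,akq->eaiq", inv_jt, QP_DN2)
    dh = np.einsum("eik,ak->eai", inv_jt, P1_GRAD)
    return dn2, dh
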